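"""Hydrogen-bond counting, radial distribution functions, distance series.

All pair distances are evaluated under the minimum-image convention for
orthorhombic periodic cells.  The hydrogen-bond criterion is geometric:
donor-acceptor distance d(X, Y) <= 3.5 Å and angle <= 30°, where the angle
is taken at the donor heavy atom between the X-H bond and the X->Y
direction (the Y-X-H angle).  An alternative reading that places the cone
at the hydrogen (X-H...Y) is available via ``angle_at='hydrogen'``.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .traj_io import Frame, Trajectory, minimum_image

__all__ = [
    "HBondCriteria",
    "RDFResult",
    "DistanceSeries",
    "count_hbonds",
    "hbond_series",
    "rdf",
    "distance_series",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criterion: d(X,Y) <= d_max (Å) and donor angle <= ang_max (deg)."""

    d_max: float = 3.5
    ang_max: float = 30.0
    angle_at: str = "donor"  # 'donor' (Y-X-H) or 'hydrogen' (X-H...Y cone)

    def __post_init__(self) -> None:
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if not 0.0 <= self.ang_max <= 180.0:
            raise ValueError("ang_max must lie in [0, 180] degrees")
        if self.angle_at not in ("donor", "hydrogen"):
            raise ValueError("angle_at must be 'donor' or 'hydrogen'")


@dataclass
class RDFResult:
    """Binned g(r): bin centers (Å), g values, pair count and pair density."""

    r_centers: np.ndarray
    g: np.ndarray
    n_pairs: int
    density: float  # pairs per Å^3


@dataclass
class DistanceSeries:
    """Per-frame minimum-image distance (Å) with a threshold event count."""

    time: np.ndarray  # ps
    d: np.ndarray
    threshold: float
    below_events: int

    def window_stats(self, t_lo: float, t_hi: float) -> tuple[float, float]:
        """Mean and standard deviation of d over the ps window [t_lo, t_hi]."""
        sel = (self.time >= t_lo) & (self.time <= t_hi)
        if not sel.any():
            raise ValueError("empty time window")
        return float(np.mean(self.d[sel])), float(np.std(self.d[sel]))


def _angle_deg(v1: np.ndarray, v2: np.ndarray) -> float:
    c = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def count_hbonds(
    frame: Frame,
    donors,
    acceptors,
    crit: HBondCriteria = HBondCriteria(),
) -> int:
    """Count hydrogen bonds in one frame.

    ``donors`` is a sequence of (X, H) index pairs with H covalently bound
    to its heavy atom X (topology is the caller's responsibility and is not
    recomputed per frame); ``acceptors`` is a set of heavy-atom indices Y.
    Y = X triples are skipped with a warning.
    """
    acceptors = list(acceptors)
    cell = frame.cell
    count = 0
    warned = False
    for x, h in donors:
        rx, rh = frame.coords[x], frame.coords[h]
        xh = minimum_image(rh - rx, cell)
        for y in acceptors:
            if y == x:
                if not warned:
                    warnings.warn("acceptor equals donor heavy atom; skipped")
                    warned = True
                continue
            xy = minimum_image(frame.coords[y] - rx, cell)
            d = float(np.linalg.norm(xy))
            if d > crit.d_max:
                continue
            if crit.angle_at == "donor":
                ang = _angle_deg(xh, xy)
            else:
                hy = minimum_image(frame.coords[y] - rh, cell)
                ang = _angle_deg(xh, hy)
            if ang <= crit.ang_max:
                count += 1
    return count


def hbond_series(
    traj: Trajectory | list[Frame],
    donors,
    acceptors,
    crit: HBondCriteria = HBondCriteria(),
) -> np.ndarray:
    """Hydrogen-bond count per frame (constant topology across the run)."""
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    donors = list(donors)
    return np.array([count_hbonds(f, donors, acceptors, crit) for f in frames])


def rdf(
    traj: Trajectory | list[Frame],
    set_a,
    set_b,
    dr: float,
    r_max: float,
) -> RDFResult:
    """Radial distribution function between two atom selections.

    g(r) is the observed minimum-image pair-distance density divided by the
    ideal-gas expectation at the same pair density, so a uniform random
    sample gives g = 1.  When the selections overlap, each unordered pair
    is counted once and self-pairs are excluded.  Normalization uses the
    instantaneous cell volume per frame (constant for NVT runs, but the
    contract holds generally).  Requires r_max <= min(cell)/2.
    """
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    if dr <= 0:
        raise ValueError("dr must be positive")
    a = np.asarray(list(set_a), dtype=int)
    b = np.asarray(list(set_b), dtype=int)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty atom selection")
    if not frames:
        raise ValueError("no frames")
    edges = np.arange(0.0, r_max + dr, dr)
    edges = edges[edges <= r_max + 1e-12]
    hist = np.zeros(edges.size - 1)
    expected = np.zeros_like(hist)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    n_pairs = 0
    same = a.size == b.size and np.array_equal(np.sort(a), np.sort(b))
    for frame in frames:
        if frame.cell is None:
            raise ValueError("rdf requires a periodic cell")
        if r_max > float(np.min(frame.cell)) / 2.0 + 1e-12:
            raise ValueError("r_max must not exceed half the smallest cell side")
        ra = frame.coords[a][:, None, :]
        rb = frame.coords[b][None, :, :]
        d = np.linalg.norm(minimum_image(rb - ra, frame.cell), axis=-1)
        if same:
            iu = np.triu_indices(a.size, k=1)
            dist = d[iu]
        else:
            mask = a[:, None] != b[None, :]
            dist = d[mask]
        n_pairs = dist.size
        hist += np.histogram(dist, bins=edges)[0]
        volume = float(np.prod(frame.cell))
        expected += n_pairs * shell_vol / volume
    g = np.divide(hist, expected, out=np.zeros_like(hist), where=expected > 0)
    centers = 0.5 * (edges[:-1] + edges[1:])
    volume = float(np.prod(frames[-1].cell))
    return RDFResult(r_centers=centers, g=g, n_pairs=n_pairs, density=n_pairs / volume)


def distance_series(
    traj: Trajectory | list[Frame],
    i: int,
    j: int,
    threshold: float = 4.5,
) -> DistanceSeries:
    """Minimum-image i-j distance per frame with below-threshold event count.

    The 4.5 Å default threshold marks molecular compaction events (e.g. the
    ammonium-to-nitro N-N distance closing under electrostatic attraction).
    """
    frames = traj.frames if isinstance(traj, Trajectory) else traj
    if i == j:
        raise ValueError("distance_series needs two distinct atoms")
    time = np.array([f.time for f in frames]) / 1000.0
    d = np.array(
        [
            float(
                np.linalg.norm(
                    minimum_image(f.coords[j] - f.coords[i], f.cell)
                )
            )
            for f in frames
        ]
    )
    return DistanceSeries(
        time=time, d=d, threshold=threshold, below_events=int(np.sum(d < threshold))
    )
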