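"""Coordination-number collective variable and the moving harmonic bias.

The collective variable is the smooth coordination number

    CN = sum_{i,j} s(r_ij),    s(r) = (1 - x^6) / (1 - x^12),  x = (r - d0)/sigma

with s = 1 for r <= d0.  The rational switching function has a removable
singularity at x = 1; algebraically (1 - x^6)/(1 - x^12) = 1/(1 + x^6), and
the latter form is used for all x > 0.

The pulling experiments drive CN with a moving harmonic restraint
U_e = (k/2) (CN - CN0(t))^2 whose target CN0(t) ramps linearly in time
(forward: 2 -> 1 over 2 ps after 1 ps of equilibration; backward: the water
O-H count 2*n_waters + 1 -> 2*n_waters at the same rate with k/100).
This module scores trajectories against that protocol; it applies no forces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .traj_io import Frame, minimum_image_distance

__all__ = [
    "SwitchingParams",
    "BiasSchedule",
    "CVSeries",
    "KCAL_TO_KJ",
    "switching_value",
    "coordination_number",
    "cn0_at",
    "bias_energy",
    "forward_schedule",
    "backward_schedule",
    "cv_series",
]

KCAL_TO_KJ = 4.184

#: forward-pull switching parameters (C-H coordination)
DEFAULT_D0 = 1.1  # Å
DEFAULT_SIGMA = 0.5  # Å
#: backward-pull offset: DFTB equilibrium O-H distance in water
BACKWARD_D0 = 0.98  # Å
#: forward-pull force constant, 1250 kcal/mol
DEFAULT_K = 1250.0 * KCAL_TO_KJ  # kJ/mol per CN^2


@dataclass(frozen=True)
class SwitchingParams:
    """Offset distance d0 and width sigma (Å) of the switching function."""

    d0: float = DEFAULT_D0
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be non-negative")


@dataclass(frozen=True)
class BiasSchedule:
    """Moving-restraint protocol: CN0 ramps cn0_start -> cn0_end over [t_start, t_end] ps.

    ``d0`` records the switching offset the schedule was designed for
    (differs between forward and backward pulls); it is bookkeeping only.
    """

    k: float  # kJ/mol per CN^2
    cn0_start: float
    cn0_end: float
    t_start: float  # ps
    t_end: float  # ps
    d0: float = DEFAULT_D0  # Å

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")


@dataclass
class CVSeries:
    """Time series of the CV: time (ps), CN(t), target CN0(t), bias energy (kJ/mol)."""

    time: np.ndarray
    cn: np.ndarray
    cn0: np.ndarray
    ue: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.cn = np.asarray(self.cn, dtype=float)
        self.cn0 = np.asarray(self.cn0, dtype=float)
        self.ue = np.asarray(self.ue, dtype=float)
        n = self.time.size
        if not (self.cn.size == self.cn0.size == self.ue.size == n):
            raise ValueError("CVSeries arrays must have equal length")
        if n and np.nanmin(self.cn) < 0:
            raise ValueError("CN must be non-negative")

    def __len__(self) -> int:
        return self.time.size


def switching_value(r, p: SwitchingParams = SwitchingParams()):
    """Smooth pair count s(r) in (0, 1]; exactly 1 for r <= d0.

    Vectorized over ``r``.  Uses the singularity-free form 1/(1 + x^6).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("pair distance must be non-negative")
    x = (r - p.d0) / p.sigma
    with np.errstate(over="ignore"):
        s = np.where(x <= 0.0, 1.0, 1.0 / (1.0 + np.where(x > 0, x, 0.0) ** 6))
    return float(s) if s.ndim == 0 else s


def coordination_number(
    frame: Frame,
    center_atoms,
    partner_atoms,
    p: SwitchingParams = SwitchingParams(),
    use_minimum_image: bool = True,
) -> float:
    """CN of ``center_atoms`` with respect to ``partner_atoms`` in one frame.

    Sums the switching function over every (center, partner) pair; pair
    distances are minimum-imaged when the frame is periodic (default on —
    whether the original protocol imaged these sub-Å pairs is immaterial for
    bonded distances but matters for the backward, whole-cell variant).
    """
    centers = np.asarray(list(center_atoms), dtype=int)
    partners = np.asarray(list(partner_atoms), dtype=int)
    if centers.size == 0 or partners.size == 0:
        raise ValueError("center and partner index sets must be non-empty")
    if np.intersect1d(centers, partners).size:
        raise ValueError("center and partner index sets must be disjoint")
    n = frame.n_atoms
    if centers.min() < 0 or centers.max() >= n or partners.min() < 0 or partners.max() >= n:
        raise IndexError("atom index out of range")
    cell = frame.cell if use_minimum_image else None
    ca = frame.coords[centers][:, None, :]  # (nc, 1, 3)
    pa = frame.coords[partners][None, :, :]  # (1, np, 3)
    d = minimum_image_distance(ca, pa, cell)
    return float(np.sum(switching_value(d, p)))


def cn0_at(t, sched: BiasSchedule):
    """Restraint target CN0 at time t (ps): clamped linear ramp."""
    t = np.asarray(t, dtype=float)
    frac = np.clip((t - sched.t_start) / (sched.t_end - sched.t_start), 0.0, 1.0)
    out = sched.cn0_start + frac * (sched.cn0_end - sched.cn0_start)
    return float(out) if out.ndim == 0 else out


def bias_energy(cn, cn0, k: float = DEFAULT_K):
    """Harmonic restraint energy U_e = (k/2)(CN - CN0)^2 in kJ/mol."""
    if k < 0:
        raise ValueError("force constant must be non-negative")
    cn = np.asarray(cn, dtype=float)
    out = 0.5 * k * (cn - np.asarray(cn0, dtype=float)) ** 2
    return float(out) if out.ndim == 0 else out


def forward_schedule(
    k: float = DEFAULT_K, t_equil: float = 1.0, rate_ps_per_cn: float = 2.0
) -> BiasSchedule:
    """The forward extraction protocol: CN0 2 -> 1 over 2 ps after 1 ps equilibration."""
    return BiasSchedule(
        k=k,
        cn0_start=2.0,
        cn0_end=1.0,
        t_start=t_equil,
        t_end=t_equil + rate_ps_per_cn,
        d0=DEFAULT_D0,
    )


def backward_schedule(n_waters: int, forward: BiasSchedule | None = None) -> BiasSchedule:
    """Protocol returning the extracted proton to the solute.

    CN counts H on all water O; the target drops from 2*n_waters + 1 (bath
    holds the extra proton) to 2*n_waters at the forward ramp rate (1 CN per
    2 ps), with the force constant reduced to 1/100 of the forward value and
    the O-H offset d0 = 0.98 Å.
    """
    if n_waters <= 0:
        raise ValueError("n_waters must be positive")
    if forward is None:
        forward = forward_schedule()
    rate = (forward.t_end - forward.t_start) / abs(forward.cn0_start - forward.cn0_end)
    return BiasSchedule(
        k=forward.k / 100.0,
        cn0_start=2.0 * n_waters + 1.0,
        cn0_end=2.0 * n_waters,
        t_start=forward.t_start,
        t_end=forward.t_start + rate * 1.0,
        d0=BACKWARD_D0,
    )


def cv_series(
    frames,
    center_atoms,
    partner_atoms,
    sched: BiasSchedule,
    p: SwitchingParams | None = None,
    times_ps=None,
) -> CVSeries:
    """Score a frame sequence against a bias schedule.

    ``times_ps`` overrides the frame timestamps (which are stored in fs).
    """
    if p is None:
        p = SwitchingParams(d0=sched.d0)
    frames = list(frames)
    if times_ps is None:
        times_ps = np.array([f.time for f in frames]) / 1000.0
    else:
        times_ps = np.asarray(times_ps, dtype=float)
    cn = np.array(
        [coordination_number(f, center_atoms, partner_atoms, p) for f in frames]
    )
    cn0 = cn0_at(times_ps, sched)
    return CVSeries(time=times_ps, cn=cn, cn0=cn0, ue=bias_energy(cn, cn0, sched.k))
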