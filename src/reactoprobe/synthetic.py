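"""Synthetic study inputs: conformer walks, water shells, mock steered ensembles.

Three generators emulate the stages of the steered-extraction protocol so the
whole analysis pipeline can be exercised with known ground truth:

* ``conformer_walk`` — a self-avoiding dihedral random walk of the solute,
  accepted by a Metropolis test at a per-step random temperature, emulating
  the preparation of 100 independent solute configurations;
* ``extract_and_level`` — carving a water shell around each conformer from a
  bulk box and leveling every sample to one common water count (the study
  conditions use 416 waters, i.e. 1268 atoms with the 20-atom solute);
* ``mock_ensemble`` — statistical mock of steered BOMD output: a slow
  ±100 K temperature oscillation around 300 K, AR(1)-correlated energy
  noise, a fs-scale CN drop from 2 to 1 at a random reaction time in
  reactive runs with a sustained product-state energy offset, exponential
  energy divergence in fault runs, and the true labels returned alongside.

All randomness flows from one integer seed through ``numpy.random
.SeedSequence`` spawning, so every sub-generator is independently
reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .classify import Label, TrajLabel
from .cv_bias import BiasSchedule, CVSeries, bias_energy, cn0_at, forward_schedule
from .fixtures import ReferenceTables, reference_tables
from .traj_io import GAS_CONSTANT_KJ, Frame, ScalarLog

__all__ = [
    "Dihedral",
    "WalkParams",
    "ShellParams",
    "MockParams",
    "MockTrajectory",
    "conformer_walk",
    "extract_and_level",
    "mock_ensemble",
    "synthetic_water_box",
    "nitroacetamide_solute",
    "reference_tables",
]

#: covalent radii (Å) for bond perception in synthetic structures
_COVALENT_RADII = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66}
#: van der Waals radii (Å) for the clash score
_VDW_RADII = {"H": 1.2, "C": 1.7, "N": 1.55, "O": 1.52}


@dataclass(frozen=True)
class Dihedral:
    """Rotatable dihedral a-b-c-d; ``rotating`` lists the atoms moved rigidly
    about the b-c axis (the d-side fragment, excluding b and c)."""

    a: int
    b: int
    c: int
    d: int
    rotating: tuple[int, ...]

    def __post_init__(self) -> None:
        if len({self.a, self.b, self.c, self.d}) != 4:
            raise ValueError("dihedral needs 4 distinct atoms")
        if self.b in self.rotating or self.c in self.rotating:
            raise ValueError(
                "rotating set contains an axis atom: the dihedral closes a cycle"
            )
        if self.d not in self.rotating:
            raise ValueError("rotating set must contain atom d")


@dataclass(frozen=True)
class WalkParams:
    """Metropolis walk settings: conformer count, temperature bounds (K) and
    the pairwise repulsive clash score sum (scale * (sigma_ij / r)^power)."""

    n_confs: int = 100
    t_min: float = 1e-3
    t_max: float = 1e4
    clash_power: int = 12
    clash_scale: float = 1.0  # kJ/mol

    def __post_init__(self) -> None:
        if self.n_confs < 1:
            raise ValueError("n_confs must be at least 1")
        if not 0 < self.t_min < self.t_max:
            raise ValueError("need 0 < t_min < t_max")


@dataclass(frozen=True)
class ShellParams:
    """Water-shell extraction: keep radius, solute exclusion, target count.

    ``target_count=None`` levels to the ensemble mean (rounded); the study
    conditions land at 416 waters with a 15 Å shell and 1.2 Å exclusion.
    """

    shell_radius: float = 15.0  # Å
    exclusion: float = 1.2  # Å
    target_count: int | None = None

    def __post_init__(self) -> None:
        if self.exclusion >= self.shell_radius:
            raise ValueError("exclusion must be smaller than shell_radius")


@dataclass(frozen=True)
class MockParams:
    """Statistical recipe for a mock steered-BOMD ensemble.

    Defaults are the study conditions: 100 trajectories of a 1268-atom cell,
    3 ps at 1 fs logging with the bias starting after 1 ps, a slow ±100 K
    temperature oscillation (about 200 K peak-to-peak) around 300 K, and a
    per-degree product offset sized so the compound-1 summary numbers
    (x_p = 0.07, dU' = -7.09) are reproduced in expectation.
    """

    n_traj: int = 100
    na: int = 1268
    p_react: float = 0.07
    p_fault: float = 0.05
    delta_per_deg: float = -0.0267  # injected per-degree U' offset in the product
    noise_sd: float = 10.0  # kJ/mol, stationary sd of the AR(1) energy noise
    noise_tau: float = 50.0  # fs, AR(1) correlation time
    cn_noise_sd: float = 0.05  # dimensionless CN jitter
    t_osc_amp: float = 100.0  # K
    t_osc_period: float = 2.0  # ps
    t_mean: float = 300.0  # K
    dt: float = 1.0  # fs
    length: float = 3.0  # ps
    t0: float = 1.0  # ps, bias start after equilibration
    react_window: tuple[float, float] = (1.5, 2.5)  # ps, reaction-time range
    cn_drop_width: float = 0.01  # ps, fs-scale CN transition
    fault_tau: float = 0.03  # ps, divergence e-folding time
    seed: int = 0

    def __post_init__(self) -> None:
        if self.p_react + self.p_fault > 1.0:
            raise ValueError("p_react + p_fault must not exceed 1")
        for name in ("noise_sd", "noise_tau", "t_osc_period", "dt", "length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def ndeg(self) -> int:
        return 3 * self.na - 6


@dataclass
class MockTrajectory:
    """One mock steered run: scalar log, CV series, and its metadata.

    Frames are not materialized (a 1268-atom, 3000-step coordinate set per
    run is irrelevant to the energy/CV pipeline the mock feeds).
    """

    log: ScalarLog
    cv: CVSeries
    na: int
    t0: float  # ps
    truth: TrajLabel


# ---------------------------------------------------------------------------
# conformer walk


def _bond_graph(frame: Frame, scale: float = 1.3) -> list[set[int]]:
    """Adjacency from covalent radii: bonded when r < scale*(r_i + r_j)."""
    n = frame.n_atoms
    radii = np.array([_COVALENT_RADII.get(s, 0.77) for s in frame.symbols])
    adj: list[set[int]] = [set() for _ in range(n)]
    d = np.linalg.norm(frame.coords[:, None, :] - frame.coords[None, :, :], axis=-1)
    cut = scale * (radii[:, None] + radii[None, :])
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] < cut[i, j]:
                adj[i].add(j)
                adj[j].add(i)
    return adj


def _graph_distances(adj: list[set[int]], max_depth: int = 3) -> np.ndarray:
    """All-pairs bond-path lengths up to max_depth (inf beyond)."""
    n = len(adj)
    dist = np.full((n, n), np.inf)
    for src in range(n):
        dist[src, src] = 0
        frontier = {src}
        for depth in range(1, max_depth + 1):
            frontier = {k for node in frontier for k in adj[node]} - {
                m for m in range(n) if dist[src, m] < depth
            }
            for m in frontier:
                dist[src, m] = min(dist[src, m], depth)
            if not frontier:
                break
    return dist


def _clash_energy(
    coords: np.ndarray, sigma_ij: np.ndarray, nonbonded: np.ndarray, params: WalkParams
) -> float:
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    with np.errstate(divide="ignore"):
        e = params.clash_scale * (sigma_ij / np.maximum(d, 1e-12)) ** params.clash_power
    return float(np.sum(e[nonbonded]) / 2.0)


def _rotate_about_axis(coords, idx, origin, axis, angle):
    axis = axis / np.linalg.norm(axis)
    c, s = math.cos(angle), math.sin(angle)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    Rm = np.eye(3) + s * K + (1 - c) * (K @ K)
    coords = coords.copy()
    coords[idx] = (coords[idx] - origin) @ Rm.T + origin
    return coords


def conformer_walk(
    solute: Frame,
    dihedrals: list[Dihedral],
    params: WalkParams = WalkParams(),
    seed: int | np.random.SeedSequence = 0,
    return_acceptance: bool = False,
):
    """Self-avoiding dihedral random walk of a solute.

    Each step rotates every rotatable dihedral by an independent uniform
    angle and accepts the move by a Metropolis test on the repulsive clash
    score at a per-step random temperature drawn log-uniformly from
    [t_min, t_max] (a uniform draw over seven decades would collapse onto
    the top decade).  The walk runs until ``n_confs`` accepted configurations
    are collected; bonded geometry is preserved exactly by construction
    (rigid rotations).  With zero dihedrals, returns n copies of the input.
    """
    rng = np.random.default_rng(seed)
    adj = _bond_graph(solute)
    gdist = _graph_distances(adj)
    nonbonded = gdist >= 3
    radii = np.array([_VDW_RADII.get(s, 1.6) for s in solute.symbols])
    sigma_ij = 0.5 * (radii[:, None] + radii[None, :])
    coords = solute.coords.copy()
    energy = _clash_energy(coords, sigma_ij, nonbonded, params)
    out: list[Frame] = []
    max_attempts = 1000 * params.n_confs
    attempts = 0
    while len(out) < params.n_confs:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("walk stalled: acceptance rate too low")
        trial = coords
        for dih in dihedrals:
            angle = rng.uniform(-math.pi, math.pi)
            axis = trial[dih.c] - trial[dih.b]
            trial = _rotate_about_axis(
                trial, list(dih.rotating), trial[dih.c], axis, angle
            )
        e_trial = _clash_energy(trial, sigma_ij, nonbonded, params)
        temp = 10.0 ** rng.uniform(math.log10(params.t_min), math.log10(params.t_max))
        de = e_trial - energy
        if de <= 0 or rng.random() < math.exp(-de / (GAS_CONSTANT_KJ * temp)):
            coords, energy = trial, e_trial
            out.append(
                Frame(list(solute.symbols), coords.copy(), cell=solute.cell, time=float(len(out)))
            )
    if return_acceptance:
        return out, len(out) / attempts
    return out


# ---------------------------------------------------------------------------
# water shells


def synthetic_water_box(
    side: float, seed: int | np.random.SeedSequence = 0, density: float = 0.976
) -> Frame:
    """A synthetic bulk water box: jittered cubic lattice of rigid waters.

    ``side`` in Å; ``density`` in g/cm^3 sets the molecule count.  This is a
    geometric stand-in for an equilibrated liquid snapshot — adequate for
    shell counting and leveling, with no claim to liquid structure.
    """
    rng = np.random.default_rng(seed)
    m_water = 18.0153
    n_target = int(round(density * (side * 1e-8) ** 3 / m_water * 6.02214076e23))
    n_side = max(1, round(n_target ** (1.0 / 3.0)))
    spacing = side / n_side
    symbols: list[str] = []
    coords: list[np.ndarray] = []
    # rigid TIP3P-like geometry: r(OH)=0.9572 Å, angle 104.52°
    r_oh, half = 0.9572, math.radians(104.52 / 2)
    for ix in range(n_side):
        for iy in range(n_side):
            for iz in range(n_side):
                o = (np.array([ix, iy, iz]) + 0.5) * spacing
                o = o + rng.normal(0.0, 0.08 * spacing, 3)
                u = rng.normal(size=3)
                u /= np.linalg.norm(u)
                v = np.cross(u, rng.normal(size=3))
                v /= np.linalg.norm(v)
                h1 = o + r_oh * (math.cos(half) * u + math.sin(half) * v)
                h2 = o + r_oh * (math.cos(half) * u - math.sin(half) * v)
                symbols += ["O", "H", "H"]
                coords += [o, h1, h2]
    return Frame(symbols, np.array(coords), cell=np.array([side] * 3))


def _water_triplets(box: Frame) -> list[tuple[int, int, int]]:
    """Index triplets (O, H, H) assuming consecutive water layout."""
    trips = []
    i = 0
    n = box.n_atoms
    while i < n:
        if box.symbols[i] != "O" or i + 2 >= n or box.symbols[i + 1] != "H" or box.symbols[i + 2] != "H":
            raise ValueError("water box must be consecutive O,H,H triplets")
        trips.append((i, i + 1, i + 2))
        i += 3
    return trips


def _extract_shell(
    solute_coords: np.ndarray, box: Frame, trips, radius: float, exclusion: float
) -> list[int]:
    """Indices of water triplets kept for one conformer at a given radius."""
    kept = []
    for t in trips:
        o = box.coords[t[0]]
        d = np.linalg.norm(solute_coords - o, axis=1)
        dmin = float(d.min())
        if dmin <= radius and dmin >= exclusion:
            kept.append(t)
    return kept


def extract_and_level(
    solute_confs: list[Frame],
    waterbox: Frame,
    params: ShellParams = ShellParams(),
    seed: int | np.random.SeedSequence = 0,
) -> list[Frame]:
    """Solvate each conformer with a leveled water shell.

    Per conformer (centered in the box), waters whose O lies within
    ``shell_radius`` of any solute atom are kept and those closer than
    ``exclusion`` to any solute atom are dropped.  Every sample is then
    leveled to one common count: the rounded ensemble mean (or
    ``target_count``), growing the keep radius by 2% steps for samples
    short of the target and randomly deleting the excess elsewhere.  All
    outputs carry identical water counts and a cubic cell of side
    2 * shell_radius.
    """
    rng = np.random.default_rng(seed)
    trips = _water_triplets(waterbox)
    center = (
        np.asarray(waterbox.cell, dtype=float) / 2.0
        if waterbox.cell is not None
        else waterbox.coords.mean(axis=0)
    )
    placed: list[np.ndarray] = []
    kept0: list[list] = []
    for conf in solute_confs:
        sc = conf.coords - conf.coords.mean(axis=0) + center
        placed.append(sc)
        kept0.append(_extract_shell(sc, waterbox, trips, params.shell_radius, params.exclusion))
    if params.target_count is None:
        target = int(round(float(np.mean([len(k) for k in kept0]))))
    else:
        target = params.target_count
    out: list[Frame] = []
    cell = np.array([2.0 * params.shell_radius] * 3)
    for conf, sc, kept in zip(solute_confs, placed, kept0):
        radius = params.shell_radius
        grow = 0
        while len(kept) < target:
            grow += 1
            if grow > 50:
                raise ValueError(
                    f"insufficient solvent: {len(kept)} waters < target {target}"
                )
            radius *= 1.02
            kept = _extract_shell(sc, waterbox, trips, radius, params.exclusion)
        if len(kept) > target:
            sel = rng.choice(len(kept), size=target, replace=False)
            kept = [kept[i] for i in sorted(sel)]
        symbols = list(conf.symbols)
        coords = [sc]
        for t in kept:
            symbols += [waterbox.symbols[k] for k in t]
            coords.append(waterbox.coords[list(t)])
        stacked = np.vstack(coords)
        # re-center the sample into its own cell (solute centroid at the middle)
        stacked = stacked + (cell / 2.0 - sc.mean(axis=0))
        out.append(Frame(symbols, stacked, cell=cell, time=conf.time))
    return out


# ---------------------------------------------------------------------------
# mock steered ensembles


def _ar1(rng: np.random.Generator, n: int, sd: float, tau_fs: float, dt_fs: float):
    rho = math.exp(-dt_fs / tau_fs)
    z = rng.normal(0.0, 1.0, n)
    x = np.empty(n)
    x[0] = sd * z[0]
    scale = sd * math.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + scale * z[i]
    return x


def mock_ensemble(
    params: MockParams = MockParams(),
) -> tuple[list[MockTrajectory], list[TrajLabel]]:
    """Generate a mock steered ensemble with known ground-truth labels.

    Per trajectory: T(t) = t_mean + t_osc_amp * sin(2 pi t / t_osc_period +
    phi) with a random phase; U(t) = N_deg R T(t)/2 plus AR(1) noise.
    Reactive runs (Bernoulli p_react) get a CN sigmoid 2 -> 1 at a reaction
    time uniform in ``react_window`` and a sustained product offset
    delta_per_deg * N_deg * R * T(t) thereafter; fault runs diverge
    exponentially from a random onset.  Returns (trajectories, truth labels).
    """
    root = np.random.SeedSequence(params.seed)
    children = root.spawn(params.n_traj)
    sched = forward_schedule(t_equil=params.t0)
    n = int(round(params.length * 1000.0 / params.dt)) + 1
    t_fs = np.arange(n) * params.dt
    t_ps = t_fs / 1000.0
    ndeg = params.ndeg
    trajs: list[MockTrajectory] = []
    truths: list[TrajLabel] = []
    for child in children:
        rng = np.random.default_rng(child)
        phi = rng.uniform(0.0, 2.0 * math.pi)
        u_cat = rng.random()
        T = params.t_mean + params.t_osc_amp * np.sin(
            2.0 * math.pi * t_ps / params.t_osc_period + phi
        )
        noise = _ar1(rng, n, params.noise_sd, params.noise_tau, params.dt)
        U = ndeg * GAS_CONSTANT_KJ * T / 2.0 + noise
        cn = 2.0 + rng.normal(0.0, params.cn_noise_sd, n)
        if u_cat < params.p_fault:
            truth = TrajLabel(Label.FAULT)
            onset = rng.uniform(params.t0, params.length - 0.3)
            grow = np.exp(np.clip((t_ps - onset) / params.fault_tau, None, 60.0))
            U = U + params.noise_sd * np.where(t_ps >= onset, grow - 1.0, 0.0)
        elif u_cat < params.p_fault + params.p_react:
            t_react = rng.uniform(*params.react_window)
            truth = TrajLabel(Label.REACTIVE, t_react=float(t_react))
            drop = 1.0 / (1.0 + np.exp(-(t_ps - t_react) / params.cn_drop_width))
            cn = cn - drop  # 2 -> 1
            U = U + params.delta_per_deg * ndeg * GAS_CONSTANT_KJ * T * drop
        else:
            truth = TrajLabel(Label.NON_REACTIVE)
        cn = np.maximum(cn, 0.0)
        cn0 = cn0_at(t_ps, sched)
        cv = CVSeries(time=t_ps, cn=cn, cn0=cn0, ue=bias_energy(cn, cn0, sched.k))
        log = ScalarLog(time=t_fs, U=U, T=T)
        trajs.append(MockTrajectory(log=log, cv=cv, na=params.na, t0=params.t0, truth=truth))
        truths.append(truth)
    return trajs, truths


# ---------------------------------------------------------------------------
# solute


def nitroacetamide_solute(seed: int = 0) -> tuple[Frame, list[Dihedral]]:
    """A 20-atom synthetic model of the aminoethyl nitroacetamide cation.

    Geometry is embedded from the connectivity (O2N-CH2-C(=O)-NH-CH2-CH2-
    NH3+) with RDKit's distance-geometry method; it is a synthetic stand-in
    adequate for dihedral walks and solvation counting, not an optimized
    structure.  Returns the frame and its rotatable dihedrals (acyclic
    single bonds between heavy atoms, hydrogens excluded as rotors).
    """
    from rdkit import Chem
    from rdkit.Chem import AllChem

    mol = Chem.MolFromSmiles("[NH3+]CCNC(=O)C[N+](=O)[O-]")
    mol = Chem.AddHs(mol)
    ps = AllChem.ETKDGv3()
    ps.randomSeed = seed
    if AllChem.EmbedMolecule(mol, ps) != 0:
        raise RuntimeError("embedding failed")
    conf = mol.GetConformer()
    symbols = [a.GetSymbol() for a in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())]
    )
    frame = Frame(symbols, coords)
    adj = [set() for _ in symbols]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        adj[i].add(j)
        adj[j].add(i)
    dihedrals: list[Dihedral] = []
    for b in mol.GetBonds():
        if b.GetBondType() != Chem.BondType.SINGLE or b.IsInRing():
            continue
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if symbols[i] == "H" or symbols[j] == "H":
            continue
        if len(adj[i]) < 2 or len(adj[j]) < 2:
            continue
        rotating = _component_from(adj, start=j, blocked=i)
        if i in rotating:
            continue  # cycle
        rotating.discard(j)
        if not rotating:
            continue
        a = min(adj[i] - {j})
        d = min(rotating & adj[j]) if rotating & adj[j] else min(rotating)
        dihedrals.append(Dihedral(a=a, b=i, c=j, d=d, rotating=tuple(sorted(rotating | {d}))))
    return frame, dihedrals


def _component_from(adj: list[set[int]], start: int, blocked: int) -> set[int]:
    """Atoms reachable from ``start`` without passing through ``blocked``."""
    seen = {blocked, start}
    stack = [start]
    while stack:
        node = stack.pop()
        for nb in adj[node]:
            if nb not in seen:
                seen.add(nb)
                stack.append(nb)
    seen.discard(blocked)
    return seen
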