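"""Trajectory, scalar-log and configuration I/O; units and periodic geometry.

Internal units are fixed package-wide: lengths in Å, times in fs (ps only in
user-facing schedule parameters, converted at the boundary), temperatures in
K, and energies in kJ per mole of simulation cells.  Engine outputs that
report per-cell energies in other units (e.g. Hartree) are converted on
ingest, so that downstream scaling by N_deg * R * T is dimensionless without
per-call unit flags.

The canonical trajectory dialect is extended XYZ: a plain XYZ block whose
comment line may carry ``Lattice="ax ay az bx by bz cx cy cz"``.  Only
orthorhombic lattices (diagonal matrix) are supported.  Plain XYZ files are
accepted when an explicit cell is supplied by the caller.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "AVOGADRO",
    "GAS_CONSTANT_KJ",
    "HARTREE_TO_KJ_PER_MOL",
    "Frame",
    "ScalarLog",
    "Trajectory",
    "TrajectoryFormatError",
    "read_xyz_trajectory",
    "write_xyz_trajectory",
    "read_scalar_log",
    "write_scalar_log",
    "load_run_config",
    "box_density",
    "minimum_image",
    "minimum_image_distance",
]

AVOGADRO = 6.02214076e23  # 1/mol
GAS_CONSTANT_KJ = 8.31446e-3  # kJ/(mol K)
HARTREE_TO_KJ_PER_MOL = 2625.4996394799  # 1 Ha per cell, as molar energy

#: accepted energy-unit declarations in scalar-log headers -> factor to kJ/mol
_ENERGY_FACTORS = {
    "kj_per_mol": 1.0,
    "kj/mol": 1.0,
    "hartree": HARTREE_TO_KJ_PER_MOL,
    "hartree_per_cell": HARTREE_TO_KJ_PER_MOL,
    "ev": 96.48533212,
    "kcal_per_mol": 4.184,
    "kcal/mol": 4.184,
    "j_per_cell": AVOGADRO / 1000.0,
}


class TrajectoryFormatError(ValueError):
    """Malformed trajectory or scalar-log file (message names the line)."""


@dataclass
class Frame:
    """One snapshot: element symbols, Cartesian Å coordinates, optional cell.

    ``cell`` holds the three orthorhombic side lengths in Å; ``None`` means
    non-periodic.  ``time`` is in fs.
    """

    symbols: list[str]
    coords: np.ndarray
    cell: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if len(self.symbols) != self.coords.shape[0]:
            raise ValueError(
                f"{len(self.symbols)} symbols for {self.coords.shape[0]} coordinates"
            )
        if self.cell is not None:
            self.cell = np.asarray(self.cell, dtype=float)
            if self.cell.shape != (3,) or not np.all(self.cell > 0):
                raise ValueError("cell must be three positive side lengths")
        if not math.isfinite(self.time):
            raise ValueError("frame time must be finite")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]


@dataclass
class ScalarLog:
    """Per-record scalars aligned with frames: time (fs), U (kJ/mol), T (K)."""

    time: np.ndarray
    U: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        self.T = np.asarray(self.T, dtype=float)
        if not (self.time.shape == self.U.shape == self.T.shape):
            raise ValueError("time, U and T must have equal lengths")
        if self.time.size > 1 and not np.all(np.diff(self.time) > 0):
            raise TrajectoryFormatError("scalar log time must be strictly increasing")
        if self.time.size and not np.all(self.T[np.isfinite(self.T)] > 0):
            raise ValueError("temperatures must be positive")

    def __len__(self) -> int:
        return self.time.size


@dataclass
class Trajectory:
    """Ordered frames plus their scalar log and run metadata.

    ``t0`` is the bias start time in ps (the paper-style steering runs use
    1 ps of unbiased equilibration before the ramp starts).
    """

    frames: list[Frame] = field(default_factory=list)
    log: ScalarLog | None = None
    compound: str = ""
    ensemble_id: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        counts = {f.n_atoms for f in self.frames}
        if len(counts) > 1:
            raise ValueError(f"inconsistent atom counts across frames: {sorted(counts)}")
        if self.log is not None and len(self.log) and self.frames:
            t0_fs = self.t0 * 1000.0
            if not (self.log.time[0] - 1e-6 <= t0_fs <= self.log.time[-1] + 1e-6):
                raise ValueError("t0 outside the logged time range")

    @property
    def n_atoms(self) -> int:
        return self.frames[0].n_atoms if self.frames else 0


_LATTICE_RE = re.compile(r'Lattice="([^"]+)"')
_TIME_RE = re.compile(r"(?:Time|time)=([-+0-9.eE]+)")


def _parse_lattice(comment: str) -> np.ndarray | None:
    m = _LATTICE_RE.search(comment)
    if m is None:
        return None
    vals = np.array([float(v) for v in m.group(1).split()], dtype=float)
    if vals.size != 9:
        raise TrajectoryFormatError("Lattice field must contain 9 numbers")
    mat = vals.reshape(3, 3)
    off = mat - np.diag(np.diag(mat))
    if np.any(np.abs(off) > 1e-8):
        raise TrajectoryFormatError("only orthorhombic (diagonal) lattices supported")
    return np.diag(mat).copy()


def read_xyz_trajectory(
    path: str | Path,
    cell: Sequence[float] | None = None,
    compound: str = "",
    ensemble_id: str = "",
    t0: float = 0.0,
    log: ScalarLog | None = None,
) -> Trajectory:
    """Read a (possibly multi-frame) XYZ / extended-XYZ file.

    An extended-XYZ ``Lattice`` entry in the comment line overrides the
    ``cell`` argument; a ``Time=`` entry (fs) sets the frame time, otherwise
    frames are stamped 0, 1, 2, ... fs in file order.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    n_expected: int | None = None
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"{path.name}:{i + 1}: expected atom count, got {lines[i]!r}"
            ) from None
        if n_expected is None:
            n_expected = n
        elif n != n_expected:
            raise TrajectoryFormatError(
                f"{path.name}:{i + 1}: atom count {n} != first frame's {n_expected}"
            )
        if i + 1 + n >= len(lines) + 1:
            raise TrajectoryFormatError(f"{path.name}:{i + 1}: truncated frame")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        frame_cell = _parse_lattice(comment)
        if frame_cell is None and cell is not None:
            frame_cell = np.asarray(cell, dtype=float)
        tm = _TIME_RE.search(comment)
        time = float(tm.group(1)) if tm else float(len(frames))
        symbols: list[str] = []
        coords = np.empty((n, 3), dtype=float)
        for k in range(n):
            lineno = i + 2 + k
            parts = lines[lineno].split()
            if len(parts) < 4:
                raise TrajectoryFormatError(
                    f"{path.name}:{lineno + 1}: expected 'symbol x y z'"
                )
            symbols.append(parts[0])
            try:
                coords[k] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError:
                raise TrajectoryFormatError(
                    f"{path.name}:{lineno + 1}: unparsable coordinates"
                ) from None
        frames.append(Frame(symbols, coords, cell=frame_cell, time=time))
        i += 2 + n
    return Trajectory(frames, log=log, compound=compound, ensemble_id=ensemble_id, t0=t0)


def write_xyz_trajectory(path: str | Path, traj: Trajectory | Sequence[Frame]) -> None:
    """Write frames as extended XYZ (Lattice written when a frame has a cell)."""
    frames = traj.frames if isinstance(traj, Trajectory) else list(traj)
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{frame.n_atoms}\n")
            fields = []
            if frame.cell is not None:
                a, b, c = frame.cell
                fields.append(
                    f'Lattice="{a:.10g} 0 0 0 {b:.10g} 0 0 0 {c:.10g}"'
                )
            fields.append('Properties=species:S:1:pos:R:3')
            fields.append(f"Time={frame.time:.10g}")
            fh.write(" ".join(fields) + "\n")
            for sym, (x, y, z) in zip(frame.symbols, frame.coords):
                fh.write(f"{sym} {x:.10f} {y:.10f} {z:.10f}\n")


def read_scalar_log(path: str | Path) -> ScalarLog:
    """Read a '#'-commented TSV scalar log with columns time_fs, U, T_K.

    A ``units=<name>`` token in the header comment declares the energy unit
    of the U column (per cell); values are converted to kJ/mol on ingest.
    Default is kJ/mol.
    """
    path = Path(path)
    factor = 1.0
    rows: list[tuple[float, float, float]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.search(r"units=(\S+)", line)
            if m:
                key = m.group(1).lower()
                if key not in _ENERGY_FACTORS:
                    raise TrajectoryFormatError(
                        f"{path.name}:{lineno}: unknown energy unit {key!r}"
                    )
                factor = _ENERGY_FACTORS[key]
            continue
        parts = line.split()
        if len(parts) < 3:
            raise TrajectoryFormatError(
                f"{path.name}:{lineno}: temperature required (columns time U T)"
            )
        try:
            rows.append((float(parts[0]), float(parts[1]), float(parts[2])))
        except ValueError:
            raise TrajectoryFormatError(
                f"{path.name}:{lineno}: unparsable scalar record"
            ) from None
    if not rows:
        raise TrajectoryFormatError(f"{path.name}: empty scalar log")
    arr = np.array(rows, dtype=float)
    if arr.shape[0] > 1 and not np.all(np.diff(arr[:, 0]) > 0):
        raise TrajectoryFormatError(f"{path.name}: non-monotone time column")
    return ScalarLog(time=arr[:, 0], U=arr[:, 1] * factor, T=arr[:, 2])


def write_scalar_log(path: str | Path, log: ScalarLog) -> None:
    """Write a scalar log in the canonical dialect (kJ/mol energies)."""
    with open(path, "w") as fh:
        fh.write("# time_fs U T_K units=kj_per_mol\n")
        for t, u, temp in zip(log.time, log.U, log.T):
            fh.write(f"{t:.6f}\t{u:.9f}\t{temp:.6f}\n")


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run config (paths, cell, t0, schedule parameters)."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise TrajectoryFormatError("run config must be a YAML mapping")
    return cfg


def box_density(n_molecules: float, side: float, molar_mass: float) -> float:
    """Density (g/cm^3) of ``n_molecules`` of molar mass g/mol in a cube of side nm.

    The paper-scale check: 9261 waters in a 6.571 nm cube gives 0.976 g/cm^3.
    """
    if n_molecules <= 0 or side <= 0 or molar_mass <= 0:
        raise ValueError("n_molecules, side and molar_mass must all be positive")
    volume_cm3 = (side * 1e-7) ** 3
    return n_molecules * molar_mass / (AVOGADRO * volume_cm3)


def minimum_image(dr: np.ndarray, cell: Sequence[float] | None) -> np.ndarray:
    """Wrap a displacement (Å) into the minimum-image cell, component-wise.

    Each component of the result lies in (-L/2, L/2].  ``cell=None`` is a
    no-op (non-periodic system).  Orthorhombic cells only.
    """
    dr = np.asarray(dr, dtype=float)
    if cell is None:
        return dr
    cell = np.asarray(cell, dtype=float)
    # ceil(x - 0.5) maps +L/2 -> +L/2 and -L/2 -> +L/2, giving (-L/2, L/2]
    return dr - cell * np.ceil(dr / cell - 0.5)


def minimum_image_distance(
    a: np.ndarray, b: np.ndarray, cell: Sequence[float] | None
) -> np.ndarray:
    """Minimum-image Euclidean distance(s) between points/arrays a and b."""
    dr = minimum_image(np.asarray(b, dtype=float) - np.asarray(a, dtype=float), cell)
    return np.linalg.norm(dr, axis=-1)
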