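"""Per-point pKa from partial neutralization and polyprotic model curves.

The partial-neutralization method reads one pKa per titration point,

    pKa = pH + log10([HA]/[A-]),

with the undissociated/salt ratio fixed by stoichiometry: after adding
n_b = c_b * v_b moles of strong base to n_0 = c_0 * v_0 moles of acid,
[HA]/[A-] = (n_0 - n_b)/n_b.  Past half-neutralization the log ratio is
negative; published tables sometimes print its magnitude only, so the
reader infers the sign from the stoichiometric position when the initial
volume v_0 is known (and back-solves v_0 from the printed ratios when it
is not).

Model curves for mono-/bi-/tri-protic acids solve the full charge balance
(ideal solutions, Kw = 1e-14) by bracketed root search in pH, including
dilution by the titrant volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "KW",
    "TitrationSeries",
    "PolyproticModel",
    "pka_point",
    "log_ratio_from_stoichiometry",
    "signed_log_ratios",
    "per_point_pka",
    "mean_pka",
    "infer_v0",
    "titration_curve",
    "ph_grid_scan",
]

KW = 1e-14  # water autoionization at 25 °C; no T correction applied


@dataclass
class TitrationSeries:
    """One titration: added base volumes (mL), pH readings, concentrations (M).

    ``log_ratio`` holds the per-point log10([HA]/[A-]) column when the data
    sheet provides one; values may be magnitudes only (see module docstring).
    ``v0`` (mL) is the initial acid volume, often unrecorded.
    """

    vb: np.ndarray
    ph: np.ndarray
    c0: float
    cb: float
    log_ratio: np.ndarray | None = None
    v0: float | None = None
    temperature: float = 25.0  # °C, bookkeeping only

    def __post_init__(self) -> None:
        self.vb = np.asarray(self.vb, dtype=float)
        self.ph = np.asarray(self.ph, dtype=float)
        if self.vb.shape != self.ph.shape:
            raise ValueError("vb and ph must have equal length")
        if self.vb.size > 1 and not np.all(np.diff(self.vb) > 0):
            raise ValueError("vb must be strictly increasing")
        if self.c0 <= 0 or self.cb <= 0:
            raise ValueError("concentrations must be positive")
        if self.log_ratio is not None:
            self.log_ratio = np.asarray(self.log_ratio, dtype=float)
            if self.log_ratio.shape != self.vb.shape:
                raise ValueError("log_ratio must align with vb")

    def __len__(self) -> int:
        return self.vb.size


@dataclass
class PolyproticModel:
    """HnA dissociation model: 1-3 ascending pKa values plus titration setup."""

    pkas: list[float]
    c0: float
    cb: float
    v0: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.pkas) <= 3:
            raise ValueError("1 to 3 pKa values supported")
        if any(b <= a for a, b in zip(self.pkas, self.pkas[1:])):
            raise ValueError("pKa values must be ascending")
        if min(self.c0, self.cb, self.v0) <= 0:
            raise ValueError("c0, cb and v0 must be positive")


def pka_point(ph: float, log_ratio: float) -> float:
    """pKa = pH + log10([HA]/[A-]) at one titration point."""
    if not (math.isfinite(ph) and math.isfinite(log_ratio)):
        raise ValueError("inputs must be finite")
    return ph + log_ratio


def log_ratio_from_stoichiometry(vb: float, series: TitrationSeries) -> float:
    """Signed log10([HA]/[A-]) from added-base stoichiometry (needs v0)."""
    if series.v0 is None:
        raise ValueError("v0 required for stoichiometric log ratio")
    n0 = series.c0 * series.v0
    nb = series.cb * vb
    if nb <= 0:
        raise ValueError("no base added: log ratio diverges")
    if nb >= n0:
        raise ValueError("past equivalence: all acid neutralized")
    return math.log10((n0 - nb) / nb)


def infer_v0(series: TitrationSeries) -> tuple[float, float]:
    """Back-solve the unrecorded initial volume from a printed ratio column.

    Minimizes the summed squared difference between |log ratio| predicted
    by stoichiometry and the printed magnitudes.  Returns (v0_mL, rms
    residual in log units).  Using magnitudes sidesteps ambiguous signs in
    the printed column.
    """
    if series.log_ratio is None:
        raise ValueError("series has no printed log-ratio column")
    target = np.abs(series.log_ratio)
    nb = series.cb * series.vb

    def loss(v0: float) -> float:
        n0 = series.c0 * v0
        with np.errstate(divide="ignore", invalid="ignore"):
            pred = np.log10(np.maximum(n0 / nb - 1.0, 1e-300))
        return float(np.sum((np.abs(pred) - target) ** 2))

    lo = nb[-1] / series.c0 * (1.0 + 1e-9)  # must stay before equivalence
    res = minimize_scalar(loss, bounds=(lo, lo * 100.0), method="bounded")
    v0 = float(res.x)
    return v0, math.sqrt(loss(v0) / len(series))


def signed_log_ratios(series: TitrationSeries) -> np.ndarray:
    """Printed log-ratio column with stoichiometrically consistent signs.

    Signed printed columns (any negative entry) are trusted as-is.  For
    magnitude-only columns the sign flips negative past half-neutralization
    (n_b > n_0/2), using the supplied v0 or one back-solved from the ratios.
    """
    if series.log_ratio is None:
        raise ValueError("series has no printed log-ratio column")
    lr = series.log_ratio
    if np.any(lr < 0):
        return lr.copy()
    v0 = series.v0 if series.v0 is not None else infer_v0(series)[0]
    n0 = series.c0 * v0
    sign = np.where(series.cb * series.vb <= n0 / 2.0, 1.0, -1.0)
    return sign * np.abs(lr)


def per_point_pka(series: TitrationSeries) -> np.ndarray:
    """Per-point pKa values: pH + signed log ratio.

    Uses the printed ratio column when present (with sign handling as in
    :func:`signed_log_ratios`), else stoichiometry (requires v0).
    """
    if series.log_ratio is not None:
        lr = signed_log_ratios(series)
    else:
        lr = np.array(
            [log_ratio_from_stoichiometry(v, series) for v in series.vb]
        )
    return series.ph + lr


def mean_pka(series: TitrationSeries) -> tuple[float, np.ndarray]:
    """Arithmetic-mean pKa over all points, plus the per-point values."""
    if len(series) < 1:
        raise ValueError("need at least one titration point")
    pts = per_point_pka(series)
    return float(np.mean(pts)), pts


def _charge_balance(ph: float, model: PolyproticModel, vb: float) -> float:
    """Charge-balance residual for HnA + strong base at given pH."""
    h = 10.0 ** (-ph)
    oh = KW / h
    vt = model.v0 + vb
    ca = model.c0 * model.v0 / vt
    cna = model.cb * vb / vt
    kas = [10.0 ** (-pk) for pk in model.pkas]
    n = len(kas)
    # species H_{n-j} A^{j-}: weight_j = h^(n-j) * prod(Ka_1..Ka_j)
    weights = []
    prod = 1.0
    for j in range(n + 1):
        if j > 0:
            prod *= kas[j - 1]
        weights.append(h ** (n - j) * prod)
    denom = sum(weights)
    mean_charge = sum(j * w for j, w in zip(range(n + 1), weights)) / denom
    return h + cna - oh - ca * mean_charge


def titration_curve(model: PolyproticModel, vb_grid) -> np.ndarray:
    """pH at each added-base volume (mL), by bracketed root search on [0, 14].

    Solves the full charge balance of the N-protic acid plus strong base
    and water autoionization, with dilution by the titrant volume included.
    """
    vb_grid = np.asarray(vb_grid, dtype=float)
    out = np.empty_like(vb_grid)
    for i, vb in enumerate(vb_grid.ravel()):
        f_lo = _charge_balance(0.0, model, vb)
        f_hi = _charge_balance(14.0, model, vb)
        if f_lo * f_hi > 0:
            raise ArithmeticError(
                f"no pH bracket at vb={vb} mL: f(0)={f_lo:.3g}, f(14)={f_hi:.3g}"
            )
        out.ravel()[i] = brentq(
            _charge_balance, 0.0, 14.0, args=(model, vb), xtol=1e-12, rtol=1e-14
        )
    return out


def ph_grid_scan(model: PolyproticModel, vb: float, step: float = 1e-4) -> float:
    """Exhaustive pH scan minimizing |charge balance|; independent of brentq.

    Brute-force oracle for the root solver: evaluates the residual on a
    uniform pH grid and returns the grid point of smallest magnitude.
    """
    grid = np.arange(0.0, 14.0 + step, step)
    res = np.array([abs(_charge_balance(p, model, vb)) for p in grid])
    return float(grid[int(np.argmin(res))])
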