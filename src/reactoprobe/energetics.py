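"""Shifted-and-scaled potential energy, class averages, x_p and the ΔpKa estimator.

The reactive event's energy signature is buried in equilibrium fluctuations
of the total potential energy U(t).  The estimator removes the vibrational
baseline U_vib = N_deg R T / 2 (equipartition over N_deg = 3 N_a - 6 degrees
of freedom), scales by N_deg R T to make systems of different size
comparable, and anchors each trajectory at the bias start t0:

    U'(t) = [U(t) - U_vib(t)] / (N_deg R T(t)) - U'(t0)

Averaging U'(t) separately over reactive and non-reactive trajectories and
weighting the late-time class difference by the reactive ratio
x_p = n_react / (n_react + n_nonreact) gives the dimensionless energy change

    ΔU/RT = ΔU' = x_p * <U'_p(t) - U'_r(t)> * N_deg

and the pKa shift of a compound X against a reference follows from the
thermodynamic chain  ΔpKa = (ΔU'_X - ΔU'_ref) / ln 10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .classify import Label
from .traj_io import GAS_CONSTANT_KJ, ScalarLog

__all__ = [
    "ScaledEnergySeries",
    "EnsembleSummary",
    "DeltaResult",
    "scaled_potential",
    "class_average",
    "delta_uprime",
    "delta_pka",
    "DEFAULT_WINDOW_POINTS",
]

#: late-time averaging window for <U'_p - U'_r>, in time points
DEFAULT_WINDOW_POINTS = 200


@dataclass
class ScaledEnergySeries:
    """U'(t) on a time grid re-anchored so the bias start maps to t = 0 ps."""

    time: np.ndarray  # ps, 0 at bias start
    uprime: np.ndarray  # dimensionless, 0 at t = 0 by construction
    na: int
    ndeg: int

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.uprime = np.asarray(self.uprime, dtype=float)
        if self.time.shape != self.uprime.shape:
            raise ValueError("time and uprime must have equal length")
        if self.ndeg != 3 * self.na - 6:
            raise ValueError("ndeg must equal 3*na - 6")


@dataclass
class EnsembleSummary:
    """Class-averaged U' curves with RMSD bands, counts, and x_p."""

    time: np.ndarray  # ps
    mean_up: np.ndarray | None  # reactive-class mean U'(t)
    mean_ur: np.ndarray | None  # non-reactive-class mean U'(t)
    band_up: np.ndarray | None  # per-time RMSD around mean_up
    band_ur: np.ndarray | None
    n_react: int
    n_nonreact: int
    n_fault: int

    @property
    def xp(self) -> float:
        """Reactive ratio: reactive over successful (faults excluded)."""
        n_ok = self.n_react + self.n_nonreact
        if n_ok == 0:
            raise ValueError("no successful trajectories")
        return self.n_react / n_ok


@dataclass(frozen=True)
class DeltaResult:
    """ΔU' (=ΔU/RT, dimensionless) and ΔpKa against a stated reference."""

    delta_uprime: float
    delta_pka_vs_ref: float
    window_points: int


def scaled_potential(
    log: ScalarLog,
    na: int,
    t0: float,
    use_setpoint_temperature: float | None = None,
) -> ScaledEnergySeries:
    """Compute U'(t) from a scalar log.

    ``t0`` is the bias start in ps; the returned series is re-indexed so
    t0 maps to time 0, and U'(t0) = 0 by construction.  The instantaneous
    logged temperature T(t) is used by default; passing a thermostat
    set-point via ``use_setpoint_temperature`` replaces it.
    """
    if na < 3:
        raise ValueError("need at least 3 atoms for ndeg = 3*na - 6 > 0")
    ndeg = 3 * na - 6
    t0_fs = t0 * 1000.0
    if not (log.time[0] - 1e-6 <= t0_fs <= log.time[-1] + 1e-6):
        raise ValueError("t0 outside the logged time range")
    T = (
        np.full_like(log.T, float(use_setpoint_temperature))
        if use_setpoint_temperature is not None
        else log.T
    )
    denom = ndeg * GAS_CONSTANT_KJ * T
    raw = (log.U - denom / 2.0) / denom
    i0 = int(np.argmin(np.abs(log.time - t0_fs)))
    uprime = raw - raw[i0]
    time_ps = (log.time - log.time[i0]) / 1000.0
    return ScaledEnergySeries(time=time_ps, uprime=uprime, na=na, ndeg=ndeg)


def class_average(series, labels) -> EnsembleSummary:
    """Average U'(t) within the reactive and non-reactive classes.

    Series must share one time grid; faults are dropped from every average.
    An empty class yields ``None`` curves for that class (flagged, not an
    error, so a one-sided ensemble can still report counts and x_p).
    """
    series = list(series)
    labels = list(labels)
    if len(series) != len(labels):
        raise ValueError("series and labels must align 1:1")
    if not series:
        raise ValueError("empty ensemble")
    time = series[0].time
    for s in series[1:]:
        if s.time.shape != time.shape or not np.allclose(s.time, time, atol=1e-9):
            raise ValueError("all series must share one time grid")

    def _stack(kind: Label) -> np.ndarray:
        rows = [s.uprime for s, lb in zip(series, labels) if lb.label is kind]
        return np.vstack(rows) if rows else np.empty((0, time.size))

    up = _stack(Label.REACTIVE)
    ur = _stack(Label.NON_REACTIVE)
    n_f = sum(1 for lb in labels if lb.label is Label.FAULT)

    def _mean_band(rows: np.ndarray):
        if rows.shape[0] == 0:
            return None, None
        mean = rows.mean(axis=0)
        band = np.sqrt(np.mean((rows - mean) ** 2, axis=0))
        return mean, band

    mean_up, band_up = _mean_band(up)
    mean_ur, band_ur = _mean_band(ur)
    return EnsembleSummary(
        time=time,
        mean_up=mean_up,
        mean_ur=mean_ur,
        band_up=band_up,
        band_ur=band_ur,
        n_react=up.shape[0],
        n_nonreact=ur.shape[0],
        n_fault=n_f,
    )


def delta_uprime(
    summary: EnsembleSummary, ndeg: int, window: int = DEFAULT_WINDOW_POINTS
) -> float:
    """ΔU' = x_p * <mean_up(t) - mean_ur(t)>_{last window points} * N_deg.

    The class-mean curves are differenced first and then time-averaged over
    the final ``window`` points, where the product/reactant gap is stable.
    """
    if summary.mean_up is None or summary.mean_ur is None:
        raise ValueError("both classes must be non-empty to form ΔU'")
    if window < 1:
        raise ValueError("window must be at least one point")
    n = summary.time.size
    if window > n:
        raise ValueError(f"window of {window} points exceeds series length {n}")
    gap = summary.mean_up[-window:] - summary.mean_ur[-window:]
    return float(summary.xp * np.mean(gap) * ndeg)


def delta_pka(delta_uprime_x: float, delta_uprime_ref: float) -> float:
    """pKa shift of compound X against the reference: (ΔU'_X - ΔU'_ref)/ln 10."""
    if not (math.isfinite(delta_uprime_x) and math.isfinite(delta_uprime_ref)):
        raise ValueError("ΔU' inputs must be finite")
    return (delta_uprime_x - delta_uprime_ref) / math.log(10.0)
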