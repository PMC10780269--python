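"""Trajectory labelling and chemical final-state identification.

A steered trajectory is labelled ``fault`` when its energy log diverges
(Born-Oppenheimer breakdown under a fixed time step), ``reactive`` when the
coordination number drops from the reactant value (CN = 2) below a threshold
and stays there to the end of the run, and ``non_reactive`` otherwise.
Fault takes precedence over the CV-based labels, and faults are excluded
from all downstream ensemble statistics.

The chemical final state of a reactive run is read from geometry: the
extracted proton's nearest tagged heavy atom decides between the nitro
(back on C-alpha), aci (nitro oxygen), enol (carbonyl oxygen) and nitronate
(water oxygen) forms.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np

from .cv_bias import CVSeries
from .traj_io import Frame, ScalarLog, minimum_image_distance

__all__ = [
    "Label",
    "TrajLabel",
    "FinalStateKind",
    "FinalState",
    "EnsembleCounts",
    "detect_fault",
    "classify_trajectory",
    "classify_ensemble",
    "assign_final_state",
    "DEFAULT_CN_THRESHOLD",
    "DEFAULT_HOLD_PS",
    "DEFAULT_BOND_CUTOFFS",
]

#: midpoint of the reactant (CN=2) and product (CN=1) plateaus
DEFAULT_CN_THRESHOLD = 1.5
#: minimum sustained excursion; the true transition is fs-scale, so 0.1 ps
#: rejects transient dips without risking a real event
DEFAULT_HOLD_PS = 0.1
#: fault detector defaults: rolling window (points) and drift z-score
DEFAULT_FAULT_WINDOW = 50
DEFAULT_FAULT_ZMAX = 10.0


class Label(str, Enum):
    REACTIVE = "reactive"
    NON_REACTIVE = "non_reactive"
    FAULT = "fault"


@dataclass(frozen=True)
class TrajLabel:
    """Label plus, for reactive runs only, the reaction time (ps)."""

    label: Label
    t_react: float | None = None

    def __post_init__(self) -> None:
        if (self.label is Label.REACTIVE) != (self.t_react is not None):
            raise ValueError("t_react must be present iff label is reactive")


class FinalStateKind(str, Enum):
    NITRO = "nitro"
    ACI = "aci"
    ENOL = "enol"
    NITRONATE = "nitronate"


@dataclass(frozen=True)
class FinalState:
    state: FinalStateKind
    proton_partner: int


@dataclass(frozen=True)
class EnsembleCounts:
    total: int
    non_reactive: int
    reactive: int
    faults: int

    def __post_init__(self) -> None:
        if self.non_reactive + self.reactive + self.faults != self.total:
            raise ValueError("counts must sum to total")


#: proton-binding role -> final state
_ROLE_TO_STATE = {
    "calpha": FinalStateKind.NITRO,
    "nitro_o": FinalStateKind.ACI,
    "carbonyl_o": FinalStateKind.ENOL,
    "water_o": FinalStateKind.NITRONATE,
}

#: covalent-bond cutoffs (Å) per partner role; C-H is longer than O-H/N-H
DEFAULT_BOND_CUTOFFS = {
    "calpha": 1.3,
    "nitro_o": 1.2,
    "carbonyl_o": 1.2,
    "water_o": 1.2,
}


def detect_fault(
    log: ScalarLog,
    zscore_max: float = DEFAULT_FAULT_ZMAX,
    window: int = DEFAULT_FAULT_WINDOW,
    t0: float | None = None,
    growth_lag_fs: float = 250.0,
    growth_factor: float = 2.0,
) -> tuple[bool, float | None]:
    """Flag an energy log as divergent.

    A trajectory is a fault when (a) any logged energy is non-finite, or
    (b) the rolling ``window``-point mean of U ends the run more than
    ``zscore_max`` baseline standard deviations away from the pre-bias mean
    *and* the excursion is still growing: the final drift must exceed
    ``growth_factor`` times the drift ``growth_lag_fs`` earlier (or have
    crossed the band only within that lag).  The growth qualifier separates
    unbounded electron-ground-state breakdown from the bounded energy step
    a genuine reactive event leaves in the log.

    ``t0`` (ps) bounds the pre-bias baseline segment; when omitted, the
    first quarter of the log (at least ``window`` points) is used.

    Returns ``(is_fault, onset_ps)``; onset is the time the rolling mean
    first left the drift band (or the first non-finite record).
    """
    if len(log) < window:
        raise ValueError(f"log has {len(log)} points; need at least window={window}")
    bad = ~np.isfinite(log.U)
    if bad.any():
        return True, float(log.time[int(np.argmax(bad))]) / 1000.0
    if t0 is not None:
        n_base = int(np.searchsorted(log.time, t0 * 1000.0, side="right"))
    else:
        n_base = len(log) // 4
    n_base = max(n_base, window)
    base = log.U[:n_base]
    mu, sd = float(np.mean(base)), float(np.std(base))
    if sd == 0.0:
        sd = 1e-12
    kernel = np.full(window, 1.0 / window)
    rolling = np.convolve(log.U, kernel, mode="valid")  # rolling[i] ends at i+window-1
    drift = np.abs(rolling - mu) / sd
    if drift[-1] <= zscore_max:
        return False, None
    dt = float(np.median(np.diff(log.time))) if len(log) > 1 else 1.0
    lag = int(round(growth_lag_fs / dt))
    j = drift.size - 1 - lag
    if 0 <= j and drift[j] > zscore_max and drift[-1] < growth_factor * drift[j]:
        return False, None  # bounded plateau (e.g. a product-state offset)
    over = np.nonzero(drift > zscore_max)[0]
    idx = int(over[0]) + window - 1
    return True, float(log.time[idx]) / 1000.0


def classify_trajectory(
    cv: CVSeries,
    log: ScalarLog | None = None,
    cn_threshold: float = DEFAULT_CN_THRESHOLD,
    hold: float = DEFAULT_HOLD_PS,
    t0: float | None = None,
    zscore_max: float = DEFAULT_FAULT_ZMAX,
    fault_window: int = DEFAULT_FAULT_WINDOW,
) -> TrajLabel:
    """Label one trajectory from its CV series (and optionally its energy log).

    Fault takes precedence.  Reactive requires CN < ``cn_threshold``
    continuously from some crossing to the end of the series, for at least
    ``hold`` ps; the reaction time is the first point of that sustained
    excursion.  Everything else is non-reactive.
    """
    if len(cv) == 0:
        raise ValueError("empty CV series")
    if log is not None and len(log) >= fault_window:
        is_fault, _ = detect_fault(log, zscore_max=zscore_max, window=fault_window, t0=t0)
        if is_fault:
            return TrajLabel(Label.FAULT)
    below = cv.cn < cn_threshold
    if not below[-1]:
        return TrajLabel(Label.NON_REACTIVE)
    # first index of the trailing run of below-threshold points
    above = np.nonzero(~below)[0]
    start = int(above[-1]) + 1 if above.size else 0
    duration = cv.time[-1] - cv.time[start]
    if duration >= hold:
        return TrajLabel(Label.REACTIVE, t_react=float(cv.time[start]))
    return TrajLabel(Label.NON_REACTIVE)


def classify_ensemble(labels) -> EnsembleCounts:
    """Tally labels into (total, non_reactive, reactive, faults)."""
    labels = list(labels)
    n_r = sum(1 for lb in labels if lb.label is Label.REACTIVE)
    n_f = sum(1 for lb in labels if lb.label is Label.FAULT)
    n_nr = len(labels) - n_r - n_f
    return EnsembleCounts(
        total=len(labels), non_reactive=n_nr, reactive=n_r, faults=n_f
    )


def assign_final_state(
    frame: Frame,
    proton: int,
    roles: dict[int, str],
    bond_cutoffs: dict[str, float] | None = None,
) -> FinalState:
    """Identify the tautomer/product from the proton's nearest bonded partner.

    ``roles`` maps heavy-atom indices to one of {'calpha', 'nitro_o',
    'carbonyl_o', 'water_o'}.  The partner is the nearest tagged atom lying
    within its role's covalent cutoff; its role decides the state.
    """
    if bond_cutoffs is None:
        bond_cutoffs = DEFAULT_BOND_CUTOFFS
    if proton < 0 or proton >= frame.n_atoms:
        raise IndexError("proton index out of range")
    best: tuple[float, int, str] | None = None
    p = frame.coords[proton]
    for idx, role in roles.items():
        if role not in _ROLE_TO_STATE:
            raise ValueError(f"unknown atom role {role!r}")
        if idx == proton:
            raise ValueError("proton cannot carry a heavy-atom role")
        d = float(minimum_image_distance(p, frame.coords[idx], frame.cell))
        if d <= bond_cutoffs[role] and (best is None or d < best[0]):
            best = (d, idx, role)
    if best is None:
        raise ValueError("unbound proton: no tagged partner within any cutoff")
    _, idx, role = best
    return FinalState(state=_ROLE_TO_STATE[role], proton_partner=idx)
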