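"""Real-time (impedance) cytotoxicity profiling.

An impedance-based analyzer reports a dimensionless *cell index* per well,
proportional to adherent cell number and spreading.  Traces are normalized
to the time of compound addition, a four-parameter logistic (variable-
slope sigmoid) of normalized index versus log10 dose yields an IC50 at any
time point, and the post-treatment shape of a trace is classified into the
qualitative kill profiles seen with cytotoxic agents: DNA-damage-like
(a transient rise above vehicle — enlarged, senescent-looking cells —
followed by decline), direct kill (monotone decline), or cytostasis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .errors import DegenerateDesignError, DomainError

#: Shape-classifier defaults: a "rise" is >= 5% above vehicle sustained for
#: at least 2 h; a "decline" is 20% below the treatment-time level.
DEFAULT_RISE_THRESHOLD = 0.05
DEFAULT_RISE_SUSTAINED_H = 2.0
DEFAULT_DECLINE_THRESHOLD = 0.20
DEFAULT_PLATEAU_BAND = 0.20


@dataclass(frozen=True)
class CellIndexTrace:
    """Time series of impedance-derived cell index for one well."""

    times: np.ndarray  # hours, strictly increasing
    cell_index: np.ndarray
    drug: str = ""
    dose_nM: float = 0.0
    replicate: int = 0
    normalized: bool = False

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        ci = np.asarray(self.cell_index, dtype=float)
        if t.shape != ci.shape or t.ndim != 1:
            raise DomainError("times and cell_index must be 1-D and equal length")
        if len(t) >= 2 and np.any(np.diff(t) <= 0):
            raise DomainError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "cell_index", ci)

    def value_at(self, t: float) -> float:
        """Cell index at the grid point nearest to ``t``."""
        return float(self.cell_index[int(np.argmin(np.abs(self.times - t)))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "cell_index": self.cell_index,
                "drug": self.drug,
                "dose_nM": self.dose_nM,
                "replicate": self.replicate,
            }
        )


@dataclass(frozen=True)
class IC50Estimate:
    """Result of one time-point 4PL fit; undefined fits are flagged."""

    time_h: float
    ic50_nM: float  # nan when undefined
    hill: float = float("nan")
    bottom: float = float("nan")
    top: float = float("nan")
    defined: bool = True
    reason: str = ""


@dataclass(frozen=True)
class TimeResolvedIC50:
    """IC50 as a function of time post-treatment."""

    estimates: tuple[IC50Estimate, ...]

    @property
    def times(self) -> np.ndarray:
        return np.array([e.time_h for e in self.estimates])

    @property
    def ic50(self) -> np.ndarray:
        return np.array([e.ic50_nM for e in self.estimates])

    @property
    def defined(self) -> np.ndarray:
        return np.array([e.defined for e in self.estimates])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "ic50_nM": self.ic50,
                "defined": self.defined,
                "reason": [e.reason for e in self.estimates],
            }
        )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_cell_index(trace: CellIndexTrace, t_treat: float) -> CellIndexTrace:
    """Divide a trace by its value at the grid point nearest ``t_treat``.

    The normalized index is 1.0 at treatment time, making wells with
    different seeding densities comparable.  Idempotent, and invariant to
    scaling the raw trace by a constant.
    """
    ref = trace.value_at(t_treat)
    if ref <= 0:
        raise DegenerateDesignError(
            f"cell index at treatment time is {ref}; well unusable"
        )
    return replace(trace, cell_index=trace.cell_index / ref, normalized=True)


# ---------------------------------------------------------------------------
# Time-resolved IC50
# ---------------------------------------------------------------------------

def _four_pl(logd, bottom, top, logic50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logd - logic50)))


def ic50_at_time(
    traces: Iterable[CellIndexTrace],
    t: float,
    vehicle: CellIndexTrace,
    *,
    anchor_top: bool = True,
) -> IC50Estimate:
    """Fit a variable-slope sigmoid of normalized cell index vs log10 dose
    at time ``t`` and return the IC50.

    The top plateau is anchored to the vehicle trace's level at ``t`` by
    default (set ``anchor_top=False`` to fit it); the bottom is bounded at
    zero and the slope is free.  A fit with no dose-response gradient, no
    half-effect crossing within the observed response range, or a
    non-convergent optimizer is returned flagged-undefined rather than
    raised, so time-course scans degrade gracefully.
    """
    doses, y = [], []
    for tr in traces:
        if tr.dose_nM > 0:
            doses.append(tr.dose_nM)
            y.append(tr.value_at(t))
    if len(set(doses)) < 4:
        raise DomainError("need >= 4 distinct positive doses")
    doses = np.asarray(doses, dtype=float)
    y = np.asarray(y, dtype=float)
    top_level = vehicle.value_at(t)
    if top_level <= 0:
        raise DegenerateDesignError("vehicle trace non-positive at t")

    half = top_level / 2.0
    if y.min() > half:
        return IC50Estimate(
            time_h=t, ic50_nM=float("nan"), defined=False, reason="no_crossing"
        )
    if np.ptp(y) < 0.05 * top_level:
        return IC50Estimate(
            time_h=t, ic50_nM=float("nan"), defined=False, reason="no_gradient"
        )

    logd = np.log10(doses)
    p0_logic50 = float(np.median(logd))
    try:
        if anchor_top:
            def model(logd, bottom, logic50, hill):
                return _four_pl(logd, bottom, top_level, logic50, hill)

            popt, _ = curve_fit(
                model,
                logd,
                y,
                p0=[0.0, p0_logic50, 1.0],
                bounds=([0.0, logd.min() - 3, 0.05], [top_level, logd.max() + 3, 20.0]),
                maxfev=10000,
            )
            bottom, logic50, hill = popt
            top = top_level
        else:
            popt, _ = curve_fit(
                _four_pl,
                logd,
                y,
                p0=[0.0, top_level, p0_logic50, 1.0],
                bounds=(
                    [0.0, 0.0, logd.min() - 3, 0.05],
                    [np.inf, np.inf, logd.max() + 3, 20.0],
                ),
                maxfev=10000,
            )
            bottom, top, logic50, hill = popt
    except (RuntimeError, ValueError):
        return IC50Estimate(
            time_h=t, ic50_nM=float("nan"), defined=False, reason="no_convergence"
        )
    return IC50Estimate(
        time_h=t,
        ic50_nM=float(10.0 ** logic50),
        hill=float(hill),
        bottom=float(bottom),
        top=float(top),
        defined=True,
    )


def ic50_timecourse(
    traces: Iterable[CellIndexTrace],
    time_grid: Sequence[float],
    vehicle: CellIndexTrace,
    *,
    anchor_top: bool = True,
) -> TimeResolvedIC50:
    """Evaluate :func:`ic50_at_time` over a grid of time points.

    Undefined time points (no crossing yet, no gradient, non-convergence)
    carry their flag through; nothing is interpolated or fabricated.
    """
    traces = list(traces)
    estimates = tuple(
        ic50_at_time(traces, t, vehicle, anchor_top=anchor_top)
        for t in time_grid
    )
    return TimeResolvedIC50(estimates=estimates)


# ---------------------------------------------------------------------------
# Kinetic-shape classification
# ---------------------------------------------------------------------------

def classify_kinetic_shape(
    trace: CellIndexTrace,
    vehicle: CellIndexTrace,
    *,
    rise_threshold: float = DEFAULT_RISE_THRESHOLD,
    rise_sustained_h: float = DEFAULT_RISE_SUSTAINED_H,
    decline_threshold: float = DEFAULT_DECLINE_THRESHOLD,
    plateau_band: float = DEFAULT_PLATEAU_BAND,
    t_treat: float | None = None,
) -> str:
    """Classify a normalized post-treatment trace against its vehicle.

    If ``t_treat`` is given, only the portion of both traces at
    ``times >= t_treat`` is considered (the pre-treatment growth segment
    of a full trace would otherwise register as a spurious decline).

    Labels
    ------
    ``dna_damage_like``
        The trace exceeds the vehicle by ``rise_threshold`` for a
        contiguous span of at least ``rise_sustained_h`` hours (cells
        transiently enlarge before dying), then falls below
        ``1 - decline_threshold`` of the treatment-time level.
    ``direct_kill``
        No such rise, but the trace declines below the threshold.
    ``cytostatic``
        Neither rise nor decline; the trace stays within
        ``plateau_band`` of the treatment-time level.
    ``none``
        Anything else (e.g. growth tracking the vehicle).

    Deterministic, and monotone in the thresholds: raising
    ``rise_threshold`` can only demote dna_damage_like toward
    direct_kill, never the reverse.
    """
    if trace.times.shape != vehicle.times.shape or not np.allclose(
        trace.times, vehicle.times
    ):
        raise DomainError("trace and vehicle must share a common time grid")
    keep = (
        trace.times >= t_treat if t_treat is not None
        else np.ones(len(trace.times), dtype=bool)
    )
    y = trace.cell_index[keep]
    v = vehicle.cell_index[keep]
    t = trace.times[keep]
    if len(t) == 0:
        raise DomainError("no samples at or after t_treat")

    above = y > v * (1.0 + rise_threshold)
    sustained_rise = _longest_true_span_hours(t, above) >= rise_sustained_h
    declined = bool(np.any(y < 1.0 - decline_threshold))

    if sustained_rise and declined:
        return "dna_damage_like"
    if declined:
        return "direct_kill"
    if np.all(np.abs(y - 1.0) <= plateau_band):
        return "cytostatic"
    return "none"


def _longest_true_span_hours(t: np.ndarray, mask: np.ndarray) -> float:
    """Length in hours of the longest contiguous True run of ``mask``."""
    best = 0.0
    start = None
    for i, flag in enumerate(mask):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            best = max(best, t[i - 1] - t[start])
            start = None
    if start is not None:
        best = max(best, t[-1] - t[start])
    return best


def traces_from_table(table: pd.DataFrame) -> list[CellIndexTrace]:
    """Read long-format trace CSV rows into traces.

    Expects columns ``time_h, drug, dose_nM, cell_index`` and optionally
    ``replicate``; one trace per (drug, dose, replicate) group, sorted by
    time.
    """
    required = {"time_h", "drug", "dose_nM", "cell_index"}
    missing = required - set(table.columns)
    if missing:
        raise DomainError(f"trace table missing columns {sorted(missing)}")
    if "replicate" not in table.columns:
        table = table.assign(replicate=0)
    out = []
    for (drug, dose, rep), grp in table.groupby(
        ["drug", "dose_nM", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        out.append(
            CellIndexTrace(
                times=grp["time_h"].to_numpy(float),
                cell_index=grp["cell_index"].to_numpy(float),
                drug=str(drug),
                dose_nM=float(dose),
                replicate=int(rep),
            )
        )
    return out
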