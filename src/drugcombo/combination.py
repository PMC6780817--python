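"""Two-drug interaction analysis: combination index, dose-reduction index,
isobologram, curve-shift and checkerboard summaries.

The combination index (CI) of Chou and Talalay quantifies departure from
Loewe additivity for a mixture achieving affected fraction fa:

    CI(fa) = d_a / Dx_a(fa) + d_b / Dx_b(fa)

where (d_a, d_b) are the component doses in the mixture and Dx_a, Dx_b the
single-agent doses producing the same fa.  CI < 1 indicates synergism,
CI = 1 additivity, CI > 1 antagonism.  In a constant-ratio (diagonal)
design the mixture is fitted on total molar dose, so d_a and d_b follow
from the ratio split of the total dose at each effect level.

The dose-reduction index (DRI) is the fold by which each drug's single-
agent dose for a given effect exceeds its dose in the combination; the
algebraic identity 1/DRI_a + 1/DRI_b = CI always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateDesignError, DomainError, LabelMismatchError
from .median_effect import MedianEffectFit, dose_for_effect, effect_at_dose

DEFAULT_FA_LEVELS: tuple[float, ...] = (0.50, 0.75, 0.90, 0.95)
DEFAULT_ADDITIVITY_BAND: tuple[float, float] = (0.90, 1.10)

SCHEDULES = ("simultaneous", "a_then_b", "b_then_a")
_SCHEDULE_ORDER = {s: i for i, s in enumerate(SCHEDULES)}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CombinationDesign:
    """A constant-ratio pairing of two drugs with its dosing schedule.

    ``ratio_a : ratio_b`` is the fixed molar ratio (e.g. 1:50 for a pair
    where drug b is dosed 50-fold higher).  ``schedule`` distinguishes
    simultaneous exposure from the two sequential orders; for endpoint
    analysis the schedule is metadata (total exposure is identical), but
    generators may modulate the interaction by schedule.
    """

    drug_a_label: str
    drug_b_label: str
    ratio_a: int
    ratio_b: int
    schedule: str = "simultaneous"
    exposure_hours_total: float = 72.0
    exposure_hours_first: float | None = None

    def __post_init__(self) -> None:
        if self.ratio_a < 0 or self.ratio_b < 0 or self.ratio_a + self.ratio_b == 0:
            raise DomainError(
                "ratio parts must be non-negative integers, not both zero"
            )
        if int(self.ratio_a) != self.ratio_a or int(self.ratio_b) != self.ratio_b:
            raise DomainError("ratio parts must be integers")
        if self.schedule not in SCHEDULES:
            raise DomainError(
                f"schedule must be one of {SCHEDULES}, got {self.schedule!r}"
            )

    @property
    def fraction_a(self) -> float:
        """Drug a's share of the total molar dose."""
        return self.ratio_a / (self.ratio_a + self.ratio_b)

    @property
    def fraction_b(self) -> float:
        return self.ratio_b / (self.ratio_a + self.ratio_b)

    @property
    def ratio_text(self) -> str:
        return f"{self.ratio_a}:{self.ratio_b}"


@dataclass(frozen=True)
class CIProfile:
    """Combination-index values across inhibition levels and trials."""

    fa_levels: tuple[float, ...]
    ci_per_trial: np.ndarray  # shape (n_trials, n_levels)
    ci_mean: np.ndarray
    ci_sem: np.ndarray
    classification: tuple[str, ...]
    design: CombinationDesign | None = None

    @property
    def n_trials(self) -> int:
        return self.ci_per_trial.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fa_level": self.fa_levels,
                "ci_mean": self.ci_mean,
                "ci_sem": self.ci_sem,
                "classification": self.classification,
                "n_trials": self.n_trials,
            }
        )


@dataclass(frozen=True)
class DRIResult:
    """Fold reductions of each drug's dose at a fixed effect level."""

    fa_level: float
    dri_a: float
    dri_b: float

    @property
    def ci(self) -> float:
        return 1.0 / self.dri_a + 1.0 / self.dri_b


@dataclass(frozen=True)
class Isobole:
    """Dose pairs achieving a fixed effect, against the additivity line.

    The additivity line joins the single-agent intercepts (Dx_a, 0) and
    (0, Dx_b); a combination point below the line has CI < 1.  The sum of
    a point's normalized coordinates (d_a/Dx_a + d_b/Dx_b) equals its CI.
    """

    fa_level: float
    dx_a: float
    dx_b: float
    points: tuple[tuple[float, float], ...]
    normalized_sums: tuple[float, ...] = field(default=())

    def to_frame(self) -> pd.DataFrame:
        d_a = [p[0] for p in self.points]
        d_b = [p[1] for p in self.points]
        return pd.DataFrame(
            {
                "fa_level": self.fa_level,
                "dose_a_nM": d_a,
                "dose_b_nM": d_b,
                "dx_a_nM": self.dx_a,
                "dx_b_nM": self.dx_b,
                "normalized_sum": self.normalized_sums,
            }
        )


# ---------------------------------------------------------------------------
# Combination index
# ---------------------------------------------------------------------------

def _check_labels(
    fit_a: MedianEffectFit, fit_b: MedianEffectFit, design: CombinationDesign
) -> None:
    for fit, want in ((fit_a, design.drug_a_label), (fit_b, design.drug_b_label)):
        if fit.drug_label and want and fit.drug_label != want:
            raise LabelMismatchError(
                f"fit label {fit.drug_label!r} does not match design label {want!r}"
            )


def combination_index_at(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: CombinationDesign,
    fa: float,
) -> float:
    """Two-term combination index at a single effect level.

    ``fit_combo`` must be fitted on the total molar dose of the constant-
    ratio mixture; the component doses are the ratio split of the total
    dose the mixture needs to reach ``fa``.
    """
    if not 0 < fa < 1:
        raise DomainError("fa must lie strictly inside (0, 1)")
    _check_labels(fit_a, fit_b, design)
    d_tot = dose_for_effect(fit_combo, fa)
    d_a = d_tot * design.fraction_a
    d_b = d_tot * design.fraction_b
    return d_a / dose_for_effect(fit_a, fa) + d_b / dose_for_effect(fit_b, fa)


def _as_fit_list(fits) -> list[MedianEffectFit]:
    if isinstance(fits, MedianEffectFit):
        return [fits]
    return list(fits)


def combination_index(
    fit_a,
    fit_b,
    fit_combo,
    design: CombinationDesign,
    fa_levels: Sequence[float] = DEFAULT_FA_LEVELS,
    additivity_band: tuple[float, float] = DEFAULT_ADDITIVITY_BAND,
) -> CIProfile:
    """Combination-index profile across effect levels, per trial.

    Each of ``fit_a``, ``fit_b``, ``fit_combo`` is a single fit or a
    sequence of per-trial fits (equal lengths).  CI is computed within
    each trial, then summarised as mean +/- SEM across trials, matching
    the convention of reporting one CI per independent experiment.
    """
    if len(fa_levels) == 0:
        raise DomainError("fa_levels must be non-empty")
    lists = [_as_fit_list(f) for f in (fit_a, fit_b, fit_combo)]
    n_trials = max(len(l) for l in lists)
    lists = [l * n_trials if len(l) == 1 else l for l in lists]
    if any(len(l) != n_trials for l in lists):
        raise DomainError("per-trial fit lists must have equal lengths")
    ci = np.empty((n_trials, len(fa_levels)))
    for t, (fa_t, fb_t, fc_t) in enumerate(zip(*lists)):
        for j, fa in enumerate(fa_levels):
            ci[t, j] = combination_index_at(fa_t, fb_t, fc_t, design, fa)
    mean = ci.mean(axis=0)
    sem = (
        ci.std(axis=0, ddof=1) / np.sqrt(n_trials)
        if n_trials > 1
        else np.zeros(len(fa_levels))
    )
    labels = tuple(classify_ci(c, additivity_band) for c in mean)
    return CIProfile(
        fa_levels=tuple(fa_levels),
        ci_per_trial=ci,
        ci_mean=mean,
        ci_sem=sem,
        classification=labels,
        design=design,
    )


def classify_ci(
    ci: float, additivity_band: tuple[float, float] = DEFAULT_ADDITIVITY_BAND
) -> str:
    """Label a CI value as synergism (< band), additivity (within band) or
    antagonism (> band).  The additive band defaults to (0.90, 1.10)."""
    if not ci > 0:
        raise DomainError(f"CI must be > 0, got {ci}")
    low, high = additivity_band
    if not 0 < low <= high:
        raise DomainError("additivity band must satisfy 0 < low <= high")
    if ci < low:
        return "synergism"
    if ci > high:
        return "antagonism"
    return "additivity"


def dose_reduction_index(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fit_combo: MedianEffectFit,
    design: CombinationDesign,
    fa: float,
) -> DRIResult:
    """Fold by which each single-agent dose at ``fa`` exceeds that drug's
    dose in the combination reaching the same effect."""
    if not 0 < fa < 1:
        raise DomainError("fa must lie strictly inside (0, 1)")
    _check_labels(fit_a, fit_b, design)
    d_tot = dose_for_effect(fit_combo, fa)
    d_a = d_tot * design.fraction_a
    d_b = d_tot * design.fraction_b
    return DRIResult(
        fa_level=fa,
        dri_a=dose_for_effect(fit_a, fa) / d_a,
        dri_b=dose_for_effect(fit_b, fa) / d_b,
    )


# ---------------------------------------------------------------------------
# Isobologram and curve shift
# ---------------------------------------------------------------------------

def isobologram(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    combos: Iterable[tuple[MedianEffectFit, CombinationDesign]],
    fa: float,
) -> Isobole:
    """Isobole at effect level ``fa`` for one or more constant-ratio
    mixtures.

    Returns the single-agent axis intercepts and, per mixture, the dose
    pair (d_a, d_b) achieving ``fa``; the normalized-coordinate sum of
    each point equals its combination index.
    """
    if not 0 < fa < 1:
        raise DomainError("fa must lie strictly inside (0, 1)")
    dx_a = dose_for_effect(fit_a, fa)
    dx_b = dose_for_effect(fit_b, fa)
    points: list[tuple[float, float]] = []
    sums: list[float] = []
    for fit_combo, design in combos:
        _check_labels(fit_a, fit_b, design)
        d_tot = dose_for_effect(fit_combo, fa)
        d_a = d_tot * design.fraction_a
        d_b = d_tot * design.fraction_b
        points.append((d_a, d_b))
        sums.append(d_a / dx_a + d_b / dx_b)
    return Isobole(
        fa_level=fa,
        dx_a=dx_a,
        dx_b=dx_b,
        points=tuple(points),
        normalized_sums=tuple(sums),
    )


def curve_shift_table(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    combo_points: pd.DataFrame,
    design: CombinationDesign,
) -> pd.DataFrame:
    """Overlay table for curve-shift analysis; no refitting.

    ``combo_points`` is a tidy mixture table with columns ``dose_nM``
    (total molar dose) and ``viability_pct``.  Each total dose is split
    into component concentrations by the design ratio, and each drug's
    own single-agent curve is evaluated at its component dose, so the
    combination response can be overlaid on each drug's own axis.
    """
    required = {"dose_nM", "viability_pct"}
    missing = required - set(combo_points.columns)
    if missing:
        raise DomainError(f"combo_points missing columns {sorted(missing)}")
    total = combo_points["dose_nM"].to_numpy(dtype=float)
    if np.any(total <= 0):
        raise DomainError("total mixture doses must be > 0")
    d_a = total * design.fraction_a
    d_b = total * design.fraction_b
    out = pd.DataFrame(
        {
            "total_dose_nM": total,
            "dose_a_nM": d_a,
            "dose_b_nM": d_b,
            "viability_combo_pct": combo_points["viability_pct"].to_numpy(float),
            "viability_single_a_pct": _single_agent_viability(fit_a, d_a),
            "viability_single_b_pct": _single_agent_viability(fit_b, d_b),
        }
    )
    for col in ("trial", "replicate"):
        if col in combo_points.columns:
            out[col] = combo_points[col].to_numpy()
    return out


# ---------------------------------------------------------------------------
# Potency ratio and reports
# ---------------------------------------------------------------------------

def _single_agent_viability(fit: MedianEffectFit, doses: np.ndarray) -> np.ndarray:
    """Predicted viability (%) at each dose; 100 at zero dose (degenerate
    ratio components)."""
    out = np.full_like(doses, 100.0, dtype=float)
    pos = doses > 0
    if np.any(pos):
        out[pos] = 100.0 * (1.0 - effect_at_dose(fit, doses[pos]))
    return out


def potency_ratio(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    rounding: str = "tens_half_up",
) -> tuple[float, tuple[int, int]]:
    """Potency ratio Dm_b / Dm_a and the equipotent integer design ratio.

    With drug a the more potent agent, the equipotent constant-ratio
    design doses drug b ``round(ratio)``-fold higher.  Rounding defaults
    to the nearest multiple of ten with half-up ties (59.33 -> 60); set
    ``rounding="nearest_int"`` for unit resolution.  Ratios that would
    round to zero fall back to the nearest positive integer, so equal
    potencies give 1:1.
    """
    ratio = fit_b.dm / fit_a.dm
    if rounding == "tens_half_up":
        part_b = int(np.floor(ratio / 10.0 + 0.5)) * 10
    elif rounding == "nearest_int":
        part_b = int(np.floor(ratio + 0.5))
    else:
        raise DomainError(f"unknown rounding rule {rounding!r}")
    if part_b == 0:
        part_b = max(1, int(np.floor(ratio + 0.5)))
    return ratio, (1, part_b)


def ci_summary_report(
    profiles: Iterable[CIProfile],
    additivity_band: tuple[float, float] = DEFAULT_ADDITIVITY_BAND,
) -> pd.DataFrame:
    """Classification table across designs, one row per (schedule, ratio).

    Columns mirror the conventional drug-combination summary: schedule,
    ratio, number of trials, then per effect level the CI as
    ``mean+/-sem`` and its class label.  Row order is deterministic:
    schedule (simultaneous, a then b, b then a), then ratio.
    """
    profiles = list(profiles)
    if not profiles:
        raise DomainError("need at least one CI profile")
    fa_levels = profiles[0].fa_levels
    if len(fa_levels) == 0:
        raise DomainError("fa_levels must be non-empty")
    for p in profiles:
        if p.fa_levels != fa_levels:
            raise DomainError("all profiles must share the same fa levels")
        if p.design is None:
            raise DomainError("profiles must carry their CombinationDesign")
    rows = []
    for p in profiles:
        d = p.design
        row = {
            "schedule": d.schedule,
            "ratio": d.ratio_text,
            "n": p.n_trials,
        }
        for j, fa in enumerate(fa_levels):
            key = f"IC{int(round(fa * 100))}"
            row[f"CI@{key}"] = f"{p.ci_mean[j]:.3f}±{p.ci_sem[j]:.3f}"
            row[f"class@{key}"] = classify_ci(p.ci_mean[j], additivity_band)
        rows.append(row)
    out = pd.DataFrame(rows)
    order = out.assign(
        _s=[_SCHEDULE_ORDER[s] for s in out["schedule"]],
        _ra=[int(r.split(":")[0]) for r in out["ratio"]],
        _rb=[int(r.split(":")[1]) for r in out["ratio"]],
    )
    out = (
        order.sort_values(["_s", "_ra", "_rb"], kind="stable")
        .drop(columns=["_s", "_ra", "_rb"])
        .reset_index(drop=True)
    )
    return out


def checkerboard_summary(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-cell enhancement table for a full-factorial dose grid.

    ``matrix`` holds mean viability (%) with drug-a doses as the index and
    drug-b doses as the columns; both axes must include a zero dose (the
    single-agent margins).  For each combination cell the output lists the
    observed viability, its difference from each single-agent margin, and
    a flag for cells beating both margins (candidate enhancement).
    """
    idx = np.asarray(matrix.index, dtype=float)
    cols = np.asarray(matrix.columns, dtype=float)
    if 0.0 not in idx or 0.0 not in cols:
        raise DegenerateDesignError(
            "checkerboard must include zero-dose margins for both drugs"
        )
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise DegenerateDesignError("checkerboard needs at least a 2x2 grid")
    values = matrix.to_numpy(dtype=float)
    a_margin = values[:, list(cols).index(0.0)]  # drug a alone, per row
    b_margin = values[list(idx).index(0.0), :]  # drug b alone, per column
    rows = []
    for i, da in enumerate(idx):
        for j, db in enumerate(cols):
            v = values[i, j]
            rows.append(
                {
                    "dose_a_nM": da,
                    "dose_b_nM": db,
                    "viability_pct": v,
                    "diff_vs_a_alone": v - a_margin[i],
                    "diff_vs_b_alone": v - b_margin[j],
                    "enhanced": bool(
                        da > 0
                        and db > 0
                        and v < a_margin[i]
                        and v < b_margin[j]
                    ),
                }
            )
    return pd.DataFrame(rows)
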