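"""Mass-action median-effect dose-response model.

The model relates the fraction of cells affected (``fa``) to dose ``D``
through

    fa / fu = (D / Dm) ** m,      fu = 1 - fa,

where ``Dm`` is the median-effect dose (the IC50) and ``m`` the shape
exponent (m = 1 hyperbolic, m > 1 sigmoidal).  Taking base-10 logarithms
linearises the relation,

    log10(fa / fu) = m * log10(D) - m * log10(Dm),

so ``m`` and ``Dm`` are estimated by ordinary least squares on the
median-effect plot; the correlation coefficient ``r`` of that plot measures
conformity of the data to the mass-action law.

The module also houses the plate arithmetic feeding the model: background-
subtracted percent viability from raw absorbances, conversion of viability
to affected fraction with a clipping policy, and the manual apoptotic-cell
percentage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    DegenerateDesignError,
    DomainError,
    InsufficientDataError,
    InvalidControlError,
)

logger = logging.getLogger(__name__)

#: Default clipping half-width for affected fractions, keeping log(fa/fu)
#: finite for wells at 0% or 100% effect.
DEFAULT_FA_EPS = 0.005


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseEffectPoint:
    """One well's contribution to a median-effect fit.

    Parameters
    ----------
    dose
        Concentration in nM; strictly positive.
    fa
        Affected fraction in [0, 1] (after the clipping policy).
    replicate_id, trial_id
        Plate bookkeeping; fits pool replicates within a trial.
    clipped
        True if ``fa`` was clipped into the open interval for
        log-linearisation.
    """

    dose: float
    fa: float
    replicate_id: int = 0
    trial_id: int = 0
    clipped: bool = False

    def __post_init__(self) -> None:
        if not self.dose > 0:
            raise DomainError(f"dose must be > 0, got {self.dose}")
        if not 0.0 <= self.fa <= 1.0:
            raise DomainError(f"fa must lie in [0, 1], got {self.fa}")


@dataclass(frozen=True)
class MedianEffectFit:
    """Fitted mass-action parameters for one drug (or mixture).

    Attributes
    ----------
    dm
        Median-effect dose (IC50) in nM.
    m
        Shape exponent of the curve.
    r
        Linear-correlation coefficient of the median-effect plot.
    n_points
        Number of dose-effect points behind the fit.
    drug_label
        Free-text identifier used for consistency checks downstream.
    """

    dm: float
    m: float
    r: float = 1.0
    n_points: int = 0
    drug_label: str = ""

    def __post_init__(self) -> None:
        if not self.dm > 0:
            raise DomainError(f"Dm must be > 0, got {self.dm}")
        if not self.m > 0:
            raise DomainError(f"m must be > 0, got {self.m}")
        if abs(self.r) > 1 + 1e-12:
            raise DomainError(f"|r| must be <= 1, got {self.r}")

    def to_dict(self) -> dict:
        """JSON-ready mapping (keys: drug_label, Dm, m, r, n_points)."""
        return {
            "drug_label": self.drug_label,
            "Dm": self.dm,
            "m": self.m,
            "r": self.r,
            "n_points": self.n_points,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "MedianEffectFit":
        return cls(
            dm=float(d["Dm"]),
            m=float(d["m"]),
            r=float(d.get("r", 1.0)),
            n_points=int(d.get("n_points", 0)),
            drug_label=str(d.get("drug_label", "")),
        )


@dataclass(frozen=True)
class ViabilityRecord:
    """Raw absorbances of one well with its derived percent viability."""

    absorbance_treated: float
    absorbance_vehicle: float
    absorbance_media: float
    viability_percent: float = field(init=False)
    clipped: bool = field(init=False)

    def __post_init__(self) -> None:
        v = viability_from_absorbance(
            self.absorbance_treated,
            self.absorbance_vehicle,
            self.absorbance_media,
        )
        raw = 100.0 * (
            (self.absorbance_treated - self.absorbance_media)
            / (self.absorbance_vehicle - self.absorbance_media)
        )
        object.__setattr__(self, "viability_percent", float(v))
        object.__setattr__(self, "clipped", bool(raw < 0))


# ---------------------------------------------------------------------------
# Plate arithmetic
# ---------------------------------------------------------------------------

def viability_from_absorbance(treated, vehicle, media):
    """Percent cell viability relative to the vehicle control.

    ``100 * (treated - media) / (vehicle - media)``, with negative results
    (over-kill wells reading below the media blank) clipped to 0 and logged.
    Accepts scalars or array-likes; broadcasting follows numpy rules.

    Raises
    ------
    InvalidControlError
        If any vehicle absorbance does not exceed its media blank.
    """
    treated = np.asarray(treated, dtype=float)
    vehicle = np.asarray(vehicle, dtype=float)
    media = np.asarray(media, dtype=float)
    if np.any(vehicle <= media):
        raise InvalidControlError(
            "vehicle-control absorbance must exceed the media blank"
        )
    v = 100.0 * (treated - media) / (vehicle - media)
    n_neg = int(np.count_nonzero(v < 0))
    if n_neg:
        logger.warning("clipped %d negative viability value(s) to 0", n_neg)
    v = np.maximum(v, 0.0)
    return float(v) if v.ndim == 0 else v


def fa_from_viability(viability, eps: float = DEFAULT_FA_EPS):
    """Affected fraction ``1 - viability/100``, clipped into [eps, 1-eps].

    Clipping keeps the median-effect plot's ordinate finite for wells at
    exactly 0% or 100% viability.  Scalars or arrays accepted.
    """
    viability = np.asarray(viability, dtype=float)
    if not np.all(np.isfinite(viability)):
        raise DomainError("viability must be finite")
    if not 0 < eps < 0.5:
        raise DomainError(f"eps must lie in (0, 0.5), got {eps}")
    fa = 1.0 - viability / 100.0
    fa = np.clip(fa, eps, 1.0 - eps)
    return float(fa) if fa.ndim == 0 else fa


def apoptotic_fraction(n_apoptotic: int, n_total: int) -> float:
    """Percent apoptotic cells from a manual nuclei count.

    Warns (does not fail) when fewer than 200 cells were scored, the
    conventional minimum for a stable manual estimate.
    """
    if n_total == 0:
        raise DomainError("total cell count must be positive")
    if not 0 <= n_apoptotic <= n_total:
        raise DomainError("apoptotic count must lie in [0, n_total]")
    if n_total < 200:
        warnings.warn(
            f"only {n_total} cells counted; >= 200 recommended",
            stacklevel=2,
        )
    return 100.0 * n_apoptotic / n_total


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def points_from_table(
    table: pd.DataFrame,
    *,
    eps: float = DEFAULT_FA_EPS,
    clip_policy: str = "keep",
) -> list[DoseEffectPoint]:
    """Build dose-effect points from a tidy viability table.

    Expects columns ``dose_nM`` and ``viability_pct`` (plus optional
    ``trial`` and ``replicate``).  Rows at zero dose (controls) are ignored.
    ``clip_policy`` is ``"keep"`` (clip out-of-range fa to the bounds and
    retain the point) or ``"exclude"`` (drop clipped points).
    """
    if clip_policy not in ("keep", "exclude"):
        raise DomainError(f"unknown clip_policy {clip_policy!r}")
    points: list[DoseEffectPoint] = []
    for row in table.itertuples(index=False):
        dose = float(getattr(row, "dose_nM"))
        if dose <= 0:
            continue
        v = float(getattr(row, "viability_pct"))
        raw_fa = 1.0 - v / 100.0
        fa = float(np.clip(raw_fa, eps, 1.0 - eps))
        clipped = fa != raw_fa
        if clipped and clip_policy == "exclude":
            continue
        points.append(
            DoseEffectPoint(
                dose=dose,
                fa=fa,
                replicate_id=int(getattr(row, "replicate", 0)),
                trial_id=int(getattr(row, "trial", 0)),
                clipped=clipped,
            )
        )
    return points


def fit_median_effect(
    points: Iterable[DoseEffectPoint],
    *,
    drug_label: str = "",
    exclude_clipped: bool = False,
) -> MedianEffectFit:
    """Fit ``Dm`` and ``m`` by unweighted least squares on the median-effect
    plot (log10 dose vs log10(fa/fu)).

    All points are pooled; duplicated points act as least-squares weights.
    Deterministic for a fixed input order.

    Raises
    ------
    InsufficientDataError
        Fewer than 2 usable points.
    DegenerateDesignError
        All usable points share a single dose, or the plot has a
        non-positive slope (no dose-response gradient to fit).
    """
    pts = [p for p in points if not (exclude_clipped and p.clipped)]
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 usable dose-effect points, got {len(pts)}"
        )
    dose = np.array([p.dose for p in pts], dtype=float)
    fa = np.array([p.fa for p in pts], dtype=float)
    x = np.log10(dose)
    y = np.log10(fa / (1.0 - fa))
    if np.ptp(x) == 0:
        raise DegenerateDesignError("all points share a single dose")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        raise DegenerateDesignError(
            f"median-effect plot slope is non-positive (m={m:.3g}); "
            "no increasing dose-response"
        )
    dm = float(10.0 ** (-res.intercept / m))
    # ptp(y) == 0 (perfectly flat response) is already excluded by m <= 0;
    # guard r for the 2-point case where linregress returns r = 1 exactly.
    r = float(np.clip(res.rvalue, -1.0, 1.0))
    return MedianEffectFit(
        dm=dm, m=m, r=r, n_points=len(pts), drug_label=drug_label
    )


def fit_trials(
    points: Iterable[DoseEffectPoint],
    *,
    drug_label: str = "",
    exclude_clipped: bool = False,
) -> dict[int, MedianEffectFit]:
    """Per-trial median-effect fits, keyed by ``trial_id``.

    Replicate wells are pooled within each trial; trials are kept separate
    so that downstream combination indices can report a cross-trial
    mean +/- SEM.
    """
    by_trial: dict[int, list[DoseEffectPoint]] = {}
    for p in points:
        by_trial.setdefault(p.trial_id, []).append(p)
    return {
        t: fit_median_effect(
            pts, drug_label=drug_label, exclude_clipped=exclude_clipped
        )
        for t, pts in sorted(by_trial.items())
    }


# ---------------------------------------------------------------------------
# Model evaluation
# ---------------------------------------------------------------------------

def effect_at_dose(fit: MedianEffectFit, dose):
    """Affected fraction at ``dose``: ``fa = 1 / (1 + (Dm/D)**m)``.

    Strictly increasing in dose; fa -> 0 as dose -> 0+ and fa -> 1 as
    dose -> infinity.  Accepts scalars or arrays of positive doses.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose <= 0):
        raise DomainError("dose must be > 0")
    fa = 1.0 / (1.0 + (fit.dm / dose) ** fit.m)
    return float(fa) if fa.ndim == 0 else fa


def dose_for_effect(fit: MedianEffectFit, fa):
    """Dose producing affected fraction ``fa``: ``Dm * (fa/fu)**(1/m)``.

    Exact inverse of :func:`effect_at_dose`; strictly increasing in fa.
    """
    fa = np.asarray(fa, dtype=float)
    if np.any((fa <= 0) | (fa >= 1)):
        raise DomainError("fa must lie strictly inside (0, 1)")
    d = fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)
    return float(d) if d.ndim == 0 else d


def rescale_fit(fit: MedianEffectFit, k: float) -> MedianEffectFit:
    """The fit of the same data with all doses multiplied by ``k``."""
    if not k > 0:
        raise DomainError("scale factor must be > 0")
    return replace(fit, dm=fit.dm * k)
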