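"""Synthetic MTT plates and impedance traces with known ground truth.

Every analysis stage in this package can be exercised against data whose
generating parameters are known exactly: per-drug median-effect parameters
(Dm, m), a planted interaction level alpha, a noise model, and a seed.

The planted interaction is defined on the Loewe scale.  A mixture dose
(d_a, d_b) produces the affected fraction ``fa`` solving

    d_a / Dx_a(fa) + d_b / Dx_b(fa) = alpha,

where Dx_i(fa) is the single-agent dose of drug i producing ``fa``.  By
construction the true combination index of the resulting surface equals
``alpha`` at every achieved effect level: alpha = 1 is exact Loewe
additivity, alpha < 1 synergism, alpha > 1 antagonism.  Recovering alpha
through the fit-then-CI pipeline is therefore a closed-loop test of the
whole analysis.

All generators are pure functions of (truth, seed): rerunning with the
same truth yields byte-identical tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .combination import CombinationDesign
from .errors import DomainError
from .kinetics import CellIndexTrace
from .median_effect import MedianEffectFit, dose_for_effect, effect_at_dose

# Solver bounds for the Loewe inversion; doses whose solution falls outside
# are clipped to the bound (the well is essentially untouched / fully killed).
_FA_LO = 1e-9
_FA_HI = 1.0 - 1e-9
_BISECT_TOL = 1e-10

# Plate optics used when emitting raw absorbances alongside viability:
# vehicle wells read ~1.10 OD, media blanks ~0.10 OD.
_VEHICLE_OD = 1.10
_MEDIA_OD = 0.10


@dataclass(frozen=True)
class DrugTruth:
    """Ground-truth single-agent parameters."""

    label: str
    dm_nM: float
    m: float

    def to_fit(self) -> MedianEffectFit:
        """The exact median-effect fit this drug would yield noise-free."""
        return MedianEffectFit(
            dm=self.dm_nM, m=self.m, r=1.0, n_points=0, drug_label=self.label
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything the generator plants, for later recovery testing.

    Defaults emulate the study conditions the analysis targets: a steep
    nanomolar agent (Dm = 6 nM, m = 2) paired with a shallower, ~60-fold
    less potent one (Dm = 356 nM, m = 1); quadruplicate wells, three
    independent trials, 8-dose quarter-log (10**0.2 ~ 1.585-fold) serial
    dilutions centered on the curve's own midpoint, and Gaussian noise of
    3 viability percentage points per well.  The quarter-log series spans
    a 25-fold dose range, keeping effects inside the band where the
    linearised median-effect fit is informative.
    """

    drug_a: DrugTruth = field(default_factory=lambda: DrugTruth("RM", 6.0, 2.0))
    drug_b: DrugTruth = field(default_factory=lambda: DrugTruth("DOX", 356.0, 1.0))
    alpha: float = 1.0
    viability_sd: float = 3.0  # percentage points, per well
    absorbance_sd: float = 0.0  # OD units, per well (optional second stage)
    n_doses: int = 8
    dilution: float = 10.0 ** 0.2  # quarter-log serial dilution
    n_replicates: int = 4
    n_trials: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise DomainError("alpha must be > 0")
        if self.n_doses < 2 or self.n_replicates < 1 or self.n_trials < 1:
            raise DomainError("plate layout must be non-degenerate")

    def to_manifest(self) -> dict:
        return asdict(self)

    @classmethod
    def from_manifest(cls, d: Mapping) -> "SyntheticTruth":
        d = dict(d)
        d["drug_a"] = DrugTruth(**d["drug_a"])
        d["drug_b"] = DrugTruth(**d["drug_b"])
        return cls(**d)

    def save_manifest(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_manifest(), indent=2))

    @classmethod
    def load_manifest(cls, path) -> "SyntheticTruth":
        return cls.from_manifest(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Loewe surface
# ---------------------------------------------------------------------------

def loewe_effect(
    d_a: float,
    d_b: float,
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    alpha: float = 1.0,
) -> float:
    """Affected fraction of the dose pair on the planted-alpha Loewe surface.

    Solves ``d_a/Dx_a(fa) + d_b/Dx_b(fa) = alpha`` for ``fa`` by root
    bracketing; the left side is strictly decreasing in ``fa`` so the
    solution is unique.  Dose pairs too small (or too large) to bracket a
    root within the working interval are clipped to the corresponding
    bound.  With one dose zero and alpha = 1 this reduces exactly to the
    single drug's median-effect curve.
    """
    if alpha <= 0:
        raise DomainError("alpha must be > 0")
    if d_a < 0 or d_b < 0:
        raise DomainError("doses must be >= 0")
    if d_a + d_b == 0:
        return 0.0

    def excess(fa: float) -> float:
        s = 0.0
        if d_a > 0:
            s += d_a / dose_for_effect(fit_a, fa)
        if d_b > 0:
            s += d_b / dose_for_effect(fit_b, fa)
        return s - alpha

    if excess(_FA_LO) <= 0:  # dose below resolvable effect
        return _FA_LO
    if excess(_FA_HI) >= 0:  # dose beyond resolvable effect
        return _FA_HI
    return float(brentq(excess, _FA_LO, _FA_HI, xtol=_BISECT_TOL, maxiter=200))


def additive_ic50_total(
    fit_a: MedianEffectFit,
    fit_b: MedianEffectFit,
    fraction_a: float,
    alpha: float = 1.0,
) -> float:
    """Total mixture dose at which the planted surface reaches fa = 0.5.

    Closed form: at fa = 0.5, Dx_i = Dm_i, so
    ``D_tot = alpha / (f_a/Dm_a + f_b/Dm_b)``.  Used to center the
    constant-ratio dose series on the mixture's own IC50.
    """
    return alpha / (fraction_a / fit_a.dm + (1 - fraction_a) / fit_b.dm)


def _dose_series(center: float, n: int, dilution: float) -> np.ndarray:
    """Geometric series of n doses centered on ``center``."""
    exponents = np.arange(n) - (n - 1) / 2.0
    return center * dilution ** exponents


def _rng(truth: SyntheticTruth, tag: int, trial: int) -> np.random.Generator:
    return np.random.default_rng([truth.seed, tag, trial])


def _emit_rows(
    rng: np.random.Generator,
    truth: SyntheticTruth,
    rows: list,
    drug: str,
    dose: float,
    dose_a: float,
    dose_b: float,
    trial: int,
    fa_true: float,
    well_type: str = "treated",
) -> None:
    for rep in range(truth.n_replicates):
        v = 100.0 * (1.0 - fa_true)
        if truth.viability_sd > 0:
            v += rng.normal(0.0, truth.viability_sd)
        od = _MEDIA_OD + (_VEHICLE_OD - _MEDIA_OD) * v / 100.0
        if truth.absorbance_sd > 0:
            od += rng.normal(0.0, truth.absorbance_sd)
        rows.append(
            {
                "drug": drug,
                "dose_nM": dose,
                "dose_a_nM": dose_a,
                "dose_b_nM": dose_b,
                "trial": trial,
                "replicate": rep,
                "well_type": well_type,
                "absorbance": od,
                "viability_pct": v,
            }
        )


def _control_rows(
    rng: np.random.Generator, truth: SyntheticTruth, rows: list, trial: int
) -> None:
    _emit_rows(rng, truth, rows, "vehicle", 0.0, 0.0, 0.0, trial, 0.0, "vehicle")
    for rep in range(truth.n_replicates):
        od = _MEDIA_OD + (
            rng.normal(0.0, truth.absorbance_sd) if truth.absorbance_sd > 0 else 0.0
        )
        rows.append(
            {
                "drug": "media",
                "dose_nM": 0.0,
                "dose_a_nM": 0.0,
                "dose_b_nM": 0.0,
                "trial": trial,
                "replicate": rep,
                "well_type": "media",
                "absorbance": od,
                "viability_pct": np.nan,
            }
        )


# ---------------------------------------------------------------------------
# Plate generators
# ---------------------------------------------------------------------------

def generate_single_drug_plate(
    truth: SyntheticTruth, drug: str = "a", doses: Sequence[float] | None = None
) -> pd.DataFrame:
    """Tidy dose-viability table for one drug across all trials.

    A two-fold serial dilution centered on the drug's Dm (overridable via
    ``doses``), quadruplicate wells per dose, vehicle and media-blank
    wells per trial; per-well viability is 100*(1 - fa) plus Gaussian
    noise.  Deterministic for a fixed truth.
    """
    dt = _drug_truth(truth, drug)
    fit = dt.to_fit()
    dose_arr = (
        np.asarray(doses, dtype=float)
        if doses is not None
        else _dose_series(dt.dm_nM, truth.n_doses, truth.dilution)
    )
    tag = 1 if dt is truth.drug_a else 2
    rows: list = []
    for trial in range(truth.n_trials):
        rng = _rng(truth, tag, trial)
        for dose in dose_arr:
            fa = effect_at_dose(fit, dose)
            _emit_rows(rng, truth, rows, dt.label, dose, 0.0, 0.0, trial, fa)
        _control_rows(rng, truth, rows, trial)
    return pd.DataFrame(rows)


def generate_combination_plate(
    truth: SyntheticTruth,
    design: CombinationDesign,
    total_doses: Sequence[float] | None = None,
    schedule_alpha: Mapping[str, float] | None = None,
    include_single_controls: bool = True,
) -> pd.DataFrame:
    """Constant-ratio mixture series plus parallel single-drug controls.

    The mixture's total molar dose follows a serial dilution centered on
    the planted surface's own IC50; each total dose is split into
    components by the design ratio and the well's affected fraction is
    read off the Loewe surface with the planted alpha (optionally
    multiplied by a per-schedule factor, emulating regimen effects).
    Single-drug control series at the matching component doses are
    appended, as run alongside real combination plates.
    """
    fit_a = truth.drug_a.to_fit()
    fit_b = truth.drug_b.to_fit()
    alpha = truth.alpha
    if schedule_alpha is not None:
        alpha *= float(schedule_alpha.get(design.schedule, 1.0))
    f_a = design.fraction_a
    if total_doses is None:
        center = additive_ic50_total(fit_a, fit_b, f_a, alpha)
        total_doses = _dose_series(center, truth.n_doses, truth.dilution)
    total_doses = np.asarray(total_doses, dtype=float)

    combo_label = f"{truth.drug_a.label}+{truth.drug_b.label}"
    rows: list = []
    for trial in range(truth.n_trials):
        rng = _rng(truth, 3, trial)
        for d_tot in total_doses:
            d_a = d_tot * f_a
            d_b = d_tot * (1.0 - f_a)
            fa = loewe_effect(d_a, d_b, fit_a, fit_b, alpha)
            _emit_rows(
                rng, truth, rows, combo_label, d_tot, d_a, d_b, trial, fa
            )
        if include_single_controls:
            for dt_, dose_col in ((truth.drug_a, f_a), (truth.drug_b, 1.0 - f_a)):
                fit = dt_.to_fit()
                for d_tot in total_doses:
                    d = d_tot * dose_col
                    fa = effect_at_dose(fit, d)
                    _emit_rows(rng, truth, rows, dt_.label, d, 0.0, 0.0, trial, fa)
        _control_rows(rng, truth, rows, trial)
    return pd.DataFrame(rows)


def generate_checkerboard(
    truth: SyntheticTruth,
    doses_a: Sequence[float] | None = None,
    doses_b: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Full-factorial dose grid with zero-dose single-agent margins.

    Default grids: zero plus a 5-point two-fold dilution around each
    drug's Dm.  Cells are read off the planted Loewe surface plus noise.
    """
    fit_a = truth.drug_a.to_fit()
    fit_b = truth.drug_b.to_fit()
    if doses_a is None:
        doses_a = np.concatenate([[0.0], _dose_series(truth.drug_a.dm_nM, 5, 2.0)])
    if doses_b is None:
        doses_b = np.concatenate([[0.0], _dose_series(truth.drug_b.dm_nM, 5, 2.0)])
    doses_a = np.asarray(doses_a, dtype=float)
    doses_b = np.asarray(doses_b, dtype=float)
    if 0.0 not in doses_a or 0.0 not in doses_b:
        raise DomainError("checkerboard grids must include zero dose")
    rows: list = []
    for trial in range(truth.n_trials):
        rng = _rng(truth, 4, trial)
        for d_a in doses_a:
            for d_b in doses_b:
                fa = loewe_effect(d_a, d_b, fit_a, fit_b, truth.alpha)
                for rep in range(truth.n_replicates):
                    v = 100.0 * (1.0 - fa)
                    if truth.viability_sd > 0:
                        v += rng.normal(0.0, truth.viability_sd)
                    rows.append(
                        {
                            "dose_a_nM": d_a,
                            "dose_b_nM": d_b,
                            "trial": trial,
                            "replicate": rep,
                            "viability_pct": v,
                        }
                    )
    return pd.DataFrame(rows)


def checkerboard_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a tidy checkerboard table to a mean-viability dose matrix."""
    return table.pivot_table(
        index="dose_a_nM", columns="dose_b_nM", values="viability_pct", aggfunc="mean"
    )


# ---------------------------------------------------------------------------
# Impedance (RTCA) trace generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KineticTruth:
    """Ground truth for synthetic cell-index traces.

    ``mode`` selects the survival model applied after treatment:

    ``logistic_kill``
        Survival at time t' post-treatment is a variable-slope sigmoid in
        dose, ``1 / (1 + (d / IC50(t'))**hill)`` with
        ``IC50(t') = ic50_ref * t_ref / t'`` — the half-kill dose falls as
        the reciprocal of exposure time (dose x time reciprocity), so the
        time-resolved IC50 is strictly decreasing and each time slice is
        an exact four-parameter logistic.
    ``direct_kill``
        Exponential kill, ``exp(-kill_rate * d**hill * t')``: monotone
        decline, no rise above vehicle.
    ``senescence``
        Kill as in direct_kill but delayed by ``kill_lag_h``, multiplied
        by a transient cell-size bump (Gaussian in time) that pushes the
        index above the vehicle before the decline — the DNA-damage-like
        signature of agents whose targets enlarge and flatten cells
        before killing them.
    """

    mode: str = "logistic_kill"
    doses: tuple[float, ...] = (6.25, 12.5, 25.0, 50.0, 100.0, 200.0, 400.0)
    t_treat: float = 24.0
    t_end: float = 168.0
    dt: float = 0.5
    growth_rate: float = 0.04  # 1/h logistic growth of the vehicle
    capacity: float = 6.0  # plateau of the normalized vehicle index
    ic50_ref: float = 50.0  # nM at t_ref post-treatment (logistic_kill)
    t_ref: float = 72.0  # h post-treatment
    hill: float = 2.0
    kill_rate: float = 1e-5  # 1/(h * nM**hill) (direct_kill / senescence)
    kill_lag_h: float = 36.0  # senescence mode: kill starts after the bump
    bump_amplitude: float = 0.8
    bump_peak_h: float = 24.0  # h post-treatment
    bump_width_h: float = 10.0
    noise_sd: float = 0.0  # relative, per sample
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("logistic_kill", "direct_kill", "senescence"):
            raise DomainError(f"unknown kinetic mode {self.mode!r}")


def _survival(kt: KineticTruth, dose: float, t_post: np.ndarray) -> np.ndarray:
    if dose == 0:
        return np.ones_like(t_post)
    if kt.mode == "logistic_kill":
        with np.errstate(divide="ignore"):
            ic50_t = np.where(t_post > 0, kt.ic50_ref * kt.t_ref / t_post, np.inf)
        return 1.0 / (1.0 + (dose / ic50_t) ** kt.hill)
    if kt.mode == "senescence":
        kill = np.exp(
            -kt.kill_rate
            * dose ** kt.hill
            * np.maximum(t_post - kt.kill_lag_h, 0.0)
        )
        bump = 1.0 + kt.bump_amplitude * (dose / (dose + kt.ic50_ref)) * np.exp(
            -((t_post - kt.bump_peak_h) ** 2) / (2.0 * kt.bump_width_h ** 2)
        )
        return kill * bump
    return np.exp(-kt.kill_rate * dose ** kt.hill * np.maximum(t_post, 0.0))


def generate_rtca_traces(
    truth: SyntheticTruth, kinetic: KineticTruth
) -> list[CellIndexTrace]:
    """Raw (unnormalized) cell-index traces: a logistic-growth vehicle and
    drugged wells whose growth is multiplied by the mode's survival term.

    The vehicle (dose 0) is always included; a zero-dose drugged well is
    identical to the vehicle.  Normalize with
    :func:`drugcombo.kinetics.normalize_cell_index` at ``kinetic.t_treat``.
    """
    times = np.arange(0.0, kinetic.t_end + kinetic.dt / 2, kinetic.dt)
    t_post = times - kinetic.t_treat
    # logistic growth toward the capacity, passing 1.0 at treatment time
    k = kinetic.capacity
    g = kinetic.growth_rate
    base = k / (1.0 + (k - 1.0) * np.exp(-g * t_post))  # equals 1 at t_treat

    traces: list[CellIndexTrace] = []
    all_doses = (0.0,) + tuple(kinetic.doses)
    for dose in all_doses:
        surv = np.where(t_post > 0, _survival(kinetic, dose, t_post), 1.0)
        for rep in range(kinetic.n_replicates):
            ci = base * surv
            if kinetic.noise_sd > 0:
                rng = np.random.default_rng(
                    [truth.seed, kinetic.seed, 5, int(dose * 1000), rep]
                )
                ci = ci * (1.0 + rng.normal(0.0, kinetic.noise_sd, ci.shape))
            traces.append(
                CellIndexTrace(
                    times=times,
                    cell_index=ci,
                    drug="vehicle" if dose == 0 else truth.drug_a.label,
                    dose_nM=dose,
                    replicate=rep,
                )
            )
    return traces


def _drug_truth(truth: SyntheticTruth, drug: str) -> DrugTruth:
    if drug in ("a", truth.drug_a.label):
        return truth.drug_a
    if drug in ("b", truth.drug_b.label):
        return truth.drug_b
    raise DomainError(f"unknown drug {drug!r}")
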