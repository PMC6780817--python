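"""File I/O and report assembly behind the command-line interface.

CSV dialect: comma-separated, UTF-8, '.' decimal, header required; doses
in nM.  The tidy viability table carries columns
``drug, dose_nM, trial, replicate, viability_pct`` (absorbance-mode tables
instead carry ``absorbance`` plus per-plate ``vehicle``/``media`` control
rows in ``well_type``).  Reports never silently drop failed fits: rows
that could not be analysed carry a ``status`` column.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import AnalysisConfig
from .errors import DrugComboError
from .combination import (
    CIProfile,
    CombinationDesign,
    ci_summary_report,
    combination_index,
    isobologram,
)
from .median_effect import MedianEffectFit, fit_trials, points_from_table

VIABILITY_COLUMNS = {"drug", "dose_nM", "trial", "replicate", "viability_pct"}


class MalformedInputError(DrugComboError):
    """Input file unreadable or missing required columns."""


def read_viability_csv(path) -> pd.DataFrame:
    """Read a tidy dose-viability CSV, deriving viability from absorbance
    when only raw optical densities are present."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as e:
        raise MalformedInputError(f"{path}: {e}") from e
    if "viability_pct" not in df.columns and "absorbance" in df.columns:
        df = _viability_from_plate(df, path)
    missing = VIABILITY_COLUMNS - set(df.columns)
    if missing:
        raise MalformedInputError(
            f"{path}: missing required column(s) {sorted(missing)} "
            f"(line 1: header is {list(df.columns)})"
        )
    return df


def _viability_from_plate(df: pd.DataFrame, path: Path) -> pd.DataFrame:
    from .median_effect import viability_from_absorbance

    if "well_type" not in df.columns:
        raise MalformedInputError(
            f"{path}: absorbance-mode table needs a well_type column "
            "with vehicle and media control rows"
        )
    out = []
    group_cols = ["trial"] if "trial" in df.columns else []
    for _, grp in df.groupby(group_cols) if group_cols else [((), df)]:
        vehicle = grp.loc[grp.well_type == "vehicle", "absorbance"].mean()
        media = grp.loc[grp.well_type == "media", "absorbance"].mean()
        treated = grp[grp.well_type == "treated"].copy()
        treated["viability_pct"] = viability_from_absorbance(
            treated["absorbance"].to_numpy(), vehicle, media
        )
        out.append(treated)
    return pd.concat(out, ignore_index=True)


def fit_report(table: pd.DataFrame, config: AnalysisConfig) -> pd.DataFrame:
    """Per-drug, per-trial median-effect fits from a tidy table.

    Failed fits are reported as rows with ``status`` describing the
    failure rather than being dropped.
    """
    rows = []
    for drug, sub in table.groupby("drug", sort=True):
        if drug in ("vehicle", "media"):
            continue
        points = points_from_table(
            sub, eps=config.clip_eps, clip_policy=config.clip_policy
        )
        by_trial: dict[int, list] = {}
        for p in points:
            by_trial.setdefault(p.trial_id, []).append(p)
        for trial, pts in sorted(by_trial.items()):
            try:
                fit = fit_trials(pts, drug_label=str(drug))[trial]
                rows.append(
                    {"trial": trial, "status": "ok", **fit.to_dict()}
                )
            except DrugComboError as e:
                rows.append(
                    {
                        "trial": trial,
                        "status": f"failed: {e}",
                        "drug_label": str(drug),
                        "Dm": None,
                        "m": None,
                        "r": None,
                        "n_points": len(pts),
                    }
                )
    return pd.DataFrame(rows)


def median_effect_plot_table(
    table: pd.DataFrame, config: AnalysisConfig
) -> pd.DataFrame:
    """Tidy coordinates of the median-effect plot for external plotting."""
    import numpy as np

    rows = []
    for drug, sub in table.groupby("drug", sort=True):
        if drug in ("vehicle", "media"):
            continue
        for p in points_from_table(
            sub, eps=config.clip_eps, clip_policy=config.clip_policy
        ):
            rows.append(
                {
                    "drug": str(drug),
                    "trial": p.trial_id,
                    "replicate": p.replicate_id,
                    "log10_dose": np.log10(p.dose),
                    "log10_fa_over_fu": np.log10(p.fa / (1 - p.fa)),
                    "clipped": p.clipped,
                }
            )
    return pd.DataFrame(rows)


def fits_by_trial(
    table: pd.DataFrame, drug: str, config: AnalysisConfig
) -> list[MedianEffectFit]:
    """Trial-ordered fits for one drug label, for CI profiling."""
    sub = table[table["drug"] == drug]
    if sub.empty:
        raise MalformedInputError(f"no rows for drug {drug!r}")
    points = points_from_table(
        sub, eps=config.clip_eps, clip_policy=config.clip_policy
    )
    fits = fit_trials(points, drug_label=drug)
    return [fits[t] for t in sorted(fits)]


def ci_profile_from_tables(
    table: pd.DataFrame,
    design: CombinationDesign,
    config: AnalysisConfig,
    combo_label: str | None = None,
) -> CIProfile:
    """Full CI pipeline from one tidy table holding the mixture series and
    its parallel single-agent controls (as the combination generator and
    the standard plate layout produce)."""
    if combo_label is None:
        combo_label = f"{design.drug_a_label}+{design.drug_b_label}"
    fits_a = fits_by_trial(table, design.drug_a_label, config)
    fits_b = fits_by_trial(table, design.drug_b_label, config)
    fits_c = fits_by_trial(table, combo_label, config)
    return combination_index(
        fits_a,
        fits_b,
        fits_c,
        design,
        fa_levels=config.fa_levels,
        additivity_band=config.additivity_band,
    )


def isobologram_table(
    table: pd.DataFrame,
    designs: list[CombinationDesign],
    fa: float,
    config: AnalysisConfig,
) -> pd.DataFrame:
    """Tidy isobole coordinates at one effect level across designs."""
    frames = []
    for design in designs:
        combo_label = f"{design.drug_a_label}+{design.drug_b_label}"
        fits_a = fits_by_trial(table, design.drug_a_label, config)
        fits_b = fits_by_trial(table, design.drug_b_label, config)
        fits_c = fits_by_trial(table, combo_label, config)
        # mean-parameter isobole: use the per-trial geometric means
        import numpy as np

        def _pool(fits):
            return MedianEffectFit(
                dm=float(np.exp(np.mean([np.log(f.dm) for f in fits]))),
                m=float(np.mean([f.m for f in fits])),
                r=float(np.mean([f.r for f in fits])),
                n_points=sum(f.n_points for f in fits),
                drug_label=fits[0].drug_label,
            )

        iso = isobologram(
            _pool(fits_a), _pool(fits_b), [(_pool(fits_c), design)], fa
        )
        frame = iso.to_frame()
        frame["ratio"] = design.ratio_text
        frame["schedule"] = design.schedule
        frames.append(frame)
    return pd.concat(frames, ignore_index=True)


def write_fits_json(fits: pd.DataFrame, path) -> None:
    Path(path).write_text(json.dumps(fits.to_dict(orient="records"), indent=2))


def write_ci_report(profiles: list[CIProfile], path_csv, path_json=None) -> None:
    report = ci_summary_report(profiles)
    report.to_csv(path_csv, index=False)
    if path_json is not None:
        Path(path_json).write_text(
            json.dumps(report.to_dict(orient="records"), indent=2)
        )
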