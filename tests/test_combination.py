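"""Combination index, DRI, isobologram, curve shift, reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import drugcombo as dc
from drugcombo import reporting
from conftest import full_experiment_table


class TestShamCombination:
    """A drug combined with itself must give CI = 1 at every effect level,
    whatever its potency, slope or the mixing ratio."""

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        dm=st.floats(1e-2, 1e4),
        m=st.floats(0.3, 6.0),
        ratio_a=st.integers(1, 100),
        ratio_b=st.integers(1, 100),
        fa=st.floats(0.01, 0.99),
    )
    def test_sham_identity(self, dm, m, ratio_a, ratio_b, fa):
        fit = dc.MedianEffectFit(dm=dm, m=m)
        design = dc.CombinationDesign("self", "self2", ratio_a, ratio_b)
        ci = dc.combination_index_at(fit, fit, fit, design, fa)
        assert ci == pytest.approx(1.0, abs=1e-6)

    def test_sham_dri_is_two_at_one_to_one(self, rm_fit):
        design = dc.CombinationDesign("x", "y", 1, 1)
        fit = dc.MedianEffectFit(dm=rm_fit.dm, m=rm_fit.m)
        dri = dc.dose_reduction_index(fit, fit, fit, design, 0.5)
        assert dri.dri_a == pytest.approx(2.0, abs=1e-9)
        assert dri.dri_b == pytest.approx(2.0, abs=1e-9)


class TestCombinationIndex:
    def test_additive_equal_slope_pair_gives_ci_one(
        self, equal_slope_truth, design_1_60, cfg
    ):
        """Loewe-additive data from an equal-slope pair is itself a
        median-effect curve, so the fitted CI is exactly the null."""
        table = full_experiment_table(equal_slope_truth, design_1_60)
        profile = reporting.ci_profile_from_tables(table, design_1_60, cfg)
        assert np.allclose(profile.ci_mean, 1.0, atol=0.01)
        assert all(c == "additivity" for c in profile.classification)

    def test_planted_synergy_recovered(self, design_1_60, cfg):
        truth = dc.SyntheticTruth(alpha=0.5, viability_sd=0.0, n_trials=1)
        table = full_experiment_table(truth, design_1_60)
        profile = reporting.ci_profile_from_tables(table, design_1_60, cfg)
        ci50 = profile.ci_mean[list(profile.fa_levels).index(0.5)]
        assert 0.45 <= ci50 <= 0.55

    def test_per_trial_sem(self, design_1_60, cfg):
        truth = dc.SyntheticTruth(alpha=1.0, viability_sd=3.0, n_trials=3, seed=11)
        table = full_experiment_table(truth, design_1_60)
        profile = reporting.ci_profile_from_tables(table, design_1_60, cfg)
        assert profile.ci_per_trial.shape == (3, 4)
        assert np.all(profile.ci_sem >= 0)
        # SEM consistent with the per-trial spread
        expect = profile.ci_per_trial.std(axis=0, ddof=1) / np.sqrt(3)
        assert np.allclose(profile.ci_sem, expect)

    def test_label_mismatch_rejected(self, rm_fit, dox_fit):
        design = dc.CombinationDesign("OTHER", "DOX", 1, 60)
        with pytest.raises(dc.LabelMismatchError):
            dc.combination_index_at(rm_fit, dox_fit, dox_fit, design, 0.5)

    def test_fa_outside_unit_interval_rejected(self, rm_fit, dox_fit, design_1_60):
        with pytest.raises(dc.DomainError):
            dc.combination_index_at(rm_fit, dox_fit, dox_fit, design_1_60, 1.0)

    def test_ci_decreasing_when_combo_steeper_and_additive_at_midpoint(
        self, rm_fit, dox_fit, design_1_60
    ):
        """Steeper mixture curve calibrated additive at fa=0.5 yields CI
        falling monotonically toward high inhibition levels — synergism
        emerging at >= 90% inhibition."""
        d50_tot = dc.additive_ic50_total(rm_fit, dox_fit, design_1_60.fraction_a)
        combo = dc.MedianEffectFit(dm=d50_tot, m=2.5)  # steeper than both
        fas = np.linspace(0.5, 0.95, 10)
        cis = [
            dc.combination_index_at(rm_fit, dox_fit, combo, design_1_60, fa)
            for fa in fas
        ]
        assert cis[0] == pytest.approx(1.0, rel=1e-9)
        assert np.all(np.diff(cis) < 0)
        assert cis[-1] < 0.9  # synergistic by IC95


class TestClassification:
    @pytest.mark.parametrize(
        "ci,label",
        [
            (0.524, "synergism"),
            (1.000, "additivity"),
            (1.974, "antagonism"),
            (0.90, "additivity"),  # band edges inclusive
            (1.10, "additivity"),
        ],
    )
    def test_default_band(self, ci, label):
        assert dc.classify_ci(ci) == label

    def test_nonpositive_ci_rejected(self):
        with pytest.raises(dc.DomainError):
            dc.classify_ci(0.0)

    def test_custom_band(self):
        assert dc.classify_ci(0.85, (0.8, 1.2)) == "additivity"


class TestDoseReductionIndex:
    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        dm_a=st.floats(1e-2, 1e3),
        m_a=st.floats(0.3, 5.0),
        dm_b=st.floats(1e-2, 1e3),
        m_b=st.floats(0.3, 5.0),
        dm_c=st.floats(1e-2, 1e3),
        m_c=st.floats(0.3, 5.0),
        ratio_a=st.integers(1, 100),
        ratio_b=st.integers(1, 100),
        fa=st.floats(0.02, 0.98),
    )
    def test_ci_dri_identity(
        self, dm_a, m_a, dm_b, m_b, dm_c, m_c, ratio_a, ratio_b, fa
    ):
        fit_a = dc.MedianEffectFit(dm=dm_a, m=m_a)
        fit_b = dc.MedianEffectFit(dm=dm_b, m=m_b)
        fit_c = dc.MedianEffectFit(dm=dm_c, m=m_c)
        design = dc.CombinationDesign("a", "b", ratio_a, ratio_b)
        ci = dc.combination_index_at(fit_a, fit_b, fit_c, design, fa)
        dri = dc.dose_reduction_index(fit_a, fit_b, fit_c, design, fa)
        assert abs(1 / dri.dri_a + 1 / dri.dri_b - ci) < 1e-9 * max(1.0, ci)

    def test_symmetric_synergy_doubles_sham_reduction(self):
        """Planted alpha=0.5, identical drugs, 1:1 ratio: the mixture curve
        is the single-agent curve shifted to half dose, so each component
        needs a quarter of its single-agent dose (DRI = 4)."""
        fit = dc.MedianEffectFit(dm=10.0, m=2.0)
        design = dc.CombinationDesign("a", "b", 1, 1)
        # oracle: generate the alpha=0.5 surface and fit the mixture
        truth = dc.SyntheticTruth(
            drug_a=dc.DrugTruth("a", 10.0, 2.0),
            drug_b=dc.DrugTruth("b", 10.0, 2.0),
            alpha=0.5,
            viability_sd=0.0,
            n_trials=1,
        )
        table = dc.generate_combination_plate(
            truth, design, include_single_controls=False
        )
        pts = dc.points_from_table(table[table.drug == "a+b"])
        fit_c = dc.fit_median_effect(pts)
        dri = dc.dose_reduction_index(fit, fit, fit_c, design, 0.5)
        assert dri.dri_a == pytest.approx(4.0, rel=1e-3)
        assert dri.dri_b == pytest.approx(4.0, rel=1e-3)


class TestIsobologram:
    def test_intercept_closed_form(self, rm_fit, dox_fit, design_1_60):
        combo = dc.MedianEffectFit(
            dm=dc.additive_ic50_total(rm_fit, dox_fit, design_1_60.fraction_a),
            m=1.5,
        )
        iso = dc.isobologram(rm_fit, dox_fit, [(combo, design_1_60)], 0.95)
        assert iso.dx_a == pytest.approx(26.153, abs=5e-3)

    def test_normalized_sum_equals_ci(self, rm_fit, dox_fit, design_1_60):
        combo = dc.MedianEffectFit(dm=150.0, m=1.4)
        for fa in (0.5, 0.75, 0.9, 0.95):
            iso = dc.isobologram(rm_fit, dox_fit, [(combo, design_1_60)], fa)
            ci = dc.combination_index_at(rm_fit, dox_fit, combo, design_1_60, fa)
            assert iso.normalized_sums[0] == pytest.approx(ci, abs=1e-9)

    def test_additive_point_on_segment_and_synergy_below(
        self, equal_slope_truth, design_1_60, cfg
    ):
        table = full_experiment_table(equal_slope_truth, design_1_60)
        fits_a = reporting.fits_by_trial(table, "RM", cfg)
        fits_b = reporting.fits_by_trial(table, "DOX", cfg)
        fits_c = reporting.fits_by_trial(table, "RM+DOX", cfg)
        iso = dc.isobologram(
            fits_a[0], fits_b[0], [(fits_c[0], design_1_60)], 0.95
        )
        assert iso.normalized_sums[0] == pytest.approx(1.0, abs=0.01)

        import dataclasses

        syn = dataclasses.replace(equal_slope_truth, alpha=0.5)
        table = full_experiment_table(syn, design_1_60)
        fits_c = reporting.fits_by_trial(table, "RM+DOX", cfg)
        fits_a = reporting.fits_by_trial(table, "RM", cfg)
        fits_b = reporting.fits_by_trial(table, "DOX", cfg)
        iso = dc.isobologram(
            fits_a[0], fits_b[0], [(fits_c[0], design_1_60)], 0.95
        )
        assert iso.normalized_sums[0] == pytest.approx(0.5, abs=0.01)

    def test_fa_domain(self, rm_fit, dox_fit):
        with pytest.raises(dc.DomainError):
            dc.isobologram(rm_fit, dox_fit, [], 0.0)


class TestCurveShift:
    def test_ratio_split_arithmetic(self, rm_fit, dox_fit):
        design = dc.CombinationDesign("RM", "DOX", 1, 50)
        pts = pd.DataFrame({"dose_nM": [318.75], "viability_pct": [40.0]})
        table = dc.curve_shift_table(rm_fit, dox_fit, pts, design)
        assert table.loc[0, "dose_a_nM"] == pytest.approx(6.25)
        assert table.loc[0, "dose_b_nM"] == pytest.approx(312.5)
        assert table.loc[0, "viability_combo_pct"] == 40.0

    def test_synergistic_mixture_shifts_left(self, design_1_60, cfg):
        truth = dc.SyntheticTruth(alpha=0.5, viability_sd=0.0, n_trials=1)
        table = dc.generate_combination_plate(
            truth, design_1_60, include_single_controls=False
        )
        combo = table[table.drug == "RM+DOX"]
        shift = dc.curve_shift_table(
            truth.drug_a.to_fit(), truth.drug_b.to_fit(), combo, design_1_60
        )
        mid = shift[
            (shift.viability_combo_pct > 20) & (shift.viability_combo_pct < 80)
        ]
        assert len(mid) > 0
        # synergy: the mixture kills more at each component dose than the
        # single agent would at that same dose
        assert (mid.viability_combo_pct < mid.viability_single_a_pct).all()
        assert (mid.viability_combo_pct < mid.viability_single_b_pct).all()

    def test_degenerate_ratio_reproduces_single_agent(self, rm_fit, dox_fit):
        design = dc.CombinationDesign("RM", "DOX", 1, 0)
        doses = np.array([2.0, 6.0, 18.0])
        via = 100 * (1 - 1 / (1 + (6.0 / doses) ** 2))
        pts = pd.DataFrame({"dose_nM": doses, "viability_pct": via})
        table = dc.curve_shift_table(rm_fit, dox_fit, pts, design)
        assert np.allclose(table.dose_a_nM, doses)
        assert np.allclose(table.dose_b_nM, 0.0)
        assert np.allclose(
            table.viability_combo_pct, table.viability_single_a_pct, atol=1e-9
        )


class TestPotencyRatio:
    def test_printed_ic50s_give_one_to_sixty(self, rm_fit, dox_fit):
        ratio, equip = dc.potency_ratio(rm_fit, dox_fit)
        assert ratio == pytest.approx(59.33, abs=0.01)
        assert equip == (1, 60)

    def test_identical_fits(self, rm_fit):
        ratio, equip = dc.potency_ratio(rm_fit, rm_fit)
        assert ratio == 1.0 and equip == (1, 1)

    def test_round_half_up_at_tens(self, rm_fit):
        other = dc.MedianEffectFit(dm=rm_fit.dm * 44.9, m=1.0)
        assert dc.potency_ratio(rm_fit, other)[1] == (1, 40)
        other = dc.MedianEffectFit(dm=rm_fit.dm * 45.0, m=1.0)
        assert dc.potency_ratio(rm_fit, other)[1] == (1, 50)

    def test_nearest_int_rule(self, rm_fit):
        other = dc.MedianEffectFit(dm=rm_fit.dm * 44.9, m=1.0)
        assert dc.potency_ratio(rm_fit, other, rounding="nearest_int")[1] == (1, 45)


class TestSummaryReport:
    def test_single_additive_profile(self, equal_slope_truth, design_1_60, cfg):
        table = full_experiment_table(equal_slope_truth, design_1_60)
        profile = reporting.ci_profile_from_tables(table, design_1_60, cfg)
        report = dc.ci_summary_report([profile])
        assert len(report) == 1
        assert all(
            report.loc[0, c] == "additivity"
            for c in report.columns
            if c.startswith("class@")
        )

    def test_schedule_alpha_modulation_reproduces_regimen_ordering(self, cfg):
        """Planted interaction 0.6/1.0/1.6 across the three schedules comes
        back as synergism / additivity / antagonism rows, in schedule order."""
        profiles = []
        for schedule, alpha in (
            ("simultaneous", 0.6),
            ("a_then_b", 1.0),
            ("b_then_a", 1.6),
        ):
            design = dc.CombinationDesign("RM", "DOX", 1, 60, schedule=schedule)
            truth = dc.SyntheticTruth(
                drug_a=dc.DrugTruth("RM", 6.0, 2.0),
                drug_b=dc.DrugTruth("DOX", 356.0, 2.0),
                alpha=1.0,
                viability_sd=0.0,
                n_trials=1,
            )
            table = pd.concat(
                [
                    dc.generate_single_drug_plate(truth, "a"),
                    dc.generate_single_drug_plate(truth, "b"),
                    dc.generate_combination_plate(
                        truth,
                        design,
                        include_single_controls=False,
                        schedule_alpha={
                            "simultaneous": 0.6,
                            "a_then_b": 1.0,
                            "b_then_a": 1.6,
                        },
                    ),
                ],
                ignore_index=True,
            )
            profiles.append(reporting.ci_profile_from_tables(table, design, cfg))
        report = dc.ci_summary_report(profiles)
        assert list(report["schedule"]) == ["simultaneous", "a_then_b", "b_then_a"]
        assert report.loc[0, "class@IC50"] == "synergism"
        assert report.loc[1, "class@IC50"] == "additivity"
        assert report.loc[2, "class@IC50"] == "antagonism"

    def test_empty_profiles_rejected(self):
        with pytest.raises(dc.DomainError):
            dc.ci_summary_report([])


class TestCheckerboard:
    def test_inert_drug_b_gives_zero_differences(self):
        doses_a = [0.0, 1.0, 2.0]
        doses_b = [0.0, 10.0]
        via = {0.0: 100.0, 1.0: 70.0, 2.0: 40.0}
        matrix = pd.DataFrame(
            {db: [via[da] for da in doses_a] for db in doses_b}, index=doses_a
        )
        summary = dc.checkerboard_summary(matrix)
        assert np.allclose(summary["diff_vs_a_alone"], 0.0)
        assert not summary["enhanced"].any()

    def test_planted_synergy_flags_interior_cells(self):
        truth = dc.SyntheticTruth(alpha=0.5, viability_sd=0.0, n_trials=1)
        grid = dc.generate_checkerboard(truth)
        summary = dc.checkerboard_summary(dc.checkerboard_matrix(grid))
        interior = summary[(summary.dose_a_nM > 0) & (summary.dose_b_nM > 0)]
        assert interior["enhanced"].mean() > 0.5

    def test_missing_margins_rejected(self):
        matrix = pd.DataFrame({10.0: [50.0], 20.0: [30.0]}, index=[5.0])
        with pytest.raises(dc.DegenerateDesignError):
            dc.checkerboard_summary(matrix)

    def test_one_by_one_grid_rejected(self):
        matrix = pd.DataFrame({0.0: [100.0]}, index=[0.0])
        with pytest.raises(dc.DegenerateDesignError):
            dc.checkerboard_summary(matrix)
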