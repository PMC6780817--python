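import numpy as np
import pandas as pd
import pytest

import drugcombo as dc


@pytest.fixture
def cfg():
    return dc.AnalysisConfig()


@pytest.fixture
def rm_fit():
    """Steep nanomolar agent (the study's more potent drug)."""
    return dc.MedianEffectFit(dm=6.0, m=2.0, drug_label="RM")


@pytest.fixture
def dox_fit():
    """Shallow, ~60-fold less potent agent."""
    return dc.MedianEffectFit(dm=356.0, m=1.0, drug_label="DOX")


@pytest.fixture
def design_1_60():
    return dc.CombinationDesign("RM", "DOX", 1, 60)


@pytest.fixture
def equal_slope_truth():
    """Drug pair sharing a slope: the constant-ratio Loewe-additive mixture
    is then itself a median-effect curve, so CI identities are exact."""
    return dc.SyntheticTruth(
        drug_a=dc.DrugTruth("RM", 6.0, 2.0),
        drug_b=dc.DrugTruth("DOX", 356.0, 2.0),
        alpha=1.0,
        viability_sd=0.0,
        n_trials=1,
    )


def loewe_fa_bisect(d_a, d_b, fit_a, fit_b, alpha, tol=1e-12):
    """Independent bisection oracle for the planted-interaction surface:
    solves d_a/Dx_a(fa) + d_b/Dx_b(fa) = alpha on (lo, hi) by halving."""
    def excess(fa):
        s = 0.0
        if d_a > 0:
            s += d_a / (fit_a.dm * (fa / (1 - fa)) ** (1 / fit_a.m))
        if d_b > 0:
            s += d_b / (fit_b.dm * (fa / (1 - fa)) ** (1 / fit_b.m))
        return s - alpha

    lo, hi = 1e-9, 1 - 1e-9
    if excess(lo) <= 0:
        return lo
    if excess(hi) >= 0:
        return hi
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if excess(mid) > 0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def full_experiment_table(truth, design):
    """Single-agent plates for both drugs plus the constant-ratio mixture
    series, concatenated as one tidy table — the layout of a complete
    combination experiment."""
    return pd.concat(
        [
            dc.generate_single_drug_plate(truth, "a"),
            dc.generate_single_drug_plate(truth, "b"),
            dc.generate_combination_plate(
                truth, design, include_single_controls=False
            ),
        ],
        ignore_index=True,
    )
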