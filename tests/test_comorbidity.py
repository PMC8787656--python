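"""Screening cutoffs, risk ratios, group contrasts, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bsmaskit import comorbidity as cm


@pytest.mark.parametrize(
    "score, instrument, expected",
    [
        (16, "depression", True),   # the screening threshold itself is a case
        (15, "depression", False),
        (0, "depression", False),
        (40, "anxiety", True),
        (39, "anxiety", False),
    ],
)
def test_probable_case_cutoffs(score, instrument, expected):
    assert cm.probable_case(np.array([score]), instrument)[0] == expected


def test_probable_case_monotone_in_score():
    dep = cm.probable_case(np.arange(0, 61), "depression")
    assert (np.diff(dep.astype(int)) >= 0).all()


def test_probable_case_validates_range_and_instrument():
    with pytest.raises(ValueError, match="out of range"):
        cm.probable_case(np.array([61]), "depression")
    with pytest.raises(ValueError, match="out of range"):
        cm.probable_case(np.array([10]), "anxiety")
    with pytest.raises(ValueError, match="instrument"):
        cm.probable_case(np.array([30]), "stress")


def _binary(events, size):
    out = np.zeros(size, dtype=bool)
    out[:events] = True
    return out


def test_risk_ratio_reference_values():
    exposure = np.r_[np.ones(20, bool), np.zeros(20, bool)]
    outcome = np.r_[_binary(10, 20), _binary(5, 20)]
    res = cm.risk_ratio(exposure, outcome)
    assert res.rr == pytest.approx(2.0)
    assert (res.exposed_events, res.exposed_n) == (10, 20)

    equal = np.r_[_binary(5, 20), _binary(5, 20)]
    assert cm.risk_ratio(exposure, equal).rr == pytest.approx(1.0)


def test_risk_ratio_not_computable_states():
    exposure = np.r_[np.ones(10, bool), np.zeros(10, bool)]
    no_ref_events = np.r_[_binary(5, 10), _binary(0, 10)]
    assert not cm.risk_ratio(exposure, no_ref_events).computable
    all_exposed = np.ones(20, bool)
    assert not cm.risk_ratio(all_exposed, no_ref_events).computable


@settings(max_examples=100, deadline=None, derandomize=True)
@given(st.integers(1, 50), st.integers(1, 50), st.integers(1, 50), st.integers(1, 50))
def test_risk_ratio_invariant_under_count_scaling(a, n1, c, n0):
    a, c = min(a, n1), min(c, n0)
    exposure = np.r_[np.ones(n1, bool), np.zeros(n0, bool)]
    outcome = np.r_[_binary(a, n1), _binary(c, n0)]
    single = cm.risk_ratio(exposure, outcome)
    doubled = cm.risk_ratio(np.r_[exposure, exposure], np.r_[outcome, outcome])
    if single.computable:
        assert doubled.rr == pytest.approx(single.rr)
    else:
        assert not doubled.computable


def test_item_level_rr_constant_item_not_computable():
    rng = np.random.default_rng(0)
    ratings = rng.integers(1, 6, size=(200, 6))
    ratings[:, 2] = 5  # everyone "exposed" on mood modification
    outcome = rng.random(200) < 0.3
    table = cm.item_level_rr(ratings, 4, outcome)
    assert np.isnan(table.loc["mood_modification", "rr"])


def test_item_level_rr_ranks_planted_withdrawal_effect_first():
    rng = np.random.default_rng(42)
    ratings = rng.integers(1, 6, size=(5000, 6))
    exposed = ratings[:, 4] >= 4  # withdrawal criterion drives the outcome
    outcome = rng.random(5000) < np.where(exposed, 0.45, 0.10)
    table = cm.item_level_rr(ratings, 4, outcome)
    assert table["rr"].idxmax() == "withdrawal"
    assert table.loc["withdrawal", "rr"] > 3


def test_item_level_rr_null_stays_near_one():
    rng = np.random.default_rng(7)
    ratings = rng.integers(1, 6, size=(5000, 6))
    outcome = rng.random(5000) < 0.25
    for cutoff in (3, 4):
        rr = cm.item_level_rr(ratings, cutoff, outcome)["rr"]
        assert ((rr > 0.8) & (rr < 1.25)).all()


def test_group_comparison_identical_groups():
    scores = np.r_[np.arange(50.0), np.arange(50.0)]
    groups = np.r_[np.ones(50, bool), np.zeros(50, bool)]
    res = cm.group_comparison(scores, groups)
    assert res.t == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(0.5)


def test_group_comparison_detects_one_sided_shift():
    rng = np.random.default_rng(1)
    rest = rng.normal(16, 10, 400)
    high = rng.normal(26, 10, 100)  # +1 sd shift
    groups = np.r_[np.ones(100, bool), np.zeros(400, bool)]
    up = cm.group_comparison(np.r_[high, rest], groups)
    assert up.p_value < 0.001
    down = cm.group_comparison(np.r_[rest[:100] - 10, rest], groups)
    assert down.p_value > 0.5  # shift in the untested direction


def test_group_comparison_small_group_not_computable():
    res = cm.group_comparison(np.arange(10.0), np.r_[True, np.zeros(9, bool)])
    assert not res.computable


def test_welch_and_pooled_decisions_agree_on_balanced_equal_variances():
    from scipy import stats

    agree = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 100), rng.normal(0.3, 1, 100)
        groups = np.r_[np.ones(100, bool), np.zeros(100, bool)]
        welch = cm.group_comparison(np.r_[a, b], groups)
        _, p_pooled = stats.ttest_ind(a, b, equal_var=True, alternative="greater")
        agree += (welch.p_value < 0.05) == (p_pooled < 0.05)
    assert agree == 10


def test_cronbach_alpha_reference_points():
    rng = np.random.default_rng(0)
    base = rng.normal(0, 1, 500)
    duplicated = np.tile(base[:, None], (1, 6))
    assert cm.cronbach_alpha(duplicated) == pytest.approx(1.0)

    independent = rng.normal(0, 1, (5000, 6))
    assert abs(cm.cronbach_alpha(independent)) < 0.1

    # two equicorrelated items, rho = 0.5: alpha -> 2*rho/(1+rho) = 2/3
    cov = np.array([[1.0, 0.5], [0.5, 1.0]])
    two = rng.multivariate_normal([0, 0], cov, size=20000)
    assert cm.cronbach_alpha(two) == pytest.approx(2 / 3, abs=0.02)


def test_cronbach_alpha_degenerate_inputs():
    with pytest.raises(ValueError):
        cm.cronbach_alpha(np.ones((1, 6)))
    assert np.isnan(cm.cronbach_alpha(np.ones((10, 3))))


def test_demographic_rr_uses_reference_level():
    import pandas as pd

    factor = pd.Series(["18-34"] * 50 + ["50-65"] * 50)
    labels = np.r_[_binary(20, 50), _binary(5, 50)]
    out = cm.demographic_rr(labels, factor, "50-65")
    assert out.loc["18-34", "rr"] == pytest.approx(4.0)
    assert out.loc["50-65", "reference"]
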