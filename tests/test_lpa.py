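"""EM correctness, fit indices, tests, selection, labeling, contrasts."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bsmaskit import lpa


# ---------------------------------------------------------------------------
# fitting


def test_one_class_fit_is_closed_form(uk_ratings):
    model, post = lpa.fit_lpa(uk_ratings, 1)
    np.testing.assert_allclose(model.means[0], uk_ratings.mean(axis=0), atol=1e-12)
    np.testing.assert_allclose(model.variances, uk_ratings.var(axis=0), atol=1e-12)
    direct = stats.norm.logpdf(
        uk_ratings, uk_ratings.mean(axis=0), uk_ratings.std(axis=0)
    ).sum()
    assert abs(model.loglik - direct) < 1e-8
    assert post.shape == (len(uk_ratings), 1) and (post == 1).all()


def test_fitted_loglik_equals_direct_summation(uk_fit3, uk_ratings):
    model, _ = uk_fit3
    assert abs(model.loglik - lpa.loglik_direct(model, uk_ratings)) < 1e-8


def test_em_loglik_path_is_monotone(uk_ratings):
    """Run EM from a deliberately poor start and check the LL path directly."""
    rng = np.random.default_rng(0)
    w = np.full(3, 1 / 3)
    mu = uk_ratings[rng.choice(len(uk_ratings), 3)]
    var = uk_ratings.var(axis=0)
    result, ll_path, _ = lpa._em_run(
        uk_ratings, w, mu, var, False, 200, 1e-8, lpa.VAR_FLOOR
    )
    diffs = np.diff(ll_path)
    assert (diffs >= -1e-8).all()
    assert len(ll_path) > 5  # actually iterated


def test_two_class_parameter_recovery(separated_two_cluster):
    X, cls = separated_two_cluster
    model, _ = lpa.fit_lpa(X, 2, n_starts=10, seed=1)
    order = np.argsort(model.means.mean(axis=1))
    truth = np.array([[1.5] * 6, [4.5] * 6])
    assert np.abs(model.means[order] - truth).max() < 0.05
    true_w = np.array([1 - cls.mean(), cls.mean()])
    assert np.abs(model.weights[order] - true_w).max() < 0.02


def test_row_duplication_doubles_loglik_and_keeps_mles(separated_two_cluster):
    X, _ = separated_two_cluster
    X = X[:500]
    m1, _ = lpa.fit_lpa(X, 2, n_starts=8, seed=2)
    m2, _ = lpa.fit_lpa(np.vstack([X, X]), 2, n_starts=8, seed=2)
    o1 = np.argsort(m1.means.mean(axis=1))
    o2 = np.argsort(m2.means.mean(axis=1))
    np.testing.assert_allclose(m1.means[o1], m2.means[o2], atol=1e-3)
    np.testing.assert_allclose(m1.weights[o1], m2.weights[o2], atol=1e-3)
    np.testing.assert_allclose(m1.variances, m2.variances, atol=1e-3)
    assert abs(m2.loglik - 2 * m1.loglik) < 1e-2 * abs(m1.loglik)


def test_class_varying_fit_matches_independent_em(separated_two_cluster):
    """Cross-check against scikit-learn's diagonal Gaussian mixture, which
    implements the class-varying-variance model independently."""
    from sklearn.mixture import GaussianMixture

    X, _ = separated_two_cluster
    ours, _ = lpa.fit_lpa(X, 2, n_starts=8, seed=4, class_varying=True, tol=1e-8)
    ref = GaussianMixture(
        n_components=2, covariance_type="diag", n_init=4, tol=1e-8,
        reg_covar=1e-6, random_state=0, max_iter=500,
    ).fit(X)
    assert ours.loglik == pytest.approx(ref.score(X) * len(X), rel=1e-6)
    o, r = np.argsort(ours.means.mean(1)), np.argsort(ref.means_.mean(1))
    np.testing.assert_allclose(ours.means[o], ref.means_[r], atol=1e-3)
    np.testing.assert_allclose(ours.weights[o], ref.weights_[r], atol=1e-3)
    np.testing.assert_allclose(ours.variances[o], ref.covariances_[r], atol=1e-3)


def test_identifiability_floor_and_k_validation(uk_ratings):
    with pytest.raises(ValueError, match="n_classes"):
        lpa.fit_lpa(uk_ratings, 0)
    with pytest.raises(ValueError, match="observations"):
        lpa.fit_lpa(uk_ratings[:10], 2)


# ---------------------------------------------------------------------------
# information criteria & entropy


def test_information_criteria_closed_forms():
    # class-varying, one indicator, two classes: p = (K-1) + 2K = 5
    model = lpa.LPAModel(
        n_classes=2, weights=np.array([0.5, 0.5]), means=np.zeros((2, 1)),
        variances=np.ones((2, 1)), class_varying=True, loglik=-100.0,
        n_obs=100, converged=True, n_iter=1,
    )
    assert model.n_params == 5
    ic = lpa.information_criteria(model)
    assert ic["aic"] == pytest.approx(210.0)
    assert ic["bic"] == pytest.approx(223.0259, abs=1e-3)
    assert ic["ssabic"] == pytest.approx(207.2346, abs=1e-3)


def test_parameter_counts_by_variance_structure(uk_fit3, uk_ratings):
    model, _ = uk_fit3
    assert model.n_params == (3 - 1) + 6 * 3 + 6
    mv, _ = lpa.fit_lpa(uk_ratings[:600], 2, n_starts=4, seed=0, class_varying=True)
    assert mv.n_params == (2 - 1) + 12 * 2


@pytest.mark.parametrize(
    "posterior, expected",
    [
        (np.eye(3)[[0, 1, 2, 0]], 1.0),                      # one-hot: certain
        (np.full((5, 4), 0.25), 0.0),                        # uniform: maximal doubt
        (np.array([[0.9, 0.1], [0.5, 0.5]]), 0.26554),        # hand-computed
    ],
)
def test_relative_entropy_reference_values(posterior, expected):
    assert lpa.relative_entropy(posterior) == pytest.approx(expected, abs=1e-4)


def test_relative_entropy_validates_rows_and_defines_k1():
    with pytest.raises(ValueError, match="sum to 1"):
        lpa.relative_entropy(np.array([[0.7, 0.7]]))
    assert lpa.relative_entropy(np.ones((4, 1))) == 1.0


def test_label_permutation_invariance(uk_fit3, uk_ratings):
    model, post = uk_fit3
    perm = np.array([2, 0, 1])
    permuted = dataclasses.replace(
        model, weights=model.weights[perm], means=model.means[perm]
    )
    post_p = permuted.posterior(uk_ratings)
    assert lpa.relative_entropy(post_p) == pytest.approx(
        lpa.relative_entropy(post), abs=1e-9
    )
    assert permuted.loglik == model.loglik  # stored, unchanged by reindexing
    for key, val in lpa.information_criteria(model).items():
        assert lpa.information_criteria(permuted)[key] == pytest.approx(val)
    _, labels_a, high_a = lpa.assign_and_label(model, post)
    _, labels_b, high_b = lpa.assign_and_label(permuted, post_p)
    assert (labels_a == labels_b).all()
    assert (high_a == high_b).all()


# ---------------------------------------------------------------------------
# likelihood ratio tests


def test_blrt_validates_arguments(uk_ratings):
    with pytest.raises(ValueError, match="n_boot"):
        lpa.blrt(uk_ratings, 2, n_boot=0)
    with pytest.raises(ValueError, match="n_classes"):
        lpa.blrt(uk_ratings, 1, n_boot=5)


def test_blrt_rejects_on_strongly_separated_clusters(separated_two_cluster):
    X, _ = separated_two_cluster
    res = lpa.blrt(X, 2, n_boot=99, seed=5)
    assert res.p_value == pytest.approx(0.01)
    assert res.n_boot_used == 99
    assert (res.boot_lrts < res.observed_lrt).all()


def test_adjusted_lrt_no_improvement_gives_p_one(uk_ratings):
    m1, _ = lpa.fit_lpa(uk_ratings, 1)
    fake2 = lpa.LPAModel(
        n_classes=2, weights=np.array([1.0, 0.0]),
        means=np.vstack([m1.means, m1.means]), variances=m1.variances,
        class_varying=False, loglik=m1.loglik, n_obs=m1.n_obs, converged=True,
        n_iter=1, data_checksum=m1.data_checksum,
    )
    res = lpa.adjusted_lrt(fake2, m1)
    assert res.statistic == 0.0 and res.p_value == 1.0
    assert res.approximate


def test_adjusted_lrt_agrees_with_blrt_on_separated_data(separated_two_cluster):
    X, _ = separated_two_cluster
    m1, _ = lpa.fit_lpa(X, 1)
    m2, _ = lpa.fit_lpa(X, 2, n_starts=8, seed=3)
    assert lpa.adjusted_lrt(m2, m1).p_value < 0.05


def test_adjusted_lrt_mostly_nonsignificant_under_single_gaussian():
    nonsig = 0
    for seed in range(10):
        rng = np.random.default_rng(seed)
        X = rng.normal(2.5, 0.8, size=(500, 6))
        m1, _ = lpa.fit_lpa(X, 1)
        m2, _ = lpa.fit_lpa(X, 2, n_starts=6, seed=seed + 1)
        nonsig += lpa.adjusted_lrt(m2, m1).p_value >= 0.05
    assert nonsig > 5  # the approximation is liberal but correct in tendency


def test_adjusted_lrt_refuses_mismatched_data(uk_ratings, separated_two_cluster):
    X, _ = separated_two_cluster
    m1, _ = lpa.fit_lpa(uk_ratings, 1)
    m2, _ = lpa.fit_lpa(X, 2, n_starts=4, seed=0)
    with pytest.raises(ValueError, match="different data"):
        lpa.adjusted_lrt(m2, m1)


# ---------------------------------------------------------------------------
# model selection


def _report(entropies, ps):
    return pd.DataFrame(
        {
            "entropy": entropies,
            "lmr_p": ps,
            "blrt_p": [np.nan] * len(ps),
        },
        index=pd.Index([2, 3, 4, 5], name="n_classes"),
    )


def test_selection_follows_significance_pattern():
    """LRT significant through K=3, then flat: K=3 wins."""
    sel = lpa.select_model(_report([0.94, 0.90, 0.90, 0.93], [0.004, 0.001, 0.32, 0.08]))
    assert sel.n_classes == 3
    assert any("K=3 qualifies" in line for line in sel.audit)


def test_selection_entropy_filter_can_force_k():
    sel = lpa.select_model(_report([0.90, 0.5, 0.5, 0.5], [0.001, 0.001, 0.001, 0.001]))
    assert sel.n_classes == 2
    assert sum("ruled out" in line for line in sel.audit) == 3


def test_selection_parsimony_fallback_when_nothing_significant():
    sel = lpa.select_model(_report([0.9, 0.9, 0.9, 0.9], [0.3, 0.4, 0.5, 0.6]))
    assert sel.n_classes == 2


def test_selection_errors_when_entropy_eliminates_everything():
    with pytest.raises(ValueError, match="k_range"):
        lpa.select_model(_report([0.5, 0.5, 0.5, 0.5], [0.01] * 4))


def test_selection_prefers_blrt_column_when_present():
    rep = _report([0.9] * 4, [0.001] * 4)
    rep["blrt_p"] = [0.001, 0.001, 0.6, 0.9]
    sel = lpa.select_model(rep)
    assert sel.n_classes == 3
    assert "blrt_p" in sel.audit[0]


# ---------------------------------------------------------------------------
# assignment, labels, contrasts


def test_modal_assignment_and_tie_break():
    model = lpa.LPAModel(
        n_classes=3, weights=np.full(3, 1 / 3),
        means=np.array([[1.0] * 6, [3.0] * 6, [5.0] * 6]),
        variances=np.ones(6), class_varying=False, loglik=0.0, n_obs=2,
        converged=True, n_iter=1,
    )
    post = np.array([[0.7, 0.2, 0.1], [0.5, 0.5, 0.0]])
    assignment, labels, high = lpa.assign_and_label(model, post)
    assert assignment.tolist() == [0, 0]  # tie resolves to the lower index
    assert labels.tolist() == ["low-risk", "low-risk"]
    assert not high.any()


def test_risk_labels_follow_profile_severity(uk_fit3, uk_ratings):
    model, post = uk_fit3
    _, labels, high = lpa.assign_and_label(model, post)
    df = pd.DataFrame({"label": labels, "mean": uk_ratings.mean(axis=1)})
    by = df.groupby("label")["mean"].mean()
    assert by["low-risk"] < by["at-risk"] < by["high-risk"]
    order = np.argsort(model.means.mean(axis=1))
    assert model.means[order[0]].max() < 1.5      # low tier: floor profile
    assert model.means[order[-1]].min() > 3.18    # high tier exceeds the cutoff
    assert (high == (labels == "high-risk")).all()


def test_profile_contrasts_detects_separated_groups():
    rng = np.random.default_rng(3)
    X = np.vstack([rng.normal(m, 0.3, (100, 6)) for m in (1.0, 3.0, 5.0)])
    labels = np.repeat(["a", "b", "c"], 100)
    out = lpa.profile_contrasts(X, labels)
    assert out["significant"].all()
    assert out.attrs["ordering_holds"]
    assert len(out) == 6 * 3  # six items, three pairs each


def test_profile_contrasts_null_rate_matches_oracle_and_stays_low():
    """Under identical groups the adjusted tests match a direct Welch-t
    oracle exactly, and the significant fraction stays near the Bonferroni
    per-comparison level (alpha / 3)."""
    sig = total = 0
    for seed in range(40):
        rng = np.random.default_rng(seed)
        X = rng.normal(3.0, 1.0, (300, 6))
        labels = np.repeat(["a", "b", "c"], 100)
        out = lpa.profile_contrasts(X, labels)
        blocks = {"a": X[:100], "b": X[100:200], "c": X[200:]}
        for _, row in out.iterrows():
            _, p = stats.ttest_ind(
                blocks[row.group_a][:, row["item"] - 1],
                blocks[row.group_b][:, row["item"] - 1],
                equal_var=False,
            )
            assert row.p_adj == pytest.approx(min(1.0, 3 * p))
        sig += int(out["significant"].sum())
        total += len(out)
    assert sig / total < 0.05


def test_profile_contrasts_two_groups_degenerate_bonferroni():
    rng = np.random.default_rng(1)
    X = rng.normal(3.0, 1.0, (40, 6))
    labels = np.repeat(["a", "b"], 20)
    out = lpa.profile_contrasts(X, labels)
    assert len(out) == 6  # one pair per item, adjustment factor 1


def test_profile_contrasts_tiny_group_flagged_not_computable():
    rng = np.random.default_rng(1)
    X = rng.normal(3.0, 1.0, (41, 6))
    labels = np.array(["a"] * 20 + ["b"] * 20 + ["c"])
    out = lpa.profile_contrasts(X, labels)
    involving_c = out[(out.group_a == "c") | (out.group_b == "c")]
    assert (~involving_c["computable"]).all()
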