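"""Unit and property tests for the statistical primitives."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from persistome import stats
from persistome.errors import StatsError

# ---------------------------------------------------------------------------
# fit_feature_lm


def brute_force_wls(y, X, w):
    """Independent normal-equations oracle for a single feature (weights
    carry the fit's mean-1 normalization contract)."""
    W = np.diag(np.asarray(w) / np.mean(w))
    XtWX = X.T @ W @ X
    beta = np.linalg.solve(XtWX, X.T @ W @ y)
    resid = y - X @ beta
    rss = float(resid @ W @ resid)
    df = X.shape[0] - X.shape[1]
    return beta, math.sqrt(rss / df), np.sqrt(np.diag(np.linalg.inv(XtWX)))


def test_fit_recovers_exact_column():
    X = np.column_stack([np.ones(6), np.arange(6.0)])
    Y = X[:, 1][None, :]
    fit = stats.fit_feature_lm(Y, X)
    assert np.allclose(fit.coefficients[0], [0.0, 1.0], atol=1e-12)
    assert fit.sigma[0] == pytest.approx(0.0, abs=1e-10)
    assert fit.df_residual == 4


@pytest.mark.parametrize("weighted", [False, True])
def test_fit_matches_normal_equations_oracle(weighted):
    rng = np.random.default_rng(5)
    X = rng.normal(size=(6, 3))
    Y = rng.normal(size=(5, 6))
    W = rng.uniform(0.5, 2.0, size=Y.shape) if weighted else np.ones(Y.shape)
    fit = stats.fit_feature_lm(Y, X, weights=W if weighted else None)
    for g in range(Y.shape[0]):
        beta, sigma, u = brute_force_wls(Y[g], X, W[g])
        assert np.allclose(fit.coefficients[g], beta, atol=1e-10)
        assert fit.sigma[g] == pytest.approx(sigma, abs=1e-10)
        assert np.allclose(fit.stdev_unscaled[g], u, atol=1e-10)


def test_fit_equal_weights_equals_unweighted():
    rng = np.random.default_rng(2)
    X = np.column_stack([np.ones(5), rng.normal(size=5)])
    Y = rng.normal(size=(4, 5))
    a = stats.fit_feature_lm(Y, X)
    b = stats.fit_feature_lm(Y, X, weights=np.full(Y.shape, 3.7))
    assert np.allclose(a.coefficients, b.coefficients, atol=1e-10)
    assert np.allclose(a.sigma, b.sigma, atol=1e-10)


def test_fit_rejects_bad_inputs():
    X = np.ones((5, 2))  # duplicated column -> rank deficient
    with pytest.raises(StatsError, match="rank"):
        stats.fit_feature_lm(np.zeros((2, 5)), X)
    good = np.column_stack([np.ones(5), np.arange(5.0)])
    with pytest.raises(StatsError, match="weight"):
        stats.fit_feature_lm(np.zeros((2, 5)), good, weights=np.zeros((2, 5)))


# ---------------------------------------------------------------------------
# ebayes_moderate


def _toy_fit(seed=0, n_feat=200, heteroskedastic=True):
    rng = np.random.default_rng(seed)
    X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
    scale = rng.uniform(0.5, 2.0, size=n_feat)[:, None] if heteroskedastic else 1.0
    Y = rng.normal(size=(n_feat, 8)) * scale
    return stats.fit_feature_lm(Y, X)


def test_equal_variances_drive_prior_df_infinite():
    # all residual sds equal -> moment estimator pushes d0 to infinity
    X = np.column_stack([np.ones(6), np.repeat([0.0, 1.0], 3)])
    base = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
    Y = np.vstack([base + k for k in range(30)])
    fit = stats.fit_feature_lm(Y, X)
    res = stats.ebayes_moderate(fit, contrast=1)
    assert math.isinf(res.prior_df)
    assert np.allclose(res.s_post, math.sqrt(res.prior_var), atol=1e-12)


def test_forced_zero_prior_reproduces_ordinary_t():
    fit = _toy_fit(seed=1)
    res = stats.ebayes_moderate(fit, contrast=1, prior_df=0)
    ordinary = fit.coefficients[:, 1] / (fit.stdev_unscaled[:, 1] * fit.sigma)
    assert np.allclose(res.t, ordinary, atol=1e-12)
    assert res.df_total == fit.df_residual


def test_moderation_shrinks_towards_prior_monotonically():
    fit = _toy_fit(seed=3)
    res_small = stats.ebayes_moderate(fit, contrast=1, prior_df=1.0)
    res_big = stats.ebayes_moderate(fit, contrast=1, prior_df=50.0)
    s0 = math.sqrt(res_small.prior_var)
    assert np.all(
        np.abs(res_big.s_post - s0) <= np.abs(res_small.s_post - s0) + 1e-12
    )


def test_null_type_one_error_rate():
    """Standard-normal null data: moderated p < 0.05 for ~5% of features."""
    rng = np.random.default_rng(42)
    X = np.column_stack([np.ones(8), np.repeat([0.0, 1.0], 4)])
    Y = rng.normal(size=(2000, 8))
    fit = stats.fit_feature_lm(Y, X)
    res = stats.ebayes_moderate(fit, contrast=1)
    frac = float(np.mean(res.p_value < 0.05))
    assert 0.04 <= frac <= 0.06


def test_all_zero_variances_is_degenerate():
    X = np.column_stack([np.ones(4), np.arange(4.0)])
    Y = np.vstack([X[:, 1], 2 * X[:, 1]])  # exact fits -> sigma 0
    fit = stats.fit_feature_lm(Y, X)
    with pytest.raises(StatsError, match="zero"):
        stats.ebayes_moderate(fit, contrast=1)


# ---------------------------------------------------------------------------
# bh_adjust


def test_bh_closed_forms():
    assert np.allclose(stats.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])
    assert stats.bh_adjust([0.4])[0] == pytest.approx(0.4)
    with pytest.raises(StatsError):
        stats.bh_adjust([0.5, 1.2])


@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
@settings(deadline=None, max_examples=50)
def test_bh_matches_reference_implementation(p):
    ours = stats.bh_adjust(p)
    ref = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# fisher_exact


def test_fisher_matches_hypergeometric_tail():
    for k, K, n, N in [(5, 10, 10, 100), (0, 3, 4, 20), (3, 3, 3, 9), (2, 8, 5, 40)]:
        _, p = stats.fisher_exact(k, K, n, N)
        ref = sps.hypergeom.sf(k - 1, N, K, n)
        assert p == pytest.approx(ref, rel=1e-12)


def test_fisher_extreme_table_minimal_p():
    n = 5
    K, N = 5, 1000
    _, p = stats.fisher_exact(n, K, n, N)
    assert p == pytest.approx(1.0 / math.comb(N, n) * math.comb(K, n), rel=1e-12)


def test_fisher_independence_not_significant():
    # overlap at the independence expectation: k = n*K/N
    _, p = stats.fisher_exact(2, 20, 10, 100)
    assert p >= 0.3


def test_fisher_symmetry_and_monotonicity():
    for k in range(0, 6):
        _, p_a = stats.fisher_exact(k, 12, 6, 50)
        _, p_b = stats.fisher_exact(k, 6, 12, 50)
        assert p_a == pytest.approx(p_b, rel=1e-12)
    ps = [stats.fisher_exact(k, 12, 6, 50)[1] for k in range(0, 7)]
    assert all(a >= b - 1e-15 for a, b in zip(ps, ps[1:]))


def test_fisher_rejects_infeasible_table():
    with pytest.raises(StatsError):
        stats.fisher_exact(5, 4, 10, 100)
    with pytest.raises(StatsError):
        stats.fisher_exact(0, 60, 60, 100)


# ---------------------------------------------------------------------------
# ranksum_exact


def test_ranksum_identical_singletons():
    u, p, method = stats.ranksum_exact([1.0], [1.0])
    assert p == 1.0


def test_ranksum_fully_separated_triples():
    u, p, method = stats.ranksum_exact([1, 2, 3], [4, 5, 6])
    assert method == "exact"
    assert p == pytest.approx(0.1, abs=1e-12)  # 2 of C(6,3)=20 assignments


def test_ranksum_exact_matches_scipy_enumeration():
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = rng.normal(size=5)
        y = rng.normal(size=6)
        u, p, method = stats.ranksum_exact(x, y)
        assert method == "exact"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_ranksum_normal_approximation_close_to_exact():
    rng = np.random.default_rng(9)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    _, p_exact, m1 = stats.ranksum_exact(x, y)
    assert m1 == "exact"
    # same data pushed down the approximate path via an added tie pair
    x2 = np.concatenate([x, [10.0]])
    y2 = np.concatenate([y, [10.0]])
    _, p_norm, m2 = stats.ranksum_exact(x2, y2)
    assert m2 == "normal"
    ref = sps.mannwhitneyu(x2, y2, alternative="two-sided", method="asymptotic")
    assert p_norm == pytest.approx(ref.pvalue, abs=1e-9)


def test_ranksum_rejects_empty_group():
    with pytest.raises(StatsError):
        stats.ranksum_exact([], [1.0])


# ---------------------------------------------------------------------------
# quantile_normalize


def test_quantile_normalize_properties():
    rng = np.random.default_rng(0)
    M = rng.normal(size=(10, 4))
    out = stats.quantile_normalize(M)
    sorted_cols = np.sort(out, axis=0)
    for j in range(1, 4):
        assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j], atol=1e-12)
    # idempotent
    again = stats.quantile_normalize(out)
    assert np.allclose(out, again, atol=1e-12)


def test_quantile_normalize_permuted_columns_share_multiset():
    rng = np.random.default_rng(1)
    col = rng.normal(size=20)
    M = np.column_stack([col, rng.permutation(col)])
    out = stats.quantile_normalize(M)
    assert np.allclose(np.sort(out[:, 0]), np.sort(out[:, 1]), atol=1e-12)
    assert out[:, 0].mean() == pytest.approx(out[:, 1].mean(), abs=1e-12)


def test_quantile_normalize_single_sample_warns_identity():
    M = np.arange(5.0)[:, None]
    with pytest.warns(UserWarning):
        out = stats.quantile_normalize(M)
    assert np.allclose(out, M)


def test_quantile_normalize_ties_get_mean_of_spanned_quantiles():
    M = np.array([[1.0, 1.0], [1.0, 2.0], [3.0, 3.0]])
    out = stats.quantile_normalize(M)
    means = np.sort(M, axis=0).mean(axis=1)
    # column 0 ties at ranks 1 and 2 -> both get mean of the two quantiles
    assert out[0, 0] == pytest.approx((means[0] + means[1]) / 2)
    assert out[1, 0] == pytest.approx((means[0] + means[1]) / 2)


# ---------------------------------------------------------------------------
# call_features


def test_call_features_boundaries():
    from conftest import toy_diff_table

    table = toy_diff_table(
        [0.009, 0.011, 0.009, 0.005],
        [0.59, 3.0, -0.30, -0.60],
        ids=["a", "b", "c", "d"],
    )
    calls = stats.call_features(table, p_max=0.01, min_fold=1.5)
    assert calls.up == {"a"}  # 0.59 >= log2(1.5)
    assert calls.down == {"d"}
    assert calls.total == 2


def test_call_features_row_order_invariant():
    from conftest import toy_diff_table

    table = toy_diff_table([0.001, 0.5, 0.002], [1.0, 2.0, -1.5], ids=["x", "y", "z"])
    a = stats.call_features(table, 0.01, 1.5)
    b = stats.call_features(table.iloc[::-1].reset_index(drop=True), 0.01, 1.5)
    assert a.up == b.up and a.down == b.down
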