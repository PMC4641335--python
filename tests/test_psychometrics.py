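"""Validation statistics: alpha (with independent oracles), PPV/NPV,
correlation method selection, ANOVA screen, forced-entry regression."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from semas.psychometrics import (
    anova_screen,
    convergent_regression,
    correlation,
    cronbach_alpha,
    ppv_npv,
)

rng = np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Cronbach's alpha


def test_alpha_perfectly_correlated_pair_is_one():
    x = rng.normal(size=200)
    assert cronbach_alpha(np.column_stack([x, x])).value == pytest.approx(1.0)


def test_alpha_uncorrelated_equal_variance_items_is_zero():
    # With sigma_total^2 == sum of item variances, alpha is exactly 0: build
    # orthogonal columns with identical variance.
    a = np.array([1.0, -1.0, 1.0, -1.0])
    b = np.array([1.0, 1.0, -1.0, -1.0])
    assert cronbach_alpha(np.column_stack([a, b])).value == pytest.approx(0.0)


def test_alpha_matches_covariance_trace_oracle():
    """alpha == (k/(k-1)) * (1 - tr(C) / sum(C)) on random matrices."""
    for _ in range(20):
        m = rng.integers(0, 5, size=(10, 4)).astype(float)
        res = cronbach_alpha(m)
        if res.value is None:
            continue
        c = np.cov(m, rowvar=False)
        oracle = (4 / 3) * (1 - np.trace(c) / c.sum())
        assert res.value == pytest.approx(oracle, abs=1e-12)


def test_alpha_matches_pingouin():
    """Cross-check against an independent published implementation."""
    pingouin = pytest.importorskip("pingouin")
    m = pd.DataFrame(rng.integers(0, 4, size=(60, 5)).astype(float))
    ours = cronbach_alpha(m).value
    theirs = pingouin.cronbach_alpha(data=m)[0]
    assert ours == pytest.approx(theirs, abs=1e-10)


def test_alpha_complete_cases_only():
    m = np.array([[1.0, 2.0], [2.0, 3.0], [np.nan, 1.0], [4.0, 5.0]])
    res = cronbach_alpha(m)
    assert res.n == 3
    assert res.value == pytest.approx(cronbach_alpha(m[[0, 1, 3]]).value)


def test_alpha_zero_total_variance_undefined():
    m = np.array([[1.0, 2.0], [1.0, 2.0], [1.0, 2.0]])
    res = cronbach_alpha(m)
    assert res.value is None and "variance" in res.reason


@given(shift=st.integers(-5, 5), perm=st.permutations([0, 1, 2]))
def test_alpha_invariant_to_item_shift_and_reordering(shift, perm):
    base = np.random.default_rng(7).normal(size=(30, 3))
    base = base + np.random.default_rng(8).normal(size=(30, 1))  # shared factor
    shifted = base.copy()
    shifted[:, 0] += shift
    reordered = shifted[:, list(perm)]
    assert cronbach_alpha(reordered).value == pytest.approx(
        cronbach_alpha(base).value, abs=1e-12
    )


# ---------------------------------------------------------------------------
# PPV / NPV


def test_ppv_npv_counts_oracle():
    semas = [True] * 5 + [True] * 5 + [False] * 1 + [False] * 9
    crit = [True] * 5 + [False] * 5 + [True] * 1 + [False] * 9
    table, ppv, npv = ppv_npv(semas, crit)
    assert (table.tp, table.fp, table.fn, table.tn) == (5, 5, 1, 9)
    assert ppv == pytest.approx(0.5) and npv == pytest.approx(0.9)


def test_all_true_positive_ppv_one_npv_undefined():
    table, ppv, npv = ppv_npv([True] * 4, [True] * 4)
    assert ppv == 1.0 and npv is None


def test_identity_channel_gives_perfect_values():
    flags = [True, False, True, False, False]
    _, ppv, npv = ppv_npv(flags, flags)
    assert ppv == 1.0 and npv == 1.0


def test_not_scorable_excluded_and_counted():
    table, _, _ = ppv_npv([True, None, False], [True, True, None])
    assert table.n == 1 and table.n_excluded == 2
    assert table.n + table.n_excluded == 3


@given(
    flags=st.lists(
        st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=40
    )
)
def test_ppv_npv_self_consistent_with_table(flags):
    semas, crit = zip(*flags)
    table, ppv, npv = ppv_npv(list(semas), list(crit))
    assert table.n == len(flags)
    if ppv is not None:
        assert ppv == table.tp / (table.tp + table.fp)
    if npv is not None:
        assert npv == table.tn / (table.tn + table.fn)


# ---------------------------------------------------------------------------
# correlation with normality-based method choice


def test_identity_correlates_perfectly():
    x = rng.normal(size=100)
    coef, method, p = correlation(x, x + 0.0)
    assert coef == pytest.approx(1.0)


def test_spearman_chosen_for_skewed_data_and_matches_rank_oracle():
    x = rng.exponential(size=300).round(0)  # heavy ties, skewed
    y = np.expm1(x / 3) + rng.normal(scale=0.1, size=300)
    coef, method, _ = correlation(x, y)
    assert method == "spearman"
    # independent oracle: average-rank transform then Pearson
    rx = pd.Series(x).rank().to_numpy()
    ry = pd.Series(y).rank().to_numpy()
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert coef == pytest.approx(oracle, abs=1e-12)


def test_pearson_chosen_for_bivariate_normal_and_recovers_rho():
    n, target = 5000, 0.6
    cov = [[1, target], [target, 1]]
    xy = np.random.default_rng(11).multivariate_normal([0, 0], cov, size=n)
    coef, method, _ = correlation(xy[:, 0], xy[:, 1])
    assert method == "pearson"
    assert coef == pytest.approx(target, abs=0.03)  # ~ (1 - rho^2) / sqrt(n)


def test_pearson_equals_spearman_on_strictly_monotone_linear_data():
    x = np.arange(50, dtype=float)
    y = 3 * x + 2
    r_p = np.corrcoef(x, y)[0, 1]
    rx, ry = pd.Series(x).rank(), pd.Series(y).rank()
    r_s = np.corrcoef(rx, ry)[0, 1]
    assert r_p == pytest.approx(r_s, abs=1e-12) == pytest.approx(1.0)


def test_constant_vector_undefined():
    coef, method, _ = correlation(np.ones(10), rng.normal(size=10))
    assert coef is None and method == "undefined"


# ---------------------------------------------------------------------------
# ANOVA screen


def _screen_one(flags, pam, alpha=0.05):
    df = pd.DataFrame({"c": pd.array(flags, dtype="boolean")})
    return anova_screen(df, pd.Series(pam), alpha=alpha)["c"]


def test_identical_groups_not_retained():
    flags = [True, False] * 20
    pam = [50.0] * 40
    res = _screen_one(flags, pam)
    assert not res.retained


def test_separated_groups_retained_and_f_matches_t_squared():
    r = np.random.default_rng(3)
    pam = np.concatenate([r.normal(60, 5, 20), r.normal(40, 5, 20)])
    flags = [False] * 20 + [True] * 20
    res = _screen_one(flags, pam)
    assert res.retained
    from scipy import stats

    t = stats.ttest_ind(pam[:20], pam[20:])
    assert res.f_stat == pytest.approx(t.statistic**2, rel=1e-10)


def test_tiny_group_skipped_with_reason():
    res = _screen_one([True] + [False] * 20, np.arange(21.0))
    assert not res.retained and "2 members" in res.reason


# ---------------------------------------------------------------------------
# regression


def test_single_binary_predictor_closed_form():
    """beta equals the group-mean difference; r2 the squared point-biserial r."""
    r = np.random.default_rng(5)
    barrier = r.random(200) < 0.4
    pam = 40 + 15 * (~barrier) + r.normal(0, 8, 200)
    flags = pd.DataFrame({"se": pd.array(barrier, dtype="boolean")})
    res = convergent_regression(flags, pd.Series(pam), predictors=["se"])
    diff = pam[~barrier].mean() - pam[barrier].mean()
    assert res.effects["se"].beta == pytest.approx(diff, rel=1e-10)
    rpb = np.corrcoef((~barrier).astype(float), pam)[0, 1]
    assert res.r_squared == pytest.approx(rpb**2, rel=1e-10)


def test_coefficients_match_normal_equations_oracle():
    r = np.random.default_rng(6)
    x1 = r.random(150) < 0.5
    x2 = r.random(150) < 0.3
    pam = 30 + 12 * (~x1) + 5 * (~x2) + r.normal(0, 6, 150)
    flags = pd.DataFrame(
        {"a": pd.array(x1, dtype="boolean"), "b": pd.array(x2, dtype="boolean")}
    )
    res = convergent_regression(flags, pd.Series(pam))
    # independent oracle: solve the normal equations directly
    X = np.column_stack([np.ones(150), (~x1).astype(float), (~x2).astype(float)])
    beta = np.linalg.solve(X.T @ X, X.T @ pam)
    assert res.intercept == pytest.approx(beta[0], abs=1e-10)
    assert res.effects["a"].beta == pytest.approx(beta[1], abs=1e-10)
    assert res.effects["b"].beta == pytest.approx(beta[2], abs=1e-10)


def test_rank_deficient_design_names_collinear_predictors():
    x = np.random.default_rng(9).random(50) < 0.5
    flags = pd.DataFrame(
        {"a": pd.array(x, dtype="boolean"), "b": pd.array(x, dtype="boolean")}
    )
    with pytest.raises(ValueError, match="collinear"):
        convergent_regression(flags, pd.Series(np.arange(50.0)))


def test_independent_predictors_r2_vanishes():
    r = np.random.default_rng(10)
    n = 5000
    flags = pd.DataFrame(
        {f"c{i}": pd.array(r.random(n) < 0.4, dtype="boolean") for i in range(3)}
    )
    res = convergent_regression(flags, pd.Series(r.normal(50, 10, n)))
    assert res.r_squared < 0.01


def test_positive_beta_means_barrier_free_scores_higher():
    r = np.random.default_rng(12)
    barrier = r.random(300) < 0.5
    pam = 40 + 20 * (~barrier) + r.normal(0, 5, 300)
    flags = pd.DataFrame({"se": pd.array(barrier, dtype="boolean")})
    res = convergent_regression(flags, pd.Series(pam))
    assert res.effects["se"].beta > 0
    assert 0 < res.effects["se"].standardized_beta <= 1
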