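"""Cohort statistics: t-tests, rank-sum tests, correlation screen, RDA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import fmenkit as fk
from fmenkit.errors import InputError
from fmenkit.stats import hellinger, stars


# --------------------------------------------------------------------------
# stars
# --------------------------------------------------------------------------

@pytest.mark.parametrize("p,expected", [
    (0.0005, "***"), (0.004, "**"), (0.03, "*"), (0.07, "-"), (1.0, "-"),
    (float("nan"), "-"),
])
def test_star_mapping(p, expected):
    assert stars(p) == expected


def test_star_mapping_is_monotone_step_function():
    grid = np.linspace(1e-6, 1.0, 500)
    levels = {"***": 3, "**": 2, "*": 1, "-": 0}
    mapped = [levels[stars(p)] for p in grid]
    assert all(a >= b for a, b in zip(mapped, mapped[1:]))


# --------------------------------------------------------------------------
# t-tests
# --------------------------------------------------------------------------

def test_identical_groups_give_t0_p1():
    res = fk.two_group_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)


def test_swapping_groups_negates_t_keeps_p(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(0.7, 1.3, 15)
    fw, bw = fk.two_group_t(a, b), fk.two_group_t(b, a)
    assert fw.statistic == pytest.approx(-bw.statistic)
    assert fw.p_value == pytest.approx(bw.p_value)


def test_constant_groups_equal_means_p1():
    res = fk.two_group_t([2.0, 2.0], [2.0, 2.0])
    assert res.p_value == 1.0 and not res.degenerate


def test_constant_groups_unequal_means_flagged_degenerate():
    res = fk.two_group_t([2.0, 2.0], [3.0, 3.0])
    assert res.degenerate


def test_summary_t_matches_raw_welch(rng):
    a, b = rng.normal(5, 2, 15), rng.normal(6, 1, 15)
    raw = fk.two_group_t(a, b)
    summ = fk.two_group_t_from_summary(a.mean(), sps.sem(a), 15,
                                       b.mean(), sps.sem(b), 15)
    assert summ.statistic == pytest.approx(raw.statistic)
    assert summ.df == pytest.approx(raw.df)
    assert summ.p_value == pytest.approx(raw.p_value)


def test_group_ordering_invariance(rng):
    a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
    shuffled = a.copy()
    rng.shuffle(shuffled)
    assert fk.two_group_t(a, b).p_value == pytest.approx(
        fk.two_group_t(shuffled, b).p_value)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum
# --------------------------------------------------------------------------

def test_separated_groups_exact_p():
    # U = 0; 2/20 orderings are as extreme under exact enumeration
    assert fk.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]).p_value == pytest.approx(0.1)


def test_identical_multisets_p1():
    assert fk.wilcoxon_rank_sum([1, 2, 2], [1, 2, 2]).p_value == 1.0


def test_all_tied_values_p1():
    assert fk.wilcoxon_rank_sum([5, 5, 5], [5] * 20).p_value == 1.0


def test_exact_matches_scipy_without_ties(rng):
    for _ in range(20):
        a = rng.normal(size=rng.integers(3, 7))
        b = rng.normal(size=rng.integers(3, 7))
        ours = fk.wilcoxon_rank_sum(a, b).p_value
        ref = sps.mannwhitneyu(a, b, alternative="two-sided",
                               method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)


def test_normal_approximation_close_to_exact(rng):
    """Approximate p within 0.05 of exhaustive enumeration (small n)."""
    worst = 0.0
    for _ in range(100):
        na, nb = rng.integers(3, 8), rng.integers(3, 8)
        a, b = rng.normal(size=na), rng.normal(size=nb)
        exact = fk.wilcoxon_rank_sum(a, b).p_value
        approx = fk.wilcoxon_rank_sum(a, b, exact_max_n=0).p_value
        worst = max(worst, abs(exact - approx))
    assert worst <= 0.05


def test_tie_corrected_approximation_is_valid_probability(rng):
    for _ in range(30):
        pooled = rng.integers(0, 4, 12).astype(float)  # heavy ties
        p = fk.wilcoxon_rank_sum(pooled[:5], pooled[5:],
                                 exact_max_n=0).p_value
        assert 0.0 <= p <= 1.0


# --------------------------------------------------------------------------
# correlation screen
# --------------------------------------------------------------------------

def test_screen_recovers_perfect_correlations():
    x = pd.DataFrame([[1.0, 2, 3, 4, 5]], index=["cat"],
                     columns=list("abcde"))
    y = pd.DataFrame([[1.0, 2, 3, 4, 5], [-1.0, -2, -3, -4, -5]],
                     index=["same", "neg"], columns=list("abcde"))
    screen = fk.correlation_screen(x, y)
    assert screen.r.loc["cat", "same"] == pytest.approx(1.0)
    assert screen.r.loc["cat", "neg"] == pytest.approx(-1.0)


def test_screen_constant_vector_missing_with_warning(rng):
    x = pd.DataFrame([[1.0, 1, 1, 1]], index=["flat"], columns=list("abcd"))
    y = pd.DataFrame([rng.normal(size=4)], index=["v"], columns=list("abcd"))
    with pytest.warns(UserWarning, match="constant"):
        screen = fk.correlation_screen(x, y)
    assert np.isnan(screen.r.loc["flat", "v"])


def test_screen_too_few_samples_errors():
    x = pd.DataFrame([[1.0, 2]], columns=["a", "b"])
    with pytest.raises(InputError):
        fk.correlation_screen(x, x)


def test_screen_p_matches_pearsonr(rng):
    x = pd.DataFrame(rng.normal(size=(2, 10)), index=["u", "v"],
                     columns=[f"s{i}" for i in range(10)])
    y = pd.DataFrame(rng.normal(size=(2, 10)), index=["p", "q"],
                     columns=x.columns)
    screen = fk.correlation_screen(x, y)
    for i in x.index:
        for j in y.index:
            ref = sps.pearsonr(x.loc[i], y.loc[j])
            assert screen.r.loc[i, j] == pytest.approx(ref.statistic)
            assert screen.p.loc[i, j] == pytest.approx(ref.pvalue)


def test_screen_bh_adjustment_monotone(rng):
    x = pd.DataFrame(rng.normal(size=(3, 12)),
                     columns=[f"s{i}" for i in range(12)])
    screen = fk.correlation_screen(x, x, adjust=True)
    assert (screen.p_adjusted.to_numpy() >= screen.p.to_numpy() - 1e-12).all()


# --------------------------------------------------------------------------
# RDA
# --------------------------------------------------------------------------

def _random_case(rng, n=10, q=4, p=2):
    Y = pd.DataFrame(rng.normal(size=(n, q)),
                     columns=[f"c{i}" for i in range(q)])
    X = pd.DataFrame(rng.normal(size=(n, p)),
                     columns=[f"x{i}" for i in range(p)])
    return Y, X


def test_rda_axes_match_regression_then_pca_oracle(rng):
    Y, X = _random_case(rng)
    res = fk.rda(Y, X)
    # oracle: explicit least squares, then eigendecomposition of fitted cov
    Yc = Y - Y.mean()
    Xs = (X - X.mean()) / X.std(ddof=1)
    B, *_ = np.linalg.lstsq(Xs.to_numpy(), Yc.to_numpy(), rcond=None)
    F = Xs.to_numpy() @ B
    eigvals = np.linalg.eigvalsh(F.T @ F / (len(Y) - 1))[::-1]
    np.testing.assert_allclose(res.eigenvalues, eigvals[:len(res.eigenvalues)],
                               atol=1e-9)
    # site scores spanned by the PCA of fitted values
    _, _, Vt = np.linalg.svd(F, full_matrices=False)
    k = res.site_scores.shape[1]
    np.testing.assert_allclose(np.abs(res.site_scores.to_numpy()),
                               np.abs(F @ Vt[:k].T), atol=1e-9)


def test_rda_orthogonal_predictors_explain_nothing(rng):
    n = 8
    Y = pd.DataFrame(rng.normal(size=(n, 3)))
    X = pd.DataFrame(rng.normal(size=(n, 2)))
    Yc = Y - Y.mean()
    # project response out of predictor space so fitted values vanish
    Xs = (X - X.mean()) / X.std(ddof=1)
    P = Xs.to_numpy() @ np.linalg.pinv(Xs.to_numpy())
    Y_orth = pd.DataFrame(Yc.to_numpy() - P @ Yc.to_numpy())
    assert fk.rda(Y_orth, X).proportion_constrained <= 1e-10


def test_rda_linear_response_fully_constrained(rng):
    n = 12
    X = pd.DataFrame(rng.normal(size=(n, 2)), columns=["x0", "x1"])
    Y = pd.DataFrame(X.to_numpy() @ rng.normal(size=(2, 3)),
                     columns=["c0", "c1", "c2"])
    assert fk.rda(Y, X).proportion_constrained == pytest.approx(1.0)


def test_rda_variance_decomposition(rng):
    Y, X = _random_case(rng, n=14, q=5, p=3)
    res = fk.rda(Y, X)
    assert (res.eigenvalues.sum() + res.residual_eigenvalues.sum()
            == pytest.approx(res.total_variance, abs=1e-9))


def test_rda_sample_order_invariance(rng):
    Y, X = _random_case(rng)
    res = fk.rda(Y, X)
    perm = rng.permutation(len(Y))
    res_p = fk.rda(Y.iloc[perm], X.iloc[perm])
    np.testing.assert_allclose(res.eigenvalues, res_p.eigenvalues, atol=1e-9)
    assert res.proportion_constrained == pytest.approx(
        res_p.proportion_constrained)


def test_rda_collinear_predictors_warn_not_fail(rng, caplog):
    Y, X = _random_case(rng)
    X["x2"] = X["x0"] * 2.0  # exactly collinear
    with caplog.at_level("WARNING"):
        res = fk.rda(Y, X)
    assert "collinear" in caplog.text
    assert np.isfinite(res.proportion_constrained)


def test_hellinger_transform_unit_rows():
    counts = pd.DataFrame([[1.0, 3.0], [2.0, 2.0]])
    h = hellinger(counts)
    np.testing.assert_allclose((h ** 2).sum(axis=1), 1.0)
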