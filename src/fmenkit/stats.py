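"""Between-site and correlation statistics.

Covers the cohort comparisons used throughout the analysis: Welch/Student
t-tests on soil properties (from raw values or published mean +/- SE
summaries), exact and approximate Wilcoxon rank-sum tests on functional
abundances, Pearson correlation screens with significance stars, and
redundancy analysis (RDA) of community composition on soil predictors.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import InputError

log = logging.getLogger(__name__)


def stars(p: float) -> str:
    """Significance stars: *** p<0.001, ** p<0.01, * p<0.05, else '-'."""
    if not np.isfinite(p):
        return "-"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "-"


@dataclass
class StatResult:
    """One test outcome with the reporting conventions used in tables."""

    label: str
    estimate: dict = field(default_factory=dict)
    statistic: float = np.nan
    df: float = np.nan
    p_value: float = np.nan
    degenerate: bool = False

    @property
    def stars(self) -> str:
        return stars(self.p_value)

    @property
    def p_rounded(self) -> float:
        """p at the 2-decimal precision used in printed tables."""
        return float(round(self.p_value, 2))


# --------------------------------------------------------------------------
# t-tests
# --------------------------------------------------------------------------

def two_group_t(values_a, values_b, equal_var: bool = False,
                label: str = "") -> StatResult:
    """Two-sided two-sample t-test (Welch by default).

    Zero variance in both groups: equal means give p = 1 by convention;
    unequal means are flagged as a degenerate result with p = 0.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise InputError("each group needs at least 2 values")
    est = {"mean_a": a.mean(), "se_a": sps.sem(a) if a.size > 1 else np.nan,
           "mean_b": b.mean(), "se_b": sps.sem(b) if b.size > 1 else np.nan}
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return StatResult(label, est, 0.0, np.nan, 1.0)
        return StatResult(label, est, np.inf, np.nan, 0.0, degenerate=True)
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return StatResult(label, est, float(res.statistic), float(res.df),
                      float(res.pvalue))


def two_group_t_from_summary(mean_a: float, se_a: float, n_a: int,
                             mean_b: float, se_b: float, n_b: int,
                             equal_var: bool = False,
                             label: str = "") -> StatResult:
    """t-test from published group summaries (mean, standard error, n).

    Welch: t = (m_a - m_b) / sqrt(SE_a^2 + SE_b^2) with
    Welch-Satterthwaite degrees of freedom.  Student pools the implied
    variances (s_i^2 = n_i SE_i^2) with df = n_a + n_b - 2.
    """
    if n_a < 2 or n_b < 2:
        raise InputError("group sizes must be >= 2")
    est = {"mean_a": mean_a, "se_a": se_a, "mean_b": mean_b, "se_b": se_b}
    va, vb = se_a ** 2, se_b ** 2  # variances of the group means
    if va + vb == 0.0:
        if mean_a == mean_b:
            return StatResult(label, est, 0.0, np.nan, 1.0)
        return StatResult(label, est, np.inf, np.nan, 0.0, degenerate=True)
    if equal_var:
        sp2 = ((n_a - 1) * n_a * va + (n_b - 1) * n_b * vb) / (n_a + n_b - 2)
        t = (mean_a - mean_b) / np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_b))
        df = n_a + n_b - 2
    else:
        t = (mean_a - mean_b) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / (n_a - 1) + vb ** 2 / (n_b - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return StatResult(label, est, float(t), float(df), float(p))


# --------------------------------------------------------------------------
# Wilcoxon rank-sum (Mann-Whitney)
# --------------------------------------------------------------------------

def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """Mann-Whitney U for group a, counting ties as 1/2."""
    diff = a[:, None] - b[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def wilcoxon_rank_sum(values_a, values_b, label: str = "",
                      exact_max_n: int = 14) -> StatResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test.

    The exact null distribution is enumerated over all C(n, n_a) group
    relabellings when n_a + n_b <= ``exact_max_n`` (ties handled by the
    1/2-count U definition); larger samples use the normal approximation
    with tie and continuity corrections.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InputError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    u_obs = _u_statistic(a, b)
    est = {"median_a": float(np.median(a)), "median_b": float(np.median(b)),
           "U": u_obs}

    if np.all(pooled == pooled[0]):
        return StatResult(label, est, u_obs, np.nan, 1.0)

    if na + nb <= exact_max_n:
        us = np.array([
            _u_statistic(np.asarray(combo), np.delete(pooled, idx))
            for idx, combo in zip(
                itertools.combinations(range(na + nb), na),
                itertools.combinations(pooled, na))
        ])
        lo = float(np.mean(us <= u_obs))
        hi = float(np.mean(us >= u_obs))
        p = min(1.0, 2.0 * min(lo, hi))
        return StatResult(label, est, u_obs, np.nan, p)

    n = na + nb
    mu = na * nb / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = (counts ** 3 - counts).sum() / (n * (n - 1))
    sigma2 = na * nb / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        return StatResult(label, est, u_obs, np.nan, 1.0)
    z = (u_obs - mu - 0.5 * np.sign(u_obs - mu)) / np.sqrt(sigma2)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return StatResult(label, est, u_obs, np.nan, float(p))


# --------------------------------------------------------------------------
# Pearson correlation screen
# --------------------------------------------------------------------------

@dataclass
class CorrelationScreen:
    """Matrix of pairwise Pearson tests (rows x columns)."""

    r: pd.DataFrame
    p: pd.DataFrame
    p_adjusted: pd.DataFrame | None = None

    @property
    def stars(self) -> pd.DataFrame:
        return self.p.map(stars)

    def to_long(self) -> pd.DataFrame:
        """Long format: one (row, column, r, p, stars) record per pair."""
        out = (self.r.stack(future_stack=True).rename("r").to_frame()
               .join(self.p.stack(future_stack=True).rename("p")))
        out["stars"] = out["p"].map(stars)
        if self.p_adjusted is not None:
            out = out.join(
                self.p_adjusted.stack(future_stack=True).rename("p_bh"))
        return out.reset_index(names=["category", "variable"])


def correlation_screen(left: pd.DataFrame, right: pd.DataFrame,
                       adjust: bool = False) -> CorrelationScreen:
    """Pearson r and two-sided p for every (left row, right row) pair.

    Both inputs are feature x sample matrices sharing sample columns;
    per-pair complete cases are used.  Constant vectors or fewer than 3
    complete pairs yield missing cells with a warning, never an error.
    ``adjust=True`` adds Benjamini-Hochberg adjusted p-values across all
    finite cells.
    """
    shared = left.columns.intersection(right.columns)
    if len(shared) < 3:
        raise InputError("need at least 3 shared samples")
    L, R = left[shared], right[shared]
    r = pd.DataFrame(np.nan, index=L.index, columns=R.index, dtype=float)
    p = r.copy()
    for cat, x in L.iterrows():
        for var, y in R.iterrows():
            ok = x.notna() & y.notna()
            if ok.sum() < 3:
                warnings.warn(f"<3 complete pairs for ({cat}, {var}); "
                              "cell reported missing")
                continue
            xv, yv = x[ok].to_numpy(), y[ok].to_numpy()
            if np.std(xv) == 0.0 or np.std(yv) == 0.0:
                warnings.warn(f"constant vector for ({cat}, {var}); "
                              "correlation undefined")
                continue
            res = sps.pearsonr(xv, yv)
            r.loc[cat, var] = res.statistic
            p.loc[cat, var] = res.pvalue
    p_adj = None
    if adjust:
        flat = p.to_numpy().ravel()
        finite = np.isfinite(flat)
        adj = np.full_like(flat, np.nan)
        if finite.any():
            adj[finite] = multipletests(flat[finite], method="fdr_bh")[1]
        p_adj = pd.DataFrame(adj.reshape(p.shape), index=p.index,
                             columns=p.columns)
    return CorrelationScreen(r, p, p_adj)


# --------------------------------------------------------------------------
# Redundancy analysis
# --------------------------------------------------------------------------

@dataclass
class RDAResult:
    """Constrained ordination of a community matrix on predictors."""

    eigenvalues: np.ndarray          # constrained axis variances
    residual_eigenvalues: np.ndarray
    total_variance: float
    proportion_constrained: float
    site_scores: pd.DataFrame        # samples x axes
    category_scores: pd.DataFrame    # response categories x axes
    biplot: pd.DataFrame             # predictors x axes (correlations)


def hellinger(counts: pd.DataFrame) -> pd.DataFrame:
    """Hellinger transform of a sample x category abundance matrix."""
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise InputError("sample(s) with zero total abundance")
    return np.sqrt(counts.div(totals, axis=0))


def rda(response: pd.DataFrame, predictors: pd.DataFrame) -> RDAResult:
    """Redundancy analysis: PCA of the fitted values of Y ~ X.

    ``response`` (samples x categories) is column-centered; ``predictors``
    (samples x variables) are standardized internally.  Constrained axes
    are the principal components of the least-squares fitted values;
    ``proportion_constrained`` is the fitted share of total variance.
    Collinear predictors are handled by the pseudo-inverse with a logged
    warning.
    """
    if response.shape[0] < 3:
        raise InputError("need at least 3 samples")
    if not response.index.equals(predictors.index):
        predictors = predictors.loc[response.index]
    Y = response.to_numpy(dtype=float)
    Y = Y - Y.mean(axis=0)
    X = predictors.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd[sd == 0.0] = 1.0
    X = X / sd
    if np.linalg.matrix_rank(X) < X.shape[1]:
        log.warning("collinear predictors: using least-squares pseudo-inverse")
    B = np.linalg.pinv(X) @ Y
    F = X @ B
    resid = Y - F

    n = Y.shape[0]
    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    k = min(np.linalg.matrix_rank(X), Y.shape[1])
    eig = s[:k] ** 2 / (n - 1)
    _, s_r, _ = np.linalg.svd(resid, full_matrices=False)
    resid_eig = s_r ** 2 / (n - 1)
    total = float(np.sum(Y ** 2) / (n - 1))
    prop = float((s ** 2).sum() / np.sum(Y ** 2)) if np.sum(Y ** 2) > 0 else 0.0

    axes = [f"RDA{i + 1}" for i in range(k)]
    sites = U[:, :k] * s[:k]
    site_scores = pd.DataFrame(sites, index=response.index, columns=axes)
    category_scores = pd.DataFrame(Vt[:k].T, index=response.columns,
                                   columns=axes)
    arrows = np.zeros((X.shape[1], k))
    for j in range(X.shape[1]):
        for a in range(k):
            if np.std(X[:, j]) > 0 and np.std(sites[:, a]) > 0:
                arrows[j, a] = np.corrcoef(X[:, j], sites[:, a])[0, 1]
    biplot = pd.DataFrame(arrows, index=predictors.columns, columns=axes)
    return RDAResult(eig, resid_eig, total, prop, site_scores,
                     category_scores, biplot)
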