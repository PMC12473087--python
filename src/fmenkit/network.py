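"""Signed co-occurrence network construction with RMT threshold selection.

The builder follows molecular-ecological-network practice: per-site OTU
abundances are prevalence-filtered, converted to relative abundance,
log10-transformed (zeros replaced by half the smallest nonzero relative
abundance), and correlated pairwise (Pearson).  The correlation cutoff is
chosen by random matrix theory: scanning cutoffs until the nearest-
neighbour spacing distribution (NNSD) of the thresholded matrix's
unfolded eigenvalues transitions from GOE (Wigner surmise) to Poisson
statistics.  Edges keep their correlation sign as an attribute; topology
is computed on the unweighted simple graph.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.interpolate import LSQUnivariateSpline

from .errors import EmptyNetworkError, EmptyResultError, InputError, NoTransitionError

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Abundance preparation and correlation
# --------------------------------------------------------------------------

def prepare_abundance(otu_table: pd.DataFrame, sample_sites: pd.Series,
                      site: str, min_prevalence: int | None = None
                      ) -> pd.DataFrame:
    """Site-restricted, prevalence-filtered log10 relative abundances.

    OTUs detected (count > 0) in fewer than ``min_prevalence`` of the
    site's samples are dropped (default: half the samples, rounded up).
    After conversion to relative abundance, zeros are replaced by half the
    smallest nonzero relative abundance in the prepared matrix, then
    log10 is taken.
    """
    samples = sample_sites.index[sample_sites == site]
    samples = [s for s in samples if s in otu_table.columns]
    if len(samples) < 4:
        raise InputError(f"site {site!r} has {len(samples)} samples; need >= 4")
    if min_prevalence is None:
        min_prevalence = math.ceil(len(samples) / 2)
    sub = otu_table[samples]
    keep = (sub > 0).sum(axis=1) >= min_prevalence
    if not keep.any():
        raise EmptyResultError(
            f"no OTU present in >= {min_prevalence} samples at site {site!r}")
    sub = sub.loc[keep].astype(float)
    rel = sub / sub.sum(axis=0)
    nonzero_min = rel.to_numpy()[rel.to_numpy() > 0].min()
    rel = rel.where(rel > 0, nonzero_min / 2.0)
    return np.log10(rel)


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson correlation matrix over an ordered OTU list."""

    otu_ids: list[str]
    r: np.ndarray
    n_samples: int

    def __post_init__(self):
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise InputError("correlation matrix must be symmetric")


def pairwise_pearson(prepared: pd.DataFrame) -> CorrelationMatrix:
    """Full Pearson correlation matrix between OTU abundance profiles.

    Zero-variance rows correlate 0 with every partner (warned, not an
    error); the diagonal is exactly 1.
    """
    if prepared.shape[1] < 3:
        raise InputError("need at least 3 samples for correlations")
    X = prepared.to_numpy(dtype=float)
    sd = X.std(axis=1)
    flat = sd == 0.0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance OTU(s): "
                      "correlations set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(X)
    r[flat, :] = 0.0
    r[:, flat] = 0.0
    r = np.nan_to_num(r, nan=0.0)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(list(prepared.index), r, prepared.shape[1])


# --------------------------------------------------------------------------
# Spectral unfolding and NNSD goodness of fit
# --------------------------------------------------------------------------

def unfold_spacings(eigenvalues: np.ndarray, n_knots: int = 11) -> np.ndarray:
    """Nearest-neighbour spacings of a spectrum, unfolded to unit mean.

    Degenerate (duplicate) eigenvalues are collapsed before unfolding.
    The cumulative spectral density is smoothed with a cubic least-squares
    spline on ``n_knots`` interior knots placed at quantiles; spacings are
    successive differences of the unfolded eigenvalues, normalized to
    mean 1.
    """
    ev = np.sort(np.asarray(eigenvalues, dtype=float))
    # collapse near-duplicates: spacing statistics concern distinct levels
    ev = ev[np.concatenate([[True], np.diff(ev) > 1e-8])]
    n = ev.size
    if n < 10:
        raise InputError(f"need >= 10 distinct eigenvalues, got {n}")
    cumulative = np.arange(1, n + 1, dtype=float)
    k = min(n_knots, max(1, n // 10))
    knots = np.quantile(ev, np.linspace(0, 1, k + 2)[1:-1])
    knots = np.unique(knots[(knots > ev[0]) & (knots < ev[-1])])
    try:
        spline = LSQUnivariateSpline(ev, cumulative, knots, k=3)
    except ValueError:  # knots violating Schoenberg-Whitney on clumpy spectra
        spline = LSQUnivariateSpline(ev, cumulative, knots[::2], k=3)
    unfolded = spline(ev)
    spacings = np.diff(unfolded)
    spacings = np.clip(spacings, 0.0, None)
    mean = spacings.mean()
    if mean <= 0:
        raise InputError("degenerate spectrum: all unfolded spacings are zero")
    return spacings / mean


def _chi2_gof(spacings: np.ndarray, inverse_cdf) -> tuple[float, float]:
    """Chi-square GOF of spacings against a null with the given quantile fn.

    Equal-probability bins (count = ceil(sqrt(#spacings))) keep expected
    counts uniform; df = bins - 1.
    """
    n = spacings.size
    k = max(3, math.ceil(math.sqrt(n)))
    edges = inverse_cdf(np.linspace(0.0, 1.0, k + 1))
    edges[0], edges[-1] = -np.inf, np.inf
    observed, _ = np.histogram(spacings, bins=edges)
    expected = n / k
    stat = float(((observed - expected) ** 2 / expected).sum())
    p = float(sps.chi2.sf(stat, k - 1))
    return stat, p


def _poisson_icdf(q):
    with np.errstate(divide="ignore"):
        return -np.log1p(-q)


def _wigner_icdf(q):
    with np.errstate(divide="ignore"):
        return np.sqrt(-4.0 * np.log1p(-q) / np.pi)


def nnsd_fit(eigenvalues: np.ndarray, n_knots: int = 11) -> dict:
    """Chi-square fit of a spectrum's NNSD against Poisson and GOE nulls.

    Poisson: P(d) = exp(-d) (uncorrelated levels, modular structure).
    GOE (Wigner surmise): P(d) = (pi d / 2) exp(-pi d^2 / 4) (level
    repulsion, noise-dominated spectrum).
    """
    spacings = unfold_spacings(eigenvalues, n_knots=n_knots)
    chi2_p, p_p = _chi2_gof(spacings, _poisson_icdf)
    chi2_g, p_g = _chi2_gof(spacings, _wigner_icdf)
    return {"chi2_poisson": chi2_p, "p_poisson": p_p,
            "chi2_goe": chi2_g, "p_goe": p_g,
            "n_spacings": spacings.size, "spacings": spacings}


# --------------------------------------------------------------------------
# RMT threshold scan
# --------------------------------------------------------------------------

@dataclass
class ThresholdReport:
    """Per-cutoff NNSD statistics and the chosen correlation cutoff."""

    scan: pd.DataFrame         # cutoff, n_nodes, chi2/p vs Poisson and GOE
    chosen_cutoff: float
    transition_found: bool

    def to_tsv(self, path) -> None:
        self.scan.to_csv(path, sep="\t", index=False)


def default_grid(start: float = 0.30, stop: float = 0.99,
                 step: float = 0.01) -> np.ndarray:
    return np.round(np.arange(start, stop + step / 2, step), 10)


def _thresholded_submatrix(r: np.ndarray, cutoff: float) -> np.ndarray:
    """Zero |r| < cutoff, keep unit diagonal, drop all-isolated rows."""
    m = np.where(np.abs(r) >= cutoff, r, 0.0)
    np.fill_diagonal(m, 1.0)
    active = (np.abs(m) > 0).sum(axis=1) > 1  # at least one off-diagonal
    return m[np.ix_(active, active)]


def rmt_threshold_scan(corr: CorrelationMatrix,
                       grid: np.ndarray | None = None,
                       min_nodes: int = 20,
                       n_knots: int = 11) -> ThresholdReport:
    """Scan cutoffs for the GOE -> Poisson transition of the NNSD.

    The chosen cutoff is the smallest grid value at which the Poisson fit
    is not rejected (chi-square p > 0.05) while the GOE fit is rejected.
    If no such cutoff exists, the cutoff with the best Poisson fit is
    returned with a logged warning.
    """
    if len(corr.otu_ids) < 20:
        raise InputError("NNSD statistics need >= 20 OTUs")
    if grid is None:
        grid = default_grid()
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(grid <= 0) or np.any(grid >= 1):
        raise InputError("grid cutoffs must lie strictly in (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise InputError("grid must be strictly increasing")

    rows = []
    for cutoff in grid:
        sub = _thresholded_submatrix(corr.r, float(cutoff))
        row = {"cutoff": float(cutoff), "n_nodes": sub.shape[0],
               "chi2_poisson": np.nan, "p_poisson": np.nan,
               "chi2_goe": np.nan, "p_goe": np.nan}
        if sub.shape[0] >= min_nodes:
            try:
                fit = nnsd_fit(np.linalg.eigvalsh(sub), n_knots=n_knots)
                row.update({key: fit[key] for key in
                            ("chi2_poisson", "p_poisson", "chi2_goe", "p_goe")})
            except InputError:
                pass
        rows.append(row)
    scan = pd.DataFrame(rows)

    valid = scan.dropna(subset=["p_poisson", "p_goe"])
    if valid.empty:
        raise NoTransitionError(
            "no cutoff yielded usable NNSD statistics; set a manual cutoff")
    hit = valid[(valid.p_poisson > 0.05) & (valid.p_goe <= 0.05)]
    if not hit.empty:
        return ThresholdReport(scan, float(hit.cutoff.iloc[0]), True)
    best = float(valid.loc[valid.p_poisson.idxmax(), "cutoff"])
    log.warning("no clean GOE->Poisson transition; falling back to best "
                "Poisson fit at cutoff %.3f", best)
    return ThresholdReport(scan, best, False)


# --------------------------------------------------------------------------
# Graph construction
# --------------------------------------------------------------------------

def build_network(corr: CorrelationMatrix, cutoff: float,
                  annotations: pd.DataFrame | None = None) -> nx.Graph:
    """Undirected signed network with edges where |r| >= cutoff.

    Isolated OTUs are excluded; node attributes carry trophic mode and
    guild when ``annotations`` (OTU-indexed with those columns) is given;
    edge attributes carry ``r`` and ``sign`` ('+' or '-').
    """
    if not 0.0 < cutoff <= 1.0:
        raise InputError("cutoff must lie in (0, 1]")
    ids = corr.otu_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(corr.r[iu, ju]) >= cutoff
    if not mask.any():
        raise EmptyNetworkError(f"cutoff {cutoff} yields zero edges")
    G = nx.Graph(cutoff=float(cutoff))
    for i, j in zip(iu[mask], ju[mask]):
        rij = float(corr.r[i, j])
        G.add_edge(ids[i], ids[j], r=rij, sign="+" if rij >= 0 else "-")
    if annotations is not None:
        for node in G.nodes:
            if node in annotations.index:
                G.nodes[node]["trophic_mode"] = str(
                    annotations.loc[node, "trophic_mode"])
                G.nodes[node]["guild"] = str(annotations.loc[node, "guild"])
    return G


def edge_sign_counts(G: nx.Graph) -> tuple[int, int]:
    """(positive, negative) edge counts."""
    pos = sum(1 for _, _, d in G.edges(data=True) if d.get("sign", "+") == "+")
    return pos, G.number_of_edges() - pos


def degree_powerlaw_r2(G: nx.Graph) -> float | None:
    """R^2 of the log-log least-squares fit of the degree distribution.

    Fits log10 P(k) on log10 k over observed degrees (zero-frequency
    degrees omitted).  Returns None when fewer than 3 distinct degrees
    exist.
    """
    degrees = np.array([d for _, d in G.degree()])
    ks, counts = np.unique(degrees[degrees > 0], return_counts=True)
    if ks.size < 3:
        return None
    pk = counts / counts.sum()
    fit = sps.linregress(np.log10(ks), np.log10(pk))
    return float(fit.rvalue ** 2)
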