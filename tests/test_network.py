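"""Abundance preparation, correlation, RMT thresholding, graph building."""

import numpy as np
import pandas as pd
import pytest

import fmenkit as fk
from fmenkit.errors import (EmptyNetworkError, EmptyResultError, InputError,
                            NoTransitionError)
from fmenkit.network import (CorrelationMatrix, default_grid,
                             edge_sign_counts, unfold_spacings)


def _sites(samples, site="SBT"):
    return pd.Series(site, index=samples)


# --------------------------------------------------------------------------
# prepare_abundance
# --------------------------------------------------------------------------

def test_prevalence_filter_drops_rare_otus():
    samples = [f"S{i}" for i in range(15)]
    counts = pd.DataFrame(0, index=["rare", "common"], columns=samples)
    counts.loc["rare", samples[:3]] = 5
    counts.loc["common"] = 7
    prep = fk.prepare_abundance(counts, _sites(samples), "SBT",
                                min_prevalence=8)
    assert list(prep.index) == ["common"]


def test_relative_abundance_sums_to_one_before_zero_replacement():
    samples = [f"S{i}" for i in range(6)]
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(1, 100, (5, 6)),
                          index=[f"O{i}" for i in range(5)], columns=samples)
    prep = fk.prepare_abundance(counts, _sites(samples), "SBT",
                                min_prevalence=1)
    rel = 10.0 ** prep
    np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)


def test_zeros_become_half_minimum_nonzero():
    samples = [f"S{i}" for i in range(4)]
    counts = pd.DataFrame([[0, 2, 2, 2], [998, 998, 998, 996],
                           [2, 0, 0, 2]],
                          index=["a", "b", "c"], columns=samples)
    prep = fk.prepare_abundance(counts, _sites(samples), "SBT",
                                min_prevalence=2)
    rel = 10.0 ** prep
    # min nonzero relative abundance is 2/1000; zeros -> 0.001
    assert rel.loc["a", "S0"] == pytest.approx(0.001)
    assert rel.loc["c", "S1"] == pytest.approx(0.001)


def test_empty_filter_result_errors():
    samples = [f"S{i}" for i in range(5)]
    counts = pd.DataFrame(0, index=["a"], columns=samples)
    counts.loc["a", "S0"] = 1
    with pytest.raises(EmptyResultError):
        fk.prepare_abundance(counts, _sites(samples), "SBT", min_prevalence=4)


def test_too_few_site_samples_errors():
    samples = ["S0", "S1", "S2"]
    counts = pd.DataFrame(1, index=["a"], columns=samples)
    with pytest.raises(InputError):
        fk.prepare_abundance(counts, _sites(samples), "SBT")


# --------------------------------------------------------------------------
# pairwise_pearson
# --------------------------------------------------------------------------

def test_affine_rows_fully_correlated(rng):
    x = rng.normal(size=10)
    prep = pd.DataFrame([x, 2 * x + 3], index=["a", "b"])
    corr = fk.pairwise_pearson(prep)
    assert corr.r[0, 1] == pytest.approx(1.0)
    np.testing.assert_allclose(np.diag(corr.r), 1.0)


def test_matches_covariance_formula_oracle(rng):
    X = rng.normal(size=(4, 10))
    corr = fk.pairwise_pearson(pd.DataFrame(X))
    for i in range(4):
        for j in range(4):
            xi, xj = X[i] - X[i].mean(), X[j] - X[j].mean()
            expected = (xi @ xj) / np.sqrt((xi @ xi) * (xj @ xj))
            assert corr.r[i, j] == pytest.approx(expected, abs=1e-12)


def test_zero_variance_row_warns_and_zeroes(rng):
    prep = pd.DataFrame([np.ones(6), rng.normal(size=6)], index=["flat", "x"])
    with pytest.warns(UserWarning, match="zero-variance"):
        corr = fk.pairwise_pearson(prep)
    assert corr.r[0, 1] == 0.0 and corr.r[0, 0] == 1.0


def test_asymmetric_matrix_rejected():
    bad = np.array([[1.0, 0.5], [0.4, 1.0]])
    with pytest.raises(InputError):
        CorrelationMatrix(["a", "b"], bad, 10)


# --------------------------------------------------------------------------
# unfolding and NNSD
# --------------------------------------------------------------------------

def test_unfolded_spacings_have_unit_mean(rng):
    A = rng.standard_normal((200, 200))
    spacings = unfold_spacings(np.linalg.eigvalsh((A + A.T) / 2))
    assert spacings.mean() == pytest.approx(1.0, abs=0.05)


def test_goe_spectrum_wigner_yes_poisson_no():
    """A pure GOE matrix must look Wigner, not Poisson (9+ of 10 seeds)."""
    wigner_pass = poisson_reject = 0
    for seed in range(10):
        r = np.random.default_rng(seed)
        A = r.standard_normal((500, 500))
        fit = fk.nnsd_fit(np.linalg.eigvalsh((A + A.T) / np.sqrt(2)))
        wigner_pass += fit["p_goe"] > 0.05
        poisson_reject += fit["p_poisson"] <= 0.05
    assert wigner_pass >= 9
    assert poisson_reject >= 9


def test_poisson_spectrum_accepted_as_poisson():
    """Independent uniform levels have Poisson spacing statistics."""
    accept = 0
    for seed in range(10):
        levels = np.sort(np.random.default_rng(seed).uniform(0, 1, 500))
        fit = fk.nnsd_fit(levels)
        accept += fit["p_poisson"] > 0.05
    assert accept >= 9


def _planted_blocks(rng, n_blocks=5, per_block=20, n_samples=200,
                    within_r=0.9, between_r=0.3):
    """Block factors plus a weak global factor: within-|r| ~ within_r,
    between-|r| ~ between_r."""
    a = np.sqrt(within_r - between_r)
    c = np.sqrt(between_r)
    e = np.sqrt(1 - within_r)
    g = rng.standard_normal(n_samples)
    rows = []
    for _ in range(n_blocks):
        f = rng.standard_normal(n_samples)
        rows.append(a * f[None, :] + c * g[None, :]
                    + e * rng.standard_normal((per_block, n_samples)))
    return pd.DataFrame(np.vstack(rows),
                        index=[f"V{i}" for i in range(n_blocks * per_block)])


def test_rmt_scan_finds_cutoff_between_block_correlation_levels(rng):
    prep = _planted_blocks(rng)
    corr = fk.pairwise_pearson(prep)
    report = fk.rmt_threshold_scan(corr)
    assert 0.3 < report.chosen_cutoff < 0.9
    assert report.chosen_cutoff in set(report.scan["cutoff"])


def test_rmt_scan_rejects_tiny_matrices(rng):
    prep = pd.DataFrame(rng.normal(size=(10, 30)))
    with pytest.raises(InputError):
        fk.rmt_threshold_scan(fk.pairwise_pearson(prep))


def test_rmt_scan_no_survivors_errors(rng):
    prep = pd.DataFrame(rng.normal(size=(25, 200)))
    corr = fk.pairwise_pearson(prep)
    assert np.abs(corr.r[np.triu_indices(25, 1)]).max() < 0.999
    with pytest.raises(NoTransitionError):
        fk.rmt_threshold_scan(corr, grid=np.array([0.999]))


def test_default_grid_strictly_increasing_in_unit_interval():
    grid = default_grid()
    assert np.all(np.diff(grid) > 0)
    assert grid[0] >= 0.3 and grid[-1] <= 0.99


# --------------------------------------------------------------------------
# build_network
# --------------------------------------------------------------------------

def _corr_from(offdiag):
    r = np.eye(3)
    r[0, 1] = r[1, 0] = offdiag[0]
    r[0, 2] = r[2, 0] = offdiag[1]
    r[1, 2] = r[2, 1] = offdiag[2]
    return CorrelationMatrix(["a", "b", "c"], r, 10)


def test_edges_and_signs_at_cutoff():
    G = fk.build_network(_corr_from([0.8, -0.75, 0.5]), 0.69)
    assert G.number_of_edges() == 2
    signs = sorted(d["sign"] for _, _, d in G.edges(data=True))
    assert signs == ["+", "-"]
    assert edge_sign_counts(G) == (1, 1)


def test_high_cutoff_empty_network_errors():
    with pytest.raises(EmptyNetworkError):
        fk.build_network(_corr_from([0.8, -0.75, 0.5]), 0.95)


def test_isolated_nodes_excluded():
    G = fk.build_network(_corr_from([0.8, 0.1, 0.1]), 0.69)
    assert set(G.nodes) == {"a", "b"}


def test_edge_count_matches_bruteforce_scan(rng):
    for _ in range(50):
        n = int(rng.integers(5, 15))
        A = rng.uniform(-1, 1, (n, n))
        r = np.clip((A + A.T) / 2, -1, 1)
        np.fill_diagonal(r, 1.0)
        corr = CorrelationMatrix([f"O{i}" for i in range(n)], r, 20)
        cutoff = float(rng.uniform(0.2, 0.8))
        expected = sum(1 for i in range(n) for j in range(i + 1, n)
                       if abs(r[i, j]) >= cutoff)
        if expected == 0:
            with pytest.raises(EmptyNetworkError):
                fk.build_network(corr, cutoff)
        else:
            assert fk.build_network(corr, cutoff).number_of_edges() == expected


def test_edge_count_monotone_in_cutoff(rng):
    prep = _planted_blocks(rng, n_blocks=3, per_block=10, n_samples=50)
    corr = fk.pairwise_pearson(prep)
    counts = []
    for cutoff in (0.3, 0.5, 0.7, 0.9):
        try:
            counts.append(fk.build_network(corr, cutoff).number_of_edges())
        except EmptyNetworkError:
            counts.append(0)
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_node_annotations_attached(small_community, small_assignment):
    prep = fk.prepare_abundance(small_community.otu_table,
                                small_community.soil["site"], "SBT")
    corr = fk.pairwise_pearson(prep)
    G = fk.build_network(corr, 0.8, small_assignment)
    assert all("trophic_mode" in G.nodes[n] for n in G.nodes)


# --------------------------------------------------------------------------
# degree power law
# --------------------------------------------------------------------------

def test_exact_powerlaw_histogram_r2_is_1():
    # degree counts 36, 9, 4 at degrees 1, 2, 3: exactly P(k) ~ k^-2
    counts = {1: 36, 2: 9, 3: 4}
    degrees = [k for k, c in counts.items() for _ in range(c)]

    class Stub:
        def degree(self):
            return list(enumerate(degrees))

    r2 = fk.degree_powerlaw_r2(Stub())
    assert r2 == pytest.approx(1.0, abs=1e-12)


def test_regular_graph_r2_missing():
    import networkx as nx
    assert fk.degree_powerlaw_r2(nx.cycle_graph(6)) is None


def test_toy_histogram_matches_hand_least_squares():
    degrees = [1] * 64 + [2] * 26 + [4] * 10

    class Stub:
        def degree(self):
            return list(enumerate(degrees))

    r2 = fk.degree_powerlaw_r2(Stub())
    x = np.log10([1, 2, 4])
    y = np.log10([0.64, 0.26, 0.10])
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = ((y - (slope * x + intercept)) ** 2).sum()
    ss_tot = ((y - y.mean()) ** 2).sum()
    assert r2 == pytest.approx(1 - ss_res / ss_tot, abs=1e-9)
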