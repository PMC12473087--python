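"""Module summaries and module-environment correlation.

Each network module is summarized by its eigengene — the first principal
component of the standardized log-abundance profiles of its member OTUs —
the conventional representative-module statistic.  Eigengenes are then
clustered hierarchically (average linkage on 1 - Pearson distance) and
screened against soil variables with Pearson tests, the heatmap
convention being r with (p) annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .errors import InputError
from .stats import CorrelationScreen, correlation_screen

MIN_MODULE_SIZE = 2


@dataclass
class ModuleEigengene:
    """Per-sample representative signal of one module."""

    module: int
    scores: pd.Series              # zero mean, unit variance over samples
    variance_explained: float      # leading eigenvalue share in (0, 1]


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def module_eigengene(prepared: pd.DataFrame, partition: dict,
                     module_id: int, method: str = "eigengene"
                     ) -> ModuleEigengene:
    """First principal component of a module's member profiles.

    Member OTU log abundances are z-scored across samples before the
    decomposition; the eigengene sign is oriented so its mean correlation
    with member profiles is non-negative (falling back to a positive
    first element on exact zero), making regeneration reproducible.
    A singleton module returns the member's standardized profile with
    variance explained 1 and a warning.  ``method="mean"`` swaps the PCA
    summary for the standardized mean member profile.
    """
    if method not in ("eigengene", "mean"):
        raise InputError(f"unknown summary method {method!r}")
    members = [otu for otu, mod in partition.items()
               if mod == module_id and otu in prepared.index]
    if not members:
        raise InputError(f"module {module_id} has no members in the matrix")
    Z = np.vstack([_standardize(prepared.loc[m].to_numpy(dtype=float))
                   for m in members])
    if method == "mean" and len(members) >= MIN_MODULE_SIZE:
        mean_profile = _standardize(Z.mean(axis=0))
        # variance explained analogue: share of member variance captured
        proj = np.array([np.corrcoef(mean_profile, row)[0, 1] ** 2
                         for row in Z if row.std() > 0])
        return ModuleEigengene(module_id,
                               pd.Series(mean_profile, index=prepared.columns),
                               float(proj.mean()) if proj.size else 1.0)
    if len(members) < MIN_MODULE_SIZE:
        warnings.warn(f"module {module_id} is a singleton; returning the "
                      "member profile")
        scores = _standardize(Z[0])
        return ModuleEigengene(module_id, pd.Series(scores,
                               index=prepared.columns), 1.0)
    # SVD of members x samples: right singular vectors live in sample space
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    eigengene = Vt[0]
    member_corr = np.array([np.corrcoef(eigengene, row)[0, 1] for row in Z
                            if row.std() > 0])
    orientation = member_corr.mean() if member_corr.size else 0.0
    if orientation < 0 or (orientation == 0 and eigengene[0] < 0):
        eigengene = -eigengene
    var_explained = float(s[0] ** 2 / (s ** 2).sum())
    return ModuleEigengene(module_id,
                           pd.Series(_standardize(eigengene),
                                     index=prepared.columns),
                           var_explained)


def module_eigengenes(prepared: pd.DataFrame, partition: dict,
                      min_size: int = MIN_MODULE_SIZE,
                      method: str = "eigengene"
                      ) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengenes of every module with >= ``min_size`` members.

    Returns (modules x samples score matrix, per-module variance
    explained), module rows labelled ``M<id>``.
    """
    present = pd.Series({otu: mod for otu, mod in partition.items()
                         if otu in prepared.index})
    sizes = present.value_counts()
    keep = sorted(sizes.index[sizes >= min_size])
    if not keep:
        raise InputError("no module meets the minimum size")
    scores, var = {}, {}
    for mod in keep:
        eg = module_eigengene(prepared, partition, mod, method=method)
        scores[f"M{mod}"] = eg.scores
        var[f"M{mod}"] = eg.variance_explained
    return pd.DataFrame(scores).T, pd.Series(var, name="variance_explained")


def module_hierarchy(eigengene_df: pd.DataFrame) -> np.ndarray:
    """Average-linkage merge tree of eigengenes on d = 1 - Pearson r.

    Returns a scipy linkage matrix over the rows of ``eigengene_df``
    (modules ordered as given, which fixes tie-breaking).
    """
    if eigengene_df.shape[0] < 2:
        raise InputError("need at least 2 eigengenes to cluster")
    corr = np.corrcoef(eigengene_df.to_numpy(dtype=float))
    d = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(d, 0.0)
    return linkage(squareform(d, checks=False), method="average")


def module_env_correlation(eigengene_df: pd.DataFrame, soil: pd.DataFrame,
                           adjust: bool = False) -> CorrelationScreen:
    """Pearson screen of module eigengenes against soil variables.

    ``soil`` is a samples x variables frame (a ``site`` column, if
    present, is dropped); samples are aligned on the eigengene columns.
    """
    soil_numeric = soil.drop(columns=["site"], errors="ignore")
    return correlation_screen(eigengene_df, soil_numeric.T, adjust=adjust)


def heatmap_annotation(screen: CorrelationScreen,
                       r_decimals: int = 2) -> pd.DataFrame:
    """Annotated heatmap cells in the 'r (p)' convention."""
    out = screen.r.copy().astype(object)
    for i in screen.r.index:
        for j in screen.r.columns:
            r, p = screen.r.loc[i, j], screen.p.loc[i, j]
            out.loc[i, j] = ("NA" if not np.isfinite(r)
                             else f"{round(r, r_decimals)} ({p:.2g})")
    return out
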