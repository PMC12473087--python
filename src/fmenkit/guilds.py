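"""FUNGuild-style trophic-mode / functional-guild annotation.

An OTU is matched against the guild database at its most specific
taxonomic rank that has a record of sufficient confidence; unmatched OTUs
are labelled ``Unassigned``.  Assignments are then aggregated to
relative-abundance matrices (percent of per-sample total counts) at the
trophic-mode or guild level.
"""

from __future__ import annotations

import pandas as pd

from .errors import InputError

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

#: Confidence ordering used for the ``min_confidence`` filter.
_CONFIDENCE_ORDER = {"Possible": 0, "Probable": 1, "Highly Probable": 2}

UNASSIGNED = "Unassigned"


def assign_guilds(taxonomy: pd.DataFrame, db: pd.DataFrame,
                  min_confidence: str = "Probable") -> pd.DataFrame:
    """Assign a trophic mode and guild to every OTU in ``taxonomy``.

    Parameters
    ----------
    taxonomy
        OTU-indexed frame with columns from :data:`RANKS` (missing ranks
        allowed).  Index must be unique.
    db
        Guild database with columns ``taxon``, ``taxonomicLevel``,
        ``trophicMode``, ``guild``, ``confidenceRanking`` (FUNGuild
        flat-file style).  The guild label ``"NULL"`` is an ordinary
        category and is preserved literally.
    min_confidence
        Records below this confidence are ignored.

    Returns
    -------
    DataFrame indexed like ``taxonomy`` with columns ``trophic_mode``,
    ``guild``, ``matched_rank``, ``confidence``; exactly one row per OTU.
    """
    if taxonomy.empty:
        raise InputError("taxonomy table is empty")
    if taxonomy.index.duplicated().any():
        dupes = taxonomy.index[taxonomy.index.duplicated()].unique().tolist()
        raise InputError(f"duplicate otu_id in taxonomy: {dupes}")
    if min_confidence not in _CONFIDENCE_ORDER:
        raise InputError(f"unknown confidence level {min_confidence!r}")
    floor = _CONFIDENCE_ORDER[min_confidence]

    lookup: dict[tuple[str, str], tuple[str, str, str]] = {}
    for rec in db.itertuples(index=False):
        if _CONFIDENCE_ORDER.get(rec.confidenceRanking, -1) >= floor:
            lookup[(rec.taxonomicLevel, rec.taxon)] = (
                rec.trophicMode, rec.guild, rec.confidenceRanking)

    rows = []
    ranked = [r for r in RANKS if r in taxonomy.columns]
    for otu, lineage in taxonomy[ranked].iterrows():
        record = (UNASSIGNED, UNASSIGNED, "", "")
        for rank in reversed(ranked):  # species first: most specific wins
            name = lineage[rank]
            if pd.isna(name):
                continue
            hit = lookup.get((rank, name))
            if hit is not None:
                record = (hit[0], hit[1], rank, hit[2])
                break
        rows.append(record)
    return pd.DataFrame(
        rows, index=taxonomy.index,
        columns=["trophic_mode", "guild", "matched_rank", "confidence"])


def aggregate(otu_table: pd.DataFrame, assignment: pd.DataFrame,
              level: str = "trophic_mode") -> pd.DataFrame:
    """Aggregate counts to per-sample relative abundances (%) by category.

    For each sample, a category's relative abundance is 100 x (counts of
    OTUs assigned to it) / (total counts in the sample), so assigned
    categories plus the ``Unassigned`` row sum to exactly 100%.
    """
    if level not in ("trophic_mode", "guild"):
        raise InputError(f"level must be 'trophic_mode' or 'guild', got {level!r}")
    missing = otu_table.index.difference(assignment.index)
    if len(missing):
        raise InputError(f"assignment missing OTUs: {missing.tolist()[:5]}")
    totals = otu_table.sum(axis=0)
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise InputError(f"sample(s) with zero total counts: {empty}")

    categories = assignment.loc[otu_table.index, level]
    grouped = otu_table.groupby(categories.values).sum()
    fa = 100.0 * grouped / totals
    fa.index.name = level
    return fa.sort_index()


def site_means(fa: pd.DataFrame, sample_sites: pd.Series) -> pd.DataFrame:
    """Unweighted per-site means of a categories x samples matrix."""
    return fa.T.groupby(sample_sites.loc[fa.columns]).mean().T


def dominant_guilds(fa: pd.DataFrame, k: int = 10,
                    exclude_unassigned: bool = True) -> list[str]:
    """The ``k`` categories with the highest mean relative abundance.

    Means are taken across the columns of ``fa`` (samples or sites);
    ties break by lexicographic label order.  Requesting more categories
    than exist returns them all.
    """
    if k < 1:
        raise InputError("k must be >= 1")
    means = fa.mean(axis=1)
    if exclude_unassigned:
        means = means.drop(UNASSIGNED, errors="ignore")
    ordered = means.sort_index().sort_values(ascending=False, kind="stable")
    return ordered.index[:k].tolist()
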