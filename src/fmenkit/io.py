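"""Readers, writers, Gephi export, and pipeline orchestration.

All tables travel as UTF-8 tab-separated files with a header row.
Metadata (seed, package version) is embedded as ``##``-prefixed comment
lines above the header; a BIOM-style ``#OTU ID`` first column is accepted
on read.  Networks are exported as GEXF (Gephi native) or GraphML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import guilds, module_env, network, stats, topology
from .errors import ConfigError, FmenkitError, InputError

log = logging.getLogger(__name__)

_META_PREFIX = "##"


# --------------------------------------------------------------------------
# TSV primitives
# --------------------------------------------------------------------------

def write_tsv(df: pd.DataFrame, path, metadata: dict | None = None,
              index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for key, value in (metadata or {}).items():
            fh.write(f"{_META_PREFIX} {key}: {value}\n")
        df.to_csv(fh, sep="\t", index=index)


def _read_tsv(path, **kwargs) -> pd.DataFrame:
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh if not ln.startswith(_META_PREFIX)]
    from io import StringIO
    return pd.read_csv(StringIO("".join(lines)), sep="\t", **kwargs)


def read_otu_table(path) -> pd.DataFrame:
    """Read and validate an OTU count table (OTU rows, sample columns)."""
    df = _read_tsv(path)
    if df.empty or df.shape[1] < 2:
        raise InputError(f"{path}: empty or column-less OTU table")
    first = df.columns[0]
    if first not in ("otu_id", "#OTU ID"):
        log.info("treating first column %r as the OTU id", first)
    df = df.set_index(first)
    df.index.name = "otu_id"
    dup = df.index[df.index.duplicated()].unique().tolist()
    if dup:
        raise InputError(f"{path}: duplicate OTU id(s): {dup[:5]}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna()].tolist()
        if bad:
            raise InputError(
                f"{path}: non-numeric count at row {bad[0]!r}, column {col!r}")
        if (numeric < 0).any():
            row = df.index[numeric < 0][0]
            raise InputError(
                f"{path}: negative count at row {row!r}, column {col!r}")
        if not np.allclose(numeric, numeric.round()):
            row = df.index[~np.isclose(numeric, numeric.round())][0]
            raise InputError(
                f"{path}: non-integer count at row {row!r}, column {col!r}")
        df[col] = numeric.astype(np.int64)
    return df


def read_taxonomy(path) -> pd.DataFrame:
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "otu_id"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise InputError(f"{path}: duplicate OTU id(s) in taxonomy: {dup[:5]}")
    return df


def read_guild_db(path) -> pd.DataFrame:
    # "NULL" is a literal guild category, never a missing value
    df = _read_tsv(path, keep_default_na=False)
    required = {"taxon", "taxonomicLevel", "trophicMode", "guild",
                "confidenceRanking"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: guild DB missing columns {sorted(missing)}")
    if df.duplicated(subset=["taxon", "taxonomicLevel"]).any():
        raise InputError(f"{path}: duplicate (taxon, taxonomicLevel) records")
    return df


def read_soil_table(path, site_column: str = "site") -> pd.DataFrame:
    df = _read_tsv(path)
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    if site_column not in df.columns:
        raise InputError(f"{path}: missing site column {site_column!r}")
    for col in df.columns:
        if col == site_column:
            continue
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = df.index[numeric.isna()][0]
            raise InputError(
                f"{path}: non-numeric value at row {row!r}, column {col!r}")
        df[col] = numeric
    return df


# --------------------------------------------------------------------------
# Gephi export
# --------------------------------------------------------------------------

def export_gephi(G: nx.Graph, roles: pd.DataFrame, partition: dict,
                 path, fmt: str = "gexf") -> None:
    """Write the annotated network for Gephi (GEXF) or GraphML.

    Node attributes: trophic_mode, guild, module, Zi, Pi, role; edge
    attributes: r, sign.  The graph is undirected.
    """
    missing = [n for n in G.nodes if n not in partition or n not in roles.index]
    if missing:
        raise InputError(f"roles/partition missing nodes: {missing[:5]}")
    H = nx.Graph()
    H.graph.update({k: _plain(v) for k, v in G.graph.items() if v is not None})
    for node, data in G.nodes(data=True):
        H.add_node(node,
                   trophic_mode=str(data.get("trophic_mode", "Unassigned")),
                   guild=str(data.get("guild", "Unassigned")),
                   module=int(partition[node]),
                   Zi=float(roles.loc[node, "Zi"]),
                   Pi=float(roles.loc[node, "Pi"]),
                   role=str(roles.loc[node, "role"]))
    for u, v, data in G.edges(data=True):
        H.add_edge(u, v, r=float(data["r"]), sign=str(data["sign"]))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "gexf":
        nx.write_gexf(H, path)
    elif fmt == "graphml":
        nx.write_graphml(H, path)
    else:
        raise ConfigError(f"unknown export format {fmt!r}")


def _plain(value):
    if isinstance(value, (np.floating, np.integer)):
        return value.item()
    return value


# --------------------------------------------------------------------------
# Pipeline configuration and orchestration
# --------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs."""

    otu_path: str
    taxonomy_path: str
    guild_db_path: str
    soil_path: str
    out_dir: str
    site_column: str = "site"
    min_confidence: str = "Probable"
    min_prevalence: int | None = None
    cutoff: float | None = None          # overrides the RMT scan
    grid_start: float = 0.30
    grid_stop: float = 0.99
    grid_step: float = 0.01
    equal_var: bool = False              # Student instead of Welch
    hellinger: bool = False              # RDA response transform
    adjust_p: bool = False               # Benjamini-Hochberg columns
    top_k_guilds: int = 10
    export_format: str = "gexf"
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for name in ("otu_path", "taxonomy_path", "guild_db_path", "soil_path"):
            p = getattr(self, name)
            if not Path(p).is_file():
                raise ConfigError(f"{name} does not exist: {p}")
        if self.cutoff is not None and not 0.0 < self.cutoff <= 1.0:
            raise ConfigError("cutoff override must lie in (0, 1]")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run annotate -> aggregate -> stats -> networks -> modules-env.

    Writes every report into ``config.out_dir`` and returns a result
    bundle; a manifest lists all outputs with checksums.  Any stage error
    aborts with the stage name attached.
    """
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "tool": "fmenkit"}
    bundle: dict = {}
    stage = "read-inputs"
    try:
        otu = read_otu_table(config.otu_path)
        taxonomy = read_taxonomy(config.taxonomy_path)
        db = read_guild_db(config.guild_db_path)
        soil = read_soil_table(config.soil_path, config.site_column)
        sample_sites = soil[config.site_column]
        soil_vars = soil.drop(columns=[config.site_column])
        sites = list(dict.fromkeys(sample_sites))

        stage = "annotate"
        assignment = guilds.assign_guilds(taxonomy, db, config.min_confidence)
        write_tsv(assignment, out / "guild_assignment.tsv", meta)
        bundle["assignment"] = assignment

        stage = "aggregate"
        fa_mode = guilds.aggregate(otu, assignment, "trophic_mode")
        fa_guild = guilds.aggregate(otu, assignment, "guild")
        mode_site = guilds.site_means(fa_mode, sample_sites)
        guild_site = guilds.site_means(fa_guild, sample_sites)
        dominant = guilds.dominant_guilds(fa_guild, config.top_k_guilds)
        for name, df in (("trophic_mode_by_sample", fa_mode),
                         ("trophic_mode_by_site", mode_site),
                         ("guild_by_sample", fa_guild),
                         ("guild_by_site", guild_site)):
            write_tsv(df, out / f"{name}.tsv", meta)
        bundle.update(fa_mode=fa_mode, fa_guild=fa_guild,
                      mode_site_means=mode_site, guild_site_means=guild_site,
                      dominant_guilds=dominant)

        stage = "stats"
        from .reports import (functional_comparison_report,
                              soil_property_report)
        if len(sites) >= 2:
            soil_report = soil_property_report(
                soil, site_column=config.site_column,
                equal_var=config.equal_var)
            write_tsv(soil_report, out / "soil_properties.tsv", meta,
                      index=False)
            mode_report = functional_comparison_report(fa_mode, sample_sites)
            guild_report = functional_comparison_report(fa_guild, sample_sites)
            write_tsv(mode_report, out / "trophic_mode_tests.tsv", meta,
                      index=False)
            write_tsv(guild_report, out / "guild_tests.tsv", meta,
                      index=False)
            bundle.update(soil_report=soil_report, mode_report=mode_report,
                          guild_report=guild_report)
        screens, rdas = {}, {}
        for site in sites:
            cols = sample_sites.index[sample_sites == site]
            screen = stats.correlation_screen(
                fa_mode.drop(index=guilds.UNASSIGNED, errors="ignore")[cols],
                soil_vars.loc[cols].T, adjust=config.adjust_p)
            write_tsv(screen.to_long(), out / f"trophic_soil_corr_{site}.tsv",
                      meta, index=False)
            screens[site] = screen
            response = fa_mode.drop(index=guilds.UNASSIGNED,
                                    errors="ignore")[cols].T
            if config.hellinger:
                response = stats.hellinger(response / 100.0)
            rdas[site] = stats.rda(response, soil_vars.loc[cols])
        bundle.update(trophic_soil_screens=screens, rda=rdas)

        summaries, networks, partitions, role_tables = {}, {}, {}, {}
        eigengene_frames = {}
        for site in sites:
            stage = f"network[{site}]"
            prepared = network.prepare_abundance(
                otu, sample_sites, site, config.min_prevalence)
            corr = network.pairwise_pearson(prepared)
            if config.cutoff is not None:
                cutoff, report = config.cutoff, None
            else:
                report = network.rmt_threshold_scan(
                    corr, network.default_grid(config.grid_start,
                                               config.grid_stop,
                                               config.grid_step))
                cutoff = report.chosen_cutoff
                report.scan.to_csv(out / f"rmt_scan_{site}.tsv", sep="\t",
                                   index=False)
            G = network.build_network(corr, cutoff, assignment)
            edges = pd.DataFrame(
                [(u, v, d["r"], d["sign"]) for u, v, d in G.edges(data=True)],
                columns=["source", "target", "r", "sign"])
            write_tsv(edges, out / f"edges_{site}.tsv", meta, index=False)

            stage = f"topology[{site}]"
            partition, q = topology.detect_modules(G)
            summary = topology.topology_summary(G, partition)
            roles = topology.node_roles(G, partition)
            node_table = roles.copy()
            node_table["trophic_mode"] = [
                G.nodes[n].get("trophic_mode", "Unassigned")
                for n in node_table.index]
            node_table["guild"] = [G.nodes[n].get("guild", "Unassigned")
                                   for n in node_table.index]
            write_tsv(node_table, out / f"nodes_{site}.tsv", meta)
            export_gephi(G, roles, partition,
                         out / f"network_{site}.{config.export_format}",
                         config.export_format)
            summaries[site] = summary
            networks[site] = G
            partitions[site] = partition
            role_tables[site] = roles

            stage = f"modules-env[{site}]"
            eigengenes, var_expl = module_env.module_eigengenes(
                prepared, partition)
            write_tsv(eigengenes, out / f"eigengenes_{site}.tsv", meta)
            if eigengenes.shape[0] >= 2:
                link = module_env.module_hierarchy(eigengenes)
                write_tsv(pd.DataFrame(
                    link, columns=["left", "right", "height", "size"]),
                    out / f"module_linkage_{site}.tsv", meta, index=False)
            env_screen = module_env.module_env_correlation(
                eigengenes, soil.loc[eigengenes.columns],
                adjust=config.adjust_p)
            write_tsv(env_screen.to_long(),
                      out / f"module_soil_corr_{site}.tsv", meta, index=False)
            bundle.setdefault("eigengenes", {})[site] = (eigengenes, var_expl)
            bundle.setdefault("module_soil", {})[site] = env_screen
            eigengene_frames[site] = eigengenes

        stage = "summary"
        summary_table = pd.DataFrame(
            {site: s.to_series() for site, s in summaries.items()}).T
        summary_table.index.name = "site"
        write_tsv(summary_table, out / "topology_summary.tsv", meta)
        bundle.update(networks=networks, partitions=partitions,
                      roles=role_tables, topology=summaries)
        if len(sites) >= 2:
            comparison = topology.compare_node_sets(networks[sites[0]],
                                                    networks[sites[1]])
            (out / "node_venn.json").write_text(
                json.dumps(comparison.counts, indent=2))
            bundle["node_comparison"] = comparison

        stage = "manifest"
        manifest = {
            "config": dataclasses.asdict(config),
            "seed": config.seed,
            "outputs": {p.name: _sha256(p)
                        for p in sorted(out.iterdir()) if p.is_file()
                        and p.name != "manifest.json"},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=str))
        bundle["manifest"] = manifest
        return bundle
    except FmenkitError as err:
        raise FmenkitError(f"pipeline stage {stage!r} failed: {err}") from err
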