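"""Synthetic rhizosphere fungal community generator.

Produces OTU count tables, taxonomy tables, a FUNGuild-style lookup
database, and soil physicochemical metadata with the statistical structure
the downstream analysis assumes: groups of OTUs share a latent per-sample
factor (planted correlation modules), soil variables are linear
combinations of those module factors plus noise, and a configurable
fraction of OTUs carries taxa that the guild database can resolve.

The generator is the test bed for every downstream stage; a config plus a
seed reproduces its outputs element-for-element.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigError

#: The seven composite trophic modes observed in temperate rhizosphere
#: fungal communities (atomic labels; composites are never split).
TROPHIC_MODES = (
    "Symbiotroph",
    "Saprotroph-Symbiotroph",
    "Saprotroph",
    "Pathotroph-Symbiotroph",
    "Pathotroph-Saprotroph-Symbiotroph",
    "Pathotroph-Saprotroph",
    "Pathotroph",
)

#: The 13 soil physicochemical variables tracked by the pipeline.
SOIL_VARIABLES = (
    "SWC", "pH", "TN", "AN", "NO3-N", "NH4-N", "SOC",
    "TP", "AP", "TK", "AK", "MBC", "MBN",
)

# Site-level (mean, sd) used to place soil variables on realistic scales
# (soil water content in %, pH unitless, TN/SOC/TP/TK in g/kg, the rest in
# mg/kg).  Values emulate acidic montane forest soil.
_SOIL_SCALE = {
    "SWC": ((40.5, 48.8), 15.0),
    "pH": ((4.30, 4.38), 0.22),
    "TN": ((5.57, 5.38), 1.5),
    "AN": ((285.6, 279.9), 90.0),
    "NO3-N": ((5.0, 8.7), 8.0),
    "NH4-N": ((31.1, 30.9), 13.0),
    "SOC": ((72.7, 64.2), 17.0),
    "TP": ((0.44, 0.71), 0.45),
    "AP": ((3.4, 4.7), 4.0),
    "TK": ((22.3, 17.6), 4.2),
    "AK": ((95.7, 80.8), 18.5),
    "MBC": ((1062.0, 1093.0), 440.0),
    "MBN": ((456.0, 365.0), 150.0),
}

# Lineage pool.  Genera in the "assigned" pool receive guild-database
# records; the "unassigned" pool never does.  Lineages are plausible but
# synthetic stand-ins, not a curated reference taxonomy.
_ASSIGNED_GENERA = [
    ("Ascomycota", "Leotiomycetes", "Helotiales", "Hyaloscyphaceae", "Hyaloscypha"),
    ("Ascomycota", "Leotiomycetes", "Helotiales", "Myxotrichaceae", "Oidiodendron"),
    ("Ascomycota", "Leotiomycetes", "Helotiales", "Vibrisseaceae", "Phialocephala"),
    ("Ascomycota", "Leotiomycetes", "Helotiales", "Helotiaceae", "Meliniomyces"),
    ("Ascomycota", "Leotiomycetes", "Thelebolales", "Pseudeurotiaceae", "Pseudeurotium"),
    ("Ascomycota", "Sordariomycetes", "Hypocreales", "Hypocreaceae", "Trichoderma"),
    ("Ascomycota", "Sordariomycetes", "Hypocreales", "Nectriaceae", "Fusarium"),
    ("Ascomycota", "Sordariomycetes", "Hypocreales", "Cordycipitaceae", "Beauveria"),
    ("Ascomycota", "Sordariomycetes", "Hypocreales", "Clavicipitaceae", "Metarhizium"),
    ("Ascomycota", "Sordariomycetes", "Sordariales", "Chaetomiaceae", "Chaetomium"),
    ("Ascomycota", "Sordariomycetes", "Sordariales", "Lasiosphaeriaceae", "Podospora"),
    ("Ascomycota", "Sordariomycetes", "Xylariales", "Xylariaceae", "Xylaria"),
    ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", "Aspergillus"),
    ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Aspergillaceae", "Penicillium"),
    ("Ascomycota", "Eurotiomycetes", "Eurotiales", "Trichocomaceae", "Talaromyces"),
    ("Ascomycota", "Eurotiomycetes", "Chaetothyriales", "Herpotrichiellaceae", "Exophiala"),
    ("Ascomycota", "Eurotiomycetes", "Chaetothyriales", "Herpotrichiellaceae", "Cladophialophora"),
    ("Ascomycota", "Dothideomycetes", "Capnodiales", "Cladosporiaceae", "Cladosporium"),
    ("Ascomycota", "Dothideomycetes", "Pleosporales", "Pleosporaceae", "Alternaria"),
    ("Ascomycota", "Dothideomycetes", "Venturiales", "Venturiaceae", "Venturia"),
    ("Ascomycota", "Pezizomycetes", "Pezizales", "Pyronemataceae", "Wilcoxina"),
    ("Ascomycota", "Pezizomycetes", "Pezizales", "Tuberaceae", "Tuber"),
    ("Ascomycota", "Lecanoromycetes", "Lecanorales", "Cladoniaceae", "Cladonia"),
    ("Ascomycota", "Archaeorhizomycetes", "Archaeorhizomycetales", "Archaeorhizomycetaceae", "Archaeorhizomyces"),
    ("Basidiomycota", "Agaricomycetes", "Russulales", "Russulaceae", "Russula"),
    ("Basidiomycota", "Agaricomycetes", "Russulales", "Russulaceae", "Lactarius"),
    ("Basidiomycota", "Agaricomycetes", "Agaricales", "Cortinariaceae", "Cortinarius"),
    ("Basidiomycota", "Agaricomycetes", "Agaricales", "Inocybaceae", "Inocybe"),
    ("Basidiomycota", "Agaricomycetes", "Agaricales", "Amanitaceae", "Amanita"),
    ("Basidiomycota", "Agaricomycetes", "Agaricales", "Hygrophoraceae", "Hygrophorus"),
    ("Basidiomycota", "Agaricomycetes", "Agaricales", "Mycenaceae", "Mycena"),
    ("Basidiomycota", "Agaricomycetes", "Boletales", "Boletaceae", "Boletus"),
    ("Basidiomycota", "Agaricomycetes", "Thelephorales", "Thelephoraceae", "Tomentella"),
    ("Basidiomycota", "Agaricomycetes", "Cantharellales", "Ceratobasidiaceae", "Ceratobasidium"),
    ("Basidiomycota", "Agaricomycetes", "Sebacinales", "Serendipitaceae", "Serendipita"),
    ("Basidiomycota", "Agaricomycetes", "Polyporales", "Polyporaceae", "Trametes"),
    ("Basidiomycota", "Tremellomycetes", "Tremellales", "Trimorphomycetaceae", "Saitozyma"),
    ("Basidiomycota", "Tremellomycetes", "Trichosporonales", "Trichosporonaceae", "Apiotrichum"),
    ("Basidiomycota", "Microbotryomycetes", "Sporidiobolales", "Sporidiobolaceae", "Rhodotorula"),
    ("Mortierellomycota", "Mortierellomycetes", "Mortierellales", "Mortierellaceae", "Mortierella"),
    ("Mortierellomycota", "Mortierellomycetes", "Mortierellales", "Mortierellaceae", "Podila"),
    ("Glomeromycota", "Glomeromycetes", "Glomerales", "Glomeraceae", "Glomus"),
]

_UNASSIGNED_GENERA = [
    ("Ascomycota", "Sordariomycetes", "Sordariales", "Incertae_sedis", "Sordariomycete_gen"),
    ("Ascomycota", "Dothideomycetes", "Pleosporales", "Incertae_sedis", "Pleosporale_gen"),
    ("Ascomycota", "Leotiomycetes", "Helotiales", "Incertae_sedis", "Helotiale_gen"),
    ("Ascomycota", "Incertae_sedis", "Incertae_sedis", "Incertae_sedis", "Ascomycote_gen"),
    ("Basidiomycota", "Agaricomycetes", "Agaricales", "Incertae_sedis", "Agaricale_gen"),
    ("Basidiomycota", "Incertae_sedis", "Incertae_sedis", "Incertae_sedis", "Basidiomycote_gen"),
    ("Rozellomycota", "Incertae_sedis", "Incertae_sedis", "Incertae_sedis", "Rozellomycote_gen"),
    ("Chytridiomycota", "Chytridiomycetes", "Rhizophydiales", "Incertae_sedis", "Rhizophydiale_gen"),
    ("Kickxellomycota", "Kickxellomycetes", "Kickxellales", "Incertae_sedis", "Kickxellale_gen"),
    ("Basidiobolomycota", "Basidiobolomycetes", "Basidiobolales", "Incertae_sedis", "Basidiobole_gen"),
    ("Zoopagomycota", "Zoopagomycetes", "Zoopagales", "Incertae_sedis", "Zoopagale_gen"),
    ("Fungi_unclassified", "Incertae_sedis", "Incertae_sedis", "Incertae_sedis", "Fungal_gen"),
]

# Guild pools per atomic trophic component; composite modes draw composite
# guild labels from the matching pools.  "NULL" is a literal guild category.
_GUILDS_BY_MODE = {
    "Symbiotroph": [
        "Ectomycorrhizal", "Arbuscular Mycorrhizal", "Ericoid Mycorrhizal",
        "Endophyte", "Lichenized", "Orchid Mycorrhizal",
    ],
    "Saprotroph": [
        "Undefined Saprotroph", "Wood Saprotroph", "Dung Saprotroph",
        "Litter Saprotroph", "Soil Saprotroph", "Plant Saprotroph",
        "Leaf Saprotroph",
    ],
    "Pathotroph": [
        "Plant Pathogen", "Animal Pathogen", "Fungal Parasite",
        "Lichen Parasite", "Plant Parasite", "Bryophyte Parasite",
    ],
    "Saprotroph-Symbiotroph": [
        "Ectomycorrhizal-Undefined Saprotroph",
        "Endophyte-Litter Saprotroph-Soil Saprotroph-Undefined Saprotroph",
        "Ectomycorrhizal-Undefined Saprotroph-Wood Saprotroph",
        "Endophyte-Undefined Saprotroph-Wood Saprotroph",
        "Plant Saprotroph-Wood Saprotroph",
        "Lichenized-Undefined Saprotroph",
    ],
    "Pathotroph-Symbiotroph": [
        "Ectomycorrhizal-Lichen Parasite-Lichenized-Plant Pathogen",
        "Endomycorrhizal-Plant Pathogen-Undefined Saprotroph",
        "Endophyte-Plant Pathogen",
    ],
    "Pathotroph-Saprotroph": [
        "Animal Pathogen-Fungal Parasite-Undefined Saprotroph",
        "Animal Pathogen-Undefined Saprotroph",
        "Plant Parasite-Wood Saprotroph",
        "Dung Saprotroph-Plant Saprotroph-Wood Saprotroph",
        "Fungal Parasite-Undefined Saprotroph",
    ],
    "Pathotroph-Saprotroph-Symbiotroph": [
        "Bryophyte Parasite-Dung Saprotroph-Ectomycorrhizal-Fungal Parasite-"
        "Leaf Saprotroph-Plant Parasite-Undefined Saprotroph-Wood Saprotroph",
        "Ectomycorrhizal-Fungal Parasite-Plant Pathogen-Wood Saprotroph",
        "Endophyte-Plant Pathogen-Undefined Saprotroph",
        "NULL",
    ],
}

CONFIDENCE_LEVELS = ("Possible", "Probable", "Highly Probable")


def default_env_coupling(n_modules: int) -> np.ndarray:
    """Default soil-variable <- module-factor coefficient matrix.

    Rows follow :data:`SOIL_VARIABLES`; columns are modules 1..n_modules.
    A handful of strong couplings (|coef| 0.8-0.9) are planted so the
    module-eigengene screen has recoverable signal; the rest is zero.
    """
    coupling = np.zeros((len(SOIL_VARIABLES), n_modules))
    planted = [
        ("SWC", 1, -0.9), ("AN", 2, -0.9), ("TK", 3, -0.8),
        ("TP", 4, 0.9), ("MBN", 4, -0.9), ("NO3-N", 5, -0.8),
        ("NH4-N", 6, 0.9),
    ]
    for var, module, coef in planted:
        if module <= n_modules:
            coupling[SOIL_VARIABLES.index(var), module - 1] = coef
    return coupling


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings.

    Defaults emulate the target study design: 2 sites x 15 rhizosphere
    samples, ~2900 OTUs of which 60% resolve against the guild database,
    and 6 planted correlation modules.
    """

    n_sites: int = 2
    samples_per_site: int = 15
    n_otus: int = 2900
    assigned_fraction: float = 0.60
    n_modules: int = 6
    otus_per_module: int = 25
    module_loading: float = 0.85
    noise_sd: float = 0.30
    env_coupling: np.ndarray | None = None
    detection_floor: int = 1
    depth_sd: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sites", "samples_per_site", "n_otus", "n_modules",
                     "otus_per_module"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if not 0.0 <= self.assigned_fraction <= 1.0:
            raise ConfigError("assigned_fraction must lie in [0, 1]")
        if not 0.0 <= self.module_loading <= 1.0:
            raise ConfigError("module_loading must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be non-negative")
        if self.n_modules > self.n_otus:
            raise ConfigError("n_modules cannot exceed n_otus")
        if self.n_modules * self.otus_per_module > self.n_otus:
            raise ConfigError("module OTUs exceed n_otus; shrink n_modules or otus_per_module")
        if self.env_coupling is not None:
            shape = np.asarray(self.env_coupling).shape
            if shape != (len(SOIL_VARIABLES), self.n_modules):
                raise ConfigError(
                    f"env_coupling must have shape ({len(SOIL_VARIABLES)}, "
                    f"{self.n_modules}), got {shape}")


@dataclass
class SynthTruth:
    """Ground truth behind one generated community."""

    module_of_otu: dict[str, int]
    env_coupling_signs: dict[tuple[int, str], int]
    trophic_of_otu: dict[str, str]


class SyntheticCommunity(NamedTuple):
    otu_table: pd.DataFrame      # OTUs x samples, integer counts
    taxonomy: pd.DataFrame       # OTUs x 7 ranks
    guild_db: pd.DataFrame       # FUNGuild-style flat records
    soil: pd.DataFrame           # samples x (site + 13 soil variables)
    truth: SynthTruth


def site_labels(n_sites: int) -> list[str]:
    base = ["SBT", "SJHT"]
    return base[:n_sites] + [f"SITE{i}" for i in range(3, n_sites + 1)]


def _sample_ids(config: SynthConfig) -> tuple[list[str], list[str]]:
    ids, sites = [], []
    for site in site_labels(config.n_sites):
        for j in range(1, config.samples_per_site + 1):
            ids.append(f"{site}{j:02d}")
            sites.append(site)
    return ids, sites


def generate_community(config: SynthConfig) -> SyntheticCommunity:
    """Generate one synthetic community under ``config``.

    Counts are drawn by exponentiating latent log10 abundances (a shared
    per-module factor scaled by ``module_loading`` plus Gaussian noise),
    applying a per-sample depth multiplier, rounding to integers, and
    zeroing counts below ``detection_floor``.  Soil variables are linear
    combinations of the module factors (per ``env_coupling``) plus
    unit-variance noise, rescaled onto field-realistic units.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    samples, sites = _sample_ids(config)
    n_samples = len(samples)
    otu_ids = [f"OTU{i}" for i in range(1, config.n_otus + 1)]

    # Planted module membership: modules 1..n_modules take otus_per_module
    # OTUs each; module 0 is the uncorrelated background.
    module_of = np.zeros(config.n_otus, dtype=int)
    k = 0
    for m in range(1, config.n_modules + 1):
        module_of[k:k + config.otus_per_module] = m
        k += config.otus_per_module

    # Per-module latent factors, one value per sample.
    factors = rng.standard_normal((config.n_modules, n_samples))

    base = np.where(
        module_of > 0,
        rng.normal(2.0, 0.4, config.n_otus),   # module members: prevalent
        rng.normal(0.8, 1.0, config.n_otus),   # background: sparse tail
    )
    noise = rng.standard_normal((config.n_otus, n_samples)) * config.noise_sd
    log_abund = base[:, None] + noise
    in_module = module_of > 0
    log_abund[in_module] += config.module_loading * factors[module_of[in_module] - 1]

    depth = np.exp(rng.normal(0.0, config.depth_sd, n_samples))
    counts = np.rint(depth[None, :] * 10.0 ** log_abund).astype(np.int64)
    counts[counts < config.detection_floor] = 0

    otu_table = pd.DataFrame(counts, index=pd.Index(otu_ids, name="otu_id"),
                             columns=samples)

    # --- taxonomy and guild database -------------------------------------
    n_assigned = int(round(config.assigned_fraction * config.n_otus))
    # Module OTUs are annotated first so network nodes carry trophic modes.
    order = np.concatenate([np.flatnonzero(in_module),
                            rng.permutation(np.flatnonzero(~in_module))])
    assigned_idx = set(order[:n_assigned].tolist())

    # Deterministic genus -> (trophic mode, guild) map spanning all 7 modes.
    genus_mode: dict[str, tuple[str, str]] = {}
    shuffled = list(_ASSIGNED_GENERA)
    rng.shuffle(shuffled)
    for g, (_, _, _, _, genus) in enumerate(shuffled):
        mode = TROPHIC_MODES[g % len(TROPHIC_MODES)]
        guild = _GUILDS_BY_MODE[mode][g % len(_GUILDS_BY_MODE[mode])]
        genus_mode[genus] = (mode, guild)

    ranks = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]
    lineages = []
    trophic_of: dict[str, str] = {}
    species_records: list[tuple[str, str, str, str]] = []
    for i, otu in enumerate(otu_ids):
        if i in assigned_idx:
            phylum, cls, order_, family, genus = shuffled[rng.integers(len(shuffled))]
            mode, guild = genus_mode[genus]
            trophic_of[otu] = mode
        else:
            phylum, cls, order_, family, genus = _UNASSIGNED_GENERA[
                rng.integers(len(_UNASSIGNED_GENERA))]
            trophic_of[otu] = "Unassigned"
        species = f"{genus}_sp{rng.integers(1, 9)}"
        lineages.append(("Fungi", phylum, cls, order_, family, genus, species))
        # A sprinkling of species-rank records exercises most-specific-rank
        # matching downstream.
        if i in assigned_idx and rng.random() < 0.05:
            mode, guild = genus_mode[genus]
            species_records.append((species, "species", mode, guild))
    taxonomy = pd.DataFrame(lineages, index=pd.Index(otu_ids, name="otu_id"),
                            columns=ranks)

    used_genera = sorted({taxonomy.loc[f"OTU{i + 1}", "genus"]
                          for i in assigned_idx})
    records = []
    for genus in used_genera:
        mode, guild = genus_mode[genus]
        confidence = rng.choice(CONFIDENCE_LEVELS, p=[0.15, 0.50, 0.35])
        records.append((genus, "genus", mode, guild, confidence))
    for species, rank, mode, guild in sorted(set(species_records)):
        records.append((species, rank, mode, guild, "Highly Probable"))
    guild_db = pd.DataFrame(
        records,
        columns=["taxon", "taxonomicLevel", "trophicMode", "guild",
                 "confidenceRanking"],
    ).drop_duplicates(subset=["taxon", "taxonomicLevel"], ignore_index=True)

    # --- soil metadata ----------------------------------------------------
    coupling = (np.asarray(config.env_coupling, dtype=float)
                if config.env_coupling is not None
                else default_env_coupling(config.n_modules))
    z = coupling @ factors + rng.standard_normal((len(SOIL_VARIABLES), n_samples))
    z /= np.sqrt((coupling ** 2).sum(axis=1) + 1.0)[:, None]
    labels = site_labels(config.n_sites)
    soil = pd.DataFrame({"site": sites}, index=pd.Index(samples, name="sample_id"))
    for v, var in enumerate(SOIL_VARIABLES):
        means, sd = _SOIL_SCALE[var]
        site_mean = np.array([means[min(labels.index(s), 1)] for s in sites])
        soil[var] = site_mean + sd * z[v]

    signs = {}
    for v, var in enumerate(SOIL_VARIABLES):
        for m in range(coupling.shape[1]):
            if coupling[v, m] != 0.0:
                signs[(m + 1, var)] = int(np.sign(coupling[v, m]))

    truth = SynthTruth(
        module_of_otu=dict(zip(otu_ids, module_of.tolist())),
        env_coupling_signs=signs,
        trophic_of_otu=trophic_of,
    )
    return SyntheticCommunity(otu_table, taxonomy, guild_db, soil, truth)
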