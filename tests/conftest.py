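import numpy as np
import pandas as pd
import pytest

import fmenkit as fk


@pytest.fixture(scope="session")
def small_community():
    """A 300-OTU, 2x15-sample synthetic community shared across tests."""
    return fk.generate_community(fk.SynthConfig(n_otus=300, seed=1))


@pytest.fixture(scope="session")
def small_assignment(small_community):
    return fk.assign_guilds(small_community.taxonomy,
                            small_community.guild_db, "Possible")


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def recovery_screens():
    """Truth + module-soil screens for 10 generator seeds (30 samples).

    Shared by the coupling-recovery tests; partitions use the planted
    module truth so the screens isolate the eigengene-correlation step.
    Module members are kept a small fraction of the community (90 of 600
    OTUs), matching the default configuration's proportions: when module
    OTUs dominate per-sample totals, the relative-abundance step leaks
    every module's factor into every eigengene.
    """
    runs = []
    for seed in range(10):
        cfg = fk.SynthConfig(n_sites=1, samples_per_site=30, n_otus=600,
                             otus_per_module=15, seed=seed)
        com = fk.generate_community(cfg)
        prep = fk.prepare_abundance(com.otu_table, com.soil["site"], "SBT")
        part = {o: m for o, m in com.truth.module_of_otu.items()
                if m > 0 and o in prep.index}
        eigengenes, _ = fk.module_eigengenes(prep, part)
        screen = fk.module_env_correlation(eigengenes, com.soil)
        runs.append((com, prep, screen))
    return runs


def random_graph(rng, n_max=12, p=0.35):
    """Random simple graph with at least one edge."""
    import networkx as nx
    while True:
        n = int(rng.integers(4, n_max + 1))
        G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2 ** 31)))
        if G.number_of_edges() > 0:
            return G
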