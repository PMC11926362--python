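import numpy as np
import pandas as pd
import pytest

from iegnet import (
    SyntheticConfig,
    default_panel,
    percent_positive,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def panel():
    return default_panel()


@pytest.fixture(scope="session")
def counts(panel):
    """Default synthetic counts table: 3 groups x 10 animals x 14 regions."""
    return simulate_dataset(SyntheticConfig(seed=1))


@pytest.fixture(scope="session")
def activation(counts):
    return percent_positive(counts)


@pytest.fixture
def tiny_counts():
    """Hand-written three-row counts table with known percentages."""
    return pd.DataFrame({
        "animal_id": ["a1", "a1", "a2"],
        "group": ["vehicle", "vehicle", "iso"],
        "region": ["upDG", "PL", "upDG"],
        "n_total": [200, 100, 400],
        "n_h1a_only": [20, 5, 40],
        "n_arc_only": [10, 5, 20],
        "n_double": [10, 0, 40],
    })


def random_graph(rng, n_max=8, weighted=False):
    """Random undirected graph on 2..n_max nodes for oracle checks."""
    import networkx as nx

    n = int(rng.integers(2, n_max + 1))
    g = nx.gnp_random_graph(n, float(rng.uniform(0.15, 0.9)),
                            seed=int(rng.integers(1 << 30)))
    if weighted:
        for a, b in g.edges:
            g[a][b]["weight"] = float(rng.uniform(0.5, 1.5))
    return g
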