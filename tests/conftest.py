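import numpy as np
import pandas as pd
import pytest

import tfnresponse as tfn


@pytest.fixture
def toy_graph() -> tfn.TFNGraph:
    """Small signed graph: two TFs, a cascade and a balanced gene.

    a -> b(+), a -> c(-), b -> c(+), b -> d(+), c -> d(-)
    """
    return tfn.TFNGraph.from_edges([
        ("a", "b", 1), ("a", "c", -1), ("b", "c", 1),
        ("b", "d", 1), ("c", "d", -1),
    ])


@pytest.fixture(scope="session")
def scenario() -> tfn.ScenarioResult:
    """One medium-size synthetic scenario shared across tests."""
    spec = tfn.NetworkSpec(n_genes=1500, n_tfs=120, seed=7)
    params = tfn.SimParams(seed=7)
    return tfn.run_scenario(spec, params)


def random_tfn(rng: np.random.Generator, n_nodes: int, p_edge: float = 0.12
               ) -> tfn.TFNGraph:
    """Random signed directed graph for oracle comparisons."""
    names = [f"n{i}" for i in range(n_nodes)]
    edges = []
    for u in names:
        for v in names:
            if rng.random() < p_edge:
                edges.append((u, v, int(rng.choice([-1, 0, 1]))))
    return tfn.TFNGraph.from_edges(edges)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
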