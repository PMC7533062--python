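from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260926)


def random_weighted_graph(
    rng: np.random.Generator,
    n_nodes: int,
    p_edge: float = 0.45,
    allow_isolates: bool = True,
) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < p_edge:
                g.add_edge(i, j, weight=float(rng.uniform(0.1, 5.0)))
    if not allow_isolates:
        for v in list(nx.isolates(g)):
            u = int(rng.integers(0, n_nodes))
            if u != v:
                g.add_edge(v, u, weight=float(rng.uniform(0.1, 5.0)))
    return g


def random_partition(rng: np.random.Generator, nodes, n_modules: int) -> dict:
    return {v: int(rng.integers(1, n_modules + 1)) for v in nodes}


@pytest.fixture(scope="session")
def tiny_cohort():
    """A desk-scale cohort shared across tests (expensive to build)."""
    from ampconn import SynthConfig, generate_cohort

    config = SynthConfig(n_roi=24, n_modules=4, n_trials=30, seed=42)
    epochs, atlas, truth = generate_cohort(config)
    return config, epochs, atlas, truth
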