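from __future__ import annotations

import networkx as nx
import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ppisim.network import Network

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture
def path4() -> Network:
    """Path a–b–c–d: the standard worked example for every scorer."""
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])


@pytest.fixture
def square() -> Network:
    return Network.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])


@pytest.fixture(scope="session")
def atlas_networks() -> list[Network]:
    """Every simple graph on 2..7 nodes, string-labelled."""
    nets = []
    for g in nx.graph_atlas_g():
        if g.number_of_nodes() < 2:
            continue
        h = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        nets.append(Network(h))
    return nets


def random_network(seed: int, n_max: int = 30) -> Network:
    """Seeded sparse-ish random graph with string labels."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, n_max + 1))
    p = float(rng.uniform(0.05, 0.3))
    g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
    g = nx.relabel_nodes(g, {i: f"n{i:02d}" for i in g.nodes})
    return Network(g)


@pytest.fixture(scope="session")
def random_networks() -> list[Network]:
    return [random_network(seed) for seed in range(100)]
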