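"""Random network models that emulate PPI linkage mechanisms.

Two forward simulators produce networks whose link structure mirrors
the two biological mechanisms behind neighborhood-similarity link
prediction:

* **interface complementarity** — every protein carries a d-vector of
  interface-pair states; two proteins interact iff some coordinate
  holds complementary interface halves.  Nodes with similar interface
  vectors end up sharing partners rather than interacting.
* **gene duplication** — repeatedly pick a node, duplicate it, and let
  the copy retain each of the original's links independently with
  probability p (duplication–divergence growth).  A fresh duplicate and
  its original have identical neighborhoods, hence Jaccard similarity 1.

Erdős–Rényi and Watts–Strogatz baselines are included for comparison.
All generators are reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import Network, largest_component

__all__ = [
    "InterfaceModelParams",
    "DuplicationModelParams",
    "LINKING_PAIRS",
    "interface_profiles",
    "interface_link",
    "interface_network",
    "duplication_network",
    "default_duplication_seed",
    "baseline_network",
    "profiles_to_tsv",
    "INTERFACE_PRESETS",
    "DUPLICATION_PRESETS",
]

#: Complementary interface-state pairs: state 0 = neither half of
#: interface i, 1 = the i+ half, 2 = the i- half, 3 = both halves.
#: Two nodes link iff some coordinate i has states in this set.
LINKING_PAIRS = frozenset(
    {(1, 2), (2, 1), (1, 3), (3, 1), (2, 3), (3, 2), (3, 3)}
)


@dataclass(frozen=True)
class InterfaceModelParams:
    """Parameters of the interface-complementarity model.

    Each of the n·d interface states is drawn i.i.d. from {0, 1, 2, 3}
    with probabilities (p1, p2, p3, p4).
    """

    n: int
    d: int
    p1: float
    p2: float
    p3: float
    p4: float
    seed: int = 0

    def __post_init__(self):
        probs = (self.p1, self.p2, self.p3, self.p4)
        if any(p < 0 for p in probs):
            raise ValueError("probabilities must be non-negative")
        if abs(sum(probs) - 1.0) > 1e-12:
            raise ValueError(f"p1+p2+p3+p4 must equal 1, got {sum(probs)}")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.d < 1:
            raise ValueError("d must be >= 1")

    @property
    def probs(self) -> tuple[float, float, float, float]:
        return (self.p1, self.p2, self.p3, self.p4)


@dataclass
class DuplicationModelParams:
    """Parameters of the duplication–divergence model.

    seed_network : connected network the growth starts from (defaults
        to the largest component of an Erdős–Rényi G(20, 0.3) draw).
    steps : number of duplication events.
    p : per-link retention probability of the duplicate.
    link_duplicate : when True the duplicate is also linked to its
        original (off by default: paralogs share partners rather than
        interact).
    """

    steps: int
    p: float
    seed: int = 0
    seed_network: Network | None = None
    link_duplicate: bool = False

    def __post_init__(self):
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


def interface_profiles(params: InterfaceModelParams) -> dict[str, np.ndarray]:
    """Draw one d-vector of interface states per node.

    Node labels are zero-padded (``p0000`` …) so lexicographic order
    equals creation order.
    """
    rng = np.random.default_rng(params.seed)
    states = rng.choice(4, size=(params.n, params.d), p=params.probs)
    width = max(4, len(str(params.n - 1)))
    return {f"p{i:0{width}d}": states[i] for i in range(params.n)}


def interface_link(x: np.ndarray, y: np.ndarray) -> bool:
    """Whether two interface profiles are complementary somewhere.

    True iff ∃ i with (x_i, y_i) in :data:`LINKING_PAIRS`.
    """
    return any((int(a), int(b)) in LINKING_PAIRS for a, b in zip(x, y))


# boolean 4x4 complementarity table for the vectorized edge rule
_LINK_TABLE = np.zeros((4, 4), dtype=bool)
for _a, _b in LINKING_PAIRS:
    _LINK_TABLE[_a, _b] = True


def interface_network(
    params: InterfaceModelParams,
    profiles: dict[str, np.ndarray] | None = None,
) -> Network:
    """Network induced by interface complementarity.

    Distinct nodes are linked iff their profiles are complementary in
    at least one coordinate; deterministic given the profiles (no
    self-links).
    """
    if profiles is None:
        profiles = interface_profiles(params)
    labels = sorted(profiles)
    x = np.array([profiles[u] for u in labels])
    linked = _LINK_TABLE[x[:, None, :], x[None, :, :]].any(axis=2)
    np.fill_diagonal(linked, False)
    iu, ju = np.nonzero(np.triu(linked, k=1))
    g = nx.Graph()
    g.add_nodes_from(labels)
    g.add_edges_from((labels[i], labels[j]) for i, j in zip(iu, ju))
    return Network(g)


def profiles_to_tsv(profiles: dict[str, np.ndarray], path) -> None:
    """Write profiles as TSV: node, x_1 … x_d."""
    d = len(next(iter(profiles.values())))
    with open(path, "w") as fh:
        fh.write("node\t" + "\t".join(f"x_{i + 1}" for i in range(d)) + "\n")
        for node in sorted(profiles):
            fh.write(node + "\t" + "\t".join(map(str, profiles[node])) + "\n")


def default_duplication_seed(seed: int = 0) -> Network:
    """Default growth seed: largest component of an ER G(20, 0.3) draw."""
    g = nx.gnp_random_graph(20, 0.3, seed=int(seed))
    g = nx.relabel_nodes(g, {i: f"s{i:02d}" for i in g.nodes})
    return largest_component(Network(g))


def duplication_network(params: DuplicationModelParams) -> Network:
    """Grow a network by repeated node duplication.

    Each step picks a node u uniformly at random, adds a duplicate v,
    and copies each edge u–w to v–w independently with probability p
    (u keeps all its links; no u–v edge unless ``link_duplicate``).
    Returns the largest connected component of the grown network.
    """
    rng = np.random.default_rng(params.seed)
    seed_net = (
        params.seed_network
        if params.seed_network is not None
        else default_duplication_seed(params.seed)
    )
    if seed_net.n_nodes == 0:
        raise ValueError("seed network is empty")
    if seed_net.n_rings:
        raise ValueError("seed network must be simple (no self-loops)")
    g = seed_net.copy()._g
    order = sorted(g.nodes)  # creation-order list for uniform choice
    width = max(4, len(str(params.steps)))
    for t in range(params.steps):
        u = order[int(rng.integers(len(order)))]
        v = f"v{t:0{width}d}"
        g.add_node(v)
        neigh = sorted(g.neighbors(u))
        keep = rng.random(len(neigh)) < params.p
        g.add_edges_from((v, w) for w, k in zip(neigh, keep) if k)
        if params.link_duplicate:
            g.add_edge(u, v)
        order.append(v)
    return largest_component(Network(g))


def baseline_network(
    model: str,
    n: int,
    p: float | None = None,
    k: int | None = None,
    rewire_p: float | None = None,
    seed: int = 0,
) -> Network:
    """Erdős–Rényi or Watts–Strogatz baseline graph with string labels.

    ER needs ``p``; WS needs even ``k`` < n and ``rewire_p`` and always
    has exactly n·k/2 edges (rewiring preserves edge count).
    """
    if model == "erdos_renyi":
        if p is None or not 0.0 <= p <= 1.0:
            raise ValueError("erdos_renyi requires p in [0, 1]")
        g = nx.gnp_random_graph(n, p, seed=int(seed))
    elif model == "watts_strogatz":
        if k is None or rewire_p is None:
            raise ValueError("watts_strogatz requires k and rewire_p")
        if k % 2 != 0 or not 0 < k < n:
            raise ValueError("watts_strogatz requires even k with 0 < k < n")
        if not 0.0 <= rewire_p <= 1.0:
            raise ValueError("rewire_p must be in [0, 1]")
        g = nx.watts_strogatz_graph(n, k, rewire_p, seed=int(seed))
    else:
        raise ValueError(
            f"unknown model {model!r}; choose erdos_renyi or watts_strogatz"
        )
    width = len(str(n - 1))
    g = nx.relabel_nodes(g, {i: f"n{i:0{width}d}" for i in g.nodes})
    return Network(g)


# Named presets: reconstructions of the kind of parameter sweeps used
# to exercise the two models (the original studies do not publish their
# exact values).  Probabilities are skewed toward state 0 so mean
# degree lands in the sparse range typical of curated PPI networks.
INTERFACE_PRESETS: dict[str, InterfaceModelParams] = {
    "interface1": InterfaceModelParams(n=300, d=2, p1=0.85, p2=0.06, p3=0.06, p4=0.03),
    "interface2": InterfaceModelParams(n=300, d=5, p1=0.90, p2=0.045, p3=0.045, p4=0.01),
    "interface3": InterfaceModelParams(n=500, d=2, p1=0.88, p2=0.05, p3=0.05, p4=0.02),
    "interface4": InterfaceModelParams(n=500, d=5, p1=0.92, p2=0.035, p3=0.035, p4=0.01),
    "interface5": InterfaceModelParams(n=800, d=3, p1=0.90, p2=0.04, p3=0.04, p4=0.02),
    "interface6": InterfaceModelParams(n=1000, d=4, p1=0.93, p2=0.03, p3=0.03, p4=0.01),
}

DUPLICATION_PRESETS: dict[str, DuplicationModelParams] = {
    "duplication1": DuplicationModelParams(steps=280, p=0.9),
    "duplication2": DuplicationModelParams(steps=280, p=0.7),
    "duplication3": DuplicationModelParams(steps=480, p=0.9),
    "duplication4": DuplicationModelParams(steps=480, p=0.7),
    "duplication5": DuplicationModelParams(steps=780, p=0.8),
    "duplication6": DuplicationModelParams(steps=980, p=0.9),
}
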