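"""Graph container, file I/O, preprocessing and summary statistics.

Interaction networks are undirected graphs whose nodes are proteins and
whose edges are (optionally confidence-weighted) physical interactions.
This module provides the :class:`Network` container used throughout the
package, readers for plain edge lists and Pajek ``.net`` files, the
confidence-threshold preprocessing step, largest-component extraction,
and the descriptive statistics commonly reported for such networks
(mean local clustering, degree assortativity, mean degree, degree
heterogeneity, link density, self-loop count).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "NetworkStats",
    "ParseError",
    "read_edge_list",
    "read_pajek",
    "write_edge_list",
    "normalize_and_filter",
    "largest_component",
    "compute_stats",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


def _pair(u: str, v: str) -> tuple[str, str]:
    """Canonical unordered pair: lexicographically smaller label first."""
    return (u, v) if u <= v else (v, u)


class Network:
    """Undirected interaction network with optional per-edge confidence.

    Node identity is a string label.  An edge without an explicit weight
    has confidence 1.0.  Self-loops ("rings" in curated PPI releases,
    i.e. recorded self-interactions) are kept in the container so they
    can be reported, but every scoring function in :mod:`ppisim.indices`
    requires them to be removed first via :meth:`remove_self_loops`.
    """

    def __init__(self, graph: nx.Graph | None = None):
        self._g: nx.Graph = graph if graph is not None else nx.Graph()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple[str, str] | tuple[str, str, float]],
        nodes: Iterable[str] = (),
    ) -> "Network":
        g = nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        for e in edges:
            if len(e) == 3:
                u, v, w = e
                g.add_edge(str(u), str(v), weight=float(w))
            else:
                u, v = e
                g.add_edge(str(u), str(v))
        return cls(g)

    def copy(self) -> "Network":
        return Network(self._g.copy())

    # -- basic accessors ----------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node labels in sorted order (the matrix ordering)."""
        return sorted(self._g.nodes)

    @property
    def n_nodes(self) -> int:
        return self._g.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self._g.number_of_edges()

    @property
    def n_rings(self) -> int:
        """Number of self-loops currently present."""
        return nx.number_of_selfloops(self._g)

    @property
    def is_weighted(self) -> bool:
        return any("weight" in d for _, _, d in self._g.edges(data=True))

    def edges(self) -> Iterator[tuple[str, str]]:
        """Iterate edges as canonical unordered pairs."""
        for u, v in self._g.edges:
            yield _pair(u, v)

    def has_edge(self, u: str, v: str) -> bool:
        return self._g.has_edge(u, v)

    def has_node(self, u: str) -> bool:
        return u in self._g

    def neighbors(self, u: str) -> set[str]:
        """Neighbor set Γ_u (excluding u itself even if a loop exists)."""
        return {v for v in self._g.neighbors(u) if v != u}

    def degree(self, u: str) -> int:
        """k_u = |Γ_u| (self-loops do not contribute)."""
        return len(self.neighbors(u))

    def weight(self, u: str, v: str) -> float:
        return float(self._g.edges[u, v].get("weight", 1.0))

    def __contains__(self, u: str) -> bool:
        return u in self._g

    def __repr__(self) -> str:  # pragma: no cover
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"

    # -- mutation-by-copy ---------------------------------------------

    def remove_self_loops(self) -> "Network":
        g = self._g.copy()
        g.remove_edges_from(nx.selfloop_edges(g))
        return Network(g)

    def remove_edges(self, edges: Iterable[tuple[str, str]]) -> "Network":
        """Copy with the given edges deleted; endpoints are retained as
        (possibly isolated) nodes, as required for cross-validation."""
        g = self._g.copy()
        g.remove_edges_from(edges)
        return Network(g)

    def add_edge(self, u: str, v: str, weight: float | None = None) -> None:
        if weight is None:
            self._g.add_edge(u, v)
        else:
            self._g.add_edge(u, v, weight=float(weight))

    # -- matrix view ---------------------------------------------------

    def adjacency(self, weighted: bool = False) -> tuple[np.ndarray, list[str]]:
        """Dense adjacency matrix and its row/column label order.

        a_ij is the edge confidence when ``weighted`` (1.0 where no
        explicit confidence is stored), else 1 for every edge.
        """
        labels = self.nodes
        idx = {u: i for i, u in enumerate(labels)}
        n = len(labels)
        a = np.zeros((n, n))
        for u, v, d in self._g.edges(data=True):
            w = float(d.get("weight", 1.0)) if weighted else 1.0
            i, j = idx[u], idx[v]
            a[i, j] = w
            a[j, i] = w
        return a, labels


@dataclass(frozen=True)
class NetworkStats:
    """Descriptive network statistics.

    heterogeneity is ⟨k²⟩/⟨k⟩², equal to 1 for regular graphs and large
    for hub-dominated degree distributions; density is 2E/(n(n−1));
    n_rings counts self-loops in the network as given (all other fields
    are computed on the simple graph with loops removed).
    """

    n_nodes: int
    n_edges: int
    clustering: float
    assortativity: float
    avg_degree: float
    heterogeneity: float
    density: float
    n_rings: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(self)])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# -- file I/O ----------------------------------------------------------


def read_edge_list(
    path, weighted: bool = True, delimiter: str | None = None
) -> Network:
    """Read a whitespace/tab-delimited edge list.

    Each non-comment line holds ``node1 node2 [confidence]``.  Duplicate
    lines for the same unordered pair collapse to one edge keeping the
    maximum confidence.  Lines starting with ``#`` are ignored.

    Parameters
    ----------
    weighted:
        When False a third field is ignored with a warning.
    delimiter:
        Field separator; ``None`` splits on any whitespace run.
    """
    g = nx.Graph()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split(delimiter)
            if len(fields) not in (2, 3):
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 or 3 fields, "
                    f"got {len(fields)}: {line!r}"
                )
            u, v = fields[0], fields[1]
            w: float | None = None
            if len(fields) == 3:
                if weighted:
                    try:
                        w = float(fields[2])
                    except ValueError as exc:
                        raise ParseError(
                            f"{path}: line {lineno}: third field is not "
                            f"a number: {fields[2]!r}"
                        ) from exc
                else:
                    warnings.warn(
                        f"{path}: line {lineno}: weight field ignored "
                        "(weighted=False)"
                    )
            if g.has_edge(u, v):
                old = g.edges[u, v].get("weight")
                if w is not None and (old is None or w > old):
                    g.edges[u, v]["weight"] = w
            elif w is not None:
                g.add_edge(u, v, weight=w)
            else:
                g.add_edge(u, v)
    return Network(g)


def write_edge_list(net: Network, path, header: Iterable[str] = ()) -> None:
    """Write an edge list readable back by :func:`read_edge_list`.

    Weights are written with ``repr`` so a write/read round trip
    reproduces them to full precision.
    """
    with open(path, "w") as fh:
        for line in header:
            fh.write(f"# {line}\n")
        for u, v, d in sorted(net._g.edges(data=True)):
            if "weight" in d:
                fh.write(f"{u}\t{v}\t{d['weight']!r}\n")
            else:
                fh.write(f"{u}\t{v}\n")


def read_pajek(path) -> Network:
    """Read a Pajek ``.net`` file (``*Vertices`` then ``*Edges``/``*Arcs``).

    Arcs are symmetrized into undirected edges.  Vertex labels (quoted
    or bare) name the nodes, falling back to the integer id.  An edge
    referencing an undeclared vertex id is an error.
    """
    label: dict[int, str] = {}
    g = nx.Graph()
    section = None
    n_declared = 0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("%"):
                continue
            low = line.lower()
            if low.startswith("*vertices"):
                section = "vertices"
                parts = line.split()
                if len(parts) < 2 or not parts[1].isdigit():
                    raise ParseError(
                        f"{path}: line {lineno}: malformed *Vertices header"
                    )
                n_declared = int(parts[1])
                continue
            if low.startswith("*edges") or low.startswith("*arcs"):
                if section is None:
                    raise ParseError(
                        f"{path}: line {lineno}: edge section before "
                        "*Vertices header"
                    )
                section = "edges"
                continue
            if line.startswith("*"):
                section = "other"
                continue
            if section == "vertices":
                parts = line.split(None, 1)
                vid = int(parts[0])
                name = str(vid)
                if len(parts) > 1:
                    rest = parts[1].strip()
                    if rest.startswith('"'):
                        end = rest.find('"', 1)
                        if end > 0:
                            name = rest[1:end]
                    else:
                        name = rest.split()[0]
                label[vid] = name
                g.add_node(name)
            elif section == "edges":
                parts = line.split()
                if len(parts) < 2:
                    raise ParseError(
                        f"{path}: line {lineno}: malformed edge line: {line!r}"
                    )
                a, b = int(parts[0]), int(parts[1])
                for vid in (a, b):
                    if vid not in label:
                        if vid <= n_declared:
                            label[vid] = str(vid)
                            g.add_node(str(vid))
                        else:
                            raise ParseError(
                                f"{path}: line {lineno}: edge references "
                                f"undeclared vertex {vid}"
                            )
                w = float(parts[2]) if len(parts) > 2 else None
                u, v = label[a], label[b]
                if w is None:
                    g.add_edge(u, v)
                else:
                    prev = g.edges[u, v].get("weight") if g.has_edge(u, v) else None
                    if prev is None or w > prev:
                        g.add_edge(u, v, weight=w)
    if section is None:
        raise ParseError(f"{path}: missing *Vertices header")
    return Network(g)


# -- preprocessing -----------------------------------------------------


def normalize_and_filter(net: Network, threshold: float = 0.7) -> Network:
    """Max-normalize confidences and drop low-confidence edges.

    Weights are divided by the network's maximum weight (so the maximum
    becomes 1.0, mapping e.g. 0–1000 style database scores onto [0,1]),
    then every edge with normalized weight strictly below ``threshold``
    is removed.  Unweighted networks pass through unchanged.  Applying
    the operation twice equals applying it once.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    if not net.is_weighted:
        return net.copy()
    weights = [d.get("weight", 1.0) for _, _, d in net._g.edges(data=True)]
    wmax = max(weights)
    g = nx.Graph()
    g.add_nodes_from(net._g.nodes)
    for u, v, d in net._g.edges(data=True):
        w = d.get("weight", 1.0) / wmax
        if w >= threshold:
            g.add_edge(u, v, weight=w)
    return Network(g)


def largest_component(net: Network) -> Network:
    """Induced subgraph on the largest connected component.

    Ties between equal-size components are broken toward the component
    containing the lexicographically smallest node label.
    """
    if net.n_nodes == 0:
        raise ValueError("largest_component of an empty network")
    comps = sorted(nx.connected_components(net._g), key=lambda c: (-len(c), min(c)))
    return Network(net._g.subgraph(comps[0]).copy())


# -- statistics --------------------------------------------------------


def compute_stats(net: Network) -> NetworkStats:
    """Descriptive statistics of a network.

    Self-loops are counted in ``n_rings`` but excluded from every other
    quantity (degrees, clustering, assortativity, density).  Local
    clustering of degree-0/1 nodes is 0 and included in the mean.
    """
    if net.n_nodes < 2:
        raise ValueError("compute_stats requires at least 2 nodes")
    n_rings = net.n_rings
    simple = net.remove_self_loops()._g
    n = simple.number_of_nodes()
    m = simple.number_of_edges()
    k = np.array([d for _, d in simple.degree()], dtype=float)
    clustering = float(nx.average_clustering(simple)) if m else 0.0
    if m == 0:
        assort = float("nan")
        warnings.warn("assortativity undefined: network has no edges")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            assort = float(nx.degree_assortativity_coefficient(simple))
        if math.isnan(assort):
            warnings.warn(
                "assortativity undefined (zero degree variance at edge ends)"
            )
    mean_k = k.mean()
    heterogeneity = float((k**2).mean() / mean_k**2) if mean_k > 0 else float("nan")
    density = 2.0 * m / (n * (n - 1))
    return NetworkStats(
        n_nodes=n,
        n_edges=m,
        clustering=clustering,
        assortativity=assort,
        avg_degree=float(mean_k),
        heterogeneity=heterogeneity,
        density=density,
        n_rings=n_rings,
    )
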