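"""Link-prediction scoring functions.

Implements the similarity-propagation index *Sim* together with the
baselines it is compared against:

* classical neighborhood/path indices — common neighbors (CN), Jaccard
  (JC), Leicht–Holme–Newman (LHN), Adamic–Adar (AA), preferential
  attachment (PA), resource allocation (RA), local path (LP), Katz;
* the degree-normalized 3-hop path index L3,
  ``L3_ij = Σ a_iz1 a_z1z2 a_z2j / (k_z1 k_z2)``;
* the linear-optimization index ``LO = αA(αAᵀA + I)⁻¹AᵀA``;
* the Sim family ``Sim = AS + SA`` where S is a node-similarity matrix
  (Jaccard by default; CN, PA and RA variants), scoring a pair high when
  one node is highly similar to the other node's interaction partners —
  the network signature of complementary binding interfaces and of
  gene-duplication paralogy;
* score-table combination (min-max sum or Borda) used for the L3+Sim
  integration.

All scorers return a :class:`ScoreTable` over the candidate universe:
every unordered non-adjacent node pair of the input network (self-pairs
and existing edges excluded).  Ranking is deterministic: descending
score, ties broken lexicographically on the label pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import Network

__all__ = [
    "IndexParams",
    "ScoreTable",
    "CLASSIC_INDICES",
    "DEFAULT_INDEX_SET",
    "jaccard_matrix",
    "classic_score",
    "l3_score",
    "lo_score",
    "sim_score",
    "combine_scores",
    "rank_pairs",
    "score_index",
    "available_indices",
]

CLASSIC_INDICES = ("CN", "JC", "LHN", "AA", "PA", "RA", "LP", "Katz")

#: The seven-index comparison set used throughout evaluation.
DEFAULT_INDEX_SET = ("L3", "LO", "Sim", "SimCN", "SimPA", "SimRA", "L3+Sim")


@dataclass(frozen=True)
class IndexParams:
    """Tunable parameters of the scorers.

    alpha : regularization strength of LO; must be positive and should
        be small (the index behaves as αA³ to leading order).
    beta : damping of LP and Katz; Katz requires beta < 1/λ_max(A) for
        its series to converge (checked at call time).
    katz_max_len : truncation length of the Katz series.
    l3_normalization : 'product' divides each 3-path by k_z1·k_z2,
        'sqrt' by √(k_z1·k_z2).
    combine_method : rule used to integrate score tables ('minmax_sum'
        or 'borda').
    """

    alpha: float = 1e-5
    beta: float = 1e-3
    katz_max_len: int = 10
    l3_normalization: str = "product"
    combine_method: str = "minmax_sum"

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.l3_normalization not in ("product", "sqrt"):
            raise ValueError("l3_normalization must be 'product' or 'sqrt'")
        if self.combine_method not in ("minmax_sum", "borda"):
            raise ValueError("combine_method must be 'minmax_sum' or 'borda'")


@dataclass
class ScoreTable:
    """Scores over all unordered non-adjacent node pairs of a network.

    Pairs are stored with the lexicographically smaller label first;
    the pair list order is fixed (sorted), so two tables scored on the
    same network share the same pair sequence and can be combined
    element-wise.
    """

    pairs: list[tuple[str, str]]
    scores: np.ndarray
    index_name: str

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.pairs) != self.scores.shape[0]:
            raise ValueError("pairs and scores length mismatch")

    def __len__(self) -> int:
        return len(self.pairs)

    def score_of(self, u: str, v: str) -> float:
        key = (u, v) if u <= v else (v, u)
        try:
            return float(self.scores[self.pairs.index(key)])
        except ValueError:
            raise KeyError(f"pair {key} not in table") from None

    def as_dict(self) -> dict[tuple[str, str], float]:
        return {p: float(s) for p, s in zip(self.pairs, self.scores)}

    def ranked(self, k: int | None = None) -> list[tuple[tuple[str, str], float]]:
        """Pairs sorted by descending score, lexicographic tie-break."""
        order = _rank_order(self)
        if k is not None:
            order = order[:k]
        return [(self.pairs[i], float(self.scores[i])) for i in order]

    def to_frame(self) -> pd.DataFrame:
        order = _rank_order(self)
        return pd.DataFrame(
            {
                "node1": [self.pairs[i][0] for i in order],
                "node2": [self.pairs[i][1] for i in order],
                "score": self.scores[order],
                "rank": np.arange(1, len(order) + 1),
            }
        )

    def to_csv(self, path, metadata: Sequence[str] = ()) -> None:
        with open(path, "w") as fh:
            fh.write(f"# index: {self.index_name}\n")
            for line in metadata:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


def _rank_order(table: ScoreTable) -> list[int]:
    # pairs list is sorted at construction, so a stable sort on
    # descending score alone realizes the lexicographic tie-break
    return sorted(range(len(table.pairs)), key=lambda i: -table.scores[i])


def rank_pairs(table: ScoreTable, k: int) -> list[tuple[tuple[str, str], float]]:
    """Top-k candidate pairs by descending score (deterministic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) == 0:
        warnings.warn("ranking an empty score table")
        return []
    return table.ranked(k)


# -- matrix plumbing ---------------------------------------------------


def _require_simple(net: Network) -> None:
    if net.n_rings:
        raise ValueError(
            "network contains self-loops; call remove_self_loops() first"
        )


def _candidate_index(a: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row/column indices of the upper-triangle non-adjacent pairs."""
    iu, ju = np.triu_indices(a.shape[0], k=1)
    mask = a[iu, ju] == 0
    return iu[mask], ju[mask]


def _table_from_matrix(
    m: np.ndarray, a: np.ndarray, labels: list[str], name: str
) -> ScoreTable:
    iu, ju = _candidate_index(a)
    pairs = [(labels[i], labels[j]) for i, j in zip(iu, ju)]
    return ScoreTable(pairs=pairs, scores=m[iu, ju].copy(), index_name=name)


def _safe_inv(x: np.ndarray) -> np.ndarray:
    out = np.zeros_like(x, dtype=float)
    nz = x != 0
    out[nz] = 1.0 / x[nz]
    return out


def _jaccard_from_adjacency(a: np.ndarray) -> np.ndarray:
    k = a.sum(axis=1)
    inter = a @ a
    union = k[:, None] + k[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        j = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return j


def _similarity_matrix(a: np.ndarray, kind: str) -> np.ndarray:
    """Node-similarity matrix S used inside Sim = AS + SA."""
    k = a.sum(axis=1)
    if kind == "jaccard":
        return _jaccard_from_adjacency(a)
    if kind == "CN":
        return a @ a
    if kind == "PA":
        return np.outer(k, k)
    if kind == "RA":
        return a @ (a * _safe_inv(k)[:, None])
    raise ValueError(f"unknown similarity kind: {kind!r}")


# -- scorers -----------------------------------------------------------


def jaccard_matrix(net: Network) -> pd.DataFrame:
    """Pairwise Jaccard neighborhood similarity J_ij = |Γi∩Γj|/|Γi∪Γj|.

    J_ii = 1 for any node of degree ≥ 1; pairs where both neighborhoods
    are empty score 0.
    """
    _require_simple(net)
    a, labels = net.adjacency()
    j = _jaccard_from_adjacency(a)
    return pd.DataFrame(j, index=labels, columns=labels)


def classic_score(
    net: Network, index: str, params: IndexParams = IndexParams()
) -> ScoreTable:
    """Score all candidate pairs with one of the classical indices.

    CN, JC, LHN, AA, PA, RA are set-based on the binary adjacency; LP is
    [A² + βA³]; Katz is the β-damped walk series truncated at
    ``katz_max_len`` (β must satisfy the spectral convergence bound).
    """
    _require_simple(net)
    if index not in CLASSIC_INDICES:
        raise ValueError(
            f"unknown classic index {index!r}; choose from {CLASSIC_INDICES}"
        )
    a, labels = net.adjacency()
    k = a.sum(axis=1)
    if index == "CN":
        m = a @ a
    elif index == "JC":
        m = _jaccard_from_adjacency(a)
    elif index == "LHN":
        inter = a @ a
        kk = np.outer(k, k)
        m = inter * _safe_inv(kk)
    elif index == "AA":
        # a common neighbor of two distinct non-adjacent nodes always has
        # degree >= 2, so zeroing the 1/log(k) weight at k < 2 only kills
        # walk terms that cannot correspond to a common neighbor
        w = np.where(k >= 2, _safe_inv(np.log(np.maximum(k, 2))), 0.0)
        m = a @ (a * w[:, None])
    elif index == "PA":
        m = np.outer(k, k)
    elif index == "RA":
        m = a @ (a * _safe_inv(k)[:, None])
    elif index == "LP":
        a2 = a @ a
        m = a2 + params.beta * (a2 @ a)
    else:  # Katz
        lam = float(np.linalg.eigvalsh(a)[-1]) if a.shape[0] else 0.0
        if lam > 0 and params.beta >= 1.0 / lam:
            raise ValueError(
                f"Katz series diverges: beta={params.beta} must be < "
                f"1/lambda_max = {1.0 / lam:.6g}"
            )
        m = np.zeros_like(a)
        term = np.eye(a.shape[0])
        for _ in range(params.katz_max_len):
            term = params.beta * (term @ a)
            m += term
    return _table_from_matrix(m, a, labels, index)


def l3_score(net: Network, params: IndexParams = IndexParams()) -> ScoreTable:
    """Degree-normalized 3-hop path score.

    For each candidate pair (i, j), sums over all paths i–z1–z2–j the
    product of the three link strengths divided by k_z1·k_z2 (product
    normalization, the default) or √(k_z1·k_z2).  Edge confidences enter
    as the link strengths a; degrees are neighbor counts.
    """
    _require_simple(net)
    w, labels = net.adjacency(weighted=True)
    a, _ = net.adjacency(weighted=False)
    k = a.sum(axis=1)
    kinv = _safe_inv(k) if params.l3_normalization == "product" else _safe_inv(
        np.sqrt(k)
    )
    # [W D⁻¹ W D⁻¹ W]_ij, D over the two intermediate nodes; on simple
    # graphs every length-3 walk between non-adjacent i, j is a path
    m = (w * kinv[None, :]) @ (w * kinv[None, :]) @ w
    name = "L3" if params.l3_normalization == "product" else "L3(sqrt)"
    return _table_from_matrix(m, a, labels, name)


def lo_score(net: Network, params: IndexParams = IndexParams()) -> ScoreTable:
    """Linear-optimization index LO = αA(αAᵀA + I)⁻¹AᵀA.

    Solved as a linear system (αAᵀA + I is symmetric positive definite,
    so the solve cannot fail); the result equals the alternating series
    αA³ − α²A⁵ + α³A⁷ − … up to truncation error for small α.  Output
    is symmetrized by averaging as a numerical safeguard (for undirected
    input the expression is already symmetric).
    """
    _require_simple(net)
    a, labels = net.adjacency()
    n = a.shape[0]
    g = a.T @ a
    m_sys = params.alpha * g + np.eye(n)
    x = np.linalg.solve(m_sys, g)
    resid = np.linalg.norm(m_sys @ x - g)
    denom = np.linalg.norm(g)
    if denom > 0 and resid / denom > 1e-10:
        raise RuntimeError(
            f"LO linear solve did not converge: relative residual "
            f"{resid / denom:.3e}"
        )
    lo = params.alpha * (a @ x)
    lo = 0.5 * (lo + lo.T)
    return _table_from_matrix(lo, a, labels, "LO")


def sim_score(net: Network, similarity: str = "jaccard") -> ScoreTable:
    """Similarity-propagation score Sim = AS + SA.

    Sim_ij = Σ_{u∈Γ(i)} S_uj + Σ_{v∈Γ(j)} S_vi: a candidate pair scores
    high when one node resembles the other node's interaction partners.
    With S = Jaccard this is the Sim index; S ∈ {CN, PA, RA} gives the
    SimCN/SimPA/SimRA variants.
    """
    _require_simple(net)
    a, labels = net.adjacency()
    s = _similarity_matrix(a, similarity)
    m = a @ s + s @ a
    name = "Sim" if similarity == "jaccard" else f"Sim{similarity}"
    return _table_from_matrix(m, a, labels, name)


# -- combination -------------------------------------------------------


def _minmax(scores: np.ndarray) -> np.ndarray:
    lo, hi = scores.min(), scores.max()
    if hi == lo:
        return np.zeros_like(scores)
    return (scores - lo) / (hi - lo)


def combine_scores(
    tables: Sequence[ScoreTable], method: str = "minmax_sum"
) -> ScoreTable:
    """Integrate several score tables over the same candidate universe.

    minmax_sum maps each table onto [0,1] by min-max scaling and sums;
    borda converts each table to descending ranks and scores each pair
    by the negated rank sum.  Either way a pair ranked first by every
    input is ranked first by the combination.
    """
    if not tables:
        raise ValueError("no tables to combine")
    base = tables[0]
    for t in tables[1:]:
        if t.pairs != base.pairs:
            raise ValueError(
                "tables scored on different candidate universes cannot "
                "be combined"
            )
    name = "+".join(t.index_name for t in tables)
    if method == "minmax_sum":
        total = np.zeros(len(base))
        for t in tables:
            total += _minmax(t.scores)
    elif method == "borda":
        total = np.zeros(len(base))
        for t in tables:
            ranks = np.empty(len(t), dtype=float)
            ranks[_rank_order(t)] = np.arange(len(t))
            total -= ranks
    else:
        raise ValueError("method must be 'minmax_sum' or 'borda'")
    return ScoreTable(pairs=list(base.pairs), scores=total, index_name=name)


# -- dispatcher --------------------------------------------------------


def _score_l3sim(net: Network, params: IndexParams) -> ScoreTable:
    combo = combine_scores(
        [l3_score(net, params), sim_score(net)], method=params.combine_method
    )
    combo.index_name = "L3+Sim"
    return combo


_DISPATCH: dict[str, Callable[[Network, IndexParams], ScoreTable]] = {
    "Sim": lambda net, p: sim_score(net, "jaccard"),
    "SimCN": lambda net, p: sim_score(net, "CN"),
    "SimPA": lambda net, p: sim_score(net, "PA"),
    "SimRA": lambda net, p: sim_score(net, "RA"),
    "L3": l3_score,
    "LO": lo_score,
    "L3+Sim": _score_l3sim,
}
for _name in CLASSIC_INDICES:
    _DISPATCH[_name] = (
        lambda net, p, _n=_name: classic_score(net, _n, p)
    )


def available_indices() -> list[str]:
    return sorted(_DISPATCH)


def score_index(
    net: Network, name: str, params: IndexParams = IndexParams()
) -> ScoreTable:
    """Score a network with any index by name (see available_indices)."""
    try:
        fn = _DISPATCH[name]
    except KeyError:
        raise ValueError(
            f"unknown index {name!r}; available: {', '.join(available_indices())}"
        ) from None
    return fn(net, params)
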