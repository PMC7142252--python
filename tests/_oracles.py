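"""Independent brute-force oracles used to validate the scorers.

Everything here works from neighbor sets and explicit path/walk
enumeration (or explicit matrix inverses for the series indices) and
deliberately avoids the vectorized formulations used by the package.
"""

from __future__ import annotations

import math

import numpy as np

from ppisim.network import Network


def cn(net: Network, i: str, j: str) -> float:
    return len(net.neighbors(i) & net.neighbors(j))


def jc(net: Network, i: str, j: str) -> float:
    union = net.neighbors(i) | net.neighbors(j)
    if not union:
        return 0.0
    return len(net.neighbors(i) & net.neighbors(j)) / len(union)


def lhn(net: Network, i: str, j: str) -> float:
    ki, kj = net.degree(i), net.degree(j)
    if ki == 0 or kj == 0:
        return 0.0
    return cn(net, i, j) / (ki * kj)


def aa(net: Network, i: str, j: str) -> float:
    total = 0.0
    for z in net.neighbors(i) & net.neighbors(j):
        kz = net.degree(z)
        if kz >= 2:
            total += 1.0 / math.log(kz)
    return total


def pa(net: Network, i: str, j: str) -> float:
    return net.degree(i) * net.degree(j)


def ra(net: Network, i: str, j: str) -> float:
    return sum(1.0 / net.degree(z) for z in net.neighbors(i) & net.neighbors(j))


def lp(net: Network, i: str, j: str, beta: float) -> float:
    """[A² + βA³]_ij by explicit walk enumeration over neighbor sets."""
    walks2 = len(net.neighbors(i) & net.neighbors(j))
    walks3 = sum(
        1
        for u in net.neighbors(i)
        for v in net.neighbors(j)
        if net.has_edge(u, v)
    )
    return walks2 + beta * walks3

CLASSIC_ORACLES = {"CN": cn, "JC": jc, "LHN": lhn, "AA": aa, "PA": pa, "RA": ra}


def katz_closed_form(net: Network, beta: float) -> tuple[np.ndarray, list[str]]:
    """Katz via the exact resolvent (I − βA)⁻¹ − I (full series)."""
    a, labels = net.adjacency()
    n = a.shape[0]
    m = np.linalg.inv(np.eye(n) - beta * a) - np.eye(n)
    return m, labels


def l3_brute(net: Network, i: str, j: str, normalization: str = "product") -> float:
    """Degree-normalized 3-path score by explicit path enumeration."""
    total = 0.0
    for z1 in net.neighbors(i):
        if z1 == j:
            continue
        for z2 in net.neighbors(z1) & net.neighbors(j):
            if z2 == i or z2 == z1:
                continue
            w = net.weight(i, z1) * net.weight(z1, z2) * net.weight(z2, j)
            d = net.degree(z1) * net.degree(z2)
            if normalization == "sqrt":
                d = math.sqrt(d)
            total += w / d
    return total


def sim_sum_form(net: Network, i: str, j: str, similarity: str = "jaccard") -> float:
    """Sim_ij = Σ_{u∈Γ(i)} S_uj + Σ_{v∈Γ(j)} S_vi, per-pair set arithmetic."""
    s = {
        "jaccard": jc,
        "CN": cn,
        "PA": pa,
        "RA": ra,
    }[similarity]
    return sum(s(net, u, j) for u in net.neighbors(i)) + sum(
        s(net, v, i) for v in net.neighbors(j)
    )


def lo_series(net: Network, alpha: float, terms: int = 4) -> tuple[np.ndarray, list[str]]:
    """Alternating odd-power series αA³ − α²A⁵ + α³A⁷ − α⁴A⁹ + …"""
    a, labels = net.adjacency()
    a2 = a @ a
    power = a @ a2  # A^3
    out = np.zeros_like(a)
    sign, coef = 1.0, alpha
    for _ in range(terms):
        out += sign * coef * power
        power = power @ a2
        sign, coef = -sign, coef * alpha
    return out, labels


def candidate_pairs(net: Network) -> list[tuple[str, str]]:
    """All unordered non-adjacent distinct pairs."""
    nodes = net.nodes
    return [
        (u, v)
        for a_i, u in enumerate(nodes)
        for v in nodes[a_i + 1 :]
        if not net.has_edge(u, v)
    ]
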