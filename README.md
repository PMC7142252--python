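# ppisim

Network-based link prediction for protein–protein interaction (PPI)
networks.

Known PPI networks are incomplete: high-throughput interaction assays
are costly and noisy, so ranking candidate protein pairs by how likely
they are to interact — using nothing but the network already observed —
is a practical way to prioritize experiments. `ppisim` is for
computational biologists who want to run, compare, and benchmark such
predictors on real or simulated interaction networks.

## The Sim index

Interacting proteins carry *complementary* binding interfaces, while
proteins with *similar* interfaces (often paralogs from gene
duplication) tend to share interaction partners rather than interact.
Classical two-hop indices (common neighbors, Adamic–Adar, resource
allocation, …) therefore misread PPI structure: many shared partners is
evidence of similarity, not of a missing link.

`ppisim` scores a non-adjacent pair (i, j) by propagating similarity
through the neighborhood instead:

    Sim = AJ + JA,        Sim_ij = Σ_{u∈Γ(i)} J_uj + Σ_{v∈Γ(j)} J_vi

where A is the adjacency matrix, Γ(i) the neighbor set, and
J_uv = |Γ_u ∩ Γ_v| / |Γ_u ∪ Γ_v| the Jaccard similarity. A pair scores
high when one protein resembles the other's partners — exactly the
configuration interface complementarity predicts for an unobserved
edge. Variants SimCN / SimPA / SimRA substitute common-neighbor,
preferential-attachment, or resource-allocation similarity for J.

Also implemented, as baselines and for integration:

* **L3** — degree-normalized 3-hop path count,
  `L3_ij = Σ a_iz1 a_z1z2 a_z2j / (k_z1 k_z2)`;
* **LO** — the linear-optimization index `αA(αAᵀA + I)⁻¹AᵀA`,
  computed by a positive-definite linear solve;
* **L3+Sim** — integration of the two score tables (min-max
  normalization and sum by default, Borda rank-sum as an option);
* the classical table: CN, JC, LHN, AA, PA, RA, LP, Katz.

Two seedable random-network generators emulate the mechanisms the
index is built on — an **interface-complementarity model** (nodes carry
d-vectors of interface states; complementary states link) and a
**duplication–divergence model** (duplicate a node, retain each of its
links with probability p) — plus Erdős–Rényi and Watts–Strogatz
baselines. An evaluation harness runs 10-fold edge cross-validation
and reports precision@k curves (k ≤ 200) against the random-guess
baseline.

## Worked example

```python
import ppisim as pp

# the 4-node path a-b-c-d
net = pp.Network.from_edges([("a", "b"), ("b", "c"), ("c", "d")])

pp.jaccard_matrix(net).loc["a", "c"]      # 0.5    (= |{b}| / |{b,d}|)
pp.l3_score(net).score_of("a", "d")       # 0.25   (one 3-path, 1/(k_b·k_c))
pp.sim_score(net).score_of("a", "d")      # 1.0    (= J_bd + J_ca = 0.5+0.5)
pp.sim_score(net).ranked(1)               # [(('a', 'd'), 1.0)]
```

The top-ranked candidate is (a, d): the endpoints of the path, joined
by a 3-hop path and by neighbors similar to each other — the pair the
interface-complementarity mechanism predicts.

A full benchmark on a duplication-model network:

```python
net = pp.duplication_network(pp.DuplicationModelParams(steps=280, p=0.9, seed=3))
results = pp.cross_validate(net, index_names=("Sim", "L3", "L3+Sim"),
                            n_folds=10, k_max=200, seed=3)
for name, res in results.items():
    print(name, round(res.mean_curve.area, 3), round(res.mean_curve.baseline, 4))
# Sim 0.554 0.0161
# L3 0.345 0.0161
# L3+Sim 0.543 0.0161
```

Sim's mean precision over k = 1..200 is ~0.55 versus a random-guess
baseline of ~0.016 — held-out interactions are recovered at ~34× the
chance rate on this network.

The same flows are available from the shell:

```bash
ppisim generate duplication --steps 280 -p 0.9 --seed 3 -o dup.edges
ppisim predict dup.edges --index Sim -k 100 -o predictions.csv
ppisim evaluate dup.edges --n-folds 10 --k-max 200 --seed 3 -o bench
ppisim stats dup.edges
```

Weighted inputs (third edge-list column = confidence) are
max-normalized and thresholded at 0.7 by default before scoring, the
standard guard against false-positive interactions in database exports.

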