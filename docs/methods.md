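# Methods

## Scope and model

`ppisim` predicts missing links in undirected protein–protein
interaction (PPI) networks from network topology alone. The candidate
universe is every unordered non-adjacent node pair of the input
network, including cross-component pairs; path-based indices assign
those 0, which is the honest statement that topology alone cannot
connect components. All scorers require a simple graph: self-loops
(recorded self-interactions, reported as `n_rings` by the statistics)
must be removed first, since every index formula below assumes
`a_ii = 0`.

### Scoring indices

With A the binary adjacency matrix, Γ(i) the neighbor set, k_i = |Γ(i)|:

* **Jaccard similarity** J_ij = |Γ_i ∩ Γ_j| / |Γ_i ∪ Γ_j|; J_ii = 1
  for k_i ≥ 1, and 0 when both neighborhoods are empty.
* **Sim** = AS + SA with S = J (variants: S = CN, PA, RA matrices).
  Restricted to non-adjacent pairs this equals the neighbor-sum form
  Σ_{u∈Γ(i)} S_uj + Σ_{v∈Γ(j)} S_vi; the equivalence is enforced by a
  property test against per-pair set arithmetic. The diagonal of S
  never enters a candidate pair's score (u ∈ Γ(i) can equal j only if
  the pair is adjacent), so its convention is immaterial.
* **L3**_ij = Σ over paths i–z1–z2–j of a_iz1 a_z1z2 a_z2j / D, with
  D = k_z1·k_z2 by default (`l3_normalization="product"`) or
  √(k_z1 k_z2) (`"sqrt"`, the convention of the original 3-hop
  literature). Computed as A D⁻¹ A D⁻¹ A; on simple graphs every
  length-3 walk between non-adjacent endpoints is a path, so the matrix
  product equals brute-force path enumeration (tested exhaustively on
  all graphs with ≤ 7 nodes). Edge confidences enter the numerator;
  degrees are unweighted neighbor counts. All other indices use binary
  adjacency — their definitions are set-based.
* **LO** = αA(αAᵀA + I)⁻¹AᵀA, evaluated via `numpy.linalg.solve` on
  the symmetric positive-definite system (never an explicit inverse),
  with a relative-residual guard at 1e-10. Output is symmetrized by
  averaging, a no-op up to rounding for undirected input.
* **Classical indices** CN, JC, LHN, AA, PA, RA, LP = A² + βA³, and
  Katz = Σ_{l≥1} β^l A^l truncated at `katz_max_len`.

### Parameters

| parameter | default | role |
|---|---|---|
| `alpha` | 1e-5 | LO regularization; the index behaves as αA³ to leading order, so the ranking is insensitive to α once it is small |
| `beta` | 1e-3 | LP/Katz damping; Katz demands β < 1/λ_max(A), checked against the exact spectrum at call time |
| `katz_max_len` | 10 | Katz truncation; at the default β the discarded tail is O((βλ)¹¹), far below score resolution on the graph sizes in scope |
| `l3_normalization` | product | 3-path denominator (see above) |
| `combine_method` | minmax_sum | integration rule for L3+Sim |

**L3+Sim integration.** The two score distributions live on different
scales (L3 is a normalized path count, Sim a summed similarity), so the
default maps each table onto [0,1] by min-max scaling over its
candidate pairs and sums. Borda rank-sum combination is provided as a
scale-free alternative; both preserve a pair that tops both inputs.
The rule used is recorded in the output metadata.

**Determinism.** Score tables store pairs with the smaller label first,
in sorted order; ranking is by descending score with lexicographic
tie-break. Identical inputs give byte-identical outputs, which is what
makes cross-validated precision curves reproducible.

## Preprocessing

Weighted inputs (confidence-scored database exports) are divided by
their maximum weight — mapping 0–1000-style scores onto [0,1] — and
edges below 0.7 are dropped, the usual guard against false positives.
The operation is idempotent. Duplicate edge-list lines collapse to one
edge keeping the maximum confidence (conservative for a confidence
semantic). Largest-component extraction breaks size ties toward the
component containing the lexicographically smallest label.

Network statistics (mean local clustering with degree<2 nodes counted
as 0, degree-Pearson assortativity over both edge orientations, mean
degree, heterogeneity ⟨k²⟩/⟨k⟩², density 2E/(n(n−1))) are computed on
the simple graph; self-loops are only counted, from the network as
given, since curated releases report them but no index uses them.

## Synthetic-data generators

The generators are first-class simulators of the two linkage
mechanisms; they define the conditions under which the pipeline is
validated.

**Interface-complementarity model.** Each node draws a d-vector over
{0,1,2,3} i.i.d. with probabilities (p1..p4): 0 = carries neither half
of interface pair i, 1 = the i⁺ half, 2 = the i⁻ half, 3 = both. Two
distinct nodes link iff some coordinate pairs complementary halves —
(x_i, y_i) ∈ {(1,2),(2,1),(1,3),(3,1),(2,3),(3,2),(3,3)}. Nodes with
identical profiles are structurally equivalent, hence non-adjacent
twins have Jaccard similarity 1: the model builds in exactly the signal
Sim exploits. At PPI-like sparsity a sizable fraction of nodes draw
the all-zero profile and stay isolated, so analysis uses the largest
connected component — mirroring the real-data pipeline. The shipped
presets (n = 300–1,000, d = 2–5, state probabilities skewed to 0) are
our own reconstructions targeting mean degree ≈ 9–16, the sparse range
typical of curated PPI networks; they are not replications of any
published parameter set.

**Duplication–divergence model.** Starting from a connected seed
network (default: largest component of an Erdős–Rényi G(20, 0.3) draw
under the run's seed), each step picks a node u uniformly, adds a
duplicate v, and copies each edge u–w to v–w independently with
probability p. Per-link retention is the standard divergence reading;
all-or-none copying would only produce exact twins. No u–v edge is
added by default (paralogs share partners rather than interact; a flag
enables it). The largest component of the grown network is returned.
Presets span 280–980 steps at p = 0.7–0.9.

**What the generators do not emulate:** experimental false
positives/negatives, confidence weights, hub-biased assay coverage, or
community structure beyond what duplication induces. Passing the
recovery benchmarks therefore shows the pipeline recovers links *when
the generating mechanism matches the index's assumption*, not that any
particular precision level transfers to real interactome data.

## Evaluation protocol

Edges are shuffled under a seed and partitioned into 10 near-equal
folds (sizes differ by ≤ 1). Each fold in turn is the probe set: its
edges are removed (endpoints retained, training graph possibly
disconnected and used as-is), every index scores the training graph's
candidate pairs, and precision(k) = |top-k ∩ probe| / k is recorded
for k = 1..200. Only edges are partitioned; non-edges are never
resampled as negatives. The curve summary "area" is the mean precision
over evaluated k — i.e. the area under the step curve normalized by
k_max, comparable across k_max choices. The random-guess baseline is
|probe| / |candidates|. Reported curves are pointwise means over the
10 folds, with per-fold curves retained for dispersion; tiny graphs
whose candidate count falls short of k_max get truncated curves and
the mean uses available k only.

## Numerical choices and edge cases

* Adamic–Adar uses the natural logarithm; the 1/log k_z weight is
  zeroed for k_z < 2, which only suppresses walk terms that cannot
  correspond to a common neighbor of a distinct non-adjacent pair
  (any true common neighbor has degree ≥ 2).
* LO's agreement with its alternating odd-power series
  αA³ − α²A⁵ + α³A⁷ − α⁴A⁹ is asserted in the relative 2-norm over the
  candidate score vector. Entrywise relative agreement is not
  attainable: for a pair whose shortest odd walk has length 7 the
  4-term series itself mis-states the entry by a relative
  O(αλ²) ≈ 5·10⁻⁴ truncation error, while the norm-level discrepancy
  is O((αλ²)⁴).
* Monotonicity under edge addition holds cleanly for CN/RA/AA (a fresh
  common neighbor can only raise the score) and is tested so. For L3
  and Sim it holds only when the new path's intermediates are fresh
  nodes — a new edge also raises existing intermediates' degrees and
  enlarges Jaccard unions, which can lower other terms — so the L3 test
  uses the fresh-intermediates construction and no global monotonicity
  is claimed.
* All-equal score tables min-max-scale to 0 (they carry no ranking
  information); empty candidate sets rank to an empty list with a
  warning; assortativity of degree-constant edge sets is NaN with a
  warning.

## Problem sizes

The shipped benchmarks run at desk scale, chosen so the full suite and
the reproduction script each complete in minutes on a single core:
exhaustive oracle checks on all 1,253 simple graphs with ≤ 7 nodes plus
100 seeded random graphs (n ≤ 30); recovery benchmarks on a
duplication network of ~300 nodes (280 steps, p = 0.9) and the largest
component (~200–250 nodes) of an n = 800 interface-model draw. Dense
n×n arrays are used throughout — adequate into the low thousands of
nodes; larger interactomes would want a sparse backend, which is a
known limitation. Real-database retrieval (HINT/BIOGRID/STRING
exports) is out of scope: readers accept their edge-list exports, but
no downloader is included.
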