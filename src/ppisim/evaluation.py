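"""Cross-validated precision@k evaluation of link predictors.

The protocol: partition the observed edges into folds, remove one fold
(the probe set), score every non-adjacent pair of the training network,
and measure precision(k) — the fraction of the k top-ranked candidate
pairs that are probe edges — for k = 1..k_max (default 200; very large
k has no practical value since each positive prediction is a candidate
for an expensive experiment).  The curve is summarized by its area,
defined here as the mean precision over k, and compared against the
random-guess baseline |probe| / |candidates|.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .indices import DEFAULT_INDEX_SET, IndexParams, ScoreTable, score_index
from .network import Network

__all__ = [
    "EvalSplit",
    "PrecisionCurve",
    "CVResult",
    "make_folds",
    "precision_curve",
    "cross_validate",
    "random_guess_precision",
]


@dataclass
class EvalSplit:
    """One cross-validation fold: training network + held-out probes."""

    training: Network
    probe: frozenset[tuple[str, str]]
    fold_id: int

    @property
    def n_candidates(self) -> int:
        n = self.training.n_nodes
        return n * (n - 1) // 2 - self.training.n_edges


@dataclass
class PrecisionCurve:
    """precision(k) for k = 1..k_max plus its area summary.

    area is the mean of precision over the evaluated k (the area under
    the step curve normalized by k_max, comparable across k_max
    choices); baseline is the precision of uniform random guessing.
    """

    k_values: np.ndarray
    precision: np.ndarray
    area: float
    n_probe: int
    baseline: float

    def precision_at(self, k: int) -> float:
        i = np.searchsorted(self.k_values, k)
        if i >= len(self.k_values) or self.k_values[i] != k:
            raise ValueError(f"k={k} outside evaluated range")
        return float(self.precision[i])


@dataclass
class CVResult:
    """Averaged precision curve of one index plus its per-fold curves."""

    index_name: str
    mean_curve: PrecisionCurve
    fold_curves: list[PrecisionCurve] = field(default_factory=list)

    @property
    def precision_sd(self) -> np.ndarray:
        k_max = len(self.mean_curve.k_values)
        rows = [
            np.pad(c.precision, (0, k_max - len(c.precision)), constant_values=np.nan)
            for c in self.fold_curves
        ]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return np.nanstd(np.vstack(rows), axis=0, ddof=0)


def make_folds(net: Network, n_folds: int = 10, seed: int = 0) -> list[EvalSplit]:
    """Partition the edge set into near-equal folds under a seed.

    Each split removes one fold of edges from the network (endpoints
    stay, possibly isolated; the training graph may be disconnected —
    path-based indices simply score cross-component pairs 0).  Fold
    sizes differ by at most one; the probes of all folds partition the
    original edge set.
    """
    if net.n_rings:
        raise ValueError("network must be simple (no self-loops)")
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    edges = sorted(net.edges())
    if len(edges) < n_folds:
        raise ValueError(
            f"need at least n_folds={n_folds} edges, have {len(edges)}"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(edges))
    splits = []
    bounds = np.linspace(0, len(edges), n_folds + 1).astype(int)
    for f in range(n_folds):
        probe = frozenset(edges[i] for i in perm[bounds[f] : bounds[f + 1]])
        splits.append(
            EvalSplit(
                training=net.remove_edges(probe), probe=probe, fold_id=f + 1
            )
        )
    return splits


def precision_curve(
    split: EvalSplit, table: ScoreTable, k_max: int = 200
) -> PrecisionCurve:
    """Precision of the top-k predictions against the probe set."""
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > len(table):
        warnings.warn(
            f"k_max={k_max} exceeds the {len(table)} candidate pairs; "
            "curve truncated"
        )
        k_max = len(table)
    top = table.ranked(k_max)
    hits = np.cumsum([1 if pair in split.probe else 0 for pair, _ in top])
    ks = np.arange(1, k_max + 1)
    prec = hits / ks
    baseline = len(split.probe) / len(table) if len(table) else float("nan")
    return PrecisionCurve(
        k_values=ks,
        precision=prec,
        area=float(prec.mean()),
        n_probe=len(split.probe),
        baseline=baseline,
    )


def _mean_curve(curves: list[PrecisionCurve]) -> PrecisionCurve:
    k_max = max(len(c.precision) for c in curves)
    stack = np.full((len(curves), k_max), np.nan)
    for r, c in enumerate(curves):
        stack[r, : len(c.precision)] = c.precision
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
    return PrecisionCurve(
        k_values=np.arange(1, k_max + 1),
        precision=mean,
        area=float(np.nanmean(mean)),
        n_probe=int(round(np.mean([c.n_probe for c in curves]))),
        baseline=float(np.mean([c.baseline for c in curves])),
    )


def cross_validate(
    net: Network,
    index_names: tuple[str, ...] = DEFAULT_INDEX_SET,
    params: IndexParams = IndexParams(),
    n_folds: int = 10,
    k_max: int = 200,
    seed: int = 0,
) -> dict[str, CVResult]:
    """Averaged precision curves of several indices on one network.

    For each index, each fold's training network is scored and its
    precision curve computed; the returned curve is the pointwise mean
    over folds (per-fold curves retained for dispersion reporting).
    Deterministic given (net, seed, index_names, params).
    """
    if net.n_nodes == 0:
        raise ValueError("empty network")
    splits = make_folds(net, n_folds=n_folds, seed=seed)
    curves: dict[str, list[PrecisionCurve]] = {name: [] for name in index_names}
    for split in splits:
        for name in index_names:
            table = score_index(split.training, name, params)
            curves[name].append(precision_curve(split, table, k_max=k_max))
    return {
        name: CVResult(
            index_name=name, mean_curve=_mean_curve(cs), fold_curves=cs
        )
        for name, cs in curves.items()
    }


def random_guess_precision(
    n_nodes: int, n_observed_edges: int, n_probe: int
) -> float:
    """Precision of uniform random guessing.

    Probe edges divided by the candidate-pair count C(n,2) minus the
    observed (training) edges.
    """
    candidates = n_nodes * (n_nodes - 1) // 2 - n_observed_edges
    if candidates <= 0:
        raise ValueError("no candidate pairs")
    return n_probe / candidates


def results_to_frames(
    results: dict[str, CVResult]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format per-k curve table and a per-index area summary."""
    curve_rows, summary_rows = [], []
    for name, res in results.items():
        sd = res.precision_sd
        for i, k in enumerate(res.mean_curve.k_values):
            curve_rows.append(
                {
                    "index": name,
                    "k": int(k),
                    "precision_mean": res.mean_curve.precision[i],
                    "precision_sd": sd[i] if len(res.fold_curves) else np.nan,
                }
            )
        summary_rows.append(
            {
                "index": name,
                "area": res.mean_curve.area,
                "baseline": res.mean_curve.baseline,
            }
        )
    return pd.DataFrame(curve_rows), pd.DataFrame(summary_rows)


def plot_curves(results: dict[str, CVResult], path) -> None:
    """Optional static plot of precision vs k per index (needs matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, res in results.items():
        ax.plot(res.mean_curve.k_values, res.mean_curve.precision, label=name)
    base = next(iter(results.values())).mean_curve.baseline
    ax.axhline(base, ls="--", c="gray", lw=0.8, label="random guess")
    ax.set_xlabel("k (number of predictions)")
    ax.set_ylabel("precision of top-k")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
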