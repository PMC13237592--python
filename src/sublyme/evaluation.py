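"""Homology-aware model evaluation.

Cross-validation folds are assigned at the level of homology clusters, not
proteins, so homologous sequences never straddle the train/test boundary.
Folds are built by seeded greedy size balancing: clusters are shuffled,
sorted by size (stable, so the shuffle breaks ties), and each assigned to
the currently smallest fold by protein count.  Metrics are computed for the
positive class; aggregate uncertainty uses empirical percentile confidence
intervals across iterations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from sublyme.cascade_model import fit_stage
from sublyme.dataset_builder import LabelledDataset

__all__ = [
    "IterationSplit",
    "MetricSet",
    "SweepTable",
    "CVSummary",
    "make_group_folds",
    "compute_metrics",
    "threshold_sweep",
    "evaluate_cv",
    "aggregate_ci",
]

DEFAULT_GRID = tuple(range(0, 101, 5))


@dataclass(frozen=True)
class IterationSplit:
    """One train/test division; the cluster sets of the two sides are disjoint."""

    repeat: int
    fold: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]


@dataclass(frozen=True)
class MetricSet:
    """Positive-class precision/recall/F1 plus the raw confusion counts.

    Zero-denominator cases (e.g. precision with no positive predictions)
    are ``None`` — missing, not 0 and not 1; F1 is missing whenever either
    parent is.
    """

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass
class SweepTable:
    """Per-threshold metrics over a strictly increasing percent grid."""

    grid: tuple[int, ...]
    metrics: list[MetricSet]

    def column(self, name: str) -> list[float | None]:
        return [getattr(m, name) for m in self.metrics]


@dataclass
class CVSummary:
    """Per-iteration metrics with aggregate mean and 95% CI per metric."""

    iterations: list[dict]
    aggregate: dict[str, dict[str, float]]
    skipped: list[tuple[int, int, str]] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)


def make_group_folds(
    dataset: LabelledDataset, folds: int, repeats: int, seed: int
) -> list[IterationSplit]:
    """Cluster-aware repeated k-fold splits (r x k iterations).

    Per repeat, clusters are partitioned into ``folds`` groups by seeded
    greedy balancing; each fold serves once as the test set.  Deterministic
    for a fixed seed.
    """
    cluster_members: dict[str, list[str]] = {}
    for pid in dataset.ids:
        cluster_members.setdefault(dataset.clusters[pid], []).append(pid)
    cluster_ids = sorted(cluster_members)
    if len(cluster_ids) < folds:
        raise ValueError(
            f"{len(cluster_ids)} clusters cannot be split into {folds} folds"
        )
    rng = np.random.default_rng(seed)
    splits: list[IterationSplit] = []
    for repeat in range(repeats):
        order = list(rng.permutation(cluster_ids))
        # stable sort by descending size; the prior shuffle breaks ties
        order.sort(key=lambda c: -len(cluster_members[c]))
        fold_clusters: list[list[str]] = [[] for _ in range(folds)]
        fold_sizes = np.zeros(folds, dtype=int)
        for cluster in order:
            target = int(np.argmin(fold_sizes))
            fold_clusters[target].append(cluster)
            fold_sizes[target] += len(cluster_members[cluster])
        for fold in range(folds):
            test = frozenset(
                pid for c in fold_clusters[fold] for pid in cluster_members[c]
            )
            train = frozenset(dataset.ids) - test
            splits.append(
                IterationSplit(repeat=repeat, fold=fold, train_ids=train, test_ids=test)
            )
    return splits


def compute_metrics(
    truth: Sequence[bool] | np.ndarray, predicted: Sequence[bool] | np.ndarray
) -> MetricSet:
    """Confusion counts and positive-class precision/recall/F1."""
    t = np.asarray(truth, dtype=bool)
    p = np.asarray(predicted, dtype=bool)
    if t.shape != p.shape:
        raise ValueError(f"length mismatch: truth {t.shape} vs predicted {p.shape}")
    if t.size == 0:
        raise ValueError("metric computation requires at least one example")
    tp = int(np.sum(t & p))
    fp = int(np.sum(~t & p))
    fn = int(np.sum(t & ~p))
    tn = int(np.sum(~t & ~p))
    precision = tp / (tp + fp) if (tp + fp) > 0 else None
    recall = tp / (tp + fn) if (tp + fn) > 0 else None
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricSet(tp=tp, fp=fp, fn=fn, tn=tn, precision=precision, recall=recall, f1=f1)


def threshold_sweep(
    scores: Sequence[float] | np.ndarray,
    truth: Sequence[bool] | np.ndarray,
    grid: Iterable[int] = DEFAULT_GRID,
) -> SweepTable:
    """Metrics at each percent threshold with the strict > decision rule.

    The default grid is 0..100 in steps of 5 (21 rows).  Endpoint rows can
    legitimately carry missing precision (no positive predictions at 100%).
    """
    s = np.asarray(scores, dtype=float)
    if s.size and (s.min() < 0.0 or s.max() > 1.0):
        raise ValueError("scores must lie in [0, 1]")
    grid = tuple(int(g) for g in grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly increasing")
    metrics = [compute_metrics(truth, s > g / 100.0) for g in grid]
    return SweepTable(grid=grid, metrics=metrics)


def aggregate_ci(
    values: Sequence[float] | np.ndarray, level: float = 0.95
) -> tuple[float, float, float]:
    """Mean and distribution-free empirical percentile CI bounds."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot aggregate an empty vector")
    alpha = (1.0 - level) / 2.0
    lower, upper = np.percentile(v, [100 * alpha, 100 * (1 - alpha)])
    return float(v.mean()), float(lower), float(upper)


def evaluate_cv(
    dataset: LabelledDataset,
    folds: int,
    repeats: int,
    seed: int,
    sweep: bool = False,
) -> CVSummary:
    """Run cluster-aware repeated k-fold CV of a single stage.

    Each iteration fits a fresh stage on the train side and scores the test
    side; thresholding at 50% (strict >) gives the headline metrics and,
    optionally, a full 0-100% threshold sweep from the same scores.  Splits
    whose train side lacks a class are recorded as skipped with a warning,
    never silently dropped.
    """
    splits = make_group_folds(dataset, folds, repeats, seed)
    iterations: list[dict] = []
    skipped: list[tuple[int, int, str]] = []
    for i, split in enumerate(splits):
        train_ids = sorted(split.train_ids)
        test_ids = sorted(split.test_ids)
        y_train = dataset.y(train_ids)
        if np.unique(y_train).size < 2:
            msg = "train side contains a single class"
            warnings.warn(
                f"skipping repeat {split.repeat} fold {split.fold}: {msg}",
                stacklevel=2,
            )
            skipped.append((split.repeat, split.fold, msg))
            continue
        stage = fit_stage(dataset.subset(train_ids), seed=seed + i)
        scores = stage.score(dataset.X(test_ids).astype(np.float64))
        truth = dataset.y(test_ids).astype(bool)
        record = {
            "repeat": split.repeat,
            "fold": split.fold,
            "n_train": len(train_ids),
            "n_test": len(test_ids),
            "metrics": compute_metrics(truth, scores > 0.5),
        }
        if sweep:
            record["sweep"] = threshold_sweep(scores, truth)
        iterations.append(record)

    aggregate: dict[str, dict[str, float]] = {}
    for name in ("precision", "recall", "f1"):
        vals = [
            it["metrics"].__getattribute__(name)
            for it in iterations
            if it["metrics"].__getattribute__(name) is not None
        ]
        if vals:
            mean, lo, hi = aggregate_ci(vals)
            aggregate[name] = {"mean": mean, "ci_lower": lo, "ci_upper": hi}
    return CVSummary(iterations=iterations, aggregate=aggregate, skipped=skipped)
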