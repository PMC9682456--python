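"""Nested K-fold experiment harness and the metric suite.

The study design holds out 20% of the labeled data as a fixed validation
set, then deals the remaining 80% into K=10 folds; each fold in turn is
the test set for a model trained on the other nine, giving K models to
compare against the holdout.  Models and hyperparameter-grid points are
ranked by mean fold F1.

Metrics (related = positive class):

    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 P R / (P + R)
    accuracy  = (TP + TN) / (TP + FP + FN + TN)

``f1_macro`` is the unweighted mean of the per-class F1 scores, where the
negative class's F1 treats TN as that class's true positives.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from lkdtalk.model import (
    ClassifierConfig,
    TrainedClassifier,
    predict_proba_batch,
    train,
)

__all__ = [
    "SplitPlan",
    "ConfusionCounts",
    "MetricsReport",
    "make_split",
    "compute_metrics",
    "kfold_evaluate",
    "grid_search",
    "KFoldResult",
]


@dataclass(frozen=True)
class SplitPlan:
    """Holdout indices plus K disjoint folds partitioning the remainder."""

    holdout_indices: tuple[int, ...]
    folds: tuple[tuple[int, ...], ...]
    seed: int
    k: int = 10

    def __post_init__(self) -> None:
        holdout = set(self.holdout_indices)
        all_fold = [i for f in self.folds for i in f]
        if len(all_fold) != len(set(all_fold)):
            raise ValueError("folds are not pairwise disjoint")
        if holdout & set(all_fold):
            raise ValueError("holdout overlaps the folds")
        sizes = [len(f) for f in self.folds]
        if sizes and max(sizes) - min(sizes) > 1:
            raise ValueError("fold sizes must differ by at most 1")

    @property
    def n(self) -> int:
        return len(self.holdout_indices) + sum(len(f) for f in self.folds)

    def training_indices(self, fold: int) -> list[int]:
        """All fold indices except those of ``fold``."""
        return [i for j, f in enumerate(self.folds) if j != fold for i in f]


def make_split(
    n: int,
    holdout_frac: float = 0.2,
    k: int = 10,
    seed: int = 0,
    labels: Optional[Sequence[int]] = None,
    stratify: bool = False,
) -> SplitPlan:
    """Randomly partition ``range(n)`` into a holdout set and K folds.

    The holdout size is ``n * holdout_frac`` rounded half-up; the
    remaining indices are dealt into K folds whose sizes differ by at
    most one.  Deterministic given ``seed``.  With ``stratify=True``
    (off by default) the holdout draw preserves the class balance of
    ``labels``; folds are dealt round-robin from the label-sorted
    remainder so each fold sees both classes.
    """
    if not 0 < holdout_frac < 1:
        raise ValueError("holdout_frac must lie strictly between 0 and 1")
    if k < 1:
        raise ValueError("k must be >= 1")
    holdout_size = int(math.floor(n * holdout_frac + 0.5))
    if n - holdout_size < k:
        raise ValueError(
            f"n={n} too small for holdout_frac={holdout_frac} and k={k} folds"
        )
    rng = np.random.default_rng(seed)
    if stratify:
        if labels is None or len(labels) != n:
            raise ValueError("stratify=True requires labels of length n")
        y = np.asarray(labels)
        classes = list(np.unique(y))
        per_class = {c: rng.permutation(np.flatnonzero(y == c)) for c in classes}
        # largest-remainder allocation of the holdout across classes
        raw = {c: holdout_size * len(per_class[c]) / n for c in classes}
        take = {c: int(math.floor(raw[c])) for c in classes}
        short = holdout_size - sum(take.values())
        for c in sorted(classes, key=lambda c: raw[c] - take[c], reverse=True)[:short]:
            take[c] += 1
        holdout = np.concatenate([per_class[c][: take[c]] for c in classes])
        # class-sorted remainder dealt round-robin spreads classes evenly
        rest = np.concatenate([per_class[c][take[c]:] for c in classes])
        rest = rest[np.argsort([y[i] for i in rest], kind="stable")]
        folds_rr: list[list[int]] = [[] for _ in range(k)]
        for pos, i in enumerate(rest):
            folds_rr[pos % k].append(int(i))
        return SplitPlan(
            holdout_indices=tuple(int(i) for i in holdout),
            folds=tuple(tuple(f) for f in folds_rr),
            seed=seed,
            k=k,
        )
    perm = rng.permutation(n)
    holdout = perm[:holdout_size]
    rest = perm[holdout_size:]
    base, extra = divmod(len(rest), k)
    folds, pos = [], 0
    for j in range(k):
        size = base + (1 if j < extra else 0)
        folds.append(tuple(int(i) for i in rest[pos : pos + size]))
        pos += size
    return SplitPlan(
        holdout_indices=tuple(int(i) for i in holdout),
        folds=tuple(folds),
        seed=seed,
        k=k,
    )


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/FP/FN/TN for one stratum (a source, or the aggregate)."""

    tp: int
    fp: int
    fn: int
    tn: int
    stratum: str = "aggregate"

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
            stratum="aggregate",
        )


@dataclass(frozen=True)
class MetricsReport:
    """Precision/recall/F1/macro-F1/accuracy for one confusion matrix.

    ``degenerate`` lists the metrics whose denominator was zero; those are
    reported as 0 by convention.
    """

    precision: float
    recall: float
    f1: float
    f1_macro: float
    accuracy: float
    counts: ConfusionCounts
    degenerate: tuple[str, ...] = ()


def _safe_div(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den else (0.0, True)


def _f1(p: float, r: float) -> tuple[float, bool]:
    return _safe_div(2 * p * r, p + r)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Metric suite for one stratum; zero denominators flag the metric."""
    degenerate: list[str] = []
    precision, d = _safe_div(counts.tp, counts.tp + counts.fp)
    if d:
        degenerate.append("precision")
    recall, d = _safe_div(counts.tp, counts.tp + counts.fn)
    if d:
        degenerate.append("recall")
    f1, d = _f1(precision, recall)
    if d:
        degenerate.append("f1")
    # Negative class viewed as positive: TP'=TN, FP'=FN, FN'=FP.
    neg_precision, d1 = _safe_div(counts.tn, counts.tn + counts.fn)
    neg_recall, d2 = _safe_div(counts.tn, counts.tn + counts.fp)
    neg_f1, d3 = _f1(neg_precision, neg_recall)
    if d1 or d2 or d3:
        degenerate.append("f1_macro")
    f1_macro = 0.5 * (f1 + neg_f1)
    accuracy, d = _safe_div(counts.tp + counts.tn, counts.total)
    if d:
        degenerate.append("accuracy")
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        f1_macro=f1_macro,
        accuracy=accuracy,
        counts=counts,
        degenerate=tuple(degenerate),
    )


def confusion_from_predictions(
    y_true: Sequence[int], y_pred: Sequence[int], stratum: str = "aggregate"
) -> ConfusionCounts:
    """Count TP/FP/FN/TN from parallel 0/1 label arrays (1 = related)."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("y_true and y_pred must have the same length")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        stratum=stratum,
    )


@dataclass
class KFoldResult:
    """Per-fold test metrics, holdout metrics, and summary statistics."""

    fold_reports: list[MetricsReport]
    holdout_reports: list[MetricsReport]
    models: list[TrainedClassifier]

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, reports in (("fold", self.fold_reports), ("holdout", self.holdout_reports)):
            for metric in ("precision", "recall", "f1", "f1_macro", "accuracy"):
                vals = np.array([getattr(r, metric) for r in reports])
                rows.append(
                    {"set": name, "metric": metric,
                     "mean": float(vals.mean()), "sd": float(vals.std(ddof=1)) if len(vals) > 1 else 0.0}
                )
        return pd.DataFrame(rows)

    def mean(self, metric: str, which: str = "fold") -> float:
        reports = self.fold_reports if which == "fold" else self.holdout_reports
        return float(np.mean([getattr(r, metric) for r in reports]))


def _evaluate_model(model: TrainedClassifier, dataset) -> MetricsReport:
    seqs = [s for s, _ in dataset]
    y_true = [y for _, y in dataset]
    probs = predict_proba_batch(model, seqs)
    y_pred = (probs >= 0.5).astype(int)
    return compute_metrics(confusion_from_predictions(y_true, y_pred))


def kfold_evaluate(
    config: ClassifierConfig,
    corpus: Sequence[tuple[Sequence[int], int]],
    plan: SplitPlan,
    vocab_size: Optional[int] = None,
) -> KFoldResult:
    """Run the nested K-fold experiment for one configuration.

    For each fold: train on the other K-1 folds (the fixed holdout serves
    as the per-epoch validation set), evaluate on the held-out fold, and
    also score the fold-model on the holdout.  Returns K reports of each
    kind plus the trained models.
    """
    if plan.n != len(corpus):
        raise ValueError(f"plan covers {plan.n} indices but corpus has {len(corpus)}")
    holdout = [corpus[i] for i in plan.holdout_indices]
    fold_reports, holdout_reports, models = [], [], []
    for j in range(len(plan.folds)):
        train_data = [corpus[i] for i in plan.training_indices(j)]
        test_data = [corpus[i] for i in plan.folds[j]]
        model = train(config, train_data, holdout, vocab_size=vocab_size)
        fold_reports.append(_evaluate_model(model, test_data))
        holdout_reports.append(_evaluate_model(model, holdout))
        models.append(model)
    return KFoldResult(fold_reports=fold_reports, holdout_reports=holdout_reports, models=models)


def grid_search(
    grid: Sequence[ClassifierConfig],
    corpus: Sequence[tuple[Sequence[int], int]],
    plan: SplitPlan,
    vocab_size: Optional[int] = None,
) -> tuple[pd.DataFrame, ClassifierConfig]:
    """Evaluate every grid configuration and rank them.

    Ranking: mean fold F1 descending, ties broken by mean fold accuracy
    descending, then by smaller hidden layer.  Returns the full result
    table and the winning configuration.
    """
    if not grid:
        raise ValueError("grid must be nonempty")
    rows = []
    for config in grid:
        result = kfold_evaluate(config, corpus, plan, vocab_size=vocab_size)
        rows.append(
            {
                **config.to_dict(),
                "mean_f1": result.mean("f1"),
                "mean_accuracy": result.mean("accuracy"),
                "mean_f1_macro": result.mean("f1_macro"),
                "mean_precision": result.mean("precision"),
                "mean_recall": result.mean("recall"),
            }
        )
    ranked = sorted(
        range(len(grid)),
        key=lambda i: (-rows[i]["mean_f1"], -rows[i]["mean_accuracy"], grid[i].hidden_size),
    )
    table = pd.DataFrame([rows[i] for i in ranked]).reset_index(drop=True)
    return table, grid[ranked[0]]
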