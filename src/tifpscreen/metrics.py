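"""Classification and virtual-screening metrics.

Recall, precision, TPR, FPR and accuracy follow the standard confusion-
count definitions; ROC-AUC and PRC-AUC (average precision) delegate to
scikit-learn; the enrichment factor at a screened fraction is implemented
here in both common conventions (hit-rate ratio, the default, and recall
ratio).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

__all__ = [
    "UndefinedMetricError",
    "ConfusionCounts",
    "MetricsRecord",
    "confusion_counts",
    "basic_metrics",
    "roc_auc",
    "prc_auc",
    "enrichment_factor",
    "evaluate_scores",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero for the given counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    n_tp: int
    n_fp: int
    n_tn: int
    n_fn: int

    def __post_init__(self) -> None:
        for f, v in asdict(self).items():
            if v < 0 or v != int(v):
                raise ValueError(f"{f} must be a non-negative integer")

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fp + self.n_tn + self.n_fn


@dataclass
class MetricsRecord:
    """One evaluation: threshold metrics plus ranking metrics."""

    recall: float
    precision: float
    accuracy: float
    tpr: float
    fpr: float
    roc_auc: float
    prc_auc: float
    ef: Optional[float] = None
    ef_fraction: Optional[float] = None


def _binary(arr, name: str) -> np.ndarray:
    a = np.asarray(arr)
    if a.ndim != 1 or a.size == 0:
        raise ValueError(f"{name} must be a non-empty 1-D array")
    vals = np.unique(a)
    if not np.all(np.isin(vals, [0, 1])):
        raise ValueError(f"{name} must be binary 0/1")
    return a.astype(int)


def confusion_counts(labels: Sequence[int], predictions: Sequence[int]) -> ConfusionCounts:
    """Exact four-way tally of binary labels against binary predictions."""
    y = _binary(labels, "labels")
    p = _binary(predictions, "predictions")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} labels vs {len(p)} predictions")
    return ConfusionCounts(
        n_tp=int(np.sum((y == 1) & (p == 1))),
        n_fp=int(np.sum((y == 0) & (p == 1))),
        n_tn=int(np.sum((y == 0) & (p == 0))),
        n_fn=int(np.sum((y == 1) & (p == 0))),
    )


def basic_metrics(c: ConfusionCounts) -> dict[str, float]:
    """recall = TP/(TP+FN), precision = TP/(TP+FP), tpr = recall,
    fpr = FP/(FP+TN), accuracy = (TP+TN)/total.

    A zero denominator raises :class:`UndefinedMetricError` rather than
    silently returning 0.
    """
    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            raise UndefinedMetricError(f"{name} undefined: zero denominator")
        return num / den

    recall = ratio(c.n_tp, c.n_tp + c.n_fn, "recall")
    return {
        "recall": recall,
        "precision": ratio(c.n_tp, c.n_tp + c.n_fp, "precision"),
        "tpr": recall,
        "fpr": ratio(c.n_fp, c.n_fp + c.n_tn, "fpr"),
        "accuracy": ratio(c.n_tp + c.n_tn, c.total, "accuracy"),
    }


def _check_scores(scores, labels):
    s = np.asarray(scores, dtype=float)
    y = _binary(labels, "labels")
    if len(s) != len(y):
        raise ValueError("scores and labels must have equal length")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    return s, y


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Probability that a random positive outranks a random negative
    (ties credited 1/2); requires both classes present."""
    s, y = _check_scores(scores, labels)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC-AUC requires both classes in the labels")
    return float(roc_auc_score(y, s))


def prc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Average precision (step-wise PR-curve summation); requires >= 1 positive."""
    s, y = _check_scores(scores, labels)
    if y.sum() == 0:
        raise ValueError("PRC-AUC requires at least one positive label")
    return float(average_precision_score(y, s))


def enrichment_factor(
    scores: Sequence[float],
    labels: Sequence[int],
    fraction: float = 0.05,
    convention: str = "hit_rate",
) -> float:
    """Enrichment factor at a screened fraction of the ranked list.

    The top set holds ceil(fraction * N) molecules by descending score
    (stable sort: ties keep input order).  ``hit_rate`` (default) returns
    (hits/top) / (actives/N); ``recall`` returns (hits/actives) / fraction.
    """
    s, y = _check_scores(scores, labels)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    n_pos = int(y.sum())
    if n_pos == 0:
        raise ValueError("enrichment factor requires at least one active")
    n = len(s)
    top = math.ceil(fraction * n)
    order = np.argsort(-s, kind="stable")
    hits = int(y[order[:top]].sum())
    if convention == "hit_rate":
        return (hits / top) / (n_pos / n)
    if convention == "recall":
        return (hits / n_pos) / fraction
    raise ValueError(f"unknown EF convention {convention!r}")


def evaluate_scores(
    scores: Sequence[float],
    labels: Sequence[int],
    threshold: float = 0.5,
    ef_fraction: float = 0.05,
) -> MetricsRecord:
    """Full evaluation of one score vector at a decision threshold."""
    s, y = _check_scores(scores, labels)
    preds = (s >= threshold).astype(int)
    c = confusion_counts(y, preds)
    basics = {}
    pairs = {
        "recall": (c.n_tp, c.n_tp + c.n_fn),
        "precision": (c.n_tp, c.n_tp + c.n_fp),
        "fpr": (c.n_fp, c.n_fp + c.n_tn),
        "accuracy": (c.n_tp + c.n_tn, c.total),
    }
    for name, (num, den) in pairs.items():
        basics[name] = num / den if den else float("nan")
    basics["tpr"] = basics["recall"]
    return MetricsRecord(
        recall=basics["recall"],
        precision=basics["precision"],
        accuracy=basics["accuracy"],
        tpr=basics["tpr"],
        fpr=basics["fpr"],
        roc_auc=roc_auc(s, y),
        prc_auc=prc_auc(s, y),
        ef=enrichment_factor(s, y, ef_fraction),
        ef_fraction=ef_fraction,
    )
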