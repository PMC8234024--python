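"""Confusion-matrix metrics and ROC/AUC.

AUC is the headline criterion: interaction data are heavily imbalanced, so
threshold-bound metrics (accuracy, precision, recall, F1) are reported but are
secondary.  The ROC is built by sweeping a threshold over the distinct score
values; tied scores collapse into a single step (a diagonal ROC segment), which
makes the trapezoidal area identical to the tie-adjusted Mann-Whitney statistic
U / (n_pos * n_neg).

Metrics with a 0/0 denominator are reported as None ("undefined"), never
silently as 0.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np


def _as_scores_labels(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError(f"scores {s.shape} and labels {y.shape} must be equal-length vectors")
    if not np.isin(y, (-1, 1)).all():
        raise ValueError("labels must be +/-1")
    return s, y.astype(int)


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_counts(scores, labels, threshold: float = 0.0) -> ConfusionCounts:
    """Tally the confusion matrix with 'predicted positive' meaning score > threshold."""
    s, y = _as_scores_labels(scores, labels)
    pred = s > threshold
    pos = y == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        tn=int((~pred & ~pos).sum()),
        fp=int((pred & ~pos).sum()),
        fn=int((~pred & pos).sum()),
    )


@dataclasses.dataclass
class Metrics:
    accuracy: float
    precision: float | None
    recall: float | None
    f1: float | None


def basic_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy, precision, recall and F1; any 0/0 is reported as None."""
    if c.total == 0:
        raise ValueError("no evaluated pairs: metrics undefined")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else None
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) > 0 else None
    if precision is None or recall is None or precision + recall == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return Metrics(accuracy, precision, recall, f1)


@dataclasses.dataclass
class RocCurve:
    """Threshold sweep of (FPR, TPR), from (0,0) to (1,1), plus trapezoidal AUC."""

    thresholds: np.ndarray  # one per curve point after (0,0); descending
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_curve(scores, labels) -> RocCurve:
    s, y = _as_scores_labels(scores, labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == -1).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("ROC needs at least one positive and one negative label")
    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    pos_sorted = (y[order] == 1).astype(float)
    tps = np.cumsum(pos_sorted)
    fps = np.cumsum(1.0 - pos_sorted)
    # keep only the last index of each tie group (distinct thresholds)
    distinct = np.r_[np.diff(s_sorted) != 0, True]
    thresholds = s_sorted[distinct]
    tpr = np.r_[0.0, tps[distinct] / n_pos]
    fpr = np.r_[0.0, fps[distinct] / n_neg]
    area = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds, fpr, tpr, area)


def auc(scores, labels) -> float:
    """Area under the ROC curve; equals the tie-adjusted probability that a
    random positive outscores a random negative."""
    return roc_curve(scores, labels).auc


def write_metrics_json(m: Metrics, c: ConfusionCounts, auc_value: float, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "accuracy": m.accuracy,
                "precision": m.precision,
                "recall": m.recall,
                "f1": m.f1,
                "auc": auc_value,
                "counts": {"tp": c.tp, "tn": c.tn, "fp": c.fp, "fn": c.fn},
            },
            fh,
            indent=2,
        )


def write_roc_tsv(curve: RocCurve, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("threshold\tfpr\ttpr\n")
        fh.write(f"inf\t{curve.fpr[0]:.10g}\t{curve.tpr[0]:.10g}\n")
        for th, f, t in zip(curve.thresholds, curve.fpr[1:], curve.tpr[1:]):
            fh.write(f"{th:.10g}\t{f:.10g}\t{t:.10g}\n")
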