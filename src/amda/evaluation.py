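"""Confusion-matrix metrics, ROC construction and trapezoid AUC."""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .eeg_io import ValidationError

__all__ = [
    "EvalReport",
    "UndefinedMetricError",
    "confusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "roc_and_auc",
    "evaluate",
]


class UndefinedMetricError(ZeroDivisionError):
    """A metric's denominator is zero (degenerate class composition)."""


def confusion(labels, predictions) -> tuple[int, int, int, int]:
    """(TP, TN, FP, FN) counts; inputs are equal-length binary vectors."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    if labels.shape != predictions.shape:
        raise ValidationError(f"length mismatch: {labels.shape} vs {predictions.shape}")
    if not (np.isin(labels, (0, 1)).all() and np.isin(predictions, (0, 1)).all()):
        raise ValidationError("labels and predictions must be binary")
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return tp, tn, fp, fn


def accuracy(tp: int, tn: int, fp: int, fn: int) -> float:
    total = tp + tn + fp + fn
    if total == 0:
        raise UndefinedMetricError("accuracy undefined on empty sample")
    return (tp + tn) / total


def sensitivity(tp: int, fn: int) -> float:
    if tp + fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positive samples")
    return tp / (tp + fn)


def specificity(tn: int, fp: int) -> float:
    if tn + fp == 0:
        raise UndefinedMetricError("specificity undefined: no negative samples")
    return tn / (tn + fp)


def roc_and_auc(labels, scores) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoid AUC.

    Thresholds sweep the unique scores in descending order (tied scores
    collapse into a single step), with (0,0) prepended and (1,1) at the
    end. AUC = 1/2 * sum (x_{i+1} - x_i)(y_i + y_{i+1}), which lies in
    [0, 1] (0.5 for an uninformative scorer).
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=np.float64)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    pos = int(np.sum(labels == 1))
    neg = int(np.sum(labels == 0))
    if pos == 0 or neg == 0:
        raise UndefinedMetricError("ROC undefined: both classes must be present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    cum_tp = np.cumsum(sorted_labels == 1)
    cum_fp = np.cumsum(sorted_labels == 0)
    # keep only the last index of each tied-score group
    boundary = np.flatnonzero(np.diff(sorted_scores) != 0)
    keep = np.concatenate([boundary, [len(sorted_scores) - 1]])
    xs = np.concatenate([[0.0], cum_fp[keep] / neg])
    ys = np.concatenate([[0.0], cum_tp[keep] / pos])
    if xs[-1] != 1.0 or ys[-1] != 1.0:  # pragma: no cover - always ends at (1,1)
        xs = np.append(xs, 1.0)
        ys = np.append(ys, 1.0)
    auc = 0.5 * float(np.sum((xs[1:] - xs[:-1]) * (ys[1:] + ys[:-1])))
    return list(zip(xs.tolist(), ys.tolist())), auc


@dataclass
class EvalReport:
    tp: int
    tn: int
    fp: int
    fn: int
    acc: float
    sen: float
    spe: float
    roc: list[tuple[float, float]] = field(repr=False)
    auc: float = 0.0

    def to_dict(self) -> dict:
        return {
            "TP": self.tp, "TN": self.tn, "FP": self.fp, "FN": self.fn,
            "ACC": self.acc, "SEN": self.sen, "SPE": self.spe, "AUC": self.auc,
        }

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def save_roc_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("FPR,TPR\n")
            for x, y in self.roc:
                fh.write(f"{x:.9g},{y:.9g}\n")

    def plot_roc(self, path) -> None:  # pragma: no cover - optional artifact
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        xs, ys = zip(*self.roc)
        fig, ax = plt.subplots()
        ax.plot(xs, ys, marker=".", label=f"AUC = {self.auc:.4f}")
        ax.plot([0, 1], [0, 1], "--", color="gray")
        ax.set_xlabel("FPR")
        ax.set_ylabel("TPR")
        ax.legend()
        fig.savefig(path, dpi=120)
        plt.close(fig)


def evaluate(labels, scores, threshold: float = 0.5) -> EvalReport:
    """Full per-window report from true labels and predicted scores."""
    labels = np.asarray(np.rint(labels), dtype=int)
    scores = np.asarray(scores, dtype=np.float64)
    preds = (scores >= threshold).astype(int)
    tp, tn, fp, fn = confusion(labels, preds)
    roc, auc = roc_and_auc(labels, scores)
    return EvalReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        acc=accuracy(tp, tn, fp, fn),
        sen=sensitivity(tp, fn),
        spe=specificity(tn, fp),
        roc=roc,
        auc=auc,
    )
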