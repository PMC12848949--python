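"""Evaluation metrics for multi-class edge classification.

Five standard metrics: accuracy, macro-F1, macro one-vs-rest AUROC, macro
one-vs-rest AUPR and the Matthews correlation coefficient. The multi-class
MCC is the standard multi-category correlation generalization, which
reduces exactly to the familiar binary confusion-matrix formula at C=2.
The ROC area is computed rank-based (Mann-Whitney with tie correction);
the PR area by step-wise summation over distinct score thresholds, which
avoids the optimistic trapezoidal interpolation.

All routines are implemented directly from the confusion counts / score
rankings so they can be verified against brute-force enumeration oracles.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "accuracy",
    "macro_f1",
    "mcc",
    "auroc_macro",
    "aupr_macro",
    "evaluate_predictions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """C x C matrix of (true class, predicted class) counts."""

    matrix: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.int64)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("confusion matrix must be square")
        if (m < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def total(self) -> int:
        return int(self.matrix.sum())

    @property
    def n_classes(self) -> int:
        return self.matrix.shape[0]

    def per_class(self) -> dict:
        """Per-class TP, FP, FN, TN vectors."""
        m = self.matrix
        tp = np.diag(m)
        fp = m.sum(axis=0) - tp
        fn = m.sum(axis=1) - tp
        tn = m.sum() - tp - fp - fn
        return {"tp": tp, "fp": fp, "fn": fn, "tn": tn}


def confusion_counts(labels, predictions, n_classes: int | None = None) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if labels.shape != predictions.shape:
        raise ValueError("labels and predictions must align")
    if n_classes is None:
        n_classes = int(max(labels.max(), predictions.max())) + 1
    m = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(m, (labels, predictions), 1)
    return ConfusionCounts(m)


def accuracy(cm: ConfusionCounts) -> float:
    """Fraction of instances on the confusion-matrix diagonal."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.matrix) / cm.total)


def macro_f1(cm: ConfusionCounts) -> float:
    """Unweighted mean over classes of 2PR/(P+R); 0 where P+R = 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    pc = cm.per_class()
    tp, fp, fn = pc["tp"].astype(float), pc["fp"].astype(float), pc["fn"].astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    return float(f1.mean())


def mcc(labels, predictions) -> float:
    """Matthews correlation coefficient; multi-category generalization.

    Returns 0 when any denominator factor vanishes. Raises if the true
    labels contain a single class (the coefficient is undefined there).
    """
    labels = np.asarray(labels, dtype=np.int64)
    predictions = np.asarray(predictions, dtype=np.int64)
    if len(np.unique(labels)) < 2:
        raise ValueError("MCC undefined: labels contain a single class")
    cm = confusion_counts(labels, predictions).matrix.astype(float)
    t = cm.sum(axis=1)   # true-class totals
    p = cm.sum(axis=0)   # predicted-class totals
    s = cm.sum()
    c = np.trace(cm)
    numer = c * s - (t * p).sum()
    denom = np.sqrt(s**2 - (p * p).sum()) * np.sqrt(s**2 - (t * t).sum())
    if denom == 0:
        return 0.0
    return float(numer / denom)


def _binary_auroc(scores: np.ndarray, y: np.ndarray) -> float:
    """Rank-based AUROC = (concordant + 0.5*ties) / (n_pos * n_neg)."""
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    r = rankdata(scores)
    return float((r[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _binary_aupr(scores: np.ndarray, y: np.ndarray) -> float:
    """Step-wise PR area: sum over thresholds of (dRecall * Precision)."""
    order = np.argsort(-scores, kind="stable")
    scores, y = scores[order], y[order]
    n_pos = int(y.sum())
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at the last index of each distinct score (threshold points)
    distinct = np.r_[scores[1:] != scores[:-1], True]
    tp_t, fp_t = tp[distinct], fp[distinct]
    prec = tp_t / (tp_t + fp_t)
    rec = tp_t / n_pos
    d_rec = np.diff(np.r_[0.0, rec])
    return float((d_rec * prec).sum())


def _macro_ovr(scores, labels, binary_fn) -> float:
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    if scores.ndim != 2 or scores.shape[0] != len(labels):
        raise ValueError("scores must be (n, C) aligned with labels")
    present = np.unique(labels)
    if len(present) < 2:
        raise ValueError("need at least two classes present in labels")
    n_classes = scores.shape[1]
    skipped = [c for c in range(n_classes) if c not in present]
    if skipped:
        warnings.warn(f"classes absent from labels skipped: {skipped}",
                      stacklevel=3)
    vals = [binary_fn(scores[:, c], (labels == c).astype(np.int64))
            for c in present]
    return float(np.mean(vals))


def auroc_macro(scores, labels) -> float:
    """Macro-averaged one-vs-rest area under the ROC curve."""
    return _macro_ovr(scores, labels, _binary_auroc)


def aupr_macro(scores, labels) -> float:
    """Macro-averaged one-vs-rest area under the precision-recall curve."""
    return _macro_ovr(scores, labels, _binary_aupr)


@dataclass
class MetricsReport:
    """The five-metric bundle with per-class breakdowns."""

    acc: float
    macro_f1: float
    auroc: float
    aupr: float
    mcc: float
    n_evaluated: int
    per_class: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "acc": self.acc, "macro_f1": self.macro_f1, "auroc": self.auroc,
            "aupr": self.aupr, "mcc": self.mcc, "n_evaluated": self.n_evaluated,
            "per_class": self.per_class,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def evaluate_predictions(probs, labels) -> MetricsReport:
    """Full report from predicted class distributions and true labels."""
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.int64)
    preds = probs.argmax(axis=1)
    cm = confusion_counts(labels, preds, n_classes=probs.shape[1])
    pc = cm.per_class()
    tp, fp, fn = (pc[k].astype(float) for k in ("tp", "fp", "fn"))
    with np.errstate(divide="ignore", invalid="ignore"):
        prec = np.where(tp + fp > 0, tp / (tp + fp), 0.0)
        rec = np.where(tp + fn > 0, tp / (tp + fn), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / (prec + rec), 0.0)
    per_class = {
        str(c): {"precision": float(prec[c]), "recall": float(rec[c]),
                 "f1": float(f1[c])}
        for c in range(probs.shape[1])
    }
    return MetricsReport(
        acc=accuracy(cm),
        macro_f1=macro_f1(cm),
        auroc=auroc_macro(probs, labels),
        aupr=aupr_macro(probs, labels),
        mcc=mcc(labels, preds),
        n_evaluated=len(labels),
        per_class=per_class,
    )
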