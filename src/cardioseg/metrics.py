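"""Segmentation and classification metrics.

Confusion counts are computed for a chosen positive class; accuracy,
sensitivity (true-positive rate) and specificity (true-negative rate)
follow the usual closed forms.  Dice overlap is available per binary mask
or macro-averaged over the classes present in either mask.  ROC curves are
threshold sweeps over a positive-class score, with AUC as the trapezoidal
area (equivalently the Mann-Whitney pairwise statistic).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imaging import LabelMask


class UndefinedMetricError(ValueError):
    """The metric's denominator is empty for these counts."""


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _classes_of(mask) -> np.ndarray:
    return mask.classes if isinstance(mask, LabelMask) else np.asarray(mask)


def confusion(pred, truth, positive_class: int) -> ConfusionCounts:
    """Pixelwise confusion counts for one positive class."""
    p, t = _classes_of(pred), _classes_of(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    pp, tp_ = p == positive_class, t == positive_class
    return ConfusionCounts(
        tp=int(np.sum(pp & tp_)),
        tn=int(np.sum(~pp & ~tp_)),
        fp=int(np.sum(pp & ~tp_)),
        fn=int(np.sum(~pp & tp_)),
    )


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise UndefinedMetricError("accuracy undefined for zero counts")
    return (c.tp + c.tn) / c.total


def sensitivity(c: ConfusionCounts) -> float:
    if c.tp + c.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no positives")
    return c.tp / (c.tp + c.fn)


def specificity(c: ConfusionCounts) -> float:
    if c.tn + c.fp == 0:
        raise UndefinedMetricError("specificity undefined: no negatives")
    return c.tn / (c.fp + c.tn)


def _binary_dice(p: np.ndarray, t: np.ndarray) -> float:
    inter = int(np.sum(p & t))
    size = int(np.sum(p)) + int(np.sum(t))
    # both masks empty: both correctly predict "nothing"
    return 1.0 if size == 0 else 2.0 * inter / size


def dice(pred, truth, mode: str = "binary") -> float:
    """Dice overlap 2|P∩L|/(|P|+|L|).

    ``binary`` scores the class-1 pixel sets of two-class masks; ``macro``
    averages the per-class binary Dice over every class present in either
    mask.  Empty-vs-empty is defined as 1.0.
    """
    p, t = _classes_of(pred), _classes_of(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {t.shape}")
    if mode == "binary":
        for m in (pred, truth):
            if isinstance(m, LabelMask) and m.n_classes != 2:
                raise ValueError("binary Dice requires two-class masks")
        return _binary_dice(p == 1, t == 1)
    if mode == "macro":
        present = np.union1d(np.unique(p), np.unique(t))
        return float(
            np.mean([_binary_dice(p == c, t == c) for c in present])
        )
    raise ValueError(f"mode must be 'binary' or 'macro', got {mode!r}")


@dataclass(frozen=True)
class RocCurve:
    """Threshold-sweep ROC: (FPR, TPR) points ordered from (0,0) to (1,1)."""

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.fpr, self.tpr])

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.thresholds}
        ).to_csv(path, index=False)


def roc_curve(scores, labels) -> RocCurve:
    """Sweep every unique score as a threshold; ties share a threshold."""
    from sklearn.metrics import roc_curve as _sk_roc

    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if labels.min() == labels.max():
        raise ValueError("ROC requires at least one positive and one negative")
    fpr, tpr, thr = _sk_roc(labels, scores, drop_intermediate=False)
    return RocCurve(fpr, tpr, thr)


def auc(curve: RocCurve) -> float:
    """Trapezoidal area under the (FPR, TPR) polyline."""
    return float(np.trapezoid(curve.tpr, curve.fpr))
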