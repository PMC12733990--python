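"""Segmentation and classification evaluation metrics.

Segmentation: per-class Dice, HD95 (95th percentile of pooled symmetric
surface distances, spacing-aware, mm) and boundary IoU on 1-voxel bands.
Classes absent from both masks score Dice 1 / HD95 0 / bIoU 1; classes
absent from exactly one side score Dice 0 / bIoU 0 with HD95 undefined
(NaN), and summary means are NaN-aware.

Classification: accuracy, per-class precision/recall/F1 (zero-division
convention 0), one-vs-rest AUC by the rank statistic, confusion matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn import metrics as skm

from .clsnet import CLS_CLASSES, DirichletPrediction

__all__ = ["SegClassMetrics", "EvalReport", "seg_metrics", "cls_metrics", "hd95",
           "boundary_iou", "dice_coefficient"]


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def _surface(mask: np.ndarray) -> np.ndarray:
    """Region voxels with a 6-neighbour outside (volume border counts)."""
    m = mask.astype(bool)
    if not m.any():
        return np.empty((0, 3), dtype=int)
    eroded = ndimage.binary_erosion(m)  # border_value=0: edges erode away
    return np.argwhere(m & ~eroded)


def hd95(a: np.ndarray, b: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """95th percentile of the pooled two-way surface distances in mm."""
    sa = _surface(a)
    sb = _surface(b)
    if len(sa) == 0 and len(sb) == 0:
        return 0.0
    if len(sa) == 0 or len(sb) == 0:
        return float("nan")
    sp = np.asarray(spacing, dtype=float)
    pa = sa * sp
    pb = sb * sp
    d_ab = cKDTree(pb).query(pa)[0]
    d_ba = cKDTree(pa).query(pb)[0]
    return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))


def boundary_iou(a: np.ndarray, b: np.ndarray) -> float:
    """IoU of the 1-voxel-dilated boundary bands of the two regions."""
    a = a.astype(bool)
    b = b.astype(bool)
    if not a.any() and not b.any():
        return 1.0
    struct = np.ones((3, 3, 3), dtype=bool)

    def band(m):
        if not m.any():
            return np.zeros_like(m)
        surf = m & ~ndimage.binary_erosion(m)
        return ndimage.binary_dilation(surf, structure=struct)

    ba, bb = band(a), band(b)
    union = int((ba | bb).sum())
    if union == 0:
        return 1.0
    return int((ba & bb).sum()) / union


@dataclass
class SegClassMetrics:
    dice: float
    hd95_mm: float
    boundary_iou: float


def seg_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray,
                spacing=(1.0, 1.0, 1.0)) -> dict[int, SegClassMetrics]:
    """Per-class metrics over the four foreground labels {1, 2, 3, 4}."""
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("masks must be aligned")
    out = {}
    for c in range(1, 5):
        p = pred_mask == c
        g = gt_mask == c
        if not p.any() and not g.any():
            out[c] = SegClassMetrics(1.0, 0.0, 1.0)
            continue
        out[c] = SegClassMetrics(
            dice_coefficient(p, g), hd95(p, g, spacing), boundary_iou(p, g)
        )
    return out


def mean_foreground_dice(per_class: dict[int, SegClassMetrics]) -> float:
    return float(np.mean([m.dice for m in per_class.values()]))


@dataclass
class EvalReport:
    accuracy: float
    precision: dict[str, float]
    recall: dict[str, float]
    f1: dict[str, float]
    support: dict[str, int]
    auc: dict[str, float | None]
    confusion: np.ndarray  # rows = true class, columns = predicted

    def __post_init__(self):
        n = int(self.confusion.sum())
        row_sums = self.confusion.sum(axis=1)
        for i, cls in enumerate(CLS_CLASSES):
            if row_sums[i] != self.support.get(cls, 0):
                raise ValueError("confusion-matrix rows must equal class supports")
        if not 0.0 <= self.accuracy <= 1.0:
            raise ValueError("accuracy out of range")


def cls_metrics(predictions, labels) -> EvalReport:
    """Evaluate ROI classifications.

    ``predictions``: DirichletPrediction list, or an (N, 4) probability /
    concentration array.  ``labels``: integer class indices.
    """
    labels = np.asarray(labels, dtype=int)
    if len(labels) == 0:
        raise ValueError("need at least one prediction")
    if len(predictions) and isinstance(predictions[0], DirichletPrediction):
        scores = np.stack([p.expected_probs for p in predictions])
    else:
        scores = np.asarray(predictions, dtype=float)
        scores = scores / scores.sum(axis=1, keepdims=True)
    pred = scores.argmax(axis=1)
    k = len(CLS_CLASSES)
    acc = float((pred == labels).mean())
    prec, rec, f1, supp = skm.precision_recall_fscore_support(
        labels, pred, labels=range(k), zero_division=0
    )
    auc = {}
    for i, cls in enumerate(CLS_CLASSES):
        mask = labels == i
        if mask.all() or not mask.any():
            auc[cls] = None  # one-vs-rest AUC undefined without both outcomes
        else:
            auc[cls] = float(skm.roc_auc_score(mask, scores[:, i]))
    conf = skm.confusion_matrix(labels, pred, labels=range(k))
    return EvalReport(
        accuracy=acc,
        precision={c: float(v) for c, v in zip(CLS_CLASSES, prec)},
        recall={c: float(v) for c, v in zip(CLS_CLASSES, rec)},
        f1={c: float(v) for c, v in zip(CLS_CLASSES, f1)},
        support={c: int(v) for c, v in zip(CLS_CLASSES, supp)},
        auc=auc,
        confusion=conf,
    )
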