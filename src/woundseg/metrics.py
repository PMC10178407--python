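"""Pixel-level segmentation evaluation.

Confusion counts, recall, dice, IoU, mean IoU over classes, per-image average
precision (the all-thresholds step rule) averaged into mAP, and pooled
pixel-level ROC/AUC.  Metrics whose denominator is empty are *missing*
(returned as ``None``), never silently zero.

Dice is the harmonic mean of pixel precision and recall, equivalently
``2TP / (2TP + FP + FN)``; IoU is ``TP / (TP + FP + FN)``; the two are linked
by ``dice = 2·iou / (1 + iou)``.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion",
    "recall",
    "precision",
    "dice",
    "iou",
    "miou",
    "average_precision",
    "map_over_set",
    "roc_curve",
    "roc_auc",
    "evaluate_set",
    "measure_throughput",
]


def _check_binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    uniq = np.unique(arr)
    if not np.isin(uniq, (0, 1)).all():
        raise ValueError(f"{name} must be binary (0/1); got values {uniq[:8]}")
    return arr.astype(bool)


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def table(self) -> np.ndarray:
        """2x2 table p[i, j] = count of true-class-i pixels predicted as j
        (class 0 = background, class 1 = wound)."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]], dtype=np.int64)


def confusion(pred_mask, gt_mask) -> ConfusionCounts:
    pred = _check_binary(pred_mask, "pred_mask")
    gt = _check_binary(gt_mask, "gt_mask")
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    tn = int(np.count_nonzero(~pred & ~gt))
    return ConfusionCounts(tp, fp, fn, tn)


def recall(counts: ConfusionCounts) -> float | None:
    if counts.tp + counts.fn == 0:
        return None
    return counts.tp / (counts.tp + counts.fn)


def precision(counts: ConfusionCounts) -> float | None:
    if counts.tp + counts.fp == 0:
        return None
    return counts.tp / (counts.tp + counts.fp)


def dice(counts: ConfusionCounts) -> float | None:
    denom = 2 * counts.tp + counts.fp + counts.fn
    if denom == 0:
        return None
    return 2 * counts.tp / denom


def iou(counts: ConfusionCounts) -> float | None:
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        return None
    return counts.tp / denom


def miou(table: np.ndarray) -> float:
    """Mean per-class IoU from a (k+1)x(k+1) table p[i, j] of true-class-i
    pixels predicted as class j.  Classes absent from both prediction and
    truth (zero union) are excluded from the mean with a warning."""
    p = np.asarray(table, dtype=np.float64)
    if p.ndim != 2 or p.shape[0] != p.shape[1] or p.shape[0] < 2:
        raise ValueError("expected a square table with at least 2 classes")
    ious = []
    for i in range(p.shape[0]):
        union = p[i, :].sum() + p[:, i].sum() - p[i, i]
        if union == 0:
            warnings.warn(f"class {i} absent from prediction and truth; excluded from mIoU")
            continue
        ious.append(p[i, i] / union)
    if not ious:
        raise ValueError("no class has a non-empty union")
    return float(np.mean(ious))


def average_precision(prob_map, gt_mask) -> float | None:
    """Pixelwise average precision: the area under the precision–recall curve
    swept over every distinct threshold (step interpolation)."""
    gt = _check_binary(gt_mask, "gt_mask").ravel()
    scores = np.asarray(prob_map, dtype=np.float64).ravel()
    if scores.shape != gt.shape:
        raise ValueError("prob_map and gt_mask differ in size")
    n_pos = int(gt.sum())
    if n_pos == 0:
        return None
    order = np.argsort(-scores, kind="stable")
    sorted_gt = gt[order]
    sorted_scores = scores[order]
    tp_cum = np.cumsum(sorted_gt)
    fp_cum = np.cumsum(~sorted_gt)
    # keep only the last entry of each tied-score run
    last = np.r_[sorted_scores[1:] != sorted_scores[:-1], True]
    tp_c, fp_c = tp_cum[last], fp_cum[last]
    prec = tp_c / (tp_c + fp_c)
    rec = tp_c / n_pos
    drec = np.diff(np.r_[0.0, rec])
    return float(np.sum(prec * drec))


def map_over_set(pairs) -> float:
    """Mean average precision over (prob_map, gt_mask) items; items with an
    empty ground truth are skipped with a warning."""
    aps = []
    for prob_map, gt_mask in pairs:
        ap = average_precision(prob_map, gt_mask)
        if ap is None:
            warnings.warn("item with empty ground truth skipped in mAP")
            continue
        aps.append(ap)
    if not aps:
        raise ValueError("no item with a non-empty ground truth")
    return float(np.mean(aps))


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """Pooled ROC points (fpr, tpr, threshold), thresholds descending."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    last = np.r_[s[1:] != s[:-1], True]
    tp = np.cumsum(y)[last]
    fp = np.cumsum(~y)[last]
    n_pos, n_neg = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    thr = np.r_[np.inf, s[last]]
    return fpr, tpr, thr


def roc_auc(prob_maps, gt_masks):
    """Pixel-pooled ROC over a set of images; AUC by the trapezoidal rule.

    Returns ``((fpr, tpr, thresholds), auc)``.
    """
    if isinstance(prob_maps, np.ndarray) and prob_maps.ndim == 2:
        prob_maps, gt_masks = [prob_maps], [gt_masks]
    scores = np.concatenate([np.asarray(p, dtype=np.float64).ravel() for p in prob_maps])
    labels = np.concatenate([_check_binary(g, "gt_mask").ravel() for g in gt_masks])
    if labels.all() or not labels.any():
        raise ValueError("ROC needs both classes among the pooled pixels")
    fpr, tpr, thr = roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thr), auc


@dataclass
class MetricsReport:
    """Aggregate evaluation over a set of (probability map, truth) pairs."""

    n_items: int
    map: float
    miou: float
    recall: float
    dice: float
    auc: float
    per_image: pd.DataFrame = field(repr=False)
    roc: tuple = field(repr=False, default=None)

    def to_json(self, path: str) -> None:
        payload = {
            "n_items": self.n_items,
            "mAP": self.map,
            "mIoU": self.miou,
            "recall": self.recall,
            "dice": self.dice,
            "AUC": self.auc,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def to_csv(self, path: str) -> None:
        self.per_image.to_csv(path, index=False)

    def roc_to_csv(self, path: str) -> None:
        fpr, tpr, thr = self.roc
        pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr}).to_csv(path, index=False)


def evaluate_set(prob_maps, gt_masks, threshold: float = 0.5) -> MetricsReport:
    """Full evaluation: per-image dice/IoU/recall/AP (mean over images is the
    primary aggregation) plus the pooled pixel ROC/AUC."""
    rows = []
    for i, (p, g) in enumerate(zip(prob_maps, gt_masks)):
        pred = (np.asarray(p) >= threshold).astype(np.uint8)
        c = confusion(pred, g)
        rows.append(
            {
                "item": i,
                "ap": average_precision(p, g),
                "iou": iou(c),
                "miou": miou(c.table()),
                "recall": recall(c),
                "dice": dice(c),
            }
        )
    df = pd.DataFrame(rows)
    roc, auc = roc_auc(list(prob_maps), list(gt_masks))
    return MetricsReport(
        n_items=len(df),
        map=float(df["ap"].dropna().mean()),
        miou=float(df["miou"].dropna().mean()),
        recall=float(df["recall"].dropna().mean()),
        dice=float(df["dice"].dropna().mean()),
        auc=auc,
        per_image=df,
        roc=roc,
    )


def measure_throughput(network, images, repeats: int = 1) -> float:
    """Diagnostic images/second over a timed loop (hardware dependent; not an
    evaluation surface)."""
    from .segnet import segment_image

    t0 = time.perf_counter()
    n = 0
    for _ in range(repeats):
        for img in images:
            segment_image(network, img)
            n += 1
    return n / (time.perf_counter() - t0)
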