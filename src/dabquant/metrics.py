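"""Evaluation metrics: pixel-level segmentation scores and per-class F1.

Segmentation quality is measured at pixel level on the binary union of
instances: precision = TP/(TP+FP), recall = TP/(TP+FN), F1 (Dice) and
IoU (Jaccard) = TP/(TP+FP+FN); Dice always dominates Jaccard.  Nucleus
classification is summarised by a 4x4 confusion matrix (rows = ground
truth; class order Strong, Moderate, Weak, Negative) and macro-F1, the
unweighted mean of the four one-vs-rest F1 values.  An instance-level
matched F1 (greedy IoU >= 0.5 matching) is provided separately for readers
who prefer object counts over pixel counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .classification import StainClass
from .errors import ParameterError, ShapeError
from .segmentation import InstanceMask

__all__ = [
    "PixelConfusion",
    "pixel_metrics",
    "class_confusion",
    "macro_f1",
    "matched_instance_f1",
    "match_instances",
]

_CLASS_ORDER = list(StainClass)


@dataclass(frozen=True)
class PixelConfusion:
    """Pixel-level TP/FP/FN counts between a predicted and a truth mask."""

    tp: int
    fp: int
    fn: int


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: 0/0 encountered, defining the value as 0", stacklevel=3)
        return 0.0
    return num / den


def pixel_metrics(pred_mask: np.ndarray, gt_mask: np.ndarray) -> tuple[float, float, float, float]:
    """(precision, recall, f1, iou) between two binary rasters.

    Any 0/0 (empty prediction or empty truth) is defined as 0 with a warning.
    """
    pred = np.asarray(pred_mask).astype(bool)
    gt = np.asarray(gt_mask).astype(bool)
    if pred.shape != gt.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    tp = int(np.count_nonzero(pred & gt))
    fp = int(np.count_nonzero(pred & ~gt))
    fn = int(np.count_nonzero(~pred & gt))
    precision = _safe_div(tp, tp + fp, "precision")
    recall = _safe_div(tp, tp + fn, "recall")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "f1")
    iou = _safe_div(tp, tp + fp + fn, "iou")
    return precision, recall, f1, iou


def class_confusion(
    pred_classes: Sequence[StainClass | str], gt_classes: Sequence[StainClass | str]
) -> np.ndarray:
    """4x4 confusion matrix; rows = ground truth, columns = prediction."""
    if len(pred_classes) != len(gt_classes):
        raise ParameterError("pred and gt class lists must have equal length")
    mat = np.zeros((4, 4), dtype=np.int64)
    for p, g in zip(pred_classes, gt_classes):
        mat[_CLASS_ORDER.index(StainClass(g)), _CLASS_ORDER.index(StainClass(p))] += 1
    return mat


def macro_f1(
    conf: np.ndarray, present_only: bool = False
) -> tuple[float, dict[StainClass, dict[str, float]]]:
    """Macro-F1 and per-class precision/recall/F1 from a confusion matrix.

    By default classes absent from both ground truth and prediction
    contribute F1 = 0 (with a warning), keeping the 4-class denominator
    fixed.  With ``present_only=True`` the mean runs over populated classes
    only.
    """
    conf = np.asarray(conf)
    if conf.shape != (4, 4):
        raise ParameterError(f"confusion matrix must be 4x4, got {conf.shape}")
    if conf.sum() == 0:
        raise ParameterError("confusion matrix is all-zero")
    per_class: dict[StainClass, dict[str, float]] = {}
    f1s: list[float] = []
    populated: list[bool] = []
    for c, cls in enumerate(_CLASS_ORDER):
        tp = float(conf[c, c])
        gt_tot = float(conf[c].sum())
        pred_tot = float(conf[:, c].sum())
        if gt_tot == 0 and pred_tot == 0:
            warnings.warn(
                f"class {cls.value} absent from both gt and prediction; F1 set to 0",
                stacklevel=2,
            )
            per_class[cls] = {"precision": 0.0, "recall": 0.0, "f1": 0.0}
            f1s.append(0.0)
            populated.append(False)
            continue
        precision = tp / pred_tot if pred_tot else 0.0
        recall = tp / gt_tot if gt_tot else 0.0
        f1 = 2 * tp / (pred_tot + gt_tot)
        per_class[cls] = {"precision": precision, "recall": recall, "f1": f1}
        f1s.append(f1)
        populated.append(True)
    if present_only:
        chosen = [f for f, keep in zip(f1s, populated) if keep]
    else:
        chosen = f1s
    return float(np.mean(chosen)), per_class


def match_instances(
    pred: InstanceMask, gt: InstanceMask, iou_threshold: float = 0.5
) -> list[tuple[int, int, float]]:
    """Greedy one-to-one instance matching by descending IoU.

    Returns (gt_id, pred_id, iou) for every accepted match with
    IoU >= ``iou_threshold``.
    """
    if pred.shape != gt.shape:
        raise ShapeError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    gt_ids = gt.ids
    pred_ids = pred.ids
    if gt_ids.size == 0 or pred_ids.size == 0:
        return []
    # joint histogram of (gt label, pred label) over pixels
    joint = (gt.labels.astype(np.int64) * (pred_ids.max() + 1)) + pred.labels
    counts = np.bincount(joint.ravel(), minlength=(gt_ids.max() + 1) * (pred_ids.max() + 1))
    counts = counts.reshape(gt_ids.max() + 1, pred_ids.max() + 1)
    gt_area = np.bincount(gt.labels.ravel(), minlength=gt_ids.max() + 1)
    pred_area = np.bincount(pred.labels.ravel(), minlength=pred_ids.max() + 1)

    candidates: list[tuple[float, int, int]] = []
    for g in gt_ids:
        for p in pred_ids:
            inter = counts[g, p]
            if inter == 0:
                continue
            union = gt_area[g] + pred_area[p] - inter
            iou = inter / union
            if iou >= iou_threshold:
                candidates.append((float(iou), int(g), int(p)))
    candidates.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g: set[int] = set()
    used_p: set[int] = set()
    matches: list[tuple[int, int, float]] = []
    for iou, g, p in candidates:
        if g in used_g or p in used_p:
            continue
        used_g.add(g)
        used_p.add(p)
        matches.append((g, p, iou))
    return matches


def matched_instance_f1(
    pred: InstanceMask, gt: InstanceMask, iou_threshold: float = 0.5
) -> tuple[float, float, float]:
    """Object-level (precision, recall, f1) from greedy IoU >= 0.5 matching."""
    matches = match_instances(pred, gt, iou_threshold)
    tp = len(matches)
    fp = pred.n_nuclei - tp
    fn = gt.n_nuclei - tp
    precision = _safe_div(tp, tp + fp, "instance precision")
    recall = _safe_div(tp, tp + fn, "instance recall")
    f1 = _safe_div(2 * precision * recall, precision + recall, "instance f1")
    return precision, recall, f1
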