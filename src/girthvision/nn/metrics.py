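"""Segmentation quality metrics: PA, MPA and MIOU (percent).

Computed from the confusion matrix of predicted vs reference class masks:
pixel accuracy is the trace over the total; mean pixel accuracy averages the
per-class recall; mean IoU averages intersection over union.  Classes absent
from both masks are excluded from the class means.
"""

from __future__ import annotations

import numpy as np

__all__ = ["confusion_matrix", "segmentation_metrics"]


def confusion_matrix(pred: np.ndarray, truth: np.ndarray, num_classes: int) -> np.ndarray:
    p = np.asarray(pred).ravel()
    t = np.asarray(truth).ravel()
    if np.asarray(pred).shape != np.asarray(truth).shape:
        raise ValueError("incompatible masks: shapes differ")
    if p.min() < 0 or p.max() >= num_classes or t.min() < 0 or t.max() >= num_classes:
        raise ValueError("mask values must lie in [0, num_classes)")
    return np.bincount(
        t.astype(np.int64) * num_classes + p.astype(np.int64),
        minlength=num_classes * num_classes,
    ).reshape(num_classes, num_classes)


def segmentation_metrics(pred: np.ndarray, truth: np.ndarray, num_classes: int):
    """Return (PA, MPA, MIOU) in percent for a pair of class-index masks."""
    cm = confusion_matrix(pred, truth, num_classes).astype(float)
    total = cm.sum()
    pa = 100.0 * np.trace(cm) / total

    truth_count = cm.sum(axis=1)
    pred_count = cm.sum(axis=0)
    present = (truth_count + pred_count) > 0
    tp = np.diag(cm)

    with np.errstate(invalid="ignore", divide="ignore"):
        per_class_acc = np.where(truth_count > 0, tp / truth_count, np.nan)
        union = truth_count + pred_count - tp
        iou = np.where(union > 0, tp / union, np.nan)

    # classes absent from the reference but present in the prediction have
    # zero recall / IoU; classes absent from both are excluded
    per_class_acc = np.where(present & np.isnan(per_class_acc), 0.0, per_class_acc)
    iou = np.where(present & np.isnan(iou), 0.0, iou)
    mpa = 100.0 * np.nanmean(np.where(present, per_class_acc, np.nan))
    miou = 100.0 * np.nanmean(np.where(present, iou, np.nan))
    return float(pa), float(mpa), float(miou)
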