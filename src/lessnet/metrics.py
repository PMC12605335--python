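"""Segmentation evaluation battery.

Region overlap (Dice, per-class IoU / mIoU), pixel agreement (mean recall
and two accuracy variants), boundary error (95th-percentile Hausdorff
distance), probability calibration (expected calibration error) and
per-pixel predictive entropy.

Conventions, applied consistently and checked against brute-force oracles
in the test suite:

* ``accuracy_eq8`` uses the printed form sum(TP_i) / sum(TP_i + FP_i +
  FN_i), in which every misclassified pixel appears once as FP and once as
  FN in the denominator; the standard trace/total ``pixel_accuracy`` is
  reported alongside.
* a class absent from both truth and prediction has IoU 1 (flagged);
* Dice of two empty masks is 1; HD95 of two empty masks is 0, and of
  exactly one empty mask is +inf (flagged);
* boundary pixels are foreground pixels with at least one non-foreground
  4-neighbour; directed boundary distances from both masks are pooled
  before taking the 95th percentile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


@dataclass
class MetricReport:
    dice: float
    miou: float
    per_class_iou: list[float]
    mrecall: float
    accuracy_eq8: float
    pixel_accuracy: float
    f1: float
    hd95: float
    ece: float
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {k: (v if not isinstance(v, np.floating) else float(v))
                for k, v in self.__dict__.items()}


def confusion(pred: np.ndarray, truth: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Pixel confusion matrix; rows = true class, columns = predicted."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    p = pred.reshape(-1).astype(np.int64)
    t = truth.reshape(-1).astype(np.int64)
    if p.min() < 0 or p.max() >= n_classes or t.min() < 0 or t.max() >= n_classes:
        raise ValueError(f"labels out of range [0, {n_classes - 1}]")
    return np.bincount(t * n_classes + p, minlength=n_classes ** 2).reshape(n_classes, n_classes)


def dice(pred_mask: np.ndarray, truth_mask: np.ndarray) -> float:
    """2|X∩Y| / (|X| + |Y|); 1.0 when both masks are empty."""
    x = np.asarray(pred_mask).astype(bool)
    y = np.asarray(truth_mask).astype(bool)
    denom = x.sum() + y.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(x, y).sum() / denom


def miou(cm: np.ndarray) -> tuple[list[float], float, list[str]]:
    """Per-class IoU TP/(TP+FP+FN) and their mean.  A class missing from
    both truth and prediction scores 1 by convention and is flagged."""
    cm = np.asarray(cm)
    n = cm.shape[0]
    ious, flags = [], []
    for i in range(n):
        tp = cm[i, i]
        union = cm[i, :].sum() + cm[:, i].sum() - tp
        if union == 0:
            ious.append(1.0)
            flags.append(f"class {i} absent from truth and prediction; IoU set to 1")
        else:
            ious.append(float(tp / union))
    return ious, float(np.mean(ious)), flags


def mrecall_and_accuracy(cm: np.ndarray) -> tuple[float, float, float, list[str]]:
    """(mRecall, accuracy in the summed TP/(TP+FP+FN) form, pixel accuracy)."""
    cm = np.asarray(cm)
    n = cm.shape[0]
    recalls, flags = [], []
    for i in range(n):
        support = cm[i, :].sum()
        if support == 0:
            flags.append(f"class {i} absent from truth; excluded from mRecall")
            continue
        recalls.append(float(cm[i, i] / support))
    mrec = float(np.mean(recalls)) if recalls else float("nan")
    tp_sum = np.trace(cm)
    total = cm.sum()
    fp_sum = total - tp_sum  # every error is one FP (and one FN)
    acc8 = float(tp_sum / (tp_sum + 2 * fp_sum)) if total else float("nan")
    pix = float(tp_sum / total) if total else float("nan")
    return mrec, acc8, pix, flags


def f1_from_confusion(cm: np.ndarray, positive: int = 1) -> float:
    """F1 of the positive class: 2TP / (2TP + FP + FN).  Algebraically the
    Dice coefficient of the positive-class masks."""
    cm = np.asarray(cm)
    tp = cm[positive, positive]
    fn = cm[positive, :].sum() - tp
    fp = cm[:, positive].sum() - tp
    denom = 2 * tp + fp + fn
    return float(2 * tp / denom) if denom else 1.0


def _boundary(mask: np.ndarray) -> np.ndarray:
    """Foreground pixels with at least one non-foreground 4-neighbour."""
    m = np.asarray(mask).astype(bool)
    if not m.any():
        return np.zeros_like(m)
    padded = np.pad(m, 1, constant_values=False)
    interior = (padded[:-2, 1:-1] & padded[2:, 1:-1]
                & padded[1:-1, :-2] & padded[1:-1, 2:])
    return m & ~interior


def hd95(pred_mask: np.ndarray, truth_mask: np.ndarray,
         spacing: float | None = None) -> float:
    """95th percentile of pooled directed boundary distances.

    Units are pixels, or physical units when ``spacing`` (length per pixel)
    is given.  Both masks empty -> 0; exactly one empty -> +inf.
    """
    x = np.asarray(pred_mask).astype(bool)
    y = np.asarray(truth_mask).astype(bool)
    if not x.any() and not y.any():
        return 0.0
    if x.any() != y.any():
        return float("inf")
    bx = np.argwhere(_boundary(x))
    by = np.argwhere(_boundary(y))
    d = cdist(bx.astype(float), by.astype(float))
    directed = np.concatenate([d.min(axis=1), d.min(axis=0)])
    out = float(np.percentile(directed, 95))
    return out * spacing if spacing else out


def ece(probs: np.ndarray, truth: np.ndarray, n_bins: int = 15) -> float:
    """Expected calibration error over max-class confidence bins.

    ``probs`` is (C, H, W) or (B, C, H, W); ``truth`` the matching integer
    label array.  Equal-width bins over [0, 1]; ECE is the bin-weighted
    mean absolute gap between confidence and accuracy.
    """
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == 3:
        probs = probs[None]
        truth = np.asarray(truth)[None]
    c_axis = 1
    conf = probs.max(axis=c_axis).reshape(-1)
    pred = probs.argmax(axis=c_axis).reshape(-1)
    correct = (pred == np.asarray(truth).reshape(-1)).astype(np.float64)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(conf, edges[1:-1]), 0, n_bins - 1)
    total = conf.size
    val = 0.0
    for b in range(n_bins):
        sel = idx == b
        nb = sel.sum()
        if nb == 0:
            continue
        val += (nb / total) * abs(correct[sel].mean() - conf[sel].mean())
    return float(val)


def entropy_map(probs: np.ndarray) -> np.ndarray:
    """Per-pixel Shannon entropy -sum_c p_c ln p_c (natural log)."""
    p = np.asarray(probs, dtype=np.float64)
    c_axis = 0 if p.ndim == 3 else 1
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(p > 0, p * np.log(p), 0.0)
    return -term.sum(axis=c_axis)


def evaluate_predictions(preds: list[np.ndarray], truths: list[np.ndarray],
                         probs: list[np.ndarray] | None = None,
                         n_classes: int = 2, n_bins: int = 15,
                         spacing: float | None = None) -> MetricReport:
    """Aggregate the full battery over a test set.

    mIoU/mRecall/accuracy/F1 come from one global confusion matrix; Dice
    and HD95 are averaged per image over images with non-empty truth
    (images whose HD95 is infinite are excluded from the mean and
    flagged).  ECE pools all pixels.
    """
    if not preds:
        raise ValueError("no predictions to evaluate")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    dices, hds = [], []
    n_inf = 0
    for p, t in zip(preds, truths):
        cm += confusion(p, t, n_classes)
        if np.asarray(t).astype(bool).any():
            dices.append(dice(p, t))
            h = hd95(p, t, spacing)
            if np.isinf(h):
                n_inf += 1
            else:
                hds.append(h)
    ious, mean_iou, flags = miou(cm)
    mrec, acc8, pix, f2 = mrecall_and_accuracy(cm)
    flags += f2
    if n_inf:
        flags.append(f"{n_inf} image(s) with empty prediction or truth boundary "
                     f"excluded from HD95 mean")
    ece_val = float("nan")
    if probs is not None:
        ece_val = ece(np.stack(probs), np.stack(truths), n_bins)
    return MetricReport(
        dice=float(np.mean(dices)) if dices else 1.0,
        miou=mean_iou,
        per_class_iou=ious,
        mrecall=mrec,
        accuracy_eq8=acc8,
        pixel_accuracy=pix,
        f1=f1_from_confusion(cm),
        hd95=float(np.mean(hds)) if hds else 0.0,
        ece=ece_val,
        flags=flags,
    )
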