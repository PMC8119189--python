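"""Segmentation scoring: pixel Dice, object-level matching and Dice,
ROC / precision-recall curves with trapezoidal AUC."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn import metrics as skmetrics

from .imaging import LabeledObjects

__all__ = ["dice_pixel", "match_objects", "dice_object", "curve_sweep",
           "EvalReport", "evaluate_sample"]


def dice_pixel(gt: np.ndarray, pred: np.ndarray) -> float:
    """2|A∩B| / (|A|+|B|); two empty masks score 1.0 by convention."""
    gt = np.asarray(gt) > 0
    pred = np.asarray(pred) > 0
    if gt.shape != pred.shape:
        raise ValueError(f"shape mismatch {gt.shape} vs {pred.shape}")
    denom = gt.sum() + pred.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(gt, pred).sum() / denom)


def _iou_matrix(gt_labels: np.ndarray, pred_labels: np.ndarray,
                k_gt: int, k_pred: int) -> np.ndarray:
    """Pairwise IoU between labeled objects via a joint label histogram."""
    if k_gt == 0 or k_pred == 0:
        return np.zeros((k_gt, k_pred))
    joint = (gt_labels.astype(np.int64) * (k_pred + 1)
             + pred_labels.astype(np.int64))
    counts = np.bincount(joint.ravel(),
                         minlength=(k_gt + 1) * (k_pred + 1))
    inter = counts.reshape(k_gt + 1, k_pred + 1)[1:, 1:].astype(float)
    area_gt = np.bincount(gt_labels.ravel(), minlength=k_gt + 1)[1:]
    area_pred = np.bincount(pred_labels.ravel(), minlength=k_pred + 1)[1:]
    union = area_gt[:, None] + area_pred[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou


def match_objects(gt: LabeledObjects, pred: LabeledObjects,
                  iou_min: float = 0.5):
    """Greedy one-to-one object matching in descending IoU order.

    Returns (TP, FP, FN, matching) where matching is a list of
    (gt_label, pred_label, iou) for accepted pairs.
    """
    if not 0.0 < iou_min <= 1.0:
        raise ValueError("iou_min must lie in (0, 1]")
    if gt.labels.shape != pred.labels.shape:
        raise ValueError("labelings cover different grids")
    kg, kp = gt.n_objects, pred.n_objects
    iou = _iou_matrix(gt.labels, pred.labels, kg, kp)
    pairs = [(iou[i, j], i, j) for i in range(kg) for j in range(kp)
             if iou[i, j] >= iou_min]
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    used_g, used_p, matching = set(), set(), []
    for v, i, j in pairs:
        if i in used_g or j in used_p:
            continue
        used_g.add(i)
        used_p.add(j)
        matching.append((i + 1, j + 1, float(v)))
    tp = len(matching)
    return tp, kp - tp, kg - tp, matching


def dice_object(tp: int, fp: int, fn: int) -> float:
    """Object-level Dice 2TP / (2TP + FP + FN); no objects at all -> 1.0."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    denom = 2 * tp + fp + fn
    if denom == 0:
        return 1.0
    return 2.0 * tp / denom


def curve_sweep(gt: np.ndarray, prob: np.ndarray,
                n_thresholds: int | None = None):
    """Pixelwise ROC and precision-recall curves with trapezoidal AUCs.

    With n_thresholds=None the sweep uses every distinct probability value
    (exact; the ROC AUC then equals the Mann-Whitney rank statistic); an
    integer gives an evenly spaced grid, e.g. for compact exported curves.
    Returns a dict with roc, pr, auc_roc, auc_pr and a degenerate flag
    when gt contains a single class.
    """
    gt = (np.asarray(gt) > 0).ravel().astype(int)
    prob = np.asarray(prob, dtype=float).ravel()
    if gt.shape != prob.shape:
        raise ValueError("shape mismatch")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if gt.min() == gt.max():
        return dict(roc=None, pr=None, auc_roc=np.nan, auc_pr=np.nan,
                    degenerate=True)
    if n_thresholds is None:
        fpr, tpr, _ = skmetrics.roc_curve(gt, prob)
        prec, rec, _ = skmetrics.precision_recall_curve(gt, prob)
        prec, rec = prec[::-1], rec[::-1]
    else:
        thr = np.linspace(0.0, 1.0, int(n_thresholds))
        pos = gt.sum()
        neg = gt.size - pos
        tpr, fpr, prec, rec = [], [], [], []
        for t in thr[::-1]:
            predicted = prob >= t
            tp = int((predicted & (gt == 1)).sum())
            fp = int(predicted.sum()) - tp
            tpr.append(tp / pos)
            fpr.append(fp / neg)
            rec.append(tp / pos)
            prec.append(tp / predicted.sum() if predicted.sum() else 1.0)
        tpr, fpr = np.array(tpr), np.array(fpr)
        prec, rec = np.array(prec), np.array(rec)
    # ensure ROC endpoints (0,0) and (1,1)
    fpr = np.concatenate([[0.0], fpr, [1.0]])
    tpr = np.concatenate([[0.0], tpr, [1.0]])
    auc_roc = float(np.trapezoid(tpr, fpr))
    auc_pr = float(np.trapezoid(prec, rec))
    return dict(roc=np.column_stack([fpr, tpr]),
                pr=np.column_stack([rec, prec]),
                auc_roc=auc_roc, auc_pr=auc_pr, degenerate=False)


@dataclass
class EvalReport:
    """Per-image segmentation scores for both tasks."""

    dice_pixel_glom: float
    dice_pixel_podo: float
    tp: int
    fp: int
    fn: int
    dice_object_podo: float
    auc_roc_glom: float = np.nan
    auc_roc_podo: float = np.nan
    auc_pr_glom: float = np.nan
    auc_pr_podo: float = np.nan
    empty_convention_used: bool = False


def evaluate_sample(gt_masks, pred_masks, gt_podo_objs: LabeledObjects,
                    pred_podo_objs: LabeledObjects, iou_min: float = 0.5,
                    probs=None) -> EvalReport:
    """Score one image: pixel Dice for both tasks plus object-level Dice
    for podocytes; optionally AUCs from the raw probability maps."""
    d_g = dice_pixel(gt_masks.glom, pred_masks.glom)
    d_p = dice_pixel(gt_masks.podo, pred_masks.podo)
    tp, fp, fn, _ = match_objects(gt_podo_objs, pred_podo_objs, iou_min)
    rep = EvalReport(d_g, d_p, tp, fp, fn, dice_object(tp, fp, fn),
                     empty_convention_used=(gt_masks.glom.sum() == 0
                                            or gt_masks.podo.sum() == 0))
    if probs is not None:
        for task, prob in (("glom", probs.glom_prob), ("podo", probs.podo_prob)):
            res = curve_sweep(getattr(gt_masks, task), prob)
            setattr(rep, f"auc_roc_{task}", res["auc_roc"])
            setattr(rep, f"auc_pr_{task}", res["auc_pr"])
    return rep
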