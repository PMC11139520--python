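"""Segmentation and recognition evaluation metrics.

Voxel accuracy, instance-level precision/recall/F1 with IoU matching, the
aggregated Jaccard index (AJI), the size-balanced per-instance IoU mean
(IIoU), AP@t = TP/(TP+FP+FN), and an identity-aware recognition AP where a
prediction only counts as a true positive if it both overlaps its matched
ground-truth instance at IoU >= t and carries that instance's identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class InstanceMatching:
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, gt, IoU)
    unmatched_pred: list[int] = field(default_factory=list)
    unmatched_gt: list[int] = field(default_factory=list)


def _check_shapes(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {gt.shape}")
    return pred, gt


def voxel_accuracy(pred: np.ndarray, gt: np.ndarray) -> float:
    """Fraction of voxels whose binary foreground/background status agrees."""
    pred, gt = _check_shapes(pred, gt)
    return float(((pred > 0) == (gt > 0)).mean())


def _iou_table(pred: np.ndarray, gt: np.ndarray):
    """Pairwise IoU between pred and gt instances via a joint contingency table."""
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    gt_ids = np.unique(gt)
    gt_ids = gt_ids[gt_ids > 0]
    if pred_ids.size == 0 or gt_ids.size == 0:
        return pred_ids, gt_ids, np.zeros((pred_ids.size, gt_ids.size))
    p_index = np.searchsorted(pred_ids, pred.ravel())
    g_index = np.searchsorted(gt_ids, gt.ravel())
    both = (pred.ravel() > 0) & (gt.ravel() > 0)
    inter = np.zeros((pred_ids.size, gt_ids.size), dtype=np.int64)
    np.add.at(inter, (p_index[both], g_index[both]), 1)
    p_area = np.bincount(p_index[pred.ravel() > 0], minlength=pred_ids.size)
    g_area = np.bincount(g_index[gt.ravel() > 0], minlength=gt_ids.size)
    union = p_area[:, None] + g_area[None, :] - inter
    iou = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return pred_ids, gt_ids, iou


def match_instances(pred: np.ndarray, gt: np.ndarray, iou_t: float = 0.5) -> InstanceMatching:
    """Greedy one-to-one matching by descending IoU among pairs with IoU >= iou_t."""
    if not 0.0 < iou_t <= 1.0:
        raise ValueError("iou_t must be in (0, 1]")
    pred, gt = _check_shapes(pred, gt)
    pred_ids, gt_ids, iou = _iou_table(pred, gt)
    m = InstanceMatching()
    used_p: set[int] = set()
    used_g: set[int] = set()
    if iou.size:
        order = np.argsort(iou, axis=None)[::-1]
        for flat in order:
            i, j = np.unravel_index(flat, iou.shape)
            if iou[i, j] < iou_t:
                break
            if i in used_p or j in used_g:
                continue
            used_p.add(int(i))
            used_g.add(int(j))
            m.pairs.append((int(pred_ids[i]), int(gt_ids[j]), float(iou[i, j])))
    m.unmatched_pred = [int(p) for k, p in enumerate(pred_ids) if k not in used_p]
    m.unmatched_gt = [int(g) for k, g in enumerate(gt_ids) if k not in used_g]
    return m


def instance_prf(pred: np.ndarray, gt: np.ndarray, iou_t: float = 0.5):
    """Instance-level (precision, recall, F1) at the given IoU threshold."""
    m = match_instances(pred, gt, iou_t)
    tp = len(m.pairs)
    fp = len(m.unmatched_pred)
    fn = len(m.unmatched_gt)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def aji(pred: np.ndarray, gt: np.ndarray) -> float:
    """Aggregated Jaccard index.

    Each ground-truth instance is greedily matched to its best-IoU
    prediction; AJI = sum of matched intersections over (sum of matched
    unions + areas of predictions never used).
    """
    pred, gt = _check_shapes(pred, gt)
    pred_ids, gt_ids, iou = _iou_table(pred, gt)
    if gt_ids.size == 0:
        raise ValueError("AJI undefined for empty ground truth")
    p_area = {int(p): int((pred == p).sum()) for p in pred_ids}
    g_area = {int(g): int((gt == g).sum()) for g in gt_ids}
    inter_sum = 0.0
    union_sum = 0.0
    used: set[int] = set()
    for j, g in enumerate(gt_ids):
        if pred_ids.size and iou[:, j].max() > 0:
            i = int(np.argmax(iou[:, j]))
            p = int(pred_ids[i])
            inter = int(((pred == p) & (gt == g)).sum())
            inter_sum += inter
            union_sum += p_area[p] + g_area[int(g)] - inter
            used.add(p)
        else:
            union_sum += g_area[int(g)]
    for p in pred_ids:
        if int(p) not in used:
            union_sum += p_area[int(p)]
    return float(inter_sum / union_sum) if union_sum else 0.0


def iiou(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean per-ground-truth-cell IoU (size-balanced instance IoU).

    Each ground-truth cell is paired one-to-one with a prediction by
    best-IoU matching at any positive overlap; unmatched cells contribute
    zero, so every cell counts equally regardless of its size.
    """
    pred, gt = _check_shapes(pred, gt)
    gt_ids = np.unique(gt)
    gt_ids = gt_ids[gt_ids > 0]
    if gt_ids.size == 0:
        raise ValueError("IIoU undefined for empty ground truth")
    m = match_instances(pred, gt, iou_t=1e-12)
    by_gt = {g: i for _, g, i in m.pairs}
    return float(np.mean([by_gt.get(int(g), 0.0) for g in gt_ids]))


def ap_at(pred: np.ndarray, gt: np.ndarray, iou_t: float = 0.5) -> float:
    """AP at one threshold: TP / (TP + FP + FN)."""
    m = match_instances(pred, gt, iou_t)
    tp = len(m.pairs)
    denom = tp + len(m.unmatched_pred) + len(m.unmatched_gt)
    return tp / denom if denom else 0.0


def ap_range(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean AP over IoU thresholds 0.50, 0.55, ..., 0.95."""
    ts = np.arange(0.50, 0.951, 0.05)
    return float(np.mean([ap_at(pred, gt, t) for t in ts]))


def recognition_ap(
    pred: np.ndarray,
    gt: np.ndarray,
    pred_ids: dict[int, str],
    gt_ids: dict[int, str],
    iou_t: float = 0.5,
) -> float:
    """Identity-aware AP: a prediction is TP iff it matches a ground-truth
    instance at IoU >= iou_t AND carries that instance's identity."""
    m = match_instances(pred, gt, iou_t)
    tp = sum(
        1
        for p, g, _ in m.pairs
        if p in pred_ids and g in gt_ids and pred_ids[p] == gt_ids[g]
    )
    fp_from_pairs = len(m.pairs) - tp
    denom = tp + fp_from_pairs + len(m.unmatched_pred) + len(m.unmatched_gt)
    return tp / denom if denom else 0.0
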