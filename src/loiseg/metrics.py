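"""Instance-segmentation evaluation: ranked AP, mAP, AJI, and detection F1.

Average precision follows the instance-detection convention

    AP = (1/C) * sum_k P(k) * T(k)

where ``C`` is the number of ground-truth cells, ``T(k)`` indicates
whether the ``k``-th ranked detection is positive at the chosen IOU
threshold, and ``P(k)`` is the precision of the first ``k`` detections.
Matching is greedy in rank order and a ground-truth instance can be
matched at most once (no double-matching).  mAP averages AP over IOU
thresholds 0.50 to 0.95 in steps of 0.05.

The aggregated Jaccard index (AJI) extends the Jaccard index to
instance results: each ground-truth cell G_i greedily claims its
best-Jaccard unused prediction S*_i, and predictions left unmatched
count against the denominator:

    AJI = sum_i |G_i ∩ S*_i| / ( sum_i |G_i ∪ S*_i| + sum_unused |S_j| )

Detection precision/recall/F1 use an IOU threshold of 0.6 by default.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .types import EvalReport, InstanceSet

__all__ = [
    "iou_matrix",
    "match_detections",
    "average_precision",
    "aggregated_jaccard",
    "detection_f1",
    "evaluate_instances",
    "IOU_GRID",
]

#: IOU thresholds for mAP: 0.50, 0.55, ..., 0.95.
IOU_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))


def _as_mask_list(masks) -> list[np.ndarray]:
    if isinstance(masks, InstanceSet):
        return masks.masks
    return [np.asarray(m, dtype=bool) for m in masks]


def iou_matrix(detections, gts) -> np.ndarray:
    """Pairwise IOU between detection masks (rows) and ground-truth masks (cols)."""
    det = _as_mask_list(detections)
    gt = _as_mask_list(gts)
    if not det or not gt:
        return np.zeros((len(det), len(gt)))
    d = np.stack([m.ravel() for m in det]).astype(np.float32)
    g = np.stack([m.ravel() for m in gt]).astype(np.float32)
    inter = d @ g.T
    union = d.sum(1, keepdims=True) + g.sum(1) - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        iou = np.where(union > 0, inter / union, 0.0)
    return iou.astype(np.float64)


def _check_sorted(scores) -> None:
    if scores is not None:
        s = np.asarray(scores, dtype=float)
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("detections must be sorted by descending score")


def match_detections(
    detections,
    gts,
    iou_threshold: float,
    scores: Sequence[float] | None = None,
    iou: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Greedy rank-order matching with the no-double-match rule.

    Detections must arrive sorted by descending score (ties by input
    order); pass ``scores`` to have the ordering verified.  Detection
    ``k`` is positive iff its best-IOU *unmatched* ground truth reaches
    ``iou_threshold``; that ground truth is then consumed.

    Returns
    -------
    T : (n,) uint8 indicator of positive detections in rank order.
    matching : (n,) int array, index of the matched GT or -1.
    """
    _check_sorted(scores)
    if iou is None:
        iou = iou_matrix(detections, gts)
    n, m = iou.shape
    T = np.zeros(n, dtype=np.uint8)
    matching = np.full(n, -1, dtype=np.int64)
    used = np.zeros(m, dtype=bool)
    for k in range(n):
        row = np.where(used, -1.0, iou[k])
        if m == 0:
            continue
        j = int(np.argmax(row))
        if row[j] >= iou_threshold and row[j] > 0:
            T[k] = 1
            matching[k] = j
            used[j] = True
    return T, matching


def average_precision(T: Sequence[int], C: int) -> float:
    """AP of a ranked indicator sequence against ``C`` ground-truth cells.

    Empty conventions: C = 0 with no detections -> 1 (nothing to find,
    nothing claimed); C = 0 with detections -> 0.
    """
    T = np.asarray(T, dtype=np.float64)
    n = len(T)
    if C == 0:
        return 1.0 if n == 0 else 0.0
    if n == 0:
        return 0.0
    precision_at_k = np.cumsum(T) / np.arange(1, n + 1)
    return float(np.sum(precision_at_k * T) / C)


def aggregated_jaccard(
    predictions,
    gts,
    exclusive_matching: bool = True,
) -> float:
    """AJI between a predicted label partition and ground-truth cells.

    ``predictions`` is a label map (int array, 0 = background) or a list
    of disjoint masks.  Ground-truth cells are visited in id order; ties
    in the best-Jaccard choice go to the lowest prediction index.  A GT
    cell with zero overlap against every unused prediction contributes
    its own area to the denominator and consumes nothing.  With
    ``exclusive_matching`` (default) each prediction is used at most
    once; disable to allow one prediction to serve several GT cells (it
    then still counts only once in the unused sum, i.e. never).
    """
    if isinstance(predictions, np.ndarray) and predictions.ndim == 2 and not (
        predictions.dtype == bool
    ):
        preds = InstanceSet.from_label_map(predictions).masks
    else:
        preds = _as_mask_list(predictions)
    gt = _as_mask_list(gts)
    if not gt:
        return 1.0 if not preds else 0.0
    areas_p = np.array([p.sum() for p in preds], dtype=np.float64)
    iou = iou_matrix(preds, gt)  # rows preds, cols gt
    inter_num = 0.0
    union_den = 0.0
    used = np.zeros(len(preds), dtype=bool)
    for i, g in enumerate(gt):
        if len(preds) == 0:
            union_den += g.sum()
            continue
        jac = np.where(used, -1.0, iou[:, i]) if exclusive_matching else iou[:, i]
        j = int(np.argmax(jac))
        if jac[j] > 0:
            inter = np.logical_and(preds[j], g).sum()
            union = np.logical_or(preds[j], g).sum()
            inter_num += inter
            union_den += union
            used[j] = True
        else:
            union_den += g.sum()
    unused = (~used) & (areas_p > 0)
    union_den += areas_p[unused].sum()
    return float(inter_num / union_den) if union_den > 0 else 1.0


def detection_f1(
    detections,
    gts,
    iou_threshold: float = 0.6,
    scores: Sequence[float] | None = None,
) -> tuple[float, float, float]:
    """Cell-detection precision, recall, and F1 at the given IOU threshold."""
    det = _as_mask_list(detections)
    gt = _as_mask_list(gts)
    T, _ = match_detections(det, gt, iou_threshold, scores=scores)
    tp = float(T.sum())
    n, C = len(det), len(gt)
    precision = tp / n if n else 0.0
    recall = tp / C if C else 0.0
    f1 = (
        2 * precision * recall / (precision + recall)
        if (precision + recall) > 0
        else 0.0
    )
    return precision, recall, f1


def evaluate_instances(
    per_image: Sequence[tuple],
    label_maps: Sequence[np.ndarray] | None = None,
    iou_grid: Sequence[float] = IOU_GRID,
    f1_iou: float = 0.6,
) -> EvalReport:
    """Full evaluation over one or more images.

    Parameters
    ----------
    per_image
        Sequence of ``(det_masks, det_scores, gt_instance_set)`` per
        image.  Detections are pooled across images by score before the
        ranked-AP computation (the convention of the AP literature).
    label_maps
        Optional flattened predicted label maps, one per image, for the
        AJI; when omitted the (possibly overlapping) detection masks are
        used directly in score order.
    """
    # pooled ranking: (score, image_index, local_index)
    pool = []
    C = 0
    for img_idx, (det_masks, det_scores, gts) in enumerate(per_image):
        C += len(_as_mask_list(gts))
        for k, s in enumerate(det_scores):
            pool.append((float(s), img_idx, k))
    pool.sort(key=lambda t: (-t[0], t[1], t[2]))
    n = len(pool)

    # per-image IOU matrices, then pooled greedy matching per threshold
    ious = []
    for det_masks, det_scores, gts in per_image:
        ious.append(iou_matrix(_as_mask_list(det_masks), gts))

    ap_by_iou: dict[float, float] = {}
    f1_stats = (0.0, 0.0, 0.0)
    for thr in list(iou_grid) + [f1_iou]:
        used = [np.zeros(m.shape[1], dtype=bool) for m in ious]
        T = np.zeros(n, dtype=np.float64)
        for rank, (_, img_idx, k) in enumerate(pool):
            iou = ious[img_idx]
            if iou.shape[1] == 0:
                continue
            row = np.where(used[img_idx], -1.0, iou[k])
            j = int(np.argmax(row))
            if row[j] >= thr and row[j] > 0:
                T[rank] = 1
                used[img_idx][j] = True
        if thr == f1_iou:
            tp = float(T.sum())
            precision = tp / n if n else 0.0
            recall = tp / C if C else 0.0
            f1 = (
                2 * precision * recall / (precision + recall)
                if (precision + recall) > 0
                else 0.0
            )
            f1_stats = (precision, recall, f1)
        if thr in iou_grid:
            ap_by_iou[float(thr)] = average_precision(T, C)

    # AJI averaged over images (it is a per-partition metric)
    ajis = []
    for img_idx, (det_masks, det_scores, gts) in enumerate(per_image):
        if label_maps is not None:
            ajis.append(aggregated_jaccard(label_maps[img_idx], gts))
        else:
            ajis.append(aggregated_jaccard(_as_mask_list(det_masks), gts))
    aji = float(np.mean(ajis)) if ajis else 1.0

    precision, recall, f1 = f1_stats
    return EvalReport(
        ap_by_iou=ap_by_iou,
        map_score=float(np.mean(list(ap_by_iou.values()))) if ap_by_iou else 0.0,
        aji=aji,
        precision=precision,
        recall=recall,
        f1=f1,
        n_ground_truth=C,
        n_detections=n,
    )
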