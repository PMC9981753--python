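"""Independent brute-force reference implementations used by the tests.

These deliberately mirror the written definitions with naive loops and
stay independent of the package code paths they check.
"""

import numpy as np


def random_blob_scene(rng, shape=(24, 24), n_det=None, n_gt=None):
    """Random small masks with scores: (det_masks sorted by score, scores, gt_masks)."""
    n_det = int(rng.integers(1, 9)) if n_det is None else n_det
    n_gt = int(rng.integers(1, 11)) if n_gt is None else n_gt

    def blobs(n):
        out = []
        for _ in range(n):
            m = np.zeros(shape, dtype=bool)
            r, c = rng.integers(2, shape[0] - 2, 2)
            rad = int(rng.integers(1, 5))
            rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]]
            m[(rr - r) ** 2 + (cc - c) ** 2 <= rad**2] = True
            out.append(m)
        return out

    det = blobs(n_det)
    gts = blobs(n_gt)
    scores = np.sort(rng.random(n_det))[::-1]
    return det, scores, gts


def iou(a, b):
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


def brute_match(det_masks, gt_masks, thr):
    """Greedy rank-order matching, one GT per detection, naive loops."""
    matched = set()
    T = []
    assign = []
    for d in det_masks:
        best_iou, best = -1.0, None
        for gi, g in enumerate(gt_masks):
            if gi in matched:
                continue
            v = iou(d, g)
            if v > best_iou:
                best_iou, best = v, gi
        if best is not None and best_iou >= thr and best_iou > 0:
            T.append(1)
            assign.append(best)
            matched.add(best)
        else:
            T.append(0)
            assign.append(-1)
    return T, assign


def brute_ap(T, C):
    """Direct evaluation of AP = (1/C) sum_k P(k) T(k)."""
    if C == 0:
        return 1.0 if len(T) == 0 else 0.0
    total = 0.0
    for k in range(1, len(T) + 1):
        P_k = sum(T[:k]) / k
        total += P_k * T[k - 1]
    return total / C


def brute_aji(pred_masks, gt_masks):
    """Direct evaluation of the aggregated Jaccard index sums."""
    if not gt_masks:
        return 1.0 if not pred_masks else 0.0
    used = set()
    num = 0.0
    den = 0.0
    for g in gt_masks:
        best_j, best_jac = None, 0.0
        for j, p in enumerate(pred_masks):
            if j in used:
                continue
            v = iou(p, g)
            if v > best_jac:
                best_jac, best_j = v, j
        if best_j is not None and best_jac > 0:
            num += np.logical_and(pred_masks[best_j], g).sum()
            den += np.logical_or(pred_masks[best_j], g).sum()
            used.add(best_j)
        else:
            den += g.sum()
    for j, p in enumerate(pred_masks):
        if j not in used:
            den += p.sum()
    return num / den if den > 0 else 1.0


def brute_f1(det_masks, gt_masks, thr=0.6):
    T, _ = brute_match(det_masks, gt_masks, thr)
    tp = sum(T)
    n, C = len(det_masks), len(gt_masks)
    precision = tp / n if n else 0.0
    recall = tp / C if C else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1


def partition_from_masks(masks, shape):
    """Resolve overlapping detection masks into a partition (first claim wins)."""
    taken = np.zeros(shape, dtype=bool)
    out = []
    for m in masks:
        mm = m & ~taken
        out.append(mm)
        taken |= mm
    return [m for m in out if m.any()]
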