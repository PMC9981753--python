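"""Inference: image -> LPN proposals -> per-LOI soft masks -> instances.

There is no post-processing beyond proposal non-maximum suppression and
a 0.5 probability threshold: the per-cell soft masks *are* the output.
Overlapping instances are preserved in the instance list; the label-map
view flattens them by assigning contested pixels to the higher soft
probability (ties to the higher-scoring instance).
"""

from __future__ import annotations

import numpy as np

from .network import CellModel, LoiProposal, normalize_image
from .types import InstancePrediction, SegmentationResult

__all__ = ["propose_lois", "segment_image", "flatten_predictions"]


def propose_lois(
    score_map: np.ndarray,
    offsets: np.ndarray,
    stride: int,
    score_threshold: float = 0.5,
    nms_window: int = 5,
    max_proposals: int = 2048,
    image_shape: tuple[int, int] | None = None,
) -> list[LoiProposal]:
    """Decode score/offset maps into a score-sorted LOI list.

    A grid cell survives NMS iff its score is a maximum within the
    sliding window (``nms_window`` in image pixels, at least one grid
    cell); ties inside a window are broken toward the lowest
    ``(row, col)`` cell.  Survivors above ``score_threshold`` are
    decoded as ``(stride * i + dr, stride * j + dc)``, sorted by
    descending score, and truncated to ``max_proposals``.
    """
    score = np.asarray(score_map, dtype=np.float64).reshape(
        np.asarray(score_map).shape[-2:]
    )
    off = np.asarray(offsets, dtype=np.float64).reshape(2, *score.shape)
    gh, gw = score.shape
    half = max(1, int(round(nms_window / (2 * stride))))

    keep = score >= score_threshold
    if not keep.any():
        return []
    rr, cc = np.nonzero(keep)
    out: list[tuple[float, float, float]] = []
    for i, j in zip(rr, cc):
        s = score[i, j]
        is_max = True
        for di in range(-half, half + 1):
            for dj in range(-half, half + 1):
                if di == 0 and dj == 0:
                    continue
                ni, nj = i + di, j + dj
                if not (0 <= ni < gh and 0 <= nj < gw):
                    continue
                sn = score[ni, nj]
                if sn > s or (sn == s and (ni, nj) < (i, j)):
                    is_max = False
                    break
            if not is_max:
                break
        if is_max:
            r = stride * i + off[0, i, j]
            c = stride * j + off[1, i, j]
            out.append((s, r, c))
    if image_shape is not None:
        h, w = image_shape
        out = [(s, r, c) for s, r, c in out if 0 <= r < h and 0 <= c < w]
    out.sort(key=lambda t: (-t[0], t[1], t[2]))
    return [LoiProposal(location=(r, c), score=float(s)) for s, r, c in out[:max_proposals]]


def segment_image(
    image: np.ndarray,
    model: CellModel,
    score_threshold: float | None = None,
) -> SegmentationResult:
    """Segment every cell in an image with a trained model.

    Runs the backbone once, the LPN once, and the segmentation head
    once per proposal.  Deterministic given weights.
    """
    cfg = model.cfg
    thr = cfg.score_threshold if score_threshold is None else score_threshold
    img = normalize_image(image)
    shape = img.shape[-2:]
    features = model.backbone(img)
    score_logits, offsets = model.lpn(features)
    proposals = propose_lois(
        score_logits.sigmoid().data,
        offsets.data,
        stride=cfg.lpn_stride,
        score_threshold=thr,
        nms_window=cfg.nms_window,
        max_proposals=cfg.max_proposals,
        image_shape=shape,
    )
    if not proposals:
        return SegmentationResult(
            instances=[], label_map=np.zeros(shape, dtype=np.int32), image_shape=shape
        )
    lois = np.array([p.location for p in proposals], dtype=float)
    logits, origins = model.segment_at_lois(features, lois)
    probs = logits.sigmoid().data[:, 0]  # (n, s, s)

    predictions: list[InstancePrediction] = []
    h, w = shape
    s = cfg.crop_size
    for k, prop in enumerate(proposals):
        r0, c0 = int(origins[k][0]), int(origins[k][1])
        fr0, fc0 = max(0, r0), max(0, c0)
        fr1, fc1 = min(h, r0 + s), min(w, c0 + s)
        patch = probs[k, fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0]
        if patch.size == 0 or not (patch >= 0.5).any():
            continue
        predictions.append(
            InstancePrediction(
                anchor=prop.location,
                crop_origin=(fr0, fc0),
                soft_mask=patch.astype(np.float32),
                score=prop.score,
            )
        )
    label_map = flatten_predictions(predictions, shape)
    return SegmentationResult(instances=predictions, label_map=label_map, image_shape=shape)


def flatten_predictions(
    predictions: list[InstancePrediction], shape: tuple[int, int]
) -> np.ndarray:
    """Flatten overlapping soft instances into a label partition.

    A pixel goes to the instance with the highest soft probability
    among those claiming it (probability >= 0.5); ties go to the
    higher-scoring (earlier) instance.  No pixel outside the union of
    hard masks is ever labeled.
    """
    n = len(predictions)
    label = np.zeros(shape, dtype=np.int32)
    if n == 0:
        return label
    best_p = np.zeros(shape, dtype=np.float32)
    for k, pred in enumerate(predictions):
        frame = pred.soft_in_frame(shape)
        claim = (frame >= 0.5) & (frame > best_p)
        label[claim] = k + 1
        best_p[claim] = frame[claim]
    return label
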