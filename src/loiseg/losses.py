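"""Training losses for full supervision, weak supervision, and auxnet co-training.

Full supervision pairs each predicted soft mask with its ground-truth
instance (plain per-pixel binary cross-entropy) and trains the LPN
against heatmaps rendered from the ground-truth LOIs.

Weak supervision has no per-cell masks, so the segmentation head is
driven by two consistency terms instead:

* *image consistency* — the probabilistic union of all per-cell soft
  masks, ``q(x) = 1 - prod_k (1 - p_k(x))``, must reproduce the
  image-level foreground mask (binary cross-entropy over pixels);
* *overlap* — pairwise products ``sum_{j<k} p_j(x) p_k(x)`` are
  penalized, normalized by the total predicted foreground ``sum_x q``,
  so distinct cells claim disjoint pixels.

Both terms are zero exactly when the predictions hard-tile the image
mask without overlap, which is the intended optimum.

The auxnet is co-trained in a stop-gradient loop: it fits
pseudo-boundaries derived from the main network's (detached) masks,
and the main network's soft-mask edges are in turn pulled toward the
(detached) auxnet boundary map.  Gradient isolation between the two
directions is a hard contract, covered by tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .nn import Tensor, conv2d
from .types import InstancePrediction

__all__ = [
    "EPS",
    "LossBreakdown",
    "render_lpn_target",
    "lpn_loss",
    "supervised_segmentation_loss",
    "weak_segmentation_loss",
    "auxnet_fit_loss",
    "boundary_consistency_loss",
    "edge_suppression_loss",
    "pseudo_boundary_target",
    "prediction_frames",
    "bce_with_logits",
]

#: clamp bound for all logarithm arguments
EPS = 1e-6

_STRUCT3 = np.ones((3, 3), dtype=bool)


@dataclass
class LossBreakdown:
    """Per-term loss values; inactive terms are simply absent."""

    terms: dict[str, float] = field(default_factory=dict)
    weights: dict[str, float] = field(default_factory=dict)
    total: float = 0.0

    @classmethod
    def combine(cls, terms: dict[str, Tensor], weights: dict[str, float]):
        """Weighted sum of the active terms; returns (Tensor total, breakdown)."""
        total: Tensor | None = None
        vals = {}
        used = {}
        for name, t in terms.items():
            w = weights.get(name, 1.0)
            vals[name] = float(t.data)
            used[name] = w
            wt = t * w
            total = wt if total is None else total + wt
        if total is None:
            total = Tensor(0.0)
        return total, cls(terms=vals, weights=used, total=float(total.data))

    def to_row(self) -> dict:
        return {**self.terms, "total": self.total}


def bce_with_logits(logits: Tensor, target: np.ndarray | Tensor) -> Tensor:
    """Numerically stable elementwise binary cross-entropy from logits."""
    y = target.data if isinstance(target, Tensor) else np.asarray(target, np.float32)
    return logits.relu() - logits * y + (1.0 + (-logits.abs()).exp()).log()


def _bce(p: Tensor, target: np.ndarray) -> Tensor:
    """Elementwise BCE on probabilities (clamped to [EPS, 1-EPS])."""
    y = np.asarray(target, dtype=np.float32)
    pc = p.clamp(EPS, 1.0 - EPS)
    return -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log())


# ---------------------------------------------------------------------------
# LPN loss
# ---------------------------------------------------------------------------

def render_lpn_target(
    gt_lois: np.ndarray,
    grid_shape: tuple[int, int],
    stride: int,
    sigma: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Target heatmap, offsets, and positive-cell mask for the LPN level.

    The heatmap is the pointwise max of unit-height Gaussians (stated
    ``sigma`` in image pixels) centered on each ground-truth LOI; the
    grid cell containing a LOI is the positive cell (target exactly 1)
    and carries the sub-stride offset target.
    """
    gh, gw = grid_shape
    heat = np.zeros((gh, gw), dtype=np.float32)
    offsets = np.zeros((2, gh, gw), dtype=np.float32)
    pos = np.zeros((gh, gw), dtype=bool)
    if len(gt_lois):
        rr, cc = np.mgrid[0:gh, 0:gw]
        gr, gc = rr * stride, cc * stride
        for r, c in np.asarray(gt_lois, dtype=float).reshape(-1, 2):
            g = np.exp(-((gr - r) ** 2 + (gc - c) ** 2) / (2.0 * sigma**2))
            np.maximum(heat, g, out=heat)
            i, j = int(r // stride), int(c // stride)
            i, j = min(max(i, 0), gh - 1), min(max(j, 0), gw - 1)
            pos[i, j] = True
            heat[i, j] = 1.0
            offsets[0, i, j] = r - i * stride
            offsets[1, i, j] = c - j * stride
    return heat, offsets, pos


def lpn_loss(
    score_logits: Tensor,
    offsets: Tensor,
    gt_lois: np.ndarray,
    stride: int,
    sigma: float,
) -> Tensor:
    """Penalty-reduced focal BCE on the score map + L1 on offsets at positives.

    Positive cells (target 1) contribute ``-(1-p)^2 log p``; the rest
    contribute ``-(1-t)^4 p^2 log(1-p)`` so near-peak cells are softly
    discounted.  Offset L1 is evaluated at positive cells only.  With
    zero ground-truth LOIs the loss reduces to the pure background
    term.
    """
    grid_shape = score_logits.shape[2:]
    heat, off_t, pos = render_lpn_target(gt_lois, grid_shape, stride, sigma)
    p = score_logits.sigmoid().clamp(EPS, 1.0 - EPS)
    p = p.reshape(*grid_shape)
    pos_f = pos.astype(np.float32)
    neg_w = ((1.0 - heat) ** 4 * (1.0 - pos_f)).astype(np.float32)
    pos_term = Tensor(pos_f) * ((1.0 - p) ** 2.0) * (-(p.log()))
    neg_term = Tensor(neg_w) * (p**2.0) * (-((1.0 - p).log()))
    n_pos = max(1.0, float(pos.sum()))
    score_loss = (pos_term + neg_term).sum() * (1.0 / n_pos)
    if pos.any():
        off_pred = offsets.reshape(2, *grid_shape)
        mask2 = np.stack([pos_f, pos_f])
        off_loss = ((off_pred - Tensor(off_t)) * Tensor(mask2)).abs().sum() * (
            1.0 / (2.0 * n_pos)
        )
        return score_loss + off_loss
    return score_loss


# ---------------------------------------------------------------------------
# segmentation losses
# ---------------------------------------------------------------------------

def supervised_segmentation_loss(
    mask_logits: Tensor,
    origins: np.ndarray,
    gt_masks: list[np.ndarray],
) -> Tensor:
    """Mean per-pixel BCE between each soft-mask crop and its matched GT mask.

    Training anchors come from ground-truth LOIs, so prediction ``k``
    is paired with instance ``k``; an unmatched prediction is a caller
    bug and raises.
    """
    n, _, s, _ = mask_logits.shape
    if len(gt_masks) != n:
        raise ValueError(
            f"{n} predictions but {len(gt_masks)} matched ground-truth masks"
        )
    targets = np.zeros((n, 1, s, s), dtype=np.float32)
    for k, (gt, (r0, c0)) in enumerate(zip(gt_masks, origins)):
        h, w = gt.shape
        fr0, fc0 = max(0, r0), max(0, c0)
        fr1, fc1 = min(h, r0 + s), min(w, c0 + s)
        if fr1 > fr0 and fc1 > fc0:
            targets[k, 0, fr0 - r0 : fr1 - r0, fc0 - c0 : fc1 - c0] = gt[
                fr0:fr1, fc0:fc1
            ]
    return bce_with_logits(mask_logits, targets).mean()


def prediction_frames(
    predictions: list[InstancePrediction], frame_shape: tuple[int, int]
) -> Tensor:
    """Constant (no-gradient) per-instance probability frames from predictions."""
    n = len(predictions)
    frames = np.zeros((n, 1, *frame_shape), dtype=np.float32)
    for k, p in enumerate(predictions):
        frames[k, 0] = p.soft_in_frame(frame_shape)
    return Tensor(frames)


def weak_segmentation_loss(
    pred_frames: Tensor,
    image_mask: np.ndarray,
) -> tuple[Tensor, Tensor]:
    """(image consistency, overlap) from per-instance probability frames.

    ``pred_frames`` is (n, 1, H, W) with each instance's soft mask
    placed in the image frame (zero outside its crop) — see
    :meth:`loiseg.nn.Tensor.scatter_crops`.  Invariant to the order of
    instances; overlap is identically 0 for a single instance.
    """
    mask = np.asarray(image_mask, dtype=np.float32)
    H, W = mask.shape
    n = pred_frames.shape[0]
    if n == 0:
        # no predictions: union is all-background, nothing to differentiate
        q0 = Tensor(np.zeros((H, W), dtype=np.float32))
        return _bce(q0, mask).mean(), Tensor(0.0)
    p = pred_frames.clamp(0.0, 1.0 - EPS)
    log1m = (1.0 - p).log().sum(axis=0)  # (1, H, W)
    q = 1.0 - log1m.exp()
    consistency = _bce(q.reshape(H, W), mask).mean()
    s1 = p.sum(axis=0)
    s2 = (p * p).sum(axis=0)
    pairwise = ((s1 * s1 - s2) * 0.5).sum()
    q_total = q.sum()
    if float(q_total.data) <= EPS:
        overlap = Tensor(0.0)
    else:
        overlap = pairwise / q_total
    return consistency, overlap


# ---------------------------------------------------------------------------
# auxnet co-training
# ---------------------------------------------------------------------------

def pseudo_boundary_target(
    predictions: list[np.ndarray] | np.ndarray, frame_shape: tuple[int, int]
) -> np.ndarray:
    """Union of 3x3 morphological gradients of thresholded predictions.

    ``predictions`` is a stack/list of per-instance probability frames;
    each is thresholded at 0.5, its dilation-minus-erosion ring is
    taken, and rings are unioned across instances.
    """
    target = np.zeros(frame_shape, dtype=bool)
    for frame in predictions:
        hard = np.asarray(frame).reshape(frame_shape) >= 0.5
        if not hard.any():
            continue
        ring = ndimage.binary_dilation(hard, _STRUCT3) & ~ndimage.binary_erosion(
            hard, _STRUCT3
        )
        target |= ring
    return target


def auxnet_fit_loss(aux_logits: Tensor, pred_frames: Tensor) -> Tensor:
    """BCE between the auxnet boundary map and pseudo-boundaries of the
    (detached) main-network predictions.

    The predictions enter as constants — no gradient flows into the
    main network through this term.
    """
    H, W = aux_logits.shape[2:]
    target = pseudo_boundary_target(pred_frames.data[:, 0], (H, W))
    return bce_with_logits(aux_logits, target.astype(np.float32)[None, None]).mean()


# central-difference kernels for the soft edge magnitude
_KDR = np.zeros((1, 1, 3, 3), dtype=np.float32)
_KDR[0, 0, 0, 1], _KDR[0, 0, 2, 1] = -0.5, 0.5
_KDC = np.zeros((1, 1, 3, 3), dtype=np.float32)
_KDC[0, 0, 1, 0], _KDC[0, 0, 1, 2] = -0.5, 0.5


def soft_edge_map(pred_frames: Tensor) -> Tensor:
    """Total soft edge magnitude sum_k 2|grad p_k|, clipped to [0, 1].

    The factor 2 calibrates a unit step edge (central-difference
    magnitude 1/2 on the two pixels flanking it) to saturate at 1,
    matching the unit-valued 2-px morphological-gradient rings the
    auxnet is fitted to.
    """
    gr = conv2d(pred_frames, Tensor(_KDR), None, pad=1)
    gc = conv2d(pred_frames, Tensor(_KDC), None, pad=1)
    mag = ((gr * gr + gc * gc + 1e-12) ** 0.5) * 2.0
    return mag.sum(axis=0).clamp(0.0, 1.0)  # (1, H, W)


def boundary_consistency_loss(
    pred_frames: Tensor,
    aux_boundary: Tensor | np.ndarray,
    image_mask: np.ndarray,
    dilate: int = 3,
) -> Tensor:
    """Mean squared difference between predicted soft edges and the
    (detached) auxnet boundary map, restricted to the dilated image mask.

    The auxnet map enters as a constant — no gradient flows into the
    auxnet through this term.
    """
    if isinstance(aux_boundary, Tensor):
        aux = aux_boundary.data.reshape(image_mask.shape)
    else:
        aux = np.asarray(aux_boundary, dtype=np.float32).reshape(image_mask.shape)
    region = ndimage.binary_dilation(
        np.asarray(image_mask, bool), _STRUCT3, iterations=dilate
    ).astype(np.float32)
    n_px = max(1.0, float(region.sum()))
    edges = soft_edge_map(pred_frames).reshape(*image_mask.shape)
    diff = (edges - Tensor(aux)) * Tensor(region)
    return (diff * diff).sum() * (1.0 / n_px)


def edge_suppression_loss(
    pred_frames: Tensor,
    aux_boundary: Tensor | np.ndarray,
    image_mask: np.ndarray,
    dilate: int = 3,
) -> Tensor:
    """One-sided boundary consistency: prediction edges are penalized
    wherever the (detached) auxnet sees no boundary.

    Mean of ``edge(x) * (1 - B(x))`` over the dilated image mask.  Soft
    mask transitions are free to sit on auxnet boundary lines but pay
    for wandering through boundary-free interior, so cell borders snap
    to the seams the auxnet finds without being forced into
    overconfident rings.  Like the squared-difference form, no gradient
    reaches the auxnet through this term.
    """
    if isinstance(aux_boundary, Tensor):
        aux = aux_boundary.data.reshape(image_mask.shape)
    else:
        aux = np.asarray(aux_boundary, dtype=np.float32).reshape(image_mask.shape)
    region = ndimage.binary_dilation(
        np.asarray(image_mask, bool), _STRUCT3, iterations=dilate
    ).astype(np.float32)
    n_px = max(1.0, float(region.sum()))
    edges = soft_edge_map(pred_frames).reshape(*image_mask.shape)
    weight = ((1.0 - aux) * region).astype(np.float32)
    return (edges * Tensor(weight)).sum() * (1.0 / n_px)
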