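"""Core data containers shared across the package.

Coordinates are 0-based ``(row, col)`` everywhere.  Centroid-style
locations-of-interest (LOIs) may be fractional; detector outputs are
integer pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InstanceSet",
    "WeakAnnotation",
    "InstancePrediction",
    "SegmentationResult",
    "EvalReport",
]


@dataclass
class InstanceSet:
    """A set of per-cell binary masks over a common image shape.

    Masks may overlap (cells can crawl on top of each other); each mask
    must be nonempty and all masks share one shape.  ``ids`` default to
    1..n and must be unique.
    """

    masks: list[np.ndarray]
    ids: list[int] | None = None

    def __post_init__(self) -> None:
        masks = [np.asarray(m, dtype=bool) for m in self.masks]
        if masks:
            shape = masks[0].shape
            for i, m in enumerate(masks):
                if m.ndim != 2:
                    raise ValueError(f"instance mask {i} is not 2-D")
                if m.shape != shape:
                    raise ValueError(
                        f"instance mask {i} has shape {m.shape}, expected {shape}"
                    )
                if not m.any():
                    raise ValueError(f"instance mask {i} is empty")
        self.masks = masks
        if self.ids is None:
            self.ids = list(range(1, len(masks) + 1))
        else:
            self.ids = [int(i) for i in self.ids]
            if len(self.ids) != len(masks):
                raise ValueError("ids length does not match number of masks")
            if len(set(self.ids)) != len(self.ids):
                raise ValueError("instance ids must be unique")

    def __len__(self) -> int:
        return len(self.masks)

    @property
    def shape(self) -> tuple[int, int] | None:
        return self.masks[0].shape if self.masks else None

    def label_map(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        """Render a label image; overlaps resolved by draw order (later wins)."""
        if shape is None:
            if self.shape is None:
                raise ValueError("shape required for an empty InstanceSet")
            shape = self.shape
        lab = np.zeros(shape, dtype=np.int32)
        for mask, iid in zip(self.masks, self.ids):
            lab[mask] = iid
        return lab

    @classmethod
    def from_label_map(cls, label_map: np.ndarray) -> "InstanceSet":
        label_map = np.asarray(label_map)
        if not np.issubdtype(label_map.dtype, np.integer):
            raise ValueError("label map must have an integer dtype")
        ids = [int(v) for v in np.unique(label_map) if v != 0]
        masks = [label_map == v for v in ids]
        return cls(masks=masks, ids=ids)


@dataclass
class WeakAnnotation:
    """Image-level foreground mask plus a list of LOI coordinates.

    The mask separates all-cell pixels from background without instance
    identity; LOIs mark the approximate location of each cell.
    """

    image_mask: np.ndarray
    lois: np.ndarray  # (n, 2) float array of (row, col)

    def __post_init__(self) -> None:
        self.image_mask = np.asarray(self.image_mask, dtype=bool)
        if self.image_mask.ndim != 2:
            raise ValueError("image_mask must be 2-D")
        lois = np.asarray(self.lois, dtype=float).reshape(-1, 2)
        h, w = self.image_mask.shape
        for i, (r, c) in enumerate(lois):
            if not (-0.5 <= r <= h - 0.5 and -0.5 <= c <= w - 0.5):
                raise ValueError(
                    f"LOI {i} at ({r}, {c}) lies outside the {h}x{w} image"
                )
        self.lois = lois

    @property
    def n_lois(self) -> int:
        return len(self.lois)


@dataclass
class InstancePrediction:
    """One predicted cell: a soft mask patch anchored at a LOI.

    ``soft_mask`` holds probabilities on a crop whose top-left corner in
    the image frame is ``crop_origin``; pixels outside the crop are
    implicitly probability 0.  Predictions from different cells may
    overlap in the image frame.
    """

    anchor: tuple[float, float]
    crop_origin: tuple[int, int]
    soft_mask: np.ndarray
    score: float = 1.0

    def hard_mask(self, shape: tuple[int, int], threshold: float = 0.5) -> np.ndarray:
        """Binary mask in the full image frame."""
        out = np.zeros(shape, dtype=bool)
        r0, c0 = self.crop_origin
        h, w = self.soft_mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.soft_mask >= threshold
        return out

    def soft_in_frame(self, shape: tuple[int, int]) -> np.ndarray:
        out = np.zeros(shape, dtype=np.float64)
        r0, c0 = self.crop_origin
        h, w = self.soft_mask.shape
        out[r0 : r0 + h, c0 : c0 + w] = self.soft_mask
        return out


@dataclass
class SegmentationResult:
    """Instance list (score-sorted, overlaps preserved) plus a flattened label map."""

    instances: list[InstancePrediction]
    label_map: np.ndarray
    image_shape: tuple[int, int]

    def __len__(self) -> int:
        return len(self.instances)

    def to_instance_set(self) -> InstanceSet:
        """Hard (possibly overlapping) masks, in score order."""
        masks = [p.hard_mask(self.image_shape) for p in self.instances]
        keep = [i for i, m in enumerate(masks) if m.any()]
        return InstanceSet(masks=[masks[i] for i in keep], ids=[i + 1 for i in keep])


@dataclass
class EvalReport:
    """Evaluation summary: AP per IOU threshold, mAP, AJI, and F1 at IOU 0.6."""

    ap_by_iou: dict[float, float]
    map_score: float
    aji: float
    precision: float
    recall: float
    f1: float
    n_ground_truth: int
    n_detections: int
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "ap_by_iou": {f"{t:.2f}": v for t, v in sorted(self.ap_by_iou.items())},
            "mAP": self.map_score,
            "AJI": self.aji,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "n_ground_truth": self.n_ground_truth,
            "n_detections": self.n_detections,
            **self.extras,
        }


def as_loi_array(lois: Sequence) -> np.ndarray:
    """Normalize any (row, col) sequence into an (n, 2) float array."""
    arr = np.asarray(list(lois), dtype=float)
    if arr.size == 0:
        return arr.reshape(0, 2)
    return arr.reshape(-1, 2)
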