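"""Training orchestration for full- and weak-supervision runs.

Three modes are supported:

``full``
    Per-cell ground-truth masks drive a supervised cross-entropy
    segmentation loss; LPN targets come from instance centroids.
``weak``
    Only the image-level mask and the LOI list are read.  The
    segmentation head trains through the consistency/overlap losses,
    and a low-FOV auxnet is co-trained to sharpen cell-cell borders.
``weak_no_auxnet``
    Exactly ``weak`` with the auxnet terms absent (ablation axis).

Training anchors are teacher-forced: the segmentation head is driven by
jittered annotated LOIs rather than LPN proposals, so it learns from
step 0 while the LPN trains in parallel from its own loss.

A strict information-hygiene contract holds: a weak-mode run never
reads instance masks and a full-mode run never reads the weak
annotation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotations import instances_to_lois
from .losses import (
    LossBreakdown,
    auxnet_fit_loss,
    boundary_consistency_loss,
    edge_suppression_loss,
    lpn_loss,
    supervised_segmentation_loss,
    weak_segmentation_loss,
)
from .network import CellModel, ModelConfig, normalize_image
from .types import InstanceSet, WeakAnnotation

__all__ = ["TrainConfig", "TrainSample", "TrainResult", "train", "training_anchors"]

MODES = ("full", "weak", "weak_no_auxnet")


@dataclass
class TrainConfig:
    """Run-level hyperparameters (the architecture lives in ModelConfig)."""

    mode: str = "weak"
    epochs: int = 10
    batch_size: int = 1
    learning_rate: float | None = None  # None -> ModelConfig.learning_rate
    adam_betas: tuple[float, float] | None = None
    seed: int = 0
    augment_flips: bool = True
    augment_rot90: bool = True
    anchor_jitter: float = 2.0
    warmup_fraction: float = 0.1  # auxnet terms ramp in after this fraction
    checkpoint_every: int = 0  # epochs; 0 = only final
    val_every: int = 1  # epochs between validation passes

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainSample:
    """One training record; only the annotation matching the mode is read."""

    image: np.ndarray
    instances: InstanceSet | None = None
    weak: WeakAnnotation | None = None


@dataclass
class TrainResult:
    model: CellModel
    log: list[dict] = field(default_factory=list)
    best_val_ap50: float | None = None
    val_history: list[tuple[int, float]] = field(default_factory=list)


def training_anchors(
    gt_lois: np.ndarray,
    jitter: float,
    image_shape: tuple[int, int],
    rng: np.random.Generator,
) -> np.ndarray:
    """Ground-truth LOIs perturbed by uniform jitter, clipped to the image."""
    lois = np.asarray(gt_lois, dtype=float).reshape(-1, 2)
    if jitter > 0 and len(lois):
        lois = lois + rng.uniform(-jitter, jitter, size=lois.shape)
    h, w = image_shape
    if len(lois):
        lois[:, 0] = np.clip(lois[:, 0], 0, h - 1)
        lois[:, 1] = np.clip(lois[:, 1], 0, w - 1)
    return lois


def _augment(image, masks, lois, shape, rng, flips=True, rot90=True):
    """Random flips / 90-degree rotations applied to image, masks, and LOIs."""
    h, w = shape
    img = image
    ops = []
    if flips and rng.random() < 0.5:
        ops.append("ud")
    if flips and rng.random() < 0.5:
        ops.append("lr")
    if rot90 and h == w and rng.random() < 0.5:
        ops.append("rot")
    for op in ops:
        if op == "ud":
            img = img[..., ::-1, :]
            masks = [m[::-1, :] for m in masks]
            if len(lois):
                lois = np.stack([h - 1 - lois[:, 0], lois[:, 1]], axis=1)
        elif op == "lr":
            img = img[..., :, ::-1]
            masks = [m[:, ::-1] for m in masks]
            if len(lois):
                lois = np.stack([lois[:, 0], w - 1 - lois[:, 1]], axis=1)
        else:
            img = np.rot90(img, axes=(-2, -1))
            masks = [np.rot90(m) for m in masks]
            if len(lois):
                lois = np.stack([w - 1 - lois[:, 1], lois[:, 0]], axis=1)
    return np.ascontiguousarray(img), [np.ascontiguousarray(m) for m in masks], lois


def _check_dataset(dataset, mode: str) -> None:
    """Mode/annotation mismatch fails before any training step."""
    for i, sample in enumerate(dataset):
        if mode == "full":
            if getattr(sample, "instances", None) is None:
                raise ValueError(
                    f"sample {i}: full-supervision training needs instance masks"
                )
        else:
            if getattr(sample, "weak", None) is None:
                raise ValueError(
                    f"sample {i}: weak-supervision training needs a WeakAnnotation"
                )


def train(
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    dataset,
    val_dataset=None,
    out_dir: str | Path | None = None,
    model: CellModel | None = None,
) -> TrainResult:
    """Run one training job; returns the model with best-validation weights.

    ``dataset`` is a sequence of objects with ``.image`` plus
    ``.instances`` (full mode) or ``.weak`` (weak modes).
    ``val_dataset`` is a sequence of ``(image, InstanceSet)`` pairs;
    when given, the model with the highest validation AP at IOU 0.5 is
    kept.
    """
    from .inference import segment_image  # deferred: inference imports network
    from .metrics import evaluate_instances

    mode = train_cfg.mode
    _check_dataset(dataset, mode)
    use_auxnet = mode == "weak"
    if model is None:
        model = CellModel(model_cfg, with_auxnet=use_auxnet)
    elif use_auxnet and model.auxnet is None:
        raise ValueError("weak mode needs a model built with an auxnet")
    if train_cfg.learning_rate is not None:
        model.cfg.learning_rate = train_cfg.learning_rate
    if train_cfg.adam_betas is not None:
        model.cfg.adam_betas = tuple(train_cfg.adam_betas)
    opt = model.make_optimizer()
    rng = np.random.default_rng(train_cfg.seed)
    weights = model.cfg.loss_weights

    n = len(dataset)
    total_steps = train_cfg.epochs * n
    warmup_steps = int(train_cfg.warmup_fraction * total_steps)
    log: list[dict] = []
    best_ap50 = None
    best_state = None
    val_history: list[tuple[int, float]] = []
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)
        (out_path / "config.json").write_text(
            json.dumps(
                {"model": model.cfg.to_dict(), "train": train_cfg.to_dict()}, indent=2
            )
        )

    step = 0
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(n)
        for idx in order:
            sample = dataset[idx]
            breakdown = _train_step(
                model, sample, mode, train_cfg, rng, weights, opt,
                active_auxnet=use_auxnet and step >= warmup_steps,
            )
            row = {"step": step, "epoch": epoch, **breakdown.to_row()}
            log.append(row)
            step += 1
        if val_dataset is not None and (
            (epoch + 1) % train_cfg.val_every == 0 or epoch == train_cfg.epochs - 1
        ):
            per_image = []
            for image, gts in val_dataset:
                res = segment_image(image, model)
                per_image.append(
                    (
                        [p.hard_mask(res.image_shape) for p in res.instances],
                        [p.score for p in res.instances],
                        gts,
                    )
                )
            report = evaluate_instances(per_image, iou_grid=[0.5])
            ap50 = report.ap_by_iou[0.5]
            val_history.append((epoch, ap50))
            if best_ap50 is None or ap50 > best_ap50:
                best_ap50 = ap50
                best_state = [a.copy() for a in model.state_arrays()]
        if out_path is not None and train_cfg.checkpoint_every and (
            (epoch + 1) % train_cfg.checkpoint_every == 0
        ):
            model.save(out_path / f"epoch_{epoch:04d}.ckpt")

    if best_state is not None:
        model.load_state_arrays(best_state)
    if out_path is not None:
        model.save(out_path / "final.ckpt")
        with open(out_path / "train_log.jsonl", "w") as fh:
            for row in log:
                fh.write(json.dumps(row) + "\n")
    return TrainResult(
        model=model, log=log, best_val_ap50=best_ap50, val_history=val_history
    )


def _train_step(
    model: CellModel,
    sample,
    mode: str,
    train_cfg: TrainConfig,
    rng: np.random.Generator,
    weights: dict,
    opt,
    active_auxnet: bool,
) -> LossBreakdown:
    cfg = model.cfg
    image = normalize_image(sample.image)
    shape = image.shape[-2:]

    if mode == "full":
        instances = sample.instances
        gt_masks = [m.astype(np.float32) for m in instances.masks]
        gt_lois = instances_to_lois(instances)
        image, gt_masks, gt_lois = _augment(
            image, gt_masks, gt_lois, shape, rng,
            flips=train_cfg.augment_flips, rot90=train_cfg.augment_rot90,
        )
    else:
        weak = sample.weak
        gt_lois = weak.lois
        image, aug_masks, gt_lois = _augment(
            image, [weak.image_mask], gt_lois, shape, rng,
            flips=train_cfg.augment_flips, rot90=train_cfg.augment_rot90,
        )
        image_mask = aug_masks[0]
    shape = image.shape[-2:]

    features = model.backbone(image)
    score, offsets = model.lpn(features)
    terms = {}
    terms["lpn"] = lpn_loss(
        score, offsets, gt_lois, stride=cfg.lpn_stride, sigma=cfg.heatmap_sigma
    )

    anchors = training_anchors(gt_lois, train_cfg.anchor_jitter, shape, rng)
    if len(anchors):
        logits, origins = model.segment_at_lois(features, anchors)
        if mode == "full":
            terms["segmentation"] = supervised_segmentation_loss(
                logits, origins, gt_masks
            )
        else:
            frames = logits.sigmoid().scatter_crops(origins, shape)
            consistency, overlap = weak_segmentation_loss(frames, image_mask)
            terms["image_consistency"] = consistency
            terms["overlap"] = overlap
            if active_auxnet and model.auxnet is not None:
                aux_logits = model.auxnet(image)
                terms["auxnet_fit"] = auxnet_fit_loss(aux_logits, frames.detach())
                boundary_fn = (
                    edge_suppression_loss
                    if cfg.boundary_loss == "suppress"
                    else boundary_consistency_loss
                )
                terms["boundary_consistency"] = boundary_fn(
                    frames, aux_logits.sigmoid().detach(), image_mask
                )

    total, breakdown = LossBreakdown.combine(terms, weights)
    opt.zero_grad()
    total.backward()
    opt.step()
    return breakdown
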