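"""Network architecture: backbone, location-proposal head, segmentation
head with positional encoding, and the training-only low-FOV auxnet.

The backbone is a small fully convolutional encoder/decoder with U-Net
style skip connections producing a feature pyramid (strides 1, 2, 4).
The location proposal network (LPN) is a keypoint-heatmap head on the
coarse level: a per-cell objectness score plus a sub-stride (row, col)
offset — deliberately *no* size/box regression, since locations of
interest carry no shape information.  The segmentation head runs once
per proposed LOI on a fixed-size crop of the high-resolution features,
concatenated with a positional encoding of each pixel *relative to the
LOI*; this is what breaks the translational invariance of the
convolutional features so that different LOIs on the same image yield
different cells.

The auxnet predicts cell-boundary probability directly from the image
through a few small-kernel, stride-1 convolutions, keeping its
receptive field far below the backbone's so it learns local edge
evidence rather than whole-cell shape.  It participates only in
training.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .nn import Adam, Conv2d, ConvBlock, Module, Tensor, concat

__all__ = [
    "ModelConfig",
    "FeaturePyramid",
    "LoiProposal",
    "Backbone",
    "LPNHead",
    "SegmentationHead",
    "AuxNet",
    "CellModel",
    "encode_position",
    "normalize_image",
]


@dataclass
class ModelConfig:
    """All architecture / loss / optimizer hyperparameters.

    ``crop_size`` must be divisible by the backbone's maximum stride;
    it should comfortably exceed the largest expected cell diameter.
    ``auxnet_fov`` is an upper bound on the auxnet receptive field,
    enforced structurally (small kernels, no downsampling).
    """

    in_channels: int = 1
    widths: tuple[int, int, int] = (16, 32, 64)
    lpn_stride: int = 4
    crop_size: int = 32
    encode_dim: int = 4
    heatmap_sigma: float = 3.0  # px, Gaussian rendered at each GT LOI
    nms_window: int = 5  # px, sliding-max window for proposal NMS
    score_threshold: float = 0.5
    max_proposals: int = 2048
    auxnet_fov: int = 13
    auxnet_width: int = 16
    auxnet_layers: int = 4
    # boundary-consistency form: "suppress" (one-sided edge suppression,
    # default) or "mse" (squared difference to the auxnet map)
    boundary_loss: str = "suppress"
    loss_weights: dict = field(
        default_factory=lambda: {
            "lpn": 1.0,
            "segmentation": 1.0,
            "image_consistency": 1.0,
            "overlap": 1.0,
            "auxnet_fit": 1.0,
            "boundary_consistency": 1.0,
        }
    )
    learning_rate: float = 2e-3
    adam_betas: tuple[float, float] = (0.9, 0.999)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.crop_size % self.max_stride != 0:
            raise ValueError("crop_size must be divisible by the maximum stride")
        if self.boundary_loss not in ("suppress", "mse"):
            raise ValueError("boundary_loss must be 'suppress' or 'mse'")
        rf = 1 + 2 * (self.auxnet_layers)  # 3x3 stride-1 layers
        if rf > self.auxnet_fov:
            raise ValueError(
                f"auxnet receptive field {rf} exceeds auxnet_fov={self.auxnet_fov}"
            )

    @property
    def max_stride(self) -> int:
        return 4

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("widths", "adam_betas"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class FeaturePyramid:
    """Per-stride feature maps plus padding bookkeeping."""

    levels: dict[int, Tensor]  # stride -> (1, C, H/stride, W/stride)
    image_shape: tuple[int, int]  # original (unpadded) size
    pad: tuple[int, int]  # bottom/right padding applied before the backbone


@dataclass
class LoiProposal:
    location: tuple[float, float]
    score: float


def normalize_image(image: np.ndarray, p_low: float = 1.0, p_high: float = 99.8) -> np.ndarray:
    """Per-channel percentile normalization to roughly [0, 1]."""
    img = np.asarray(image, dtype=np.float32)
    if img.ndim == 2:
        img = img[None]
    out = np.empty_like(img)
    for c in range(img.shape[0]):
        lo, hi = np.percentile(img[c], [p_low, p_high])
        out[c] = (img[c] - lo) / max(hi - lo, 1e-6)
    return out


class Backbone(Module):
    """Encoder/decoder FCN producing features at strides 1, 2, and 4."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        w0, w1, w2 = cfg.widths
        self.stem = ConvBlock(cfg.in_channels, w0, n=2, rng=rng)
        self.down1 = Conv2d(w0, w1, k=3, stride=2, pad=1, rng=rng)
        self.enc1 = ConvBlock(w1, w1, n=1, rng=rng)
        self.down2 = Conv2d(w1, w2, k=3, stride=2, pad=1, rng=rng)
        self.enc2 = ConvBlock(w2, w2, n=2, rng=rng)
        self.dec1 = ConvBlock(w2 + w1, w1, n=1, rng=rng)
        self.dec0 = ConvBlock(w1 + w0, w0, n=1, rng=rng)

    def __call__(self, image: np.ndarray) -> FeaturePyramid:
        """Run the backbone; pads reflectively to a multiple of the max stride."""
        img = np.asarray(image, dtype=np.float32)
        if img.ndim == 2:
            img = img[None]
        _, h, w = img.shape
        pad_h = (-h) % 4
        pad_w = (-w) % 4
        if pad_h or pad_w:
            img = np.pad(img, ((0, 0), (0, pad_h), (0, pad_w)), mode="reflect")
        x = Tensor(img[None])  # (1, C, H, W)
        f0 = self.stem(x)
        e1 = self.enc1(self.down1(f0).relu())
        e2 = self.enc2(self.down2(e1).relu())
        d1 = self.dec1(concat([e2.upsample2(), e1]))
        d0 = self.dec0(concat([d1.upsample2(), f0]))
        return FeaturePyramid(
            levels={1: d0, 2: d1, 4: e2},
            image_shape=(h, w),
            pad=(pad_h, pad_w),
        )


class LPNHead(Module):
    """Score heatmap + sub-stride offset regression on the coarse level."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        c_in = cfg.widths[-1]
        self.conv = Conv2d(c_in, c_in, k=3, rng=rng)
        self.out = Conv2d(c_in, 3, k=1, rng=rng)  # [score logit, d_row, d_col]
        self.stride = cfg.lpn_stride

    def __call__(self, features: FeaturePyramid) -> tuple[Tensor, Tensor]:
        """Returns (score logits (1,1,h,w), offsets (1,2,h,w) in pixels)."""
        x = features.levels[self.stride]
        y = self.out(self.conv(x).relu())
        score = Tensor(y.data[:, :1], (y,))

        def bw_s(g):
            if y.requires_grad:
                gy = np.zeros_like(y.data)
                gy[:, :1] = g
                y._accumulate(gy)

        score._bw = bw_s
        offsets = Tensor(y.data[:, 1:], (y,))

        def bw_o(g):
            if y.requires_grad:
                gy = np.zeros_like(y.data)
                gy[:, 1:] = g
                y._accumulate(gy)

        offsets._bw = bw_o
        return score, offsets


def encode_position(
    crop_size: int, loi_offset: tuple[float, float] | None = None
) -> np.ndarray:
    """Closed-form positional code of each crop pixel relative to the LOI.

    Channels: (Δrow/crop_size, Δcol/crop_size, radius/crop_size) where
    Δ is the pixel position minus the LOI position within the crop.  By
    construction the code depends only on position *relative* to the
    LOI, so two LOIs related by a translation receive identical codes.

    ``loi_offset`` is the LOI's sub-pixel position relative to the crop
    center (default (0, 0): LOI at the exact center pixel).
    """
    half = crop_size // 2
    dr0, dc0 = loi_offset if loi_offset is not None else (0.0, 0.0)
    rr, cc = np.mgrid[0:crop_size, 0:crop_size].astype(np.float32)
    drow = (rr - half - dr0) / crop_size
    dcol = (cc - half - dc0) / crop_size
    rad = np.sqrt(drow**2 + dcol**2)
    return np.stack([drow, dcol, rad])


class SegmentationHead(Module):
    """Per-LOI FCN: features + (projected) positional encoding -> soft mask logits."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        w0 = cfg.widths[0]
        self.cfg = cfg
        # light-weight linear projection of the 3 positional channels
        self.pos_proj = Conv2d(3, cfg.encode_dim, k=1, rng=rng)
        self.block = ConvBlock(w0 + cfg.encode_dim, 2 * w0, n=2, rng=rng)
        self.mid = ConvBlock(2 * w0, w0, n=1, rng=rng)
        self.out = Conv2d(w0, 1, k=1, rng=rng)

    def __call__(self, feature_crops: Tensor, encodings: np.ndarray) -> Tensor:
        """feature_crops: (n, C, s, s); encodings: (n, 3, s, s) -> logits (n, 1, s, s)."""
        pos = self.pos_proj(Tensor(encodings))
        x = concat([feature_crops, pos])
        return self.out(self.mid(self.block(x)))


class AuxNet(Module):
    """Low receptive-field boundary predictor (training aid only).

    Stride-1 3x3 convolutions only, so the receptive field is
    ``2 * n_layers + 1`` pixels — structurally below ``auxnet_fov``.
    """

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        w = cfg.auxnet_width
        chans = [cfg.in_channels] + [w] * (cfg.auxnet_layers - 1) + [1]
        self.layers = [
            Conv2d(chans[i], chans[i + 1], k=3, rng=rng)
            for i in range(cfg.auxnet_layers)
        ]
        self.fov = 2 * cfg.auxnet_layers + 1

    def __call__(self, image: np.ndarray | Tensor) -> Tensor:
        """Returns boundary logits (1, 1, H, W)."""
        if isinstance(image, Tensor):
            x = image
        else:
            img = np.asarray(image, dtype=np.float32)
            if img.ndim == 2:
                img = img[None]
            x = Tensor(img[None])
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        return self.layers[-1](x)


class CellModel(Module):
    """The full model: backbone + LPN + segmentation head (+ auxnet when training)."""

    def __init__(self, cfg: ModelConfig, with_auxnet: bool = False):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.backbone = Backbone(cfg, rng)
        self.lpn = LPNHead(cfg, rng)
        self.seg_head = SegmentationHead(cfg, rng)
        self.auxnet = AuxNet(cfg, rng) if with_auxnet else None

    # ---- per-LOI segmentation ---------------------------------------
    def segment_at_lois(
        self, features: FeaturePyramid, lois: np.ndarray
    ) -> tuple[Tensor, np.ndarray]:
        """Soft-mask logits for a batch of LOIs.

        Returns (logits (n, 1, s, s), origins (n, 2) in image-frame
        coordinates, possibly negative near borders).
        """
        s = self.cfg.crop_size
        half = s // 2
        f = features.levels[1]
        fpad = f.pad2d(half)
        lois = np.asarray(lois, dtype=float).reshape(-1, 2)
        anchors = np.rint(lois).astype(int)
        # origins in padded coords are anchor - half + half = anchor
        crops = fpad.gather_crops(anchors, s)
        encodings = np.stack(
            [
                encode_position(s, loi_offset=(r - ar, c - ac))
                for (r, c), (ar, ac) in zip(lois, anchors)
            ]
        ).astype(np.float32)
        logits = self.seg_head(crops, encodings)
        origins = anchors - half
        return logits, origins

    def make_optimizer(self) -> Adam:
        return Adam(
            self.parameters(),
            lr=self.cfg.learning_rate,
            betas=self.cfg.adam_betas,
        )

    # ---- checkpointing ----------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: config JSON + weight arrays."""
        arrays = {f"arr_{i}": a for i, a in enumerate(self.state_arrays())}
        buf = io.BytesIO()
        np.savez(buf, **arrays)
        with open(path, "wb") as fh:
            header = json.dumps(
                {"config": self.cfg.to_dict(), "with_auxnet": self.auxnet is not None}
            ).encode()
            fh.write(len(header).to_bytes(8, "little"))
            fh.write(header)
            fh.write(buf.getvalue())

    @classmethod
    def load(cls, path) -> "CellModel":
        with open(path, "rb") as fh:
            n = int.from_bytes(fh.read(8), "little")
            meta = json.loads(fh.read(n).decode())
            data = np.load(io.BytesIO(fh.read()))
        cfg = ModelConfig.from_dict(meta["config"])
        model = cls(cfg, with_auxnet=meta["with_auxnet"])
        model.load_state_arrays([data[f"arr_{i}"] for i in range(len(data.files))])
        return model

    def describe(self) -> str:
        """Human-readable layer / parameter / receptive-field summary."""
        lines = [
            f"backbone widths {self.cfg.widths}, strides (1, 2, 4)",
            f"  parameters: {self.backbone.n_parameters():,}",
            f"LPN at stride {self.cfg.lpn_stride} (heatmap + offsets, no sizes)",
            f"  parameters: {self.lpn.n_parameters():,}",
            f"segmentation head, crop {self.cfg.crop_size} px, "
            f"positional-encoding dim {self.cfg.encode_dim}",
            f"  parameters: {self.seg_head.n_parameters():,}",
        ]
        if self.auxnet is not None:
            lines.append(
                f"auxnet: {self.cfg.auxnet_layers} stride-1 3x3 layers, "
                f"receptive field {self.auxnet.fov} px (<= {self.cfg.auxnet_fov})"
            )
            lines.append(f"  parameters: {self.auxnet.n_parameters():,}")
        lines.append(f"total parameters: {self.n_parameters():,}")
        return "\n".join(lines)
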