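"""Minimal reverse-mode automatic differentiation on numpy arrays.

A small tape-based engine providing exactly the operations the
segmentation networks need: elementwise arithmetic, (strided, padded)
2-D convolution via im2col, nearest-neighbor upsampling, channel
concatenation, window gather/scatter for per-cell crops, sigmoid /
log / exp / abs / clamp, and reductions.  Arrays are float32 by
default; gradients accumulate in the same dtype.

Image tensors follow the (N, C, H, W) layout.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "conv2d"]


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(np.float32) if x.dtype != np.float32 else x
    return np.asarray(x, dtype=np.float32)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Reduce a broadcast gradient back to the operand's shape."""
    if grad.shape == shape:
        return grad
    # sum over leading extra axes
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, (g, s) in enumerate(zip(grad.shape, shape)):
        if s == 1 and g != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A node in the computation tape."""

    __slots__ = ("data", "grad", "_parents", "_bw", "requires_grad")

    def __init__(self, data, parents=(), bw=None, requires_grad=False):
        self.data = _as_array(data)
        self.grad = None
        self._parents = parents
        self._bw = bw
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    # ---- structural -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def detach(self) -> "Tensor":
        """Stop-gradient: the returned tensor is a constant on the tape."""
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.copy() if g.base is not None or g is self.data else g
        else:
            self.grad = self.grad + g

    def backward(self) -> None:
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._bw is not None:
                node._bw(node.grad)

    # ---- arithmetic -------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._bw = bw
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(-g)

        out._bw = bw
        return out

    def __sub__(self, other):
        return self + (-(other if isinstance(other, Tensor) else Tensor(other)))

    def __rsub__(self, other):
        return Tensor(other) + (-self)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, (self, other))

        def bw(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._bw = bw
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor(other) * self ** -1.0

    def __pow__(self, n: float):
        out = Tensor(self.data ** np.float32(n), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * np.float32(n) * self.data ** np.float32(n - 1))

        out._bw = bw
        return out

    # ---- nonlinearities ---------------------------------------------
    def relu(self):
        mask = self.data > 0
        out = Tensor(np.where(mask, self.data, 0.0), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.where(mask, g, 0.0))

        out._bw = bw
        return out

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-np.clip(self.data, -30, 30)))
        out = Tensor(s, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * s * (1.0 - s))

        out._bw = bw
        return out

    def exp(self):
        e = np.exp(np.clip(self.data, -60, 60))
        out = Tensor(e, (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * e)

        out._bw = bw
        return out

    def log(self):
        out = Tensor(np.log(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        out._bw = bw
        return out

    def abs(self):
        sign = np.sign(self.data)
        out = Tensor(np.abs(self.data), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g * sign)

        out._bw = bw
        return out

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient passes only where the value is inside the range."""
        inside = (self.data > lo) & (self.data < hi)
        out = Tensor(np.clip(self.data, lo, hi), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(np.where(inside, g, 0.0))

        out._bw = bw
        return out

    # ---- reductions & reshapes --------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), (self,))

        def bw(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape).astype(np.float32))
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                self._accumulate(np.broadcast_to(gg, self.data.shape).astype(np.float32))

        out._bw = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        orig = self.data.shape
        out = Tensor(self.data.reshape(*shape), (self,))

        def bw(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        out._bw = bw
        return out

    def pad2d(self, pad: int):
        """Zero-pad the two trailing spatial axes by ``pad`` on every side."""
        if pad == 0:
            return self
        widths = [(0, 0)] * (self.ndim - 2) + [(pad, pad), (pad, pad)]
        out = Tensor(np.pad(self.data, widths), (self,))

        def bw(g):
            if self.requires_grad:
                sl = (Ellipsis, slice(pad, -pad), slice(pad, -pad))
                self._accumulate(g[sl])

        out._bw = bw
        return out

    def upsample2(self):
        """Nearest-neighbor 2x upsampling of (N, C, H, W)."""
        up = self.data.repeat(2, axis=-2).repeat(2, axis=-1)
        out = Tensor(up, (self,))

        def bw(g):
            if self.requires_grad:
                n, c, h2, w2 = g.shape
                gg = g.reshape(n, c, h2 // 2, 2, w2 // 2, 2).sum(axis=(3, 5))
                self._accumulate(gg)

        out._bw = bw
        return out

    # ---- crop gather / scatter --------------------------------------
    def gather_crops(self, origins: np.ndarray, size: int) -> "Tensor":
        """Extract ``size``x``size`` windows from a (1, C, H, W) tensor.

        ``origins`` is an (n, 2) int array of top-left corners; every
        window must lie fully inside.  Returns (n, C, size, size).
        """
        x = self.data
        n = len(origins)
        c = x.shape[1]
        crops = np.empty((n, c, size, size), dtype=np.float32)
        for k, (r0, c0) in enumerate(origins):
            crops[k] = x[0, :, r0 : r0 + size, c0 : c0 + size]
        out = Tensor(crops, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            gx = np.zeros_like(x)
            for k, (r0, c0) in enumerate(origins):
                gx[0, :, r0 : r0 + size, c0 : c0 + size] += g[k]
            self._accumulate(gx)

        out._bw = bw
        return out

    def scatter_crops(
        self, origins: np.ndarray, frame_shape: tuple[int, int]
    ) -> "Tensor":
        """Place (n, 1, h, w) patches into n zero frames of ``frame_shape``.

        Origins are in frame coordinates and may be negative or run past
        the frame; out-of-frame pixels are dropped (crop clipping at
        image borders).  Returns (n, 1, H, W).
        """
        patches = self.data
        n, _, h, w = patches.shape
        H, W = frame_shape
        frames = np.zeros((n, 1, H, W), dtype=np.float32)
        spans = []
        for k, (r0, c0) in enumerate(origins):
            fr0, fc0 = max(0, r0), max(0, c0)
            fr1, fc1 = min(H, r0 + h), min(W, c0 + w)
            pr0, pc0 = fr0 - r0, fc0 - c0
            spans.append((fr0, fr1, fc0, fc1, pr0, pc0))
            if fr1 > fr0 and fc1 > fc0:
                frames[k, 0, fr0:fr1, fc0:fc1] = patches[
                    k, 0, pr0 : pr0 + (fr1 - fr0), pc0 : pc0 + (fc1 - fc0)
                ]
        out = Tensor(frames, (self,))

        def bw(g):
            if not self.requires_grad:
                return
            gp = np.zeros_like(patches)
            for k, (fr0, fr1, fc0, fc1, pr0, pc0) in enumerate(spans):
                if fr1 > fr0 and fc1 > fc0:
                    gp[k, 0, pr0 : pr0 + (fr1 - fr0), pc0 : pc0 + (fc1 - fc0)] = g[
                        k, 0, fr0:fr1, fc0:fc1
                    ]
            self._accumulate(gp)

        out._bw = bw
        return out


class Parameter(Tensor):
    """A trainable leaf tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)

    def zero_grad(self) -> None:
        self.grad = None


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (default: channels)."""
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data, tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, o0, o1 in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(o0, o1)
                t._accumulate(g[tuple(sl)])

    out._bw = bw
    return out


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*kh*kw, L) patch matrix."""
    n, c, h, w = x.shape
    ho = (h - kh) // stride + 1
    wo = (w - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    view = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
        writeable=False,
    )
    return np.ascontiguousarray(view).reshape(n, c * kh * kw, ho * wo), ho, wo


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution (cross-correlation) of (N, C, H, W) with (O, C, kh, kw)."""
    xp = x.pad2d(pad) if pad else x
    kh, kw = w.data.shape[2:]
    cols, ho, wo = _im2col(xp.data, kh, kw, stride)
    n = xp.data.shape[0]
    o = w.data.shape[0]
    w2 = w.data.reshape(o, -1)
    out_data = np.matmul(w2, cols).reshape(n, o, ho, wo)
    if b is not None:
        out_data = out_data + b.data.reshape(1, o, 1, 1)
    parents = (xp, w) + ((b,) if b is not None else ())
    out = Tensor(out_data, parents)

    def bw(g):
        g2 = g.reshape(n, o, ho * wo)
        if w.requires_grad:
            gw = np.einsum("nol,nkl->ok", g2, cols, optimize=True).reshape(w.data.shape)
            w._accumulate(gw)
        if b is not None and b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if xp.requires_grad:
            gcols = np.matmul(w2.T, g2)  # (n, C*kh*kw, L)
            gx = np.zeros_like(xp.data)
            c = xp.data.shape[1]
            gcols = gcols.reshape(n, c, kh, kw, ho, wo)
            for i in range(kh):
                for j in range(kw):
                    gx[
                        :,
                        :,
                        i : i + stride * ho : stride,
                        j : j + stride * wo : stride,
                    ] += gcols[:, :, i, j]
            xp._accumulate(gx)

    out._bw = bw
    return out
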