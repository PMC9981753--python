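"""Convolutional building blocks and the ADAM optimizer.

Weights use He (Kaiming) initialization, the standard choice for
ReLU networks trained from scratch.
"""

from __future__ import annotations

import numpy as np

from .autograd import Parameter, Tensor, conv2d

__all__ = ["Module", "Conv2d", "ConvBlock", "Adam"]


class Module:
    """Base class: recursive parameter collection and state (de)serialization."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"checkpoint holds {len(arrays)} arrays, model has {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)


class Conv2d(Module):
    """3x3 (or kxk) convolution with He-initialized weights."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        k: int = 3,
        stride: int = 1,
        pad: int | None = None,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng()
        fan_in = c_in * k * k
        std = np.sqrt(2.0 / fan_in)
        self.w = Parameter(rng.normal(0.0, std, (c_out, c_in, k, k)))
        self.b = Parameter(np.zeros(c_out))
        self.stride = stride
        self.pad = (k - 1) // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class ConvBlock(Module):
    """Conv -> ReLU (optionally repeated)."""

    def __init__(self, c_in: int, c_out: int, n: int = 1, k: int = 3, rng=None):
        self.layers = [
            Conv2d(c_in if i == 0 else c_out, c_out, k=k, rng=rng) for i in range(n)
        ]

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x).relu()
        return x


class Adam:
    """ADAM optimizer with the standard bias correction."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
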