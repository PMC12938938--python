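"""Layers with explicit forward/backward passes.

Conventions: activations are ``float32`` arrays shaped ``(N, C, H, W)`` (or
``(N, D)`` after pooling); ``forward(x, train)`` caches whatever ``backward``
needs; ``backward(dout)`` accumulates parameter gradients in-place and returns
the gradient w.r.t. the layer input. Convolution is implemented as a sum of
strided-slice contractions over the (at most 4x4) kernel offsets, which keeps
memory flat and avoids im2col scatter in the backward pass.
"""

from __future__ import annotations

import numpy as np
from scipy.special import erf

_SQRT2 = np.float32(np.sqrt(2.0))
_INV_SQRT2PI = np.float32(1.0 / np.sqrt(2.0 * np.pi))


class Parameter:
    """A trainable tensor with its gradient accumulator."""

    __slots__ = ("name", "value", "grad")

    def __init__(self, name: str, value: np.ndarray):
        self.name = name
        self.value = np.ascontiguousarray(value, dtype=np.float32)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base class: parameter-free identity."""

    def parameters(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def trunc_normal(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    """Near-truncated normal init: normal samples clipped at +/- 2 std."""
    v = rng.standard_normal(shape) * std
    return np.clip(v, -2.0 * std, 2.0 * std).astype(np.float32)


class Conv2d(Layer):
    """2-D convolution with optional channel groups.

    ``groups == in_channels`` with ``out_channels == m * in_channels`` gives a
    depth-wise convolution with channel multiplier ``m``; ``groups == 1`` is a
    dense convolution; 1x1 kernels give point-wise convolutions.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 bias: bool = True, *, name: str = "conv",
                 rng: np.random.Generator | None = None):
        if in_channels % groups or out_channels % groups:
            raise ValueError("channel counts must be divisible by groups")
        self.cin, self.cout, self.k = in_channels, out_channels, kernel
        self.stride, self.padding, self.groups = stride, padding, groups
        rng = rng or np.random.default_rng(0)
        w = trunc_normal(rng, (out_channels, in_channels // groups, kernel, kernel))
        self.weight = Parameter(f"{name}.weight", w)
        self.bias = Parameter(f"{name}.bias", np.zeros(out_channels)) if bias else None
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.weight] + ([self.bias] if self.bias is not None else [])

    def _out_side(self, side: int) -> int:
        return (side + 2 * self.padding - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, cin, h, w = x.shape
        if cin != self.cin:
            raise ValueError(f"expected {self.cin} input channels, got {cin}")
        p, s, k, g = self.padding, self.stride, self.k, self.groups
        ho, wo = self._out_side(h), self._out_side(w)
        if ho < 1 or wo < 1:
            raise ValueError(f"input side {h} too small for kernel {k}/stride {s}")
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        icg, ocg = self.cin // g, self.cout // g
        xg = xp.reshape(n, g, icg, *xp.shape[2:])
        wg = self.weight.value.reshape(g, ocg, icg, k, k)
        out = np.zeros((n, g, ocg, ho, wo), dtype=np.float32)
        for di in range(k):
            ei = di + (ho - 1) * s + 1
            for dj in range(k):
                ej = dj + (wo - 1) * s + 1
                xs = xg[:, :, :, di:ei:s, dj:ej:s]
                out += np.einsum("goc,ngchw->ngohw", wg[:, :, :, di, dj], xs,
                                 optimize=True)
        out = out.reshape(n, self.cout, ho, wo)
        if self.bias is not None:
            out += self.bias.value[None, :, None, None]
        if train:
            self._cache = (xg, (n, h, w, ho, wo))
        else:
            self._cache = None
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called without a train-mode forward")
        xg, (n, h, w, ho, wo) = self._cache
        p, s, k, g = self.padding, self.stride, self.k, self.groups
        icg, ocg = self.cin // g, self.cout // g
        dg = dout.reshape(n, g, ocg, ho, wo)
        wg = self.weight.value.reshape(g, ocg, icg, k, k)
        dwg = self.weight.grad.reshape(g, ocg, icg, k, k)
        dxg = np.zeros_like(xg)
        for di in range(k):
            ei = di + (ho - 1) * s + 1
            for dj in range(k):
                ej = dj + (wo - 1) * s + 1
                xs = xg[:, :, :, di:ei:s, dj:ej:s]
                dwg[:, :, :, di, dj] += np.einsum("ngohw,ngchw->goc", dg, xs,
                                                  optimize=True)
                dxg[:, :, :, di:ei:s, dj:ej:s] += np.einsum(
                    "goc,ngohw->ngchw", wg[:, :, :, di, dj], dg, optimize=True)
        if self.bias is not None:
            self.bias.grad += dout.sum(axis=(0, 2, 3))
        dxp = dxg.reshape(n, self.cin, h + 2 * p, w + 2 * p)
        return dxp[:, :, p:p + h, p:p + w] if p else dxp


class BatchNorm2d(Layer):
    """Per-channel batch normalisation over (N, H, W) with running statistics."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1,
                 *, name: str = "bn"):
        self.eps, self.momentum = eps, momentum
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def state(self) -> dict[str, np.ndarray]:
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(np.float32)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(np.float32)
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv[None, :, None, None]
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        self._cache = (xhat, inv.astype(np.float32), train)
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv, was_train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        gi = (self.gamma.value * inv)[None, :, None, None]
        if not was_train:  # running stats are constants
            return dout * gi
        n, _, h, w = dout.shape
        m = n * h * w
        sum_d = dout.sum(axis=(0, 2, 3))[None, :, None, None]
        sum_dx = (dout * xhat).sum(axis=(0, 2, 3))[None, :, None, None]
        return gi / m * (m * dout - sum_d - xhat * sum_dx)


class ChannelLayerNorm(Layer):
    """Layer norm across the channel axis at every spatial position (ConvNeXt style)."""

    def __init__(self, channels: int, eps: float = 1e-6, *, name: str = "ln"):
        self.eps = eps
        self.gamma = Parameter(f"{name}.gamma", np.ones(channels))
        self.beta = Parameter(f"{name}.beta", np.zeros(channels))
        self._cache = None

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        mu = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv
        self._cache = (xhat.astype(np.float32), inv.astype(np.float32))
        out = self.gamma.value[None, :, None, None] * xhat + self.beta.value[None, :, None, None]
        return out.astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.value[None, :, None, None]
        c = dout.shape[1]
        return inv / c * (c * dxhat
                          - dxhat.sum(axis=1, keepdims=True)
                          - xhat * (dxhat * xhat).sum(axis=1, keepdims=True))


class GELU(Layer):
    """Exact (erf-based) Gaussian error linear unit."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return (0.5 * x * (1.0 + erf(x / _SQRT2))).astype(np.float32)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / _SQRT2))
        pdf = _INV_SQRT2PI * np.exp(-0.5 * x * x)
        return (dout * (cdf + x * pdf)).astype(np.float32)


class GlobalAvgPool(Layer):
    """Spatial mean per channel: (N, C, H, W) -> (N, C)."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        return np.broadcast_to(dout[:, :, None, None] / (h * w), self._shape).astype(np.float32)


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, *, name: str = "fc",
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(f"{name}.weight",
                                trunc_normal(rng, (out_features, in_features)))
        self.bias = Parameter(f"{name}.bias", np.zeros(out_features))

    def parameters(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.value.T + self.bias.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.weight.grad += dout.T @ self._x
        self.bias.grad += dout.sum(axis=0)
        return dout @ self.weight.value


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def parameters(self) -> list[Parameter]:
        return [p for layer in self.layers for p in layer.parameters()]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class Residual(Layer):
    """Additive shortcut around a body: y = x + body(x)."""

    def __init__(self, body: Layer):
        self.body = body

    def parameters(self) -> list[Parameter]:
        return self.body.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        return x + self.body.forward(x, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout + self.body.backward(dout)
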