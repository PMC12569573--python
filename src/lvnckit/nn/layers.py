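"""Minimal numpy layers with explicit forward/backward passes.

Each layer caches what its backward pass needs during ``forward`` and
releases the gradient of its input from ``backward``; parameter gradients
accumulate into ``Parameter.grad``.  Layers are single-use per forward
(no weight sharing across calls within one step), which is all the
segmentation model requires.
"""

from __future__ import annotations

import math
from typing import Iterable

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import erf

__all__ = [
    "Parameter",
    "Layer",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "GELU",
    "MaxPool2x2",
    "UpsampleNearest2x",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "Sequential",
]


class Parameter:
    """A trainable tensor and its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.name = name

    @property
    def size(self) -> int:
        return self.data.size

    def zero_grad(self) -> None:
        self.grad.fill(0.0)


class Layer:
    """Base layer: override forward/backward; list parameters."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for value in self.__dict__.values():
            if isinstance(value, Parameter):
                params.append(value)
            elif isinstance(value, Layer):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Layer):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return self.forward(x, train)


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), shape)


class Conv2d(Layer):
    """3x3 (or kxk) same-padding convolution, stride 1, via im2col."""

    def __init__(
        self,
        in_ch: int,
        out_ch: int,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.kernel = kernel
        self.in_ch = in_ch
        self.out_ch = out_ch
        fan_in = in_ch * kernel * kernel
        self.weight = Parameter(_kaiming(rng, (out_ch, fan_in), fan_in), "conv.w")
        self.bias = Parameter(np.zeros(out_ch), "conv.b")
        self._cols: np.ndarray | None = None
        self._x_shape: tuple[int, ...] | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        k = self.kernel
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        # (B, C, H, W, k, k) -> (B*H*W, C*k*k)
        windows = sliding_window_view(xp, (k, k), axis=(2, 3))
        cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(b * h * w, c * k * k)
        out = cols @ self.weight.data.T + self.bias.data
        self._cols = cols if train else None
        self._x_shape = x.shape
        return out.reshape(b, h, w, self.out_ch).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, h, w = dout.shape
        k = self.kernel
        p = k // 2
        c = self.in_ch
        dflat = dout.transpose(0, 2, 3, 1).reshape(b * h * w, self.out_ch)
        self.weight.grad += dflat.T @ self._cols
        self.bias.grad += dflat.sum(axis=0)
        dcols = (dflat @ self.weight.data).reshape(b, h, w, c, k, k)
        dcols = dcols.transpose(0, 3, 1, 2, 4, 5)  # (B, C, H, W, k, k)
        dxp = np.zeros((b, c, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
        self._cols = None
        return dxp[:, :, p : p + h, p : p + w]


class BatchNorm2d(Layer):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(channels), "bn.gamma")
        self.beta = Parameter(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.gamma.data[None, :, None, None]
        b = self.beta.data[None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mean
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var + self.momentum * var
            )
            inv_std = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
            self._cache = (xhat, inv_std)
            return g * xhat + b
        inv_std = 1.0 / np.sqrt(self.running_var + self.eps)
        xhat = (x - self.running_mean[None, :, None, None]) * inv_std[
            None, :, None, None
        ]
        self._cache = (xhat, inv_std)
        return g * xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        n = dout.shape[0] * dout.shape[2] * dout.shape[3]
        self.gamma.grad += (dout * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dout.sum(axis=(0, 2, 3))
        dxhat = dout * self.gamma.data[None, :, None, None]
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        ) * inv_std[None, :, None, None]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class GELU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return 0.5 * x * (1.0 + erf(x / math.sqrt(2.0)))

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        cdf = 0.5 * (1.0 + erf(x / math.sqrt(2.0)))
        pdf = np.exp(-0.5 * x * x) / math.sqrt(2.0 * math.pi)
        return dout * (cdf + x * pdf)


class MaxPool2x2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, c, h, w = x.shape
        xr = x.reshape(b, c, h // 2, 2, w // 2, 2)
        out = xr.max(axis=(3, 5))
        self._mask = xr == out[:, :, :, None, :, None]
        # break ties: keep only the first maximal element per window
        flat = self._mask.transpose(0, 1, 2, 4, 3, 5).reshape(b, c, h // 2, w // 2, 4)
        first = np.cumsum(flat, axis=-1) == 1
        self._mask = (flat & first).reshape(b, c, h // 2, w // 2, 2, 2).transpose(
            0, 1, 2, 4, 3, 5
        )
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h2, w2 = dout.shape
        dx = self._mask * dout[:, :, :, None, :, None]
        return dx.reshape(b, c, h2 * 2, w2 * 2)


class UpsampleNearest2x(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, c, h, w = dout.shape
        return dout.reshape(b, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class Linear(Layer):
    def __init__(
        self, in_dim: int, out_dim: int, rng: np.random.Generator | None = None
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(
            rng.normal(0.0, math.sqrt(1.0 / in_dim), (in_dim, out_dim)), "lin.w"
        )
        self.bias = Parameter(np.zeros(out_dim), "lin.b")

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.weight.data + self.bias.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        d2 = dout.reshape(-1, dout.shape[-1])
        self.weight.grad += x2.T @ d2
        self.bias.grad += d2.sum(axis=0)
        self._x = None
        return dout @ self.weight.data.T


class LayerNorm(Layer):
    def __init__(self, dim: int, eps: float = 1e-5) -> None:
        self.gamma = Parameter(np.ones(dim), "ln.gamma")
        self.beta = Parameter(np.zeros(dim), "ln.beta")
        self.eps = eps

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        mean = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.data * xhat + self.beta.data

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self.gamma.grad += (dout * xhat).reshape(-1, xhat.shape[-1]).sum(axis=0)
        self.beta.grad += dout.reshape(-1, dout.shape[-1]).sum(axis=0)
        dxhat = dout * self.gamma.data
        dx = (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        ) * inv_std
        self._cache = None
        return dx


class MultiHeadSelfAttention(Layer):
    """Standard scaled dot-product self-attention over (B, N, D) tokens."""

    def __init__(
        self, dim: int, heads: int, rng: np.random.Generator | None = None
    ) -> None:
        if dim % heads != 0:
            raise ValueError("embedding width must be divisible by head count")
        rng = rng or np.random.default_rng(0)
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        b, n, d = x.shape
        h, hd = self.heads, self.head_dim
        qkv = self.qkv.forward(x, train).reshape(b, n, 3, h, hd)
        q = qkv[:, :, 0].transpose(0, 2, 1, 3)  # (B, H, N, hd)
        k = qkv[:, :, 1].transpose(0, 2, 1, 3)
        v = qkv[:, :, 2].transpose(0, 2, 1, 3)
        scale = 1.0 / math.sqrt(hd)
        scores = (q @ k.transpose(0, 1, 3, 2)) * scale
        scores -= scores.max(axis=-1, keepdims=True)
        attn = np.exp(scores)
        attn /= attn.sum(axis=-1, keepdims=True)
        ctx = attn @ v  # (B, H, N, hd)
        out = ctx.transpose(0, 2, 1, 3).reshape(b, n, d)
        self._cache = (q, k, v, attn, scale)
        return self.proj.forward(out, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        q, k, v, attn, scale = self._cache
        b, h, n, hd = q.shape
        dctx_flat = self.proj.backward(dout)
        dctx = dctx_flat.reshape(b, n, h, hd).transpose(0, 2, 1, 3)
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn.transpose(0, 1, 3, 2) @ dctx
        # softmax backward
        dscores = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
        dscores *= scale
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dqkv = np.empty((b, n, 3, h, hd))
        dqkv[:, :, 0] = dq.transpose(0, 2, 1, 3)
        dqkv[:, :, 1] = dk.transpose(0, 2, 1, 3)
        dqkv[:, :, 2] = dv.transpose(0, 2, 1, 3)
        self._cache = None
        return self.qkv.backward(dqkv.reshape(b, n, 3 * self.dim))


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


def n_parameters(params: Iterable[Parameter]) -> int:
    return sum(p.size for p in params)
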