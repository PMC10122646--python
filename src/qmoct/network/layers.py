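"""Minimal numpy layers with explicit forward/backward passes.

Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, features) for dense layers.  Every layer exposes
``forward(x, training)``, ``backward(grad)`` returning the gradient with
respect to its input, and ``params()`` yielding :class:`Param` objects.
Gradients accumulate into ``Param.grad`` and are consumed by the Adam
optimizer in :mod:`qmoct.network.train`.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm1d",
    "ReLU",
    "AvgPool1d",
    "Flatten",
    "Dense",
    "Dropout",
    "LayerNorm",
    "Sigmoid",
    "ConvBlock",
]

DTYPE = np.float32


class Param:
    """A trainable tensor and its gradient accumulator."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = "") -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name


class Layer:
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []


class Conv1d(Layer):
    """Same-padded 1-D convolution with odd kernel size, stride 1."""

    def __init__(self, c_in: int, c_out: int, kernel: int,
                 rng: np.random.Generator) -> None:
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (c_in * kernel))  # He initialisation
        self.w = Param(rng.normal(0.0, scale, size=(c_out, c_in, kernel)), "conv.w")
        self.b = Param(np.zeros(c_out), "conv.b")
        self._windows: np.ndarray | None = None
        self._in_len = 0

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        self._in_len = x.shape[2]
        xp = np.pad(x, ((0, 0), (0, 0), (self.pad, self.pad)))
        # windows: (B, C_in, L, K)
        win = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=2)
        self._windows = win if training else None
        out = np.einsum("bclk,ock->bol", win, self.w.value, optimize=True)
        return out + self.b.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        win = self._windows
        if win is None:
            raise RuntimeError("backward called without a training forward pass")
        grad = np.ascontiguousarray(grad, dtype=DTYPE)
        self.w.grad += np.einsum("bol,bclk->ock", grad, win, optimize=True)
        self.b.grad += grad.sum(axis=(0, 2))
        # full correlation of grad with the flipped kernel gives d/dx
        k = self.kernel
        gp = np.pad(grad, ((0, 0), (0, 0), (k - 1, k - 1)))
        gwin = np.lib.stride_tricks.sliding_window_view(gp, k, axis=2)
        wflip = self.w.value[:, :, ::-1]
        dxp = np.einsum("bolk,ock->bcl", gwin, wflip, optimize=True)
        return dxp[:, :, self.pad: self.pad + self._in_len]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm1d(Layer):
    """Per-channel batch normalisation over (batch, length)."""

    def __init__(self, channels: int, momentum: float = 0.9,
                 eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels), "bn.gamma")
        self.beta = Param(np.zeros(channels), "bn.beta")
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (self.momentum * self.running_mean
                                 + (1 - self.momentum) * mean).astype(DTYPE)
            self.running_var = (self.momentum * self.running_var
                                + (1 - self.momentum) * var).astype(DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None]) * inv_std[None, :, None]
        if training:
            self._cache = (xhat, inv_std, x.shape[0] * x.shape[2])
        return self.gamma.value[None, :, None] * xhat + self.beta.value[None, :, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std, m = self._cache
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2))
        self.beta.grad += grad.sum(axis=(0, 2))
        g = grad * self.gamma.value[None, :, None]
        # standard batch-norm backward, reduced over batch and length
        sum_g = g.sum(axis=(0, 2), keepdims=True)
        sum_gx = (g * xhat).sum(axis=(0, 2), keepdims=True)
        return (inv_std[None, :, None] / m) * (m * g - sum_g - xhat * sum_gx)

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0)


class AvgPool1d(Layer):
    """Non-overlapping average pooling along the length axis."""

    def __init__(self, factor: int = 2) -> None:
        if factor < 1:
            raise ValueError("pool factor must be >= 1")
        self.factor = factor

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        b, c, l = x.shape
        if l % self.factor:
            raise ValueError(f"length {l} not divisible by pool factor {self.factor}")
        return x.reshape(b, c, l // self.factor, self.factor).mean(axis=3)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.repeat(grad, self.factor, axis=2) / self.factor


class Flatten(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator) -> None:
        scale = np.sqrt(2.0 / n_in)
        self.w = Param(rng.normal(0.0, scale, size=(n_in, n_out)), "dense.w")
        self.b = Param(np.zeros(n_out), "dense.b")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x if training else None
        return x @ self.w.value + self.b.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        grad = grad.astype(DTYPE, copy=False)
        self.w.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator) -> None:
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad if self._mask is None else grad * self._mask


class LayerNorm(Layer):
    """Normalisation over the feature axis of a (batch, features) tensor."""

    def __init__(self, n_features: int, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(n_features), "ln.gamma")
        self.beta = Param(np.zeros(n_features), "ln.beta")
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        mean = x.mean(axis=1, keepdims=True)
        var = x.var(axis=1, keepdims=True)
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean) * self._inv_std
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._xhat, self._inv_std
        n = xhat.shape[1]
        self.gamma.grad += (grad * xhat).sum(axis=0)
        self.beta.grad += grad.sum(axis=0)
        g = grad * self.gamma.value
        return (inv_std / n) * (
            n * g - g.sum(axis=1, keepdims=True)
            - xhat * (g * xhat).sum(axis=1, keepdims=True)
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class Sigmoid(Layer):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-x))
        return self._y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad * self._y * (1.0 - self._y)


class ConvBlock(Layer):
    """Convolutional block with an alpha-gated residual connection.

    ``n_convs`` (convolution -> batch norm -> ReLU) stages followed by
    average pooling form the main path; the block input, projected by a
    1x1 convolution when the channel count changes and pooled, forms the
    skip path.  The output is the convex combination
    ``alpha * main + (1 - alpha) * skip`` with a learnable scalar gate
    per block.
    """

    def __init__(self, c_in: int, c_out: int, n_convs: int, kernel: int,
                 rng: np.random.Generator, pool: int = 2,
                 alpha_init: float = 0.5) -> None:
        self.stages: list[list[Layer]] = []
        c = c_in
        for _ in range(n_convs):
            self.stages.append([Conv1d(c, c_out, kernel, rng),
                                BatchNorm1d(c_out), ReLU()])
            c = c_out
        self.pool_main = AvgPool1d(pool)
        self.pool_skip = AvgPool1d(pool)
        self.proj = Conv1d(c_in, c_out, 1, rng) if c_in != c_out else None
        self.alpha = Param(np.array(alpha_init), "block.alpha")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        h = x
        for conv, bn, act in self.stages:
            h = act.forward(bn.forward(conv.forward(h, training), training), training)
        main = self.pool_main.forward(h, training)
        skip = x if self.proj is None else self.proj.forward(x, training)
        skip = self.pool_skip.forward(skip, training)
        a = float(self.alpha.value)
        self._main, self._skip = main, skip
        return a * main + (1.0 - a) * skip

    def backward(self, grad: np.ndarray) -> np.ndarray:
        a = float(self.alpha.value)
        self.alpha.grad += np.sum(grad * (self._main - self._skip)).astype(DTYPE)
        g_skip = self.pool_skip.backward((1.0 - a) * grad)
        if self.proj is not None:
            g_skip = self.proj.backward(g_skip)
        g = self.pool_main.backward(a * grad)
        for conv, bn, act in reversed(self.stages):
            g = conv.backward(bn.backward(act.backward(g)))
        return g + g_skip

    def params(self) -> list[Param]:
        out = [self.alpha]
        for conv, bn, _ in self.stages:
            out += conv.params() + bn.params()
        if self.proj is not None:
            out += self.proj.params()
        return out
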