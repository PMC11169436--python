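"""Minimal NumPy neural-network layers with explicit gradients.

Just enough machinery for the desk-scale reference backbone and the
metric-learning head: im2col convolution, batch norm, ReLU, average
pooling, linear layers, an L2-normalization layer, momentum SGD with
weight decay, an optional sharpness-aware two-step wrapper, and a cosine
learning-rate schedule.  Layers expose ``forward(x, train)`` /
``backward(dout)`` and accumulate gradients on their parameters.
Feature maps are NHWC (channel-last): no transposes in the hot path.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "Sequential",
    "Conv2d",
    "BatchNorm",
    "ReLU",
    "AvgPool2d",
    "GlobalAvgPool",
    "Linear",
    "L2Normalize",
    "SGD",
    "SAMWrapper",
    "cosine_lr",
]


class Param:
    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay  # weight decay applies (skipped for BN/bias)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def forward(self, x, train):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


def _im2col(x: np.ndarray, k: int, pad: int) -> np.ndarray:
    """(N, H, W, C) -> (N, H, W, k*k*C) patches for a stride-1 k x k conv."""
    n, h, w, c = x.shape
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    s = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, h, w, k, k, c),
        strides=(s[0], s[1], s[2], s[1], s[2], s[3]),
        writeable=False,
    )
    return windows.reshape(n, h, w, k * k * c)


class Conv2d(Layer):
    """3x3 (or k x k) stride-1 'same' convolution via im2col, NHWC layout."""

    def __init__(self, c_in: int, c_out: int, k: int, rng: np.random.Generator):
        self.c_in, self.c_out, self.k = c_in, c_out, k
        fan_in = c_in * k * k
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, c_out)).astype(np.float32))
        self.b = Param(np.zeros(c_out, dtype=np.float32), decay=False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._shape = x.shape
        self._cols = _im2col(x, self.k, self.k // 2)  # (N, H, W, fan_in)
        return self._cols @ self.W.value + self.b.value  # (N, H, W, c_out)

    def backward(self, dout):
        n, h, w, _ = self._shape
        cols2d = self._cols.reshape(-1, self.k * self.k * self.c_in)
        d2d = dout.reshape(-1, self.c_out)
        self.W.grad += cols2d.T @ d2d
        self.b.grad += d2d.sum(axis=0)
        dcols = (d2d @ self.W.value.T).reshape(n, h, w, self.k, self.k, self.c_in)
        # scatter-add patches back (col2im)
        pad = self.k // 2
        dx = np.zeros((n, h + 2 * pad, w + 2 * pad, self.c_in), dtype=dout.dtype)
        for i in range(self.k):
            for j in range(self.k):
                dx[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        return dx[:, pad : pad + h, pad : pad + w, :]


class BatchNorm(Layer):
    """Batch normalization over all axes except the channel axis.

    Works for (N, H, W, C) feature maps and (N, D) vectors (channel last).
    Training uses batch statistics and updates running averages; eval
    uses the running averages, making inference batch-size independent.
    """

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5, ndim: int = 4):
        self.gamma = Param(np.ones(c, dtype=np.float32), decay=False)
        self.beta = Param(np.zeros(c, dtype=np.float32), decay=False)
        self.momentum, self.eps, self.ndim = momentum, eps, ndim
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def params(self):
        return [self.gamma, self.beta]

    def _axes(self):
        return (0, 1, 2) if self.ndim == 4 else (0,)

    def _bshape(self):
        return (1, 1, 1, -1) if self.ndim == 4 else (1, -1)

    def forward(self, x, train):
        axes, bs = self._axes(), self._bshape()
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps)
        self._xhat = (x - mean.reshape(bs)) / self._std.reshape(bs)
        self._m = x.size // x.shape[-1 if self.ndim == 4 else 1]
        self._train = train
        return self.gamma.value.reshape(bs) * self._xhat + self.beta.value.reshape(bs)

    def backward(self, dout):
        axes, bs = self._axes(), self._bshape()
        self.gamma.grad += (dout * self._xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        dxhat = dout * self.gamma.value.reshape(bs)
        if not self._train:
            return dxhat / self._std.reshape(bs)
        m = self._m
        term = (
            dxhat
            - dxhat.mean(axis=axes).reshape(bs)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes).reshape(bs)
        )
        return term / self._std.reshape(bs)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class AvgPool2d(Layer):
    """Non-overlapping f x f average pooling (dims must be divisible by f)."""

    def __init__(self, f: int):
        self.f = f

    def forward(self, x, train):
        n, h, w, c = x.shape
        f = self.f
        self._shape = x.shape
        return x.reshape(n, h // f, f, w // f, f, c).mean(axis=(2, 4))

    def backward(self, dout):
        n, h, w, c = self._shape
        f = self.f
        d = dout[:, :, None, :, None, :] / (f * f)
        return np.broadcast_to(d, (n, h // f, f, w // f, f, c)).reshape(n, h, w, c)


class GlobalAvgPool(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, dout):
        n, h, w, c = self._shape
        return np.broadcast_to(dout[:, None, None, :] / (h * w), self._shape).copy()


class Linear(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator):
        self.W = Param(rng.normal(0.0, np.sqrt(2.0 / d_in), size=(d_in, d_out)).astype(np.float32))
        self.b = Param(np.zeros(d_out, dtype=np.float32), decay=False)

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class L2Normalize(Layer):
    """Row-wise y = x / ||x||; gradient projects out the radial component."""

    def __init__(self, eps: float = 1e-12):
        self.eps = eps

    def forward(self, x, train):
        self._norm = np.linalg.norm(x, axis=1, keepdims=True) + self.eps
        self._y = x / self._norm
        return self._y

    def backward(self, dout):
        radial = (dout * self._y).sum(axis=1, keepdims=True)
        return (dout - self._y * radial) / self._norm


class SGD:
    """Momentum SGD with decoupled-style weight decay (added to the gradient)."""

    def __init__(self, params: list[Param], lr: float, momentum: float = 0.8, weight_decay: float = 0.002):
        self.params = params
        self.lr, self.momentum, self.weight_decay = lr, momentum, weight_decay
        self._vel = [np.zeros_like(p.value) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad[...] = 0.0

    def step(self):
        for p, v in zip(self.params, self._vel):
            g = p.grad + (self.weight_decay * p.value if p.decay else 0.0)
            v *= self.momentum
            v += g
            p.value -= self.lr * v


class SAMWrapper:
    """Generic two-step sharpness-aware update around a base optimizer.

    Step A: perturb each parameter by rho * g / ||g|| (global grad norm);
    the caller recomputes gradients at the perturbed point.  Step B:
    restore the parameters and take the base optimizer step with the
    perturbed-point gradients.
    """

    def __init__(self, base: SGD, rho: float = 2.0):
        self.base = base
        self.rho = rho
        self._saved: list[np.ndarray] | None = None

    def zero_grad(self):
        self.base.zero_grad()

    def first_step(self):
        gnorm = np.sqrt(sum(float((p.grad**2).sum()) for p in self.base.params)) + 1e-12
        self._saved = [p.value.copy() for p in self.base.params]
        for p in self.base.params:
            p.value += self.rho * p.grad / gnorm
        self.base.zero_grad()

    def second_step(self):
        assert self._saved is not None, "first_step must precede second_step"
        for p, saved in zip(self.base.params, self._saved):
            p.value[...] = saved
        self._saved = None
        self.base.step()


def cosine_lr(step: int, total_steps: int, lr_init: float, lr_final: float) -> float:
    """Cosine decay from lr_init to lr_final over total_steps, no warmup."""
    if total_steps <= 1:
        return lr_final
    t = min(step, total_steps - 1) / (total_steps - 1)
    return lr_final + 0.5 * (lr_init - lr_final) * (1.0 + np.cos(np.pi * t))
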