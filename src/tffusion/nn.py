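"""Minimal NumPy neural-network layers with hand-written backpropagation.

Everything here operates on float64 arrays. Convolutional inputs are laid
out ``(N, C, T)`` (batch, channels, time); dense inputs are ``(N, F)``.
Each layer caches what its backward pass needs during ``forward`` and
accumulates parameter gradients in :class:`Param` objects. Training is
driven by :class:`Adam`.

Gradient correctness for every layer is pinned against central finite
differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Param",
    "Layer",
    "Conv1d",
    "BatchNorm",
    "ReLU",
    "Dropout",
    "GlobalAvgPool1d",
    "Dense",
    "Sequential",
    "ResidualBlock1d",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Param:
    """A trainable tensor with an accumulated gradient."""

    __slots__ = ("value", "grad", "name")

    def __init__(self, value: np.ndarray, name: str = ""):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)
        self.name = name

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


class Layer:
    """Base class; subclasses implement forward/backward and list params."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1d(Layer):
    """1-D convolution (stride 1, 'same' zero padding, odd kernel width)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        if kernel_size % 2 != 1:
            raise ValueError("kernel_size must be odd for 'same' padding")
        fan_in = in_channels * kernel_size
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                       size=(out_channels, in_channels, kernel_size))
        self.W = Param(w, "conv.W")
        self.b = Param(np.zeros(out_channels), "conv.b")
        self.kernel_size = kernel_size
        self._cache = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        k = self.kernel_size
        pad = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (pad, pad)))
        view = sliding_window_view(xp, k, axis=2)  # (N, Cin, T, k)
        out = np.einsum("nctk,ock->not", view, self.W.value, optimize=True)
        out += self.b.value[None, :, None]
        self._cache = view
        return out

    def backward(self, dout):
        view = self._cache
        k = self.kernel_size
        pad = k // 2
        self.W.grad += np.einsum("nctk,not->ock", view, dout, optimize=True)
        self.b.grad += dout.sum(axis=(0, 2))
        # dx is the 'full' correlation of dout with the flipped kernel
        dp = np.pad(dout, ((0, 0), (0, 0), (pad, pad)))
        dview = sliding_window_view(dp, k, axis=2)  # (N, Cout, T, k)
        wflip = self.W.value[:, :, ::-1]
        dx = np.einsum("notk,ock->nct", dview, wflip, optimize=True)
        return dx


class BatchNorm(Layer):
    """Batch normalisation over the batch (and time, for 3-D inputs) axes.

    Running statistics (momentum 0.9) are used in evaluation mode.
    """

    def __init__(self, n_features: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(n_features), "bn.gamma")
        self.beta = Param(np.zeros(n_features), "bn.beta")
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def params(self):
        return [self.gamma, self.beta]

    @staticmethod
    def _axes(x):
        return (0,) if x.ndim == 2 else (0, 2)

    def _expand(self, v, ndim):
        return v[None, :] if ndim == 2 else v[None, :, None]

    def forward(self, x, train=False):
        axes = self._axes(x)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mean
            self.running_var = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - self._expand(mean, x.ndim)) * self._expand(inv, x.ndim)
        out = self._expand(self.gamma.value, x.ndim) * xhat + self._expand(self.beta.value, x.ndim)
        self._cache = (xhat, inv, axes, x.ndim, train)
        return out

    def backward(self, dout):
        xhat, inv, axes, ndim, train = self._cache
        self.gamma.grad += (dout * xhat).sum(axis=axes)
        self.beta.grad += dout.sum(axis=axes)
        g = self._expand(self.gamma.value, ndim)
        dxhat = dout * g
        if not train:
            return dxhat * self._expand(inv, ndim)
        m = np.prod([xhat.shape[a] for a in axes])
        t1 = dxhat
        t2 = self._expand(dxhat.sum(axis=axes), ndim) / m
        t3 = xhat * self._expand((dxhat * xhat).sum(axis=axes), ndim) / m
        return (t1 - t2 - t3) * self._expand(inv, ndim)


class ReLU(Layer):
    def __init__(self):
        self._mask = None

    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout):
        return dout * self._mask


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode. Seeded via ``rng``."""

    def __init__(self, p: float, rng: np.random.Generator):
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask


class GlobalAvgPool1d(Layer):
    """Adaptive average pooling to a single output bin: (N, C, T) -> (N, C).

    Because the output length is fixed (one bin), any input length T is
    mapped to the same feature size, which is what lets one encoder accept
    windows of different lengths.
    """

    def __init__(self):
        self._T = None

    def forward(self, x, train=False):
        self._T = x.shape[2]
        return x.mean(axis=2)

    def backward(self, dout):
        T = self._T
        return np.repeat(dout[:, :, None], T, axis=2) / T


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        w = rng.normal(0.0, np.sqrt(2.0 / in_features), size=(in_features, out_features))
        self.W = Param(w, "dense.W")
        self.b = Param(np.zeros(out_features), "dense.b")
        self._x = None

    def params(self):
        return [self.W, self.b]

    def forward(self, x, train=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dout):
        self.W.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.W.value.T


class Sequential(Layer):
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)

    def params(self):
        out = []
        for layer in self.layers:
            out.extend(layer.params())
        return out

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


class ResidualBlock1d(Layer):
    """conv-BN-ReLU-conv-BN plus an identity/1x1-projection shortcut, then ReLU."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator):
        self.conv1 = Conv1d(in_channels, out_channels, kernel_size, rng)
        self.bn1 = BatchNorm(out_channels)
        self.relu1 = ReLU()
        self.conv2 = Conv1d(out_channels, out_channels, kernel_size, rng)
        self.bn2 = BatchNorm(out_channels)
        if in_channels != out_channels:
            self.shortcut: Sequential | None = Sequential(
                [Conv1d(in_channels, out_channels, 1, rng), BatchNorm(out_channels)]
            )
        else:
            self.shortcut = None
        self.relu_out = ReLU()

    def params(self):
        out = self.conv1.params() + self.bn1.params() + self.conv2.params() + self.bn2.params()
        if self.shortcut is not None:
            out += self.shortcut.params()
        return out

    def forward(self, x, train=False):
        h = self.conv1.forward(x, train)
        h = self.bn1.forward(h, train)
        h = self.relu1.forward(h, train)
        h = self.conv2.forward(h, train)
        h = self.bn2.forward(h, train)
        s = x if self.shortcut is None else self.shortcut.forward(x, train)
        return self.relu_out.forward(h + s, train)

    def backward(self, dout):
        d = self.relu_out.backward(dout)
        dh = self.bn2.backward(d)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dh = self.bn1.backward(dh)
        dh = self.conv1.backward(dh)
        ds = d if self.shortcut is None else self.shortcut.backward(d)
        return dh + ds


class Adam:
    """Adam optimiser; L2 penalty ``l2 * sum(w^2)`` is folded into the grads."""

    def __init__(self, params: list[Param], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.99),
                 eps: float = 1e-8, l2: float = 0.0):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.l2 = l2
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            g = p.grad
            if self.l2 > 0.0:
                g = g + 2.0 * self.l2 * p.value
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy of integer ``labels`` under softmax(logits).

    Returns ``(loss, dlogits)``.
    """
    n = logits.shape[0]
    p = softmax(logits)
    eps = 1e-12
    loss = -np.log(p[np.arange(n), labels] + eps).mean()
    d = p.copy()
    d[np.arange(n), labels] -= 1.0
    return loss, d / n
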