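"""Compact numpy CNN engine: layers, im2col convolution, and Adam.

All tensors are channel-first ``(C, H, W)`` float64 arrays, one image at a
time (the training protocol uses mini-batches of size 1).  Every layer owns
its parameter arrays and a parallel list of gradient accumulators; a forward
pass caches what the matching backward pass needs.  Parameter arrays are
updated in place by :class:`Adam` so that external references (e.g. a
checkpointed parameter list) stay live.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer",
    "Conv2d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "ChannelSoftmax",
    "Upsample2",
    "Sequential",
    "Adam",
]


class Layer:
    """Base class: a differentiable operator with (possibly zero) parameters."""

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def zero_grad(self) -> None:
        for g in self.grads():
            g[...] = 0.0

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


def _im2col(x: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(C, Hp, Wp) -> (C*k*k, Ho*Wo) patch matrix."""
    c, hp, wp = x.shape
    ho = (hp - k) // stride + 1
    wo = (wp - k) // stride + 1
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (C, Ho, Wo, k, k)
    cols = win.transpose(0, 3, 4, 1, 2).reshape(c * k * k, ho * wo)
    return np.ascontiguousarray(cols)


def _col2im(dcols: np.ndarray, c: int, k: int, stride: int,
            hp: int, wp: int, ho: int, wo: int) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patch gradients."""
    dpad = np.zeros((c, hp, wp))
    d = dcols.reshape(c, k, k, ho, wo)
    for i in range(k):
        for j in range(k):
            dpad[:, i:i + stride * ho:stride, j:j + stride * wo:stride] += d[:, i, j]
    return dpad


class Conv2d(Layer):
    """2-D convolution (cross-correlation) with zero padding.

    Weight shape ``(out_c, in_c, k, k)``, bias ``(out_c,)``.
    """

    def __init__(self, in_c: int, out_c: int, k: int, stride: int = 1,
                 pad: int | None = None, init_std: float | str = "he",
                 rng: np.random.Generator | None = None):
        self.in_c, self.out_c, self.k, self.stride = in_c, out_c, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = in_c * k * k
        std = np.sqrt(2.0 / fan_in) if init_std == "he" else float(init_std)
        self.W = rng.normal(0.0, std, size=(out_c, in_c, k, k)) if std > 0 \
            else np.zeros((out_c, in_c, k, k))
        self.b = np.zeros(out_c)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cache: tuple | None = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.dW, self.db]

    def forward(self, x):
        c, h, w = x.shape
        if c != self.in_c:
            raise ValueError(f"expected {self.in_c} input channels, got {c}")
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (self.pad, self.pad)))
        hp, wp = xp.shape[1:]
        ho = (hp - self.k) // self.stride + 1
        wo = (wp - self.k) // self.stride + 1
        cols = _im2col(xp, self.k, self.stride)
        out = self.W.reshape(self.out_c, -1) @ cols + self.b[:, None]
        self._cache = (cols, hp, wp, ho, wo)
        return out.reshape(self.out_c, ho, wo)

    def backward(self, dout):
        cols, hp, wp, ho, wo = self._cache
        d2 = dout.reshape(self.out_c, -1)
        self.dW += (d2 @ cols.T).reshape(self.W.shape)
        self.db += d2.sum(axis=1)
        dcols = self.W.reshape(self.out_c, -1).T @ d2
        dpad = _col2im(dcols, self.in_c, self.k, self.stride, hp, wp, ho, wo)
        if self.pad:
            return dpad[:, self.pad:-self.pad, self.pad:-self.pad]
        return dpad


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha
        self._mask = None

    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dout):
        return np.where(self._mask, dout, self.alpha * dout)


class ReLU(LeakyReLU):
    def __init__(self):
        super().__init__(alpha=0.0)


class Sigmoid(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x):
        self._out = 1.0 / (1.0 + np.exp(-x))
        return self._out

    def backward(self, dout):
        return dout * self._out * (1.0 - self._out)


class ChannelSoftmax(Layer):
    """Per-pixel softmax over the channel axis of a (C, H, W) map."""

    def __init__(self):
        self._out = None

    def forward(self, x):
        z = x - x.max(axis=0, keepdims=True)
        e = np.exp(z)
        self._out = e / e.sum(axis=0, keepdims=True)
        return self._out

    def backward(self, dout):
        p = self._out
        dot = (dout * p).sum(axis=0, keepdims=True)
        return p * (dout - dot)


class Upsample2(Layer):
    """Nearest-neighbour 2x upsampling."""

    def forward(self, x):
        return np.repeat(np.repeat(x, 2, axis=1), 2, axis=2)

    def backward(self, dout):
        c, h, w = dout.shape
        return dout.reshape(c, h // 2, 2, w // 2, 2).sum(axis=(2, 4))


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for l in self.layers for p in l.params()]

    def grads(self):
        return [g for l in self.layers for g in l.grads()]

    def forward(self, x):
        for l in self.layers:
            x = l.forward(x)
        return x

    def backward(self, dout):
        for l in reversed(self.layers):
            dout = l.backward(dout)
        return dout


class Adam(Layer):
    """Adam with L2 weight decay folded into the gradient.

    Updates parameter arrays in place; moment buffers are keyed by position.
    """

    def __init__(self, params: list[np.ndarray], lr: float = 2e-4,
                 beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self._params = params
        self.lr, self.beta1, self.beta2 = lr, beta1, beta2
        self.eps, self.weight_decay = eps, weight_decay
        self.t = 0
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self._params, grads, self.m, self.v):
            if self.weight_decay:
                g = g + self.weight_decay * p
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
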