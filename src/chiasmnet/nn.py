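"""Minimal numpy neural-network layers with exact backpropagation.

Kept deliberately small: just what the encoder/decoder/head architectures
need on 24x24x8 patches (3-D convolution via im2col, ELU, dense layers,
nearest-neighbour upsampling) plus an Adam optimizer and the two losses.
Everything runs in float64 so gradient checks against central finite
differences are meaningful, and all initialization is driven by an explicit
``numpy.random.Generator`` for bitwise reproducibility.

The backward pass propagates gradients all the way to the *input* tensor;
attribution methods rely on that.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3d",
    "Dense",
    "ELU",
    "Identity",
    "Sigmoid",
    "Flatten",
    "Reshape",
    "Upsample3d",
    "Sequential",
    "Adam",
    "mse_loss",
    "bce_loss",
]


class Layer:
    """A differentiable computation node with optional parameters."""

    params: list  # list of ndarrays, updated in place by the optimizer
    grads: list  # matching list of gradient accumulators

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, grad_out: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv3d(Layer):
    """3-D convolution (cross-correlation), 'same'-capable via explicit padding.

    Input/output layout: (N, C, D, H, W).
    """

    def __init__(self, c_in, c_out, kernel=3, stride=1, pad=0, rng=None):
        super().__init__()
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd")
        rng = rng if rng is not None else np.random.default_rng(0)
        fan_in = c_in * kernel**3
        # He initialization, appropriate for ELU-family nonlinearities
        self.W = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(c_out, c_in, kernel, kernel, kernel))
        self.b = np.zeros(c_out)
        self.kernel, self.stride, self.pad = kernel, stride, pad
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        k, s, p = self.kernel, self.stride, self.pad
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        # win: (N, C, Do, Ho, Wo, k, k, k)
        self._win = win
        self._x_shape = x.shape
        out = np.tensordot(win, self.W, axes=([1, 5, 6, 7], [1, 2, 3, 4]))
        # out: (N, Do, Ho, Wo, c_out) -> (N, c_out, Do, Ho, Wo)
        out = np.moveaxis(out, -1, 1)
        return out + self.b[None, :, None, None, None]

    def backward(self, grad_out):
        k, s, p = self.kernel, self.stride, self.pad
        win = self._win
        n, c, d, h, w = self._x_shape
        do, ho, wo = grad_out.shape[2:]
        self.grads[0] += np.tensordot(grad_out, win, axes=([0, 2, 3, 4], [0, 2, 3, 4]))
        self.grads[1] += grad_out.sum(axis=(0, 2, 3, 4))
        # grad wrt im2col windows: (N, Do, Ho, Wo, C, k, k, k)
        gwin = np.tensordot(np.moveaxis(grad_out, 1, -1), self.W, axes=([4], [0]))
        gx = np.zeros((n, c, d + 2 * p, h + 2 * p, w + 2 * p))
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    gx[:, :, i : i + s * do : s, j : j + s * ho : s, l : l + s * wo : s] += np.moveaxis(
                        gwin[..., i, j, l], 4, 1
                    )
        if p:
            gx = gx[:, :, p:-p, p:-p, p:-p]
        return gx


class Dense(Layer):
    def __init__(self, n_in, n_out, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.W = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.params = [self.W, self.b]
        self.grads = [np.zeros_like(self.W), np.zeros_like(self.b)]

    def forward(self, x):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad_out):
        self.grads[0] += self._x.T @ grad_out
        self.grads[1] += grad_out.sum(axis=0)
        return grad_out @ self.W.T


class ELU(Layer):
    def __init__(self, alpha=1.0):
        super().__init__()
        self.alpha = alpha

    def forward(self, x):
        y = np.where(x > 0, x, self.alpha * np.expm1(np.minimum(x, 0.0)))
        self._y = y
        self._pos = x > 0
        return y

    def backward(self, grad_out):
        return grad_out * np.where(self._pos, 1.0, self._y + self.alpha)


class Identity(Layer):
    def forward(self, x):
        return x

    def backward(self, grad_out):
        return grad_out


class Sigmoid(Layer):
    def forward(self, x):
        y = np.empty_like(x)
        pos = x >= 0
        y[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        y[~pos] = ex / (1.0 + ex)
        self._y = y
        return y

    def backward(self, grad_out):
        return grad_out * self._y * (1.0 - self._y)


class Flatten(Layer):
    def forward(self, x):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad_out):
        return grad_out.reshape(self._shape)


class Reshape(Layer):
    """Reshape (N, -1) to (N, *shape)."""

    def __init__(self, shape):
        super().__init__()
        self.shape = tuple(shape)

    def forward(self, x):
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, grad_out):
        return grad_out.reshape(grad_out.shape[0], -1)


class Upsample3d(Layer):
    """Nearest-neighbour upsampling by an integer factor per spatial axis."""

    def __init__(self, factor=2):
        super().__init__()
        self.f = int(factor)

    def forward(self, x):
        f = self.f
        return x.repeat(f, axis=2).repeat(f, axis=3).repeat(f, axis=4)

    def backward(self, grad_out):
        f = self.f
        n, c, d, h, w = grad_out.shape
        g = grad_out.reshape(n, c, d // f, f, h // f, f, w // f, f)
        return g.sum(axis=(3, 5, 7))


class Sequential(Layer):
    def __init__(self, layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad_out):
        for layer in reversed(self.layers):
            grad_out = layer.backward(grad_out)
        return grad_out

    @property
    def all_params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def all_grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def zero_grad(self):
        for g in self.all_grads:
            g[...] = 0.0

    def get_state(self):
        return [p.copy() for p in self.all_params]

    def set_state(self, state):
        for p, s in zip(self.all_params, state, strict=True):
            p[...] = s


class Adam:
    """Adaptive-moment gradient descent over a flat list of parameters."""

    def __init__(self, params, grads, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def mse_loss(pred, target):
    """Mean squared error; returns (loss, grad_wrt_pred)."""
    diff = pred - target
    return float(np.mean(diff**2)), 2.0 * diff / diff.size


def bce_loss(prob, target, eps=1e-12):
    """Binary cross entropy on probabilities; returns (loss, grad_wrt_prob)."""
    p = np.clip(prob, eps, 1.0 - eps)
    loss = float(-np.mean(target * np.log(p) + (1 - target) * np.log(1 - p)))
    grad = (p - target) / (p * (1 - p)) / p.size
    return loss, grad
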