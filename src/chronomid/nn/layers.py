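"""Minimal neural-network layers with explicit forward/backward passes.

All layers operate on channels-last arrays: images are ``(N, H, W, C)``,
flat features are ``(N, F)``. Every layer caches what its backward pass
needs during ``forward`` and releases gradients through ``backward``.

Parameters are exposed as :class:`Param` objects so a single optimizer can
walk a whole network. ``Param.regularized`` marks kernels subject to L2
weight decay (biases and batch-norm parameters are exempt).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Param:
    """A trainable (or tracked) array with its gradient buffer."""

    __slots__ = ("name", "value", "grad", "regularized", "trainable")

    def __init__(self, name, value, regularized=False, trainable=True):
        self.name = name
        self.value = value
        self.grad = np.zeros_like(value)
        self.regularized = regularized
        self.trainable = trainable

    @property
    def size(self):
        return self.value.size


class Layer:
    def params(self):
        return []

    def forward(self, x, training=False):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad):  # pragma: no cover - interface
        raise NotImplementedError


def he_normal(rng, fan_in, shape):
    """He Gaussian initialisation: N(0, sqrt(2 / fan_in))."""
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2D(Layer):
    """2-D convolution, stride 1, 'same' zero padding, channels last.

    Weights are stored as ``(k*k*C_in, C_out)`` so the forward pass is a
    single im2col matrix product.
    """

    def __init__(self, in_channels, out_channels, kernel=3, rng=None, name="conv"):
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = kernel // 2
        fan_in = kernel * kernel * in_channels
        rng = rng if rng is not None else np.random.default_rng(0)
        w = he_normal(rng, fan_in, (fan_in, out_channels))
        self.W = Param(f"{name}.W", w, regularized=True)
        self.b = Param(f"{name}.b", np.zeros(out_channels))
        self._cols = None
        self._xshape = None

    def params(self):
        return [self.W, self.b]

    def _im2col(self, x):
        k, p = self.kernel, self.pad
        n, h, w, c = x.shape
        if p:
            x = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        # (N, H, W, C, k, k) -> (N*H*W, k*k*C) matching W layout (ki, kj, C)
        win = sliding_window_view(x, (k, k), axis=(1, 2))
        cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(n * h * w, k * k * c)
        return cols

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        cols = self._im2col(x)
        out = cols @ self.W.value + self.b.value
        self._cols = cols
        self._xshape = x.shape
        return out.reshape(n, h, w, self.out_channels)

    def backward(self, grad):
        n, h, w, _ = self._xshape
        k, p, c = self.kernel, self.pad, self.in_channels
        g2 = grad.reshape(n * h * w, self.out_channels)
        self.W.grad += self._cols.T @ g2
        self.b.grad += g2.sum(axis=0)
        dcols = (g2 @ self.W.value.T).reshape(n, h, w, k, k, c)
        dxp = np.zeros((n, h + 2 * p, w + 2 * p, c))
        for i in range(k):
            for j in range(k):
                dxp[:, i : i + h, j : j + w, :] += dcols[:, :, :, i, j, :]
        self._cols = None
        if p:
            return dxp[:, p : p + h, p : p + w, :]
        return dxp


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2; odd trailing row/column is dropped."""

    def forward(self, x, training=False):
        n, h, w, c = x.shape
        ho, wo = h // 2, w // 2
        xc = x[:, : 2 * ho, : 2 * wo, :]
        xr = xc.reshape(n, ho, 2, wo, 2, c)
        out = xr.max(axis=(2, 4))
        self._mask = xr == out[:, :, None, :, None, :]
        self._xshape = x.shape
        return out

    def backward(self, grad):
        n, h, w, c = self._xshape
        ho, wo = h // 2, w // 2
        # split gradient evenly among tied maxima so it stays exact
        counts = self._mask.sum(axis=(2, 4))
        g = (grad / counts)[:, :, None, :, None, :] * self._mask
        dx = np.zeros(self._xshape)
        dx[:, : 2 * ho, : 2 * wo, :] = g.reshape(n, 2 * ho, 2 * wo, c)
        return dx


class ReLU(Layer):
    def forward(self, x, training=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, grad):
        return grad * self._mask


class BatchNorm(Layer):
    """Batch normalisation over all axes but the last (feature) axis.

    Works for both spatial ``(N, H, W, C)`` and dense ``(N, F)`` inputs.
    Moving statistics are tracked as non-trainable parameters so they are
    included in total parameter counts (4 per feature).
    """

    def __init__(self, features, momentum=0.9, eps=1e-5, name="bn"):
        self.features = features
        self.momentum = momentum
        self.eps = eps
        self.gamma = Param(f"{name}.gamma", np.ones(features))
        self.beta = Param(f"{name}.beta", np.zeros(features))
        self.moving_mean = Param(f"{name}.moving_mean", np.zeros(features), trainable=False)
        self.moving_var = Param(f"{name}.moving_var", np.ones(features), trainable=False)

    def params(self):
        return [self.gamma, self.beta, self.moving_mean, self.moving_var]

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.moving_mean.value = m * self.moving_mean.value + (1 - m) * mu
            self.moving_var.value = m * self.moving_var.value + (1 - m) * var
        else:
            mu = self.moving_mean.value
            var = self.moving_var.value
        ivstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivstd
        out = self.gamma.value * xhat + self.beta.value
        if training:
            self._cache = (xhat, ivstd, axes, x.shape)
        return out

    def backward(self, grad):
        xhat, ivstd, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).mean(axis=axes)
        ) * ivstd
        return dx


class Dropout(Layer):
    """Inverted dropout; identity outside training."""

    def __init__(self, rate, rng):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training=False):
        if not training or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dense(Layer):
    def __init__(self, in_features, out_features, rng=None, name="dense"):
        rng = rng if rng is not None else np.random.default_rng(0)
        w = he_normal(rng, in_features, (in_features, out_features))
        self.W = Param(f"{name}.W", w, regularized=True)
        self.b = Param(f"{name}.b", np.zeros(out_features))

    def params(self):
        return [self.W, self.b]

    def forward(self, x, training=False):
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, grad):
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class SoftmaxCrossEntropy:
    """Fused softmax + categorical cross-entropy (mean over the batch)."""

    def forward(self, logits, onehot):
        z = logits - logits.max(axis=1, keepdims=True)
        ez = np.exp(z)
        self.probs = ez / ez.sum(axis=1, keepdims=True)
        self._onehot = onehot
        eps = 1e-12
        return -np.mean(np.sum(onehot * np.log(self.probs + eps), axis=1))

    def backward(self):
        n = self.probs.shape[0]
        return (self.probs - self._onehot) / n


def softmax(logits):
    z = logits - logits.max(axis=1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=1, keepdims=True)
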