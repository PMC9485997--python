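"""Compact fully-connected network engine used by the physics-informed fitters.

Implements exactly the pieces the IVIM networks need — linear layers, batch
normalisation, ELU, inverted dropout, and the Adam optimiser — with manual
reverse-mode gradients in numpy.  Everything is deterministic given the
``numpy.random.Generator`` supplied at construction/training time and runs
on a single CPU thread.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Linear", "BatchNorm", "ELU", "Dropout", "Sequential", "Adam"]


class Layer:
    params: list = []
    grads: list = []

    def forward(self, x: np.ndarray, train: bool, rng) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.W = rng.normal(0.0, scale, size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.gW, self.gb]
        self._x = None

    def forward(self, x, train, rng):
        self._x = x
        return x @ self.W + self.b

    def backward(self, grad):
        self.gW[...] = self._x.T @ grad
        self.gb[...] = grad.sum(axis=0)
        return grad @ self.W.T


class BatchNorm(Layer):
    """Batch normalisation; batch statistics in training, running in eval."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = np.ones(n)
        self.beta = np.zeros(n)
        self.ggamma = np.zeros(n)
        self.gbeta = np.zeros(n)
        self.params = [self.gamma, self.beta]
        self.grads = [self.ggamma, self.gbeta]
        self.momentum = momentum
        self.eps = eps
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self._cache = None

    def forward(self, x, train, rng):
        if train:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            invstd = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mu) * invstd
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
            self._cache = (xhat, invstd, x.shape[0])
            return self.gamma * xhat + self.beta
        xhat = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xhat + self.beta

    def backward(self, grad):
        xhat, invstd, n = self._cache
        self.ggamma[...] = (grad * xhat).sum(axis=0)
        self.gbeta[...] = grad.sum(axis=0)
        dxhat = grad * self.gamma
        return (
            invstd / n
            * (n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0))
        )


class ELU(Layer):
    def __init__(self):
        self._out = None

    def forward(self, x, train, rng):
        out = np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))
        self._out = out
        return out

    def backward(self, grad):
        return grad * np.where(self._out > 0, 1.0, self._out + 1.0)


class Dropout(Layer):
    """Inverted dropout: identity in eval mode."""

    def __init__(self, rate: float):
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self._mask = None

    def forward(self, x, train, rng):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Sequential(Layer):
    def __init__(self, layers):
        self.layers = list(layers)
        self.params = [p for l in self.layers for p in l.params]
        self.grads = [g for l in self.layers for g in l.grads]

    def forward(self, x, train, rng):
        for layer in self.layers:
            x = layer.forward(x, train, rng)
        return x

    def backward(self, grad):
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class Adam:
    """Adaptive-moment optimiser over a flat list of parameter tensors.

    The learning rate is mutable so a scheduler can reduce it mid-training.
    """

    def __init__(self, params, grads, lr: float, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.grads = grads
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
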