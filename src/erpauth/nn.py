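"""Minimal 1-D convolutional network in numpy.

Self-contained layers (conv1d with "same" padding, batch normalization,
ReLU, inverted dropout, max pooling, dense, softmax cross-entropy) with
explicit forward/backward passes and an Adam optimizer. Sized for the small
dense problems this package trains (a few hundred samples of width ~300),
where a full deep-learning framework would be overkill; everything is
driven by one seeded numpy Generator so runs are bit-reproducible.

Shapes follow the (batch, channels, length) convention for convolutional
layers and (batch, features) after flattening.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D", "BatchNorm1D", "ReLU", "Dropout", "MaxPool1D", "Flatten",
    "Dense", "Sequential", "Adam", "softmax", "cross_entropy_loss",
]


class Layer:
    """Base layer: parameter-free identity."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray, training: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1D(Layer):
    """1-D convolution with odd kernel and "same" zero padding.

    Weights ``W`` have shape (filters, in_channels, kernel); He-scaled
    normal initialization (the scheme is a normal distribution with
    fan-in-dependent scale, which keeps activations bounded through depth).
    """

    def __init__(self, in_channels: int, filters: int, kernel: int,
                 rng: np.random.Generator):
        if kernel % 2 != 1:
            raise ValueError("kernel size must be odd for same padding")
        self.kernel = kernel
        scale = np.sqrt(2.0 / (in_channels * kernel))
        self.W = rng.normal(0.0, scale, size=(filters, in_channels, kernel))
        self.b = np.zeros(filters)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        p = self.kernel // 2
        self._xp = np.pad(x, ((0, 0), (0, 0), (p, p)))
        L = x.shape[2]
        y = np.zeros((x.shape[0], self.W.shape[0], L))
        for k in range(self.kernel):
            y += np.matmul(self.W[:, :, k], self._xp[:, :, k : k + L])
        return y + self.b[None, :, None]

    def backward(self, dy):
        L = dy.shape[2]
        self.db[...] = dy.sum(axis=(0, 2))
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            xs = self._xp[:, :, k : k + L]
            self.dW[:, :, k] = np.matmul(dy, xs.transpose(0, 2, 1)).sum(axis=0)
            dxp[:, :, k : k + L] += np.matmul(self.W[:, :, k].T, dy)
        p = self.kernel // 2
        return dxp[:, :, p : p + L] if p else dxp


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, length).

    ``gamma``/``beta`` are trainable; running statistics (momentum 0.1) are
    used at inference and are not counted as trainable parameters.
    """

    def __init__(self, channels: int, eps: float = 1e-5,
                 momentum: float = 0.1):
        self.gamma = np.ones(channels)
        self.beta = np.zeros(channels)
        self.dgamma = np.zeros(channels)
        self.dbeta = np.zeros(channels)
        self.run_mean = np.zeros(channels)
        self.run_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def forward(self, x, training):
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.run_mean += self.momentum * (mean - self.run_mean)
            self.run_var += self.momentum * (var - self.run_var)
        else:
            mean, var = self.run_mean, self.run_var
        self._istd = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._istd[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dy):
        n = dy.shape[0] * dy.shape[2]
        self.dgamma[...] = (dy * self._xhat).sum(axis=(0, 2))
        self.dbeta[...] = dy.sum(axis=(0, 2))
        dxhat = dy * self.gamma[None, :, None]
        dx = (dxhat - dxhat.mean(axis=(0, 2), keepdims=True)
              - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2),
                                                      keepdims=True) / n)
        return dx * self._istd[None, :, None]


class ReLU(Layer):
    def forward(self, x, training):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x, training):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.rate) / (1 - self.rate)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling (kernel == stride); trailing remainder
    samples are dropped (floor semantics)."""

    def __init__(self, size: int = 2):
        self.size = size

    def forward(self, x, training):
        B, C, L = x.shape
        Lo = L // self.size
        xv = x[:, :, : Lo * self.size].reshape(B, C, Lo, self.size)
        self._arg = xv.argmax(axis=3)
        self._shape = x.shape
        return xv.max(axis=3)

    def backward(self, dy):
        B, C, Lo = dy.shape
        dxv = np.zeros((B, C, Lo, self.size))
        np.put_along_axis(dxv, self._arg[..., None], dy[..., None], axis=3)
        dx = np.zeros(self._shape)
        dx[:, :, : Lo * self.size] = dxv.reshape(B, C, Lo * self.size)
        return dx


class Flatten(Layer):
    def forward(self, x, training):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer.

    ``gain=2`` (He) suits a following ReLU; use ``gain=1`` (Xavier-style)
    for a linear/softmax output so initial logits stay small.
    """

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 gain: float = 2.0):
        self.W = rng.normal(0.0, np.sqrt(gain / n_in), size=(n_in, n_out))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x, training):
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy):
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return dy @ self.W.T


class Sequential:
    """An ordered stack of layers with shared forward/backward plumbing."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str, np.ndarray]]:
        out = []
        for layer in self.layers:
            for name, arr in layer.params().items():
                out.append((layer, name, arr))
        return out

    def n_parameters(self) -> int:
        return sum(arr.size for _, _, arr in self.parameters())

    def state(self) -> list[np.ndarray]:
        return [arr.copy() for _, _, arr in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for (layer, name, arr), saved in zip(self.parameters(), state):
            arr[...] = saved


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy_loss(probs: np.ndarray, y: np.ndarray
                       ) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    n = len(y)
    p = np.clip(probs[np.arange(n), y], 1e-12, None)
    loss = float(-np.log(p).mean())
    dz = probs.copy()
    dz[np.arange(n), y] -= 1.0
    return loss, dz / n


class Adam:
    """Adam optimizer over a Sequential's parameters."""

    def __init__(self, net: Sequential, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(a) for _, _, a in net.parameters()]
        self.v = [np.zeros_like(a) for _, _, a in net.parameters()]

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1 ** self.t
        b2t = 1 - self.beta2 ** self.t
        for i, (layer, name, arr) in enumerate(self.net.parameters()):
            g = layer.grads()[name]
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g * g
            arr -= self.lr * (self.m[i] / b1t) / (
                np.sqrt(self.v[i] / b2t) + self.eps)
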