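"""A compact numpy engine for small 1-D convolutional networks.

Implements exactly the building blocks the classifier family needs —
length-preserving 1-D convolution (stride 1, symmetric zero padding),
ReLU, batch normalization with running inference statistics, max pooling
(size 2, stride 2, floor), inverted dropout, a dense head and a combined
softmax/cross-entropy loss — together with reverse-mode gradients and an
Adam optimizer.  Convolution (and both of its gradient passes) is
evaluated in the frequency domain, so the heavy lifting stays inside FFTs
and BLAS-backed channel contractions.

Layers are channels-last: activations have shape ``(batch, length,
channels)``.  Everything is deterministic given the ``numpy`` Generator
supplied for initialization and dropout.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = [
    "softmax",
    "relu",
    "Conv1D",
    "ReLU",
    "BatchNorm",
    "MaxPool",
    "Flatten",
    "Dropout",
    "Dense",
    "Sequential",
    "Adam",
    "softmax_cross_entropy",
]


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax (max-subtraction before exponentiation)."""
    z = np.asarray(logits, dtype=float)
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def relu(x):
    """Rectified linear unit, max(0, x)."""
    return np.maximum(x, 0)


class Layer:
    """Base layer: ``params``/``grads`` are parallel lists of arrays."""

    def __init__(self):
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Conv1D(Layer):
    """Length-preserving 1-D convolution (correlation), stride 1.

    Weights have shape ``(kernel, in_channels, out_channels)``, He-uniform
    initialized; the input is zero-padded by ``(k-1)//2`` left and
    ``k//2`` right so output length equals input length for any kernel
    size.  Forward, weight-gradient and input-gradient passes are all
    evaluated in the frequency domain (rfft along time, a per-frequency
    channel contraction, irfft), which is exact up to float rounding and
    far cheaper than sliding dot products for second-long kernels.

    ``needs_input_grad`` is cleared on the first layer of a network,
    where the gradient w.r.t. the raw signal is never consumed.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        fan_in = kernel * in_channels
        limit = np.sqrt(6.0 / fan_in)
        W = rng.uniform(-limit, limit, size=(kernel, in_channels, out_channels)).astype(dtype)
        b = np.zeros(out_channels, dtype=dtype)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel // 2
        self.needs_input_grad = True

    def _nfft(self, L: int) -> int:
        return sfft.next_fast_len(L + self.kernel - 1)

    def forward(self, x, train):
        B, L, C = x.shape
        W, b = self.params
        n = self._nfft(L)
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        U = sfft.rfft(xp, n, axis=1)            # (B, F, C)
        V = sfft.rfft(W, n, axis=0)             # (F, C, O)
        Yf = np.einsum("bfc,fco->bfo", U, V.conj(), optimize=True)
        y = sfft.irfft(Yf, n, axis=1)[:, :L, :] + b
        self._cache = (U, (B, L, C)) if train else None
        return y

    def backward(self, dy):
        U, (B, L, C) = self._cache
        W, _ = self.params
        k = self.kernel
        n = self._nfft(L)
        self.grads[1][...] = dy.sum(axis=(0, 1))
        Df = sfft.rfft(dy, n, axis=1)           # (B, F, O)
        Gf = np.einsum("bfc,bfo->fco", U, Df.conj(), optimize=True)
        self.grads[0][...] = sfft.irfft(Gf, n, axis=0)[:k]
        dx = None
        if self.needs_input_grad:
            V = sfft.rfft(W, n, axis=0)
            Cf = np.einsum("bfo,fco->bfc", Df, V, optimize=True)
            dx = sfft.irfft(Cf, n, axis=1)[:, self.pad_left : self.pad_left + L, :]
        self._cache = None
        return dx


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return x * self._mask

    def backward(self, dy):
        return dy * self._mask


class BatchNorm(Layer):
    """Per-channel batch normalization over (batch, length).

    Training uses biased batch statistics; inference uses exponential
    running averages (momentum 0.9, chosen for short training schedules).
    """

    def __init__(self, channels: int, epsilon: float = 1e-3, momentum: float = 0.9,
                 dtype=np.float32):
        super().__init__()
        self.epsilon = epsilon
        self.momentum = momentum
        gamma = np.ones(channels, dtype=dtype)
        beta = np.zeros(channels, dtype=dtype)
        self.params = [gamma, beta]
        self.grads = [np.zeros_like(gamma), np.zeros_like(beta)]
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def forward(self, x, train):
        gamma, beta = self.params
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mu
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mu, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.epsilon)
        xhat = (x - mu) * inv
        if train:
            self._cache = (xhat, inv, axes, x.shape)
        return gamma * xhat + beta

    def backward(self, dy):
        gamma, _ = self.params
        xhat, inv, axes, shape = self._cache
        M = np.prod([shape[a] for a in axes])
        self.grads[0][...] = (dy * xhat).sum(axis=axes)
        self.grads[1][...] = dy.sum(axis=axes)
        dxhat = dy * gamma
        dx = inv / M * (M * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
        self._cache = None
        return dx


class MaxPool(Layer):
    """Max pooling, size 2, stride 2; an odd trailing sample is dropped."""

    def forward(self, x, train):
        B, L, C = x.shape
        Lo = L // 2
        xv = x[:, : 2 * Lo, :].reshape(B, Lo, 2, C)
        self._idx = xv.argmax(axis=2)
        self._shape = (B, L, C)
        return np.take_along_axis(xv, self._idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, L, C = self._shape
        Lo = L // 2
        dxv = np.zeros((B, Lo, 2, C), dtype=dy.dtype)
        np.put_along_axis(dxv, self._idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, L, C), dtype=dy.dtype)
        dx[:, : 2 * Lo, :] = dxv.reshape(B, 2 * Lo, C)
        return dx


class Flatten(Layer):
    def forward(self, x, train):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference. ``rng`` is set by Sequential."""

    def __init__(self, rate: float):
        super().__init__()
        if not 0 <= rate < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.rate = rate
        self.rng: np.random.Generator | None = None

    def forward(self, x, train):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(x.dtype) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        limit = np.sqrt(6.0 / in_features)
        W = rng.uniform(-limit, limit, size=(in_features, out_features)).astype(dtype)
        b = np.zeros(out_features, dtype=dtype)
        self.params = [W, b]
        self.grads = [np.zeros_like(W), np.zeros_like(b)]

    def forward(self, x, train):
        self._x = x
        W, b = self.params
        return x @ W + b

    def backward(self, dy):
        W, _ = self.params
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        self._x = None
        return dy @ W.T


def softmax_cross_entropy(logits: np.ndarray, onehot: np.ndarray):
    """Mean categorical cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits, axis=1)
    eps = 1e-12
    loss = -np.mean(np.sum(onehot * np.log(p + eps), axis=1))
    grad = (p - onehot) / logits.shape[0]
    return loss, grad.astype(logits.dtype), p


class Sequential:
    """A feed-forward stack with a softmax classification head."""

    def __init__(self, layers: list[Layer], rng: np.random.Generator | None = None):
        self.layers = layers
        self.set_rng(rng or np.random.default_rng(0))

    def set_rng(self, rng: np.random.Generator) -> None:
        self.rng = rng
        for layer in self.layers:
            if isinstance(layer, Dropout):
                layer.rng = rng

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
        outs = [softmax(self.forward(x[i : i + batch_size], train=False), axis=1)
                for i in range(0, x.shape[0], batch_size)]
        return np.concatenate(outs, axis=0)

    def train_step(self, x: np.ndarray, onehot: np.ndarray):
        logits = self.forward(x, train=True)
        loss, grad, p = softmax_cross_entropy(logits, onehot)
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
            if grad is None:  # first conv layer skips the input gradient
                break
        return loss, p

    @property
    def params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for layer in self.layers for g in layer.grads]

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        ws = [p.copy() for p in self.params]
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                ws.extend([layer.running_mean.copy(), layer.running_var.copy()])
        return ws

    def set_weights(self, weights: list[np.ndarray]) -> None:
        n = len(self.params)
        for p, w in zip(self.params, weights[:n]):
            p[...] = w
        extra = iter(weights[n:])
        for layer in self.layers:
            if isinstance(layer, BatchNorm):
                layer.running_mean[...] = next(extra)
                layer.running_var[...] = next(extra)


class Adam:
    """Adam optimizer over a parameter list (in-place updates)."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
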