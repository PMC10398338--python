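"""Minimal feed-forward building blocks with hand-derived gradients.

The networks used here are small (a two-stage convolutional feature
extractor and fully connected heads with a few thousand parameters), so the
package carries its own dense/convolutional layers, losses and an Adam
optimizer on plain numpy arrays. Every backward pass is validated against
central-difference numerical gradients in the test suite.

All randomness flows through ``numpy.random.Generator`` instances so runs
are bit-reproducible from a seed.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np


def glorot_uniform(rng: np.random.Generator, fan_in: int, fan_out: int,
                   shape: tuple[int, ...]) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Dense:
    """Fully connected layer ``y = x @ W + b``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = glorot_uniform(rng, n_in, n_out, (n_in, n_out))
        self.b = np.zeros(n_out)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.gW = self._x.T @ dy
        self.gb = dy.sum(axis=0)
        return dy @ self.W.T

    @property
    def params(self):
        return [self.W, self.b]

    @property
    def grads(self):
        return [self.gW, self.gb]


class MLP:
    """Fully connected network with tanh hidden activations and linear output."""

    def __init__(self, n_in: int, hidden_units: Sequence[int], n_out: int,
                 rng: np.random.Generator, final_scale: float = 1.0):
        sizes = [n_in, *hidden_units, n_out]
        self.layers = [Dense(sizes[i], sizes[i + 1], rng) for i in range(len(sizes) - 1)]
        if final_scale != 1.0:
            # near-symmetric head: output logits start close to zero
            self.layers[-1].W *= final_scale

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = []
        for i, layer in enumerate(self.layers):
            x = layer.forward(x)
            if i < len(self.layers) - 1:
                x = np.tanh(x)
                self._acts.append(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for i in range(len(self.layers) - 1, -1, -1):
            if i < len(self.layers) - 1:
                dy = dy * (1.0 - self._acts[i] ** 2)
            dy = self.layers[i].backward(dy)
        return dy

    @property
    def params(self):
        return [p for layer in self.layers for p in layer.params]

    @property
    def grads(self):
        return [g for layer in self.layers for g in layer.grads]

    def copy(self) -> "MLP":
        import copy

        return copy.deepcopy(self)


class SpatioTemporalExtractor:
    """Spatial conv over electrodes -> temporal conv -> pool -> flatten.

    Input is a batch ``(n, n_times, n_channels)``. The spatial stage applies
    one kernel spanning all channels per filter (a learned spatial filter
    collapsing the electrode axis), the temporal stage a length-``k`` valid
    convolution along time mixing all spatial maps, both tanh-activated,
    followed by non-overlapping max pooling of size ``(pool, 1)`` along time
    and flattening.
    """

    def __init__(self, n_channels: int, n_times: int, n_spatial_filters: int,
                 temporal_kernel_len: int, n_temporal_filters: int,
                 pool: int, rng: np.random.Generator, pool_mode: str = "max"):
        if temporal_kernel_len > n_times:
            raise ValueError(
                f"temporal kernel ({temporal_kernel_len}) longer than input ({n_times})"
            )
        self.n_channels = n_channels
        self.n_times = n_times
        self.k = temporal_kernel_len
        self.pool = pool
        self.pool_mode = pool_mode
        self.Ws = glorot_uniform(rng, n_channels, n_spatial_filters,
                                 (n_channels, n_spatial_filters))
        self.bs = np.zeros(n_spatial_filters)
        self.Wt = glorot_uniform(rng, n_spatial_filters * temporal_kernel_len,
                                 n_temporal_filters,
                                 (temporal_kernel_len, n_spatial_filters, n_temporal_filters))
        self.bt = np.zeros(n_temporal_filters)
        self._zero_grads()

    def _zero_grads(self) -> None:
        self.gWs = np.zeros_like(self.Ws)
        self.gbs = np.zeros_like(self.bs)
        self.gWt = np.zeros_like(self.Wt)
        self.gbt = np.zeros_like(self.bt)

    @property
    def time_steps_after_temporal(self) -> int:
        return self.n_times - self.k + 1

    @property
    def time_steps_after_pool(self) -> int:
        return self.time_steps_after_temporal // self.pool

    @property
    def n_features(self) -> int:
        return self.time_steps_after_pool * self.Wt.shape[2]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.ndim != 3 or x.shape[1:] != (self.n_times, self.n_channels):
            raise ValueError(
                f"expected input (n, {self.n_times}, {self.n_channels}), got {x.shape}"
            )
        self._x = x
        self._a1 = np.tanh(x @ self.Ws + self.bs)  # (n, T, F1)
        t2 = self.time_steps_after_temporal
        z2 = np.full((x.shape[0], t2, self.Wt.shape[2]), self.bt)
        for j in range(self.k):
            z2 += self._a1[:, j:j + t2, :] @ self.Wt[j]
        self._a2 = np.tanh(z2)  # (n, T2, F2)
        tp = self.time_steps_after_pool
        blocks = self._a2[:, : tp * self.pool].reshape(
            x.shape[0], tp, self.pool, self.Wt.shape[2]
        )
        if self.pool_mode == "max":
            self._argmax = blocks.argmax(axis=2)
            pooled = blocks.max(axis=2)
        else:
            pooled = blocks.mean(axis=2)
        return pooled.reshape(x.shape[0], -1)

    def backward(self, dfeat: np.ndarray) -> np.ndarray:
        n = self._x.shape[0]
        tp, f2 = self.time_steps_after_pool, self.Wt.shape[2]
        dpooled = dfeat.reshape(n, tp, f2)
        da2 = np.zeros_like(self._a2)
        if self.pool_mode == "max":
            ni, ti, fi = np.meshgrid(np.arange(n), np.arange(tp), np.arange(f2),
                                     indexing="ij")
            da2[ni, ti * self.pool + self._argmax, fi] = dpooled
        else:
            for j in range(self.pool):
                da2[:, j: tp * self.pool: self.pool, :] = dpooled / self.pool
        dz2 = da2 * (1.0 - self._a2 ** 2)
        t2 = self.time_steps_after_temporal
        self.gbt = dz2.sum(axis=(0, 1))
        da1 = np.zeros_like(self._a1)
        for j in range(self.k):
            a1s = self._a1[:, j:j + t2, :]
            self.gWt[j] = np.einsum("ntf,ntg->fg", a1s, dz2)
            da1[:, j:j + t2, :] += dz2 @ self.Wt[j].T
        dz1 = da1 * (1.0 - self._a1 ** 2)
        self.gWs = np.einsum("ntc,ntf->cf", self._x, dz1)
        self.gbs = dz1.sum(axis=(0, 1))
        return dz1 @ self.Ws.T

    @property
    def params(self):
        return [self.Ws, self.bs, self.Wt, self.bt]

    @property
    def grads(self):
        return [self.gWs, self.gbs, self.gWt, self.gbt]

    def copy(self) -> "SpatioTemporalExtractor":
        import copy

        return copy.deepcopy(self)


class Adam:
    """Adam optimizer over a fixed list of parameter arrays (updated in place)."""

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
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray,
                          class_weights: np.ndarray | None = None):
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    p = softmax(logits)
    n = logits.shape[0]
    w = np.ones(n) if class_weights is None else class_weights[y]
    logp = np.log(np.clip(p[np.arange(n), y], 1e-12, None))
    loss = -(w * logp).sum() / w.sum()
    dlogits = p.copy()
    dlogits[np.arange(n), y] -= 1.0
    dlogits *= (w / w.sum())[:, None]
    return loss, dlogits


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray):
    """Mean binary cross-entropy of ``sigmoid(logits)`` against 0/1 targets."""
    logits = logits.ravel()
    p = sigmoid(logits)
    loss = -np.mean(targets * np.log(np.clip(p, 1e-12, None))
                    + (1 - targets) * np.log(np.clip(1 - p, 1e-12, None)))
    dlogits = (p - targets) / logits.size
    return loss, dlogits.reshape(-1, 1)
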