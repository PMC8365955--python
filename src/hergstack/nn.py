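"""Minimal seeded neural-network engine (NumPy).

Implements exactly the layer set the five base architectures and the meta
network need — dense, 1-D convolution with max-pooling, token embedding,
graph convolution with symmetric renormalization, gated global attention
pooling, inverted dropout — together with Adam, binary cross-entropy on
logits and L2 (kernel/bias) regularization. Everything is deterministic
given the seeds: initialization uses Glorot-uniform draws from a dedicated
generator, and mini-batch order and dropout masks come from the training
generator.

Models expose ``forward(X, train) -> logits``, ``backward(dlogits)``,
``params()``/``grads()`` (parallel lists of arrays) and weight
get/set for checkpointing the best-validation epoch.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .metrics import auc_roc

__all__ = [
    "TrainConfig",
    "Sequential",
    "GraphNet",
    "Dense",
    "Dropout",
    "Embedding",
    "Conv1D",
    "MaxPool1D",
    "GlobalMaxPool1D",
    "train_model",
    "predict_proba",
    "normalize_adjacency",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_with_logits(z: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy and its gradient w.r.t. the logits."""
    n = z.shape[0]
    # softplus(z) - y*z, numerically stable
    loss = float(np.mean(np.maximum(z, 0) - y * z + np.log1p(np.exp(-np.abs(z)))))
    dz = (sigmoid(z) - y) / n
    return loss, dz


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    if len(shape) > 2:
        fan_in = int(np.prod(shape[:-1]))
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter/gradient registries plus L2 bookkeeping."""

    def __init__(self) -> None:
        self._params: list[np.ndarray] = []
        self._grads: list[np.ndarray] = []
        self._l2: list[float] = []

    def add_param(self, arr: np.ndarray, l2: float = 0.0) -> np.ndarray:
        self._params.append(arr)
        self._grads.append(np.zeros_like(arr))
        self._l2.append(l2)
        return arr

    def params(self) -> list[np.ndarray]:
        return self._params

    def grads(self) -> list[np.ndarray]:
        return self._grads

    def reg_loss(self) -> float:
        return sum(l2 * float((p**2).sum()) for p, l2 in zip(self._params, self._l2) if l2)

    def add_reg_grads(self) -> None:
        for g, p, l2 in zip(self._grads, self._params, self._l2):
            if l2:
                g += 2.0 * l2 * p

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer, optional ReLU. Accepts (..., n_in) input."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 relu: bool = True, l2_kernel: float = 0.0, l2_bias: float = 0.0):
        super().__init__()
        self.w = self.add_param(_glorot(rng, (n_in, n_out)), l2_kernel)
        self.b = self.add_param(np.zeros(n_out), l2_bias)
        self.relu = relu

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._x = x
        z = x @ self.w + self.b
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        x2 = self._x.reshape(-1, self.w.shape[0])
        d2 = dout.reshape(-1, self.w.shape[1])
        self._grads[0][...] = x2.T @ d2
        self._grads[1][...] = d2.sum(axis=0)
        return dout @ self.w.T


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        super().__init__()
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout if self._mask is None else dout * self._mask


class Embedding(Layer):
    """Trainable lookup table: integer ids (B, L) -> (B, L, dim)."""

    def __init__(self, vocab_size: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.add_param(rng.uniform(-0.05, 0.05, size=(vocab_size, dim)))

    def forward(self, ids: np.ndarray, train: bool) -> np.ndarray:
        self._ids = ids
        return self.w[ids]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self._grads[0]
        g[...] = 0.0
        np.add.at(g, self._ids.reshape(-1), dout.reshape(-1, g.shape[1]))
        return dout  # no gradient to integer inputs


class Conv1D(Layer):
    """Valid-padding, stride-1 1-D convolution over (B, L, C_in), via im2col."""

    def __init__(self, c_in: int, filters: int, kernel: int,
                 rng: np.random.Generator, relu: bool = True, l2_kernel: float = 0.0):
        super().__init__()
        self.kernel = kernel
        self.c_in = c_in
        self.w = self.add_param(_glorot(rng, (kernel * c_in, filters)), l2_kernel)
        self.b = self.add_param(np.zeros(filters))
        self.relu = relu

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        k = self.kernel
        lo = length - k + 1
        win = np.lib.stride_tricks.sliding_window_view(x, k, axis=1)  # (B, Lo, C, k)
        col = win.transpose(0, 1, 3, 2).reshape(b, lo, k * c)
        self._col = col
        self._in_shape = x.shape
        z = col @ self.w + self.b
        if self.relu:
            self._mask = z > 0
            z = z * self._mask
        return z

    def backward(self, dout: np.ndarray) -> np.ndarray:
        if self.relu:
            dout = dout * self._mask
        b, lo, f = dout.shape
        k, c = self.kernel, self.c_in
        col2 = self._col.reshape(-1, k * c)
        d2 = dout.reshape(-1, f)
        self._grads[0][...] = col2.T @ d2
        self._grads[1][...] = d2.sum(axis=0)
        dcol = (dout @ self.w.T).reshape(b, lo, k, c)
        dx = np.zeros(self._in_shape)
        for t in range(k):  # k is small (<= 10)
            dx[:, t : t + lo, :] += dcol[:, :, t, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping max pooling along the length axis (trailing remainder dropped)."""

    def __init__(self, pool: int = 2):
        super().__init__()
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        b, length, c = x.shape
        lo = length // self.pool
        xr = x[:, : lo * self.pool, :].reshape(b, lo, self.pool, c)
        self._argmax = xr.argmax(axis=2)
        self._in_shape = x.shape
        return xr.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, lo, c = dout.shape
        dx = np.zeros(self._in_shape)
        dxr = dx[:, : lo * self.pool, :].reshape(b, lo, self.pool, c)
        bi, li, ci = np.ogrid[:b, :lo, :c]
        dxr[bi, li, self._argmax, ci] = dout
        return dx


class GlobalMaxPool1D(Layer):
    """Max over the length axis: (B, L, C) -> (B, C)."""

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._argmax = x.argmax(axis=1)
        self._in_shape = x.shape
        return x.max(axis=1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        b, _, c = self._in_shape
        dx = np.zeros(self._in_shape)
        bi, ci = np.ogrid[:b, :c]
        dx[bi, self._argmax, ci] = dout
        return dx


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Sequential:
    """Feed-forward composition of layers ending in a 1-unit logit."""

    def __init__(self, layers: Sequence[Layer]):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train)
        return x[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        grad = dlogits[:, None]
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        for layer in self.layers:
            layer.add_reg_grads()

    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads()]

    def reg_loss(self) -> float:
        return sum(l.reg_loss() for l in self.layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


# -- graph network ---------------------------------------------------------


def normalize_adjacency(adj: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Symmetric renormalized propagation matrix D^{-1/2}(A + I_mask)D^{-1/2}.

    Self-loops are added only on real (masked-in) nodes, so zero-padded rows
    stay inert. Accepts a batch (B, N, N) with mask (B, N) or single matrices.
    """
    single = adj.ndim == 2
    a = adj[None] if single else adj
    m = mask[None] if single else mask
    a_hat = a + np.einsum("bn,nm->bnm", m, np.eye(a.shape[1]))
    deg = a_hat.sum(axis=2)
    with np.errstate(divide="ignore"):
        dinv = np.where(deg > 0, deg**-0.5, 0.0)
    out = dinv[:, :, None] * a_hat * dinv[:, None, :]
    return out[0] if single else out


class GraphConv(Layer):
    """H' = relu(A_hat @ H @ W + b) with node-mask zeroing of padded rows."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 l2_kernel: float = 0.0):
        super().__init__()
        self.w = self.add_param(_glorot(rng, (c_in, c_out)), l2_kernel)
        self.b = self.add_param(np.zeros(c_out))

    def forward_graph(self, h: np.ndarray, a_hat: np.ndarray,
                      mask: np.ndarray) -> np.ndarray:
        self._a_hat = a_hat
        self._mask = mask
        self._m = a_hat @ h  # (B, N, C_in)
        z = self._m @ self.w + self.b
        z = z * mask[:, :, None]
        self._relu_mask = z > 0
        return z * self._relu_mask

    def backward_graph(self, dout: np.ndarray) -> np.ndarray:
        dz = dout * self._relu_mask * self._mask[:, :, None]
        m2 = self._m.reshape(-1, self.w.shape[0])
        d2 = dz.reshape(-1, self.w.shape[1])
        self._grads[0][...] = m2.T @ d2
        self._grads[1][...] = d2.sum(axis=0)
        dm = dz @ self.w.T
        # A_hat is symmetric, so A_hat^T @ dm == A_hat @ dm
        return self._a_hat @ dm


class AttentionPool(Layer):
    """Gated attention sum over nodes: sum_n mask * sigmoid(HWg+bg) * (HWf+bf)."""

    def __init__(self, c_in: int, channels: int, rng: np.random.Generator):
        super().__init__()
        self.wg = self.add_param(_glorot(rng, (c_in, channels)))
        self.bg = self.add_param(np.zeros(channels))
        self.wf = self.add_param(_glorot(rng, (c_in, channels)))
        self.bf = self.add_param(np.zeros(channels))

    def forward_graph(self, h: np.ndarray, mask: np.ndarray) -> np.ndarray:
        self._h = h
        self._mask = mask
        self._gate = sigmoid(h @ self.wg + self.bg)
        self._feat = h @ self.wf + self.bf
        self._prod = self._gate * self._feat * mask[:, :, None]
        return self._prod.sum(axis=1)

    def backward_graph(self, dout: np.ndarray) -> np.ndarray:
        d = dout[:, None, :] * self._mask[:, :, None]  # (B, N, C)
        dgate = d * self._feat * self._gate * (1 - self._gate)
        dfeat = d * self._gate
        h2 = self._h.reshape(-1, self.wg.shape[0])
        self._grads[0][...] = h2.T @ dgate.reshape(-1, self.wg.shape[1])
        self._grads[1][...] = dgate.sum(axis=(0, 1))
        self._grads[2][...] = h2.T @ dfeat.reshape(-1, self.wf.shape[1])
        self._grads[3][...] = dfeat.sum(axis=(0, 1))
        return dgate @ self.wg.T + dfeat @ self.wf.T


class GraphNet:
    """Two graph convolutions, gated attention pooling and a dense head.

    Input is a tuple of arrays (nodes (B,N,F), a_hat (B,N,N), mask (B,N)),
    where a_hat is the pre-normalized propagation matrix.
    """

    def __init__(self, n_node_features: int, rng: np.random.Generator,
                 channels: int = 64, pool_channels: int = 1024,
                 l2_kernel: float = 0.01):
        self.gc1 = GraphConv(n_node_features, channels, rng, l2_kernel)
        self.gc2 = GraphConv(channels, channels, rng, l2_kernel)
        self.pool = AttentionPool(channels, pool_channels, rng)
        self.dense = Dense(pool_channels, pool_channels, rng, relu=True)
        self.out = Dense(pool_channels, 1, rng, relu=False)
        self._layers = [self.gc1, self.gc2, self.pool, self.dense, self.out]

    def forward(self, x: tuple[np.ndarray, ...], train: bool = False) -> np.ndarray:
        nodes, a_hat, mask = x
        h = self.gc1.forward_graph(nodes, a_hat, mask)
        h = self.gc2.forward_graph(h, a_hat, mask)
        pooled = self.pool.forward_graph(h, mask)
        z = self.dense.forward(pooled, train)
        return self.out.forward(z, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.out.backward(dlogits[:, None])
        g = self.dense.backward(g)
        g = self.pool.backward_graph(g)
        g = self.gc2.backward_graph(g)
        self.gc1.backward_graph(g)
        for layer in self._layers:
            layer.add_reg_grads()

    def params(self) -> list[np.ndarray]:
        return [p for l in self._layers for p in l.params()]

    def grads(self) -> list[np.ndarray]:
        return [g for l in self._layers for g in l.grads()]

    def reg_loss(self) -> float:
        return sum(l.reg_loss() for l in self._layers)

    def get_weights(self) -> list[np.ndarray]:
        return [p.copy() for p in self.params()]

    def set_weights(self, weights: Sequence[np.ndarray]) -> None:
        for p, w in zip(self.params(), weights):
            p[...] = w


# -- optimization ----------------------------------------------------------


class Adam:
    def __init__(self, params: list[np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class TrainConfig:
    """Optimization settings for one network."""

    learning_rate: float = 1e-4
    epochs: int = 100
    batch_size: int = 32
    seed: int = 0
    select_best: bool = True  # restore the epoch with best validation AUC


def _batch_index(x, idx):
    if isinstance(x, tuple):
        return tuple(a[idx] for a in x)
    return x[idx]


def _n_samples(x) -> int:
    return (x[0] if isinstance(x, tuple) else x).shape[0]


def predict_proba(model, x) -> np.ndarray:
    """Blocker probabilities in [0,1], batched to bound memory."""
    n = _n_samples(x)
    out = np.empty(n)
    for start in range(0, n, 256):
        idx = np.arange(start, min(start + 256, n))
        out[idx] = sigmoid(model.forward(_batch_index(x, idx), train=False))
    return out


def train_model(model, x, y, x_valid=None, y_valid=None,
                cfg: TrainConfig | None = None) -> list[dict]:
    """Mini-batch Adam training with per-epoch validation AUC tracking.

    Returns the training log (one dict per epoch). When ``cfg.select_best``
    and validation data are given, the weights of the best-validation-AUC
    epoch are restored at the end.
    """
    cfg = cfg or TrainConfig()
    y = np.asarray(y, dtype=float)
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.params(), cfg.learning_rate)
    n = _n_samples(x)
    log: list[dict] = []
    best_auc, best_loss, best_weights = -np.inf, np.inf, None
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.forward(_batch_index(x, idx), train=True)
            loss, dz = bce_with_logits(logits, y[idx])
            model.backward(dz)
            opt.step(model.grads())
            epoch_loss += loss * len(idx)
        entry = {"epoch": epoch, "train_loss": epoch_loss / n}
        if x_valid is not None:
            pv = predict_proba(model, x_valid)
            vloss, _ = bce_with_logits(
                np.log(np.clip(pv, 1e-12, 1 - 1e-12) / np.clip(1 - pv, 1e-12, None)),
                np.asarray(y_valid, dtype=float),
            )
            vauc = auc_roc(y_valid, pv)
            entry.update(valid_loss=vloss, valid_auc=vauc)
            # best validation AUC wins; ties go to the lower validation loss
            # (AUC saturates early on easy data while calibration still improves)
            if cfg.select_best and vauc is not None and (
                vauc > best_auc or (vauc == best_auc and vloss < best_loss)
            ):
                best_auc, best_loss = vauc, vloss
                best_weights = model.get_weights()
        log.append(entry)
    if best_weights is not None:
        model.set_weights(best_weights)
    return log
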