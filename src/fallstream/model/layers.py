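"""Neural-network building blocks with explicit forward/backward passes.

Everything is plain numpy (float32). Each layer caches what its backward
pass needs during ``forward`` and accumulates parameter gradients into
``grads`` during ``backward``. Array layout is time-major:
``(batch, length, channels)`` for sequence layers, ``(batch, features)``
for dense ones.
"""

from __future__ import annotations

from typing import Dict, Optional

import numpy as np

DTYPE = np.float32


class Layer:
    """Base class: parameterized layers expose ``params``/``grads`` dicts."""

    def __init__(self) -> None:
        self.params: Dict[str, np.ndarray] = {}
        self.grads: Dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    """He-style uniform init, bound 1/sqrt(fan_in) (matches common conv defaults)."""
    bound = 1.0 / np.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(DTYPE)


class Conv1dSame(Layer):
    """1D convolution, kernel 3, stride 1, zero ('same') padding.

    Same padding keeps the temporal length unchanged so successive
    pool-by-2 stages halve it exactly.
    """

    KERNEL = 3

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator) -> None:
        super().__init__()
        fan_in = in_ch * self.KERNEL
        self.in_ch, self.out_ch = in_ch, out_ch
        self.params["W"] = kaiming_uniform(rng, (fan_in, out_ch), fan_in)
        self.params["b"] = kaiming_uniform(rng, (out_ch,), fan_in)
        self._cols: Optional[np.ndarray] = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, length, c = x.shape
        xp = np.zeros((n, length + 2, c), dtype=DTYPE)
        xp[:, 1:-1, :] = x
        # (n, length, c, kernel) windows flattened to rows in (channel, tap) order,
        # matching the layout of W's rows
        win = np.lib.stride_tricks.sliding_window_view(xp, self.KERNEL, axis=1)
        return win.reshape(n, length, c * self.KERNEL)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.shape[2] != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {x.shape[2]}")
        cols = self._im2col(x)
        self._cols = cols if train else None
        return cols @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols = self._cols
        n, length, _ = dy.shape
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        self.grads["W"] = cols.reshape(-1, cols.shape[2]).T @ dy.reshape(-1, self.out_ch)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dcols = (dy @ self.params["W"].T).reshape(n, length, self.in_ch, self.KERNEL)
        dxp = np.zeros((n, length + 2, self.in_ch), dtype=DTYPE)
        for k in range(self.KERNEL):
            dxp[:, k : k + length, :] += dcols[:, :, :, k]
        return dxp[:, 1:-1, :]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        self._mask = x > 0 if train else None
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class MaxPool2(Layer):
    """Temporal max-pooling, size 2, stride 2. Requires even input length."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, length, c = x.shape
        if length % 2:
            raise ValueError(f"MaxPool2 needs even length, got {length}")
        pairs = x.reshape(n, length // 2, 2, c)
        self._argmax = pairs.argmax(axis=2) if train else None
        self._inlen = length
        return pairs.max(axis=2)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, half, c = dy.shape
        dpairs = np.zeros((n, half, 2, c), dtype=DTYPE)
        np.put_along_axis(dpairs, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        return dpairs.reshape(n, self._inlen, c)


class GlobalPool(Layer):
    """Global pooling over the temporal axis: 'avg' (default) or 'max'."""

    def __init__(self, mode: str = "avg") -> None:
        super().__init__()
        if mode not in ("avg", "max"):
            raise ValueError(f"pooling must be 'avg' or 'max', got {mode!r}")
        self.mode = mode

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._inlen = x.shape[1]
        if self.mode == "avg":
            return x.mean(axis=1)
        self._argmax = x.argmax(axis=1) if train else None
        return x.max(axis=1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        n, c = dy.shape
        if self.mode == "avg":
            return np.broadcast_to(dy[:, None, :] / self._inlen, (n, self._inlen, c)).astype(DTYPE)
        dx = np.zeros((n, self._inlen, c), dtype=DTYPE)
        np.put_along_axis(dx, self._argmax[:, None, :], dy[:, None, :], axis=1)
        return dx


def _softmax_lastaxis(s: np.ndarray) -> np.ndarray:
    z = s - s.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class VectorSelfAttention(Layer):
    """Self-attention over the positions of a pooled feature vector.

    For each sample, the 64-D input ``x`` is projected to query, key and
    value vectors (``q = W_q x`` etc., 64x64 matrices). Pairwise scores
    ``S[i, j] = q_i * k_j / temperature`` are normalized row-wise with a
    softmax into a row-stochastic attention matrix ``A``; the output is
    ``A v`` — position ``i`` becomes a convex combination of value entries,
    i.e. a re-weighting of the feature vector.
    """

    def __init__(self, dim: int, rng: np.random.Generator, temperature: Optional[float] = None) -> None:
        super().__init__()
        self.dim = dim
        self.temperature = float(temperature if temperature is not None else np.sqrt(dim))
        for name in ("Wq", "Wk", "Wv"):
            self.params[name] = rng.normal(0.0, 0.02, size=(dim, dim)).astype(DTYPE)
        self.last_attention: Optional[np.ndarray] = None  # (n, dim, dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[-1] != self.dim:
            raise ValueError(f"expected {self.dim}-D input, got {x.shape[-1]}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        q = x @ self.params["Wq"].T
        k = x @ self.params["Wk"].T
        v = x @ self.params["Wv"].T
        s = q[:, :, None] * k[:, None, :] / DTYPE(self.temperature)
        a = _softmax_lastaxis(s)
        self.last_attention = a
        y = np.einsum("nij,nj->ni", a, v)
        if train:
            self._cache = (x, q, k, v, a)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, q, k, v, a = self._cache
        dy = np.ascontiguousarray(dy, dtype=DTYPE)
        dv = np.einsum("nij,ni->nj", a, dy)
        da = dy[:, :, None] * v[:, None, :]
        # softmax (rows) backward
        ds = a * (da - (da * a).sum(axis=2, keepdims=True))
        ds /= DTYPE(self.temperature)
        dq = np.einsum("nij,nj->ni", ds, k)
        dk = np.einsum("nij,ni->nj", ds, q)
        self.grads["Wq"] = dq.T @ x
        self.grads["Wk"] = dk.T @ x
        self.grads["Wv"] = dv.T @ x
        return dq @ self.params["Wq"] + dk @ self.params["Wk"] + dv @ self.params["Wv"]


class TemporalSelfAttention(Layer):
    """Scaled dot-product attention across temporal positions.

    Alternative formulation applied to the (length, 64) feature map before
    global pooling: queries/keys/values are per-position 64-D projections,
    ``A = softmax(Q K^T / temperature)`` is (length x length).
    """

    def __init__(self, dim: int, rng: np.random.Generator, temperature: Optional[float] = None) -> None:
        super().__init__()
        self.dim = dim
        self.temperature = float(temperature if temperature is not None else np.sqrt(dim))
        for name in ("Wq", "Wk", "Wv"):
            self.params[name] = rng.normal(0.0, 0.02, size=(dim, dim)).astype(DTYPE)
        self.last_attention: Optional[np.ndarray] = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        q = x @ self.params["Wq"].T
        k = x @ self.params["Wk"].T
        v = x @ self.params["Wv"].T
        s = q @ k.transpose(0, 2, 1) / DTYPE(self.temperature)
        a = _softmax_lastaxis(s)
        self.last_attention = a
        y = a @ v
        if train:
            self._cache = (x, q, k, v, a)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x, q, k, v, a = self._cache
        dv = a.transpose(0, 2, 1) @ dy
        da = dy @ v.transpose(0, 2, 1)
        ds = a * (da - (da * a).sum(axis=2, keepdims=True))
        ds /= DTYPE(self.temperature)
        dq = ds @ k
        dk = ds.transpose(0, 2, 1) @ q
        flat = lambda z: z.reshape(-1, self.dim)  # noqa: E731
        self.grads["Wq"] = flat(dq).T @ flat(x)
        self.grads["Wk"] = flat(dk).T @ flat(x)
        self.grads["Wv"] = flat(dv).T @ flat(x)
        return dq @ self.params["Wq"] + dk @ self.params["Wk"] + dv @ self.params["Wv"]


class BatchNorm(Layer):
    """Batch normalization over the batch axis of (n, features) inputs.

    Batch statistics in training, exponentially-averaged running
    statistics in evaluation.
    """

    def __init__(self, dim: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.dim, self.momentum, self.eps = dim, momentum, eps
        self.params["gamma"] = np.ones(dim, dtype=DTYPE)
        self.params["beta"] = np.zeros(dim, dtype=DTYPE)
        self.running_mean = np.zeros(dim, dtype=DTYPE)
        self.running_var = np.ones(dim, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if train:
            mean = x.mean(axis=0)
            var = x.var(axis=0)
            n = x.shape[0]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
            inv = 1.0 / np.sqrt(var + self.eps)
            xhat = (x - mean) * inv
            self._cache = (xhat, inv)
        else:
            inv = 1.0 / np.sqrt(self.running_var + self.eps)
            xhat = (x - self.running_mean) * inv
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._cache
        n = dy.shape[0]
        self.grads["gamma"] = (dy * xhat).sum(axis=0)
        self.grads["beta"] = dy.sum(axis=0)
        dxhat = dy * self.params["gamma"]
        return (inv / n) * (
            n * dxhat - dxhat.sum(axis=0) - xhat * (dxhat * xhat).sum(axis=0)
        ).astype(DTYPE)


class Dropout(Layer):
    """Inverted dropout; identity in evaluation mode."""

    def __init__(self, p: float = 0.5) -> None:
        super().__init__()
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)  # reseeded by the owning network

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.p == 0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(DTYPE) / DTYPE(keep)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_dim, self.out_dim = in_dim, out_dim
        self.params["W"] = kaiming_uniform(rng, (in_dim, out_dim), in_dim)
        self.params["b"] = kaiming_uniform(rng, (out_dim,), in_dim)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=DTYPE)
        if x.shape[1] != self.in_dim:
            raise ValueError(f"expected {self.in_dim}-D input, got {x.shape[1]}")
        self._x = x if train else None
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


def softmax(logits: np.ndarray) -> np.ndarray:
    return _softmax_lastaxis(np.asarray(logits, dtype=DTYPE))


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean cross-entropy of softmax(logits) vs integer labels; returns (loss, dlogits)."""
    n = logits.shape[0]
    p = softmax(logits)
    eps = np.finfo(DTYPE).tiny
    loss = float(-np.log(p[np.arange(n), labels] + eps).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, dlogits / DTYPE(n)
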