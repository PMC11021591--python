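"""NumPy neural-network primitives with hand-derived backpropagation.

Everything operates time-major: activations are ``(batch, time, features)``.
Each layer caches what its backward pass needs on ``forward`` and fills
``self.grads`` on ``backward``. Parameter initialization is Glorot-uniform
from an externally supplied generator so whole-model builds are seeded.
"""
from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1dSame",
    "ReLU",
    "MaxPool1d",
    "SelfAttention",
    "GRULast",
    "Dropout",
    "Dense",
    "Adam",
    "sigmoid",
    "bce_with_logits",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _softplus(z: np.ndarray) -> np.ndarray:
    return np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))


def bce_with_logits(logits: np.ndarray, targets: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; accepts soft targets in [0, 1].

    Returns ``(loss, dloss/dlogits)``. Uses the numerically stable form
    ``softplus(z) - y * z``.
    """
    logits = np.asarray(logits, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.float64)
    losses = _softplus(logits) - targets * logits
    grad = (sigmoid(logits) - targets) / logits.size
    return float(losses.mean()), grad


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, training: bool = False, rng=None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Conv1dSame(Layer):
    """1D convolution over the time axis with length-preserving zero padding."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.c_in, self.c_out, self.kernel = c_in, c_out, kernel
        self.params = {
            "W": _glorot(rng, (kernel * c_in, c_out)),
            "b": np.zeros(c_out),
        }
        self.pad_left = (kernel - 1) // 2
        self.pad_right = kernel - 1 - self.pad_left

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        xp = np.pad(x, ((0, 0), (self.pad_left, self.pad_right), (0, 0)))
        # (B, T, kernel, C) -> (B, T, kernel*C); sliding view returns (B, T, C, kernel)
        patches = np.lib.stride_tricks.sliding_window_view(xp, self.kernel, axis=1)
        patches = patches.transpose(0, 1, 3, 2).reshape(B, T, self.kernel * C)
        self._patches, self._T = patches, T
        return patches @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        B, T, _ = dy.shape
        W = self.params["W"]
        self.grads["W"] = np.einsum("btm,btf->mf", self._patches, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        dpatch = (dy @ W.T).reshape(B, T, self.kernel, self.c_in)
        dxp = np.zeros((B, T + self.kernel - 1, self.c_in))
        for j in range(self.kernel):
            dxp[:, j : j + T, :] += dpatch[:, :, j, :]
        return dxp[:, self.pad_left : self.pad_left + T, :]


class ReLU(Layer):
    def forward(self, x, training=False, rng=None):
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dy):
        return dy * self._mask


class MaxPool1d(Layer):
    """Non-overlapping max pooling over time (size == stride)."""

    def __init__(self, size: int = 2) -> None:
        super().__init__()
        self.size = size

    def forward(self, x, training=False, rng=None):
        B, T, C = x.shape
        T_out = T // self.size
        xt = x[:, : T_out * self.size, :].reshape(B, T_out, self.size, C)
        self._argmax = xt.argmax(axis=2)
        self._in_shape = x.shape
        return np.take_along_axis(xt, self._argmax[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        B, T, C = self._in_shape
        T_out = dy.shape[1]
        dxt = np.zeros((B, T_out, self.size, C))
        np.put_along_axis(dxt, self._argmax[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros((B, T, C))
        dx[:, : T_out * self.size, :] = dxt.reshape(B, T_out * self.size, C)
        return dx


class SelfAttention(Layer):
    """Scaled dot-product self-attention reconstructing each feature vector.

    Q = X Wq, K = X Wk, V = X Wv; A = rowsoftmax(Q K^T / sqrt(d)); Y = A V.
    Rows of A are non-negative and sum to one.
    """

    def __init__(self, d_in: int, d: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.d_in, self.d = d_in, d
        self.params = {
            "Wq": _glorot(rng, (d_in, d)),
            "Wk": _glorot(rng, (d_in, d)),
            "Wv": _glorot(rng, (d_in, d)),
        }

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Attention matrix A for a batch (no caching)."""
        q = x @ self.params["Wq"]
        k = x @ self.params["Wk"]
        return _rowsoftmax(q @ k.transpose(0, 2, 1) / np.sqrt(self.d))

    def forward(self, x, training=False, rng=None):
        self._x = x
        self._q = x @ self.params["Wq"]
        self._k = x @ self.params["Wk"]
        self._v = x @ self.params["Wv"]
        scores = self._q @ self._k.transpose(0, 2, 1) / np.sqrt(self.d)
        self._a = _rowsoftmax(scores)
        return self._a @ self._v

    def backward(self, dy):
        a, q, k, v, x = self._a, self._q, self._k, self._v, self._x
        dv = a.transpose(0, 2, 1) @ dy
        da = dy @ v.transpose(0, 2, 1)
        # softmax Jacobian, rows independent
        ds = a * (da - (da * a).sum(axis=-1, keepdims=True))
        ds /= np.sqrt(self.d)
        dq = ds @ k
        dk = ds.transpose(0, 2, 1) @ q
        self.grads["Wq"] = np.einsum("bti,btj->ij", x, dq)
        self.grads["Wk"] = np.einsum("bti,btj->ij", x, dk)
        self.grads["Wv"] = np.einsum("bti,btj->ij", x, dv)
        Wq, Wk, Wv = self.params["Wq"], self.params["Wk"], self.params["Wv"]
        return dq @ Wq.T + dk @ Wk.T + dv @ Wv.T


def _rowsoftmax(s: np.ndarray) -> np.ndarray:
    s = s - s.max(axis=-1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=-1, keepdims=True)


class GRULast(Layer):
    """GRU over the time axis, returning the final hidden state.

    Gate equations (default convention, ``mirror=False``)::

        z_t = sigmoid(W_z [h_prev, x_t] + b_z)
        r_t = sigmoid(W_r [h_prev, x_t] + b_r)
        hc  = tanh(W_h [r_t * h_prev, x_t] + b_h)
        h_t = (1 - z_t) * h_prev + z_t * hc

    ``mirror=True`` swaps the roles of z and 1-z in the blend.
    """

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, mirror: bool = False) -> None:
        super().__init__()
        self.d_in, self.hidden, self.mirror = d_in, hidden, mirror
        H = hidden
        self.params = {
            "Wx": _glorot(rng, (d_in, 3 * H)),  # columns: [z | r | candidate]
            "Wh": _glorot(rng, (H, 3 * H)),
            "b": np.zeros(3 * H),
        }

    def step(self, x_t: np.ndarray, h_prev: np.ndarray) -> np.ndarray:
        """Single gate-equation step (used directly by unit tests)."""
        H = self.hidden
        xp = x_t @ self.params["Wx"] + self.params["b"]
        z = sigmoid(xp[..., :H] + h_prev @ self.params["Wh"][:, :H])
        r = sigmoid(xp[..., H : 2 * H] + h_prev @ self.params["Wh"][:, H : 2 * H])
        hc = np.tanh(xp[..., 2 * H :] + (r * h_prev) @ self.params["Wh"][:, 2 * H :])
        if self.mirror:
            return z * h_prev + (1 - z) * hc
        return (1 - z) * h_prev + z * hc

    def forward(self, x, training=False, rng=None):
        B, T, _ = x.shape
        H = self.hidden
        Wx, Wh, b = self.params["Wx"], self.params["Wh"], self.params["b"]
        xp = x @ Wx + b  # (B, T, 3H) — all input projections at once
        h = np.zeros((B, H))
        zs = np.empty((T, B, H))
        rs = np.empty((T, B, H))
        hcs = np.empty((T, B, H))
        hps = np.empty((T, B, H))
        Whz, Whr, Whh = Wh[:, :H], Wh[:, H : 2 * H], Wh[:, 2 * H :]
        for t in range(T):
            hps[t] = h
            z = sigmoid(xp[:, t, :H] + h @ Whz)
            r = sigmoid(xp[:, t, H : 2 * H] + h @ Whr)
            hc = np.tanh(xp[:, t, 2 * H :] + (r * h) @ Whh)
            h = z * h + (1 - z) * hc if self.mirror else (1 - z) * h + z * hc
            zs[t], rs[t], hcs[t] = z, r, hc
        self._cache = (x, xp, zs, rs, hcs, hps)
        return h

    def backward(self, dh_last):
        x, xp, zs, rs, hcs, hps = self._cache
        B, T, _ = x.shape
        H = self.hidden
        Wh = self.params["Wh"]
        Whz, Whr, Whh = Wh[:, :H], Wh[:, H : 2 * H], Wh[:, 2 * H :]
        dxp = np.zeros((B, T, 3 * H))
        dWh = np.zeros_like(Wh)
        dh = dh_last
        for t in range(T - 1, -1, -1):
            z, r, hc, hp = zs[t], rs[t], hcs[t], hps[t]
            if self.mirror:
                dz = dh * (hp - hc)
                dhc = dh * (1 - z)
                dhp = dh * z
            else:
                dz = dh * (hc - hp)
                dhc = dh * z
                dhp = dh * (1 - z)
            dpre_c = dhc * (1 - hc * hc)
            dxp[:, t, 2 * H :] = dpre_c
            dWh[:, 2 * H :] += (r * hp).T @ dpre_c
            drh = dpre_c @ Whh.T
            dr = drh * hp
            dhp = dhp + drh * r
            dpre_z = dz * z * (1 - z)
            dpre_r = dr * r * (1 - r)
            dxp[:, t, :H] = dpre_z
            dxp[:, t, H : 2 * H] = dpre_r
            dWh[:, :H] += hp.T @ dpre_z
            dWh[:, H : 2 * H] += hp.T @ dpre_r
            dhp = dhp + dpre_z @ Whz.T + dpre_r @ Whr.T
            dh = dhp
        self.grads["Wh"] = dWh
        self.grads["Wx"] = np.einsum("bti,btj->ij", x, dxp)
        self.grads["b"] = dxp.sum(axis=(0, 1))
        return dxp @ self.params["Wx"].T


class Dropout(Layer):
    """Inverted dropout; identity in inference mode."""

    def __init__(self, p: float) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p

    def forward(self, x, training=False, rng=None):
        if not training or self.p == 0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an rng")
        self._mask = (rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask


class Dense(Layer):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.params = {"W": _glorot(rng, (d_in, d_out)), "b": np.zeros(d_out)}

    def forward(self, x, training=False, rng=None):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        self.grads["W"] = self._x.T @ dy
        self.grads["b"] = dy.sum(axis=0)
        return dy @ self.params["W"].T


class Adam:
    """Adaptive-moment gradient descent over a flat name->array param dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1**self.t)
            vhat = self.v[k] / (1 - b2**self.t)
            self.params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
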