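"""Compact numpy neural-network engine for the read classifier.

Implements exactly the layer repertoire the read model needs — 1D valid
convolution, non-overlapping max-pooling, a bidirectional LSTM, dropout,
flatten and dense layers — with hand-written backpropagation and an Adam
optimizer.  Everything is float32 by default (float64 available for gradient
checking); all randomness flows from a single ``numpy.random.Generator`` so
training is reproducible from a seed.

The engine is intentionally minimal: batch-first tensors ``(B, T, C)``,
valid (no-padding) convolutions, and a fused sigmoid/binary-cross-entropy
head (layers output logits; the sigmoid lives in the loss and in
``predict_proba``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Conv1D",
    "MaxPool1D",
    "Dropout",
    "BiLSTM",
    "Flatten",
    "Dense",
    "Network",
    "Adam",
    "sigmoid",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], dtype) -> np.ndarray:
    fan_in, fan_out = shape[0], shape[-1]
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(dtype)


class Layer:
    """Base layer: holds params/grads dicts; subclasses cache for backward."""

    def __init__(self):
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def zero_grad(self):
        self.grads = {k: np.zeros_like(v) for k, v in self.params.items()}


class Conv1D(Layer):
    """Valid 1D convolution (B, T, C) -> (B, T-w+1, F), optional ReLU."""

    def __init__(self, in_channels: int, filters: int, width: int,
                 activation: str | None = "relu", *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.in_channels = in_channels
        self.filters = filters
        self.width = width
        self.activation = activation
        self.params["W"] = _glorot(rng, (width * in_channels, filters), dtype)
        self.params["b"] = np.zeros(filters, dtype=dtype)
        self.zero_grad()

    def _cols(self, x: np.ndarray) -> np.ndarray:
        # (B, T, C) -> (B, P, w*C) sliding windows, P = T - w + 1
        win = np.lib.stride_tricks.sliding_window_view(x, self.width, axis=1)
        # win: (B, P, C, w) -> (B, P, w, C)
        win = np.ascontiguousarray(win.transpose(0, 1, 3, 2))
        B, P = win.shape[:2]
        return win.reshape(B, P, self.width * self.in_channels)

    def forward(self, x, train=False):
        if x.shape[1] < self.width:
            raise ValueError(
                f"input length {x.shape[1]} shorter than kernel width {self.width}"
            )
        cols = self._cols(x)
        z = cols @ self.params["W"] + self.params["b"]
        self._cache = (x.shape, cols, z if self.activation else None)
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dy):
        x_shape, cols, z = self._cache
        dz = dy * (z > 0) if self.activation == "relu" else dy
        B, P, _ = cols.shape
        self.grads["W"] += cols.reshape(B * P, -1).T @ dz.reshape(B * P, -1)
        self.grads["b"] += dz.sum(axis=(0, 1))
        dcols = (dz @ self.params["W"].T).reshape(B, P, self.width, self.in_channels)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        for k in range(self.width):
            dx[:, k:k + P, :] += dcols[:, :, k, :]
        return dx


class MaxPool1D(Layer):
    """Non-overlapping temporal max pool; trailing remainder is dropped."""

    def __init__(self, width: int):
        super().__init__()
        self.width = width

    def forward(self, x, train=False):
        B, T, C = x.shape
        P = T // self.width
        xr = x[:, : P * self.width].reshape(B, P, self.width, C)
        idx = xr.argmax(axis=2)
        self._cache = (x.shape, idx)
        return np.take_along_axis(xr, idx[:, :, None, :], axis=2)[:, :, 0, :]

    def backward(self, dy):
        x_shape, idx = self._cache
        B, T, C = x_shape
        P = T // self.width
        dxr = np.zeros((B, P, self.width, C), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[:, :, None, :], dy[:, :, None, :], axis=2)
        dx = np.zeros(x_shape, dtype=dy.dtype)
        dx[:, : P * self.width] = dxr.reshape(B, P * self.width, C)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, p: float, *, rng: np.random.Generator):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout p must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0.0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask.astype(dy.dtype)


class BiLSTM(Layer):
    """Bidirectional LSTM returning the full sequence (B, T, 2*units).

    Gate order [input, forget, cell, output]; forget-gate bias initialized
    to 1.  The two directions hold independent parameters; the backward
    direction reads the sequence reversed and its outputs are re-reversed
    before concatenation.
    """

    def __init__(self, in_channels: int, units: int, *, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.in_channels = in_channels
        self.units = units
        for d in ("f", "b"):
            self.params[f"W{d}"] = _glorot(rng, (in_channels, 4 * units), dtype)
            self.params[f"U{d}"] = _glorot(rng, (units, 4 * units), dtype)
            bias = np.zeros(4 * units, dtype=dtype)
            bias[units:2 * units] = 1.0  # forget gate
            self.params[f"b{d}"] = bias
        self.zero_grad()

    def _run(self, x: np.ndarray, d: str):
        B, T, _ = x.shape
        u = self.units
        W, U, b = self.params[f"W{d}"], self.params[f"U{d}"], self.params[f"b{d}"]
        xz = x.reshape(B * T, -1) @ W  # input contribution, all steps at once
        xz = xz.reshape(B, T, 4 * u)
        h = np.zeros((B, u), dtype=x.dtype)
        c = np.zeros((B, u), dtype=x.dtype)
        H = np.empty((B, T, u), dtype=x.dtype)
        cache = []
        for t in range(T):
            z = xz[:, t] + h @ U + b
            i = sigmoid(z[:, :u])
            f = sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = sigmoid(z[:, 3 * u:])
            c_prev, h_prev = c, h
            c = f * c_prev + i * g
            h = o * np.tanh(c)
            H[:, t] = h
            cache.append((h_prev, c_prev, i, f, g, o, c))
        return H, cache

    def _run_backward(self, x: np.ndarray, dH: np.ndarray, cache, d: str):
        B, T, _ = x.shape
        u = self.units
        W, U = self.params[f"W{d}"], self.params[f"U{d}"]
        dW = np.zeros_like(W)
        dU = np.zeros_like(U)
        db = np.zeros_like(self.params[f"b{d}"])
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, u), dtype=x.dtype)
        dc_next = np.zeros((B, u), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            h_prev, c_prev, i, f, g, o, c = cache[t]
            dh = dH[:, t] + dh_next
            tc = np.tanh(c)
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            df = dc * c_prev
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f), dg * (1 - g * g),
                 do * o * (1 - o)], axis=1)
            dW += x[:, t].T @ dz
            dU += h_prev.T @ dz
            db += dz.sum(axis=0)
            dx[:, t] = dz @ W.T
            dh_next = dz @ U.T
        self.grads[f"W{d}"] += dW
        self.grads[f"U{d}"] += dU
        self.grads[f"b{d}"] += db
        return dx

    def forward(self, x, train=False):
        Hf, cache_f = self._run(x, "f")
        xr = x[:, ::-1]
        Hb, cache_b = self._run(xr, "b")
        self._cache = (x, xr, cache_f, cache_b)
        return np.concatenate([Hf, Hb[:, ::-1]], axis=2)

    def backward(self, dy):
        x, xr, cache_f, cache_b = self._cache
        u = self.units
        dxf = self._run_backward(x, np.ascontiguousarray(dy[:, :, :u]), cache_f, "f")
        dxb = self._run_backward(
            xr, np.ascontiguousarray(dy[:, ::-1, u:]), cache_b, "b")
        return dxf + dxb[:, ::-1]


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected (B, n_in) -> (B, n_out), optional ReLU."""

    def __init__(self, n_in: int, n_out: int, activation: str | None = None,
                 *, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        if activation not in (None, "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.params["W"] = _glorot(rng, (n_in, n_out), dtype)
        self.params["b"] = np.zeros(n_out, dtype=dtype)
        self.zero_grad()

    def forward(self, x, train=False):
        z = x @ self.params["W"] + self.params["b"]
        self._cache = (x, z if self.activation else None)
        return np.maximum(z, 0.0) if self.activation == "relu" else z

    def backward(self, dy):
        x, z = self._cache
        dz = dy * (z > 0) if self.activation == "relu" else dy
        self.grads["W"] += x.T @ dz
        self.grads["b"] += dz.sum(axis=0)
        return dz @ self.params["W"].T


class Adam:
    """Adam optimizer over a network's parameter dictionaries."""

    def __init__(self, network: "Network", lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.network = network
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in network.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()}
                  for l in network.layers]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for li, layer in enumerate(self.network.layers):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m = self.m[li][k] = b1 * self.m[li][k] + (1 - b1) * g
                v = self.v[li][k] = b2 * self.v[li][k] + (1 - b2) * (g * g)
                p -= (self.lr * (m / corr1)
                      / (np.sqrt(v / corr2) + self.eps)).astype(p.dtype)


class Network:
    """A plain sequential stack with a fused sigmoid/BCE head."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x  # logits, shape (B, 1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def zero_grad(self):
        for layer in self.layers:
            layer.zero_grad()

    def predict_proba(self, x: np.ndarray, batch_size: int = 1024) -> np.ndarray:
        out = []
        for lo in range(0, len(x), batch_size):
            logits = self.forward(x[lo:lo + batch_size], train=False)
            out.append(sigmoid(logits)[:, 0])
        return np.concatenate(out) if out else np.empty(0)

    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in l.params.items()} for l in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]):
        for layer, w in zip(self.layers, weights):
            for k in layer.params:
                layer.params[k] = w[k].copy()


def bce_with_logits(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean binary cross-entropy on logits; returns (loss, dloss/dlogits)."""
    z = logits[:, 0]
    # stable softplus(z) - y*z
    loss = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    grad = ((sigmoid(z) - y) / len(y)).astype(logits.dtype)[:, None]
    return loss, grad
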