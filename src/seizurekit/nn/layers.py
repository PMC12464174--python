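"""Layer implementations for the NumPy network engine.

Sequence layers operate on ``(batch, length, channels)`` arrays; dense
layers on ``(batch, features)``.  Every layer implements ``forward`` (with a
``training`` flag), ``backward`` (returning the input gradient and filling
``self.grads``), and ``param_count`` following the convention used
throughout the package: batch normalization counts 4 parameters per channel
(scale, offset, moving mean, moving variance — the last two non-trainable).

Initialization mirrors common deep-learning defaults: Glorot-uniform
kernels, orthogonal LSTM recurrent weights, zero biases with the LSTM
forget-gate bias at one.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.special import expit

__all__ = [
    "Layer",
    "Conv1D",
    "BatchNorm",
    "Activation",
    "MaxPool1D",
    "LSTM",
    "Flatten",
    "Dense",
    "Dropout",
]


def _glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.standard_normal((max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q *= np.sign(np.diag(r))
    return q[:rows, :cols] if q.shape != (rows, cols) else q


class Layer:
    """Base layer: parameter dict, gradient dict, shape bookkeeping."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.input_shape: tuple[int, ...] | None = None
        self.output_shape: tuple[int, ...] | None = None

    def build(self, input_shape: tuple[int, ...], rng: np.random.Generator) -> tuple[int, ...]:
        self.input_shape = input_shape
        self.output_shape = input_shape
        return self.output_shape

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def param_count(self) -> int:
        return sum(p.size for p in self.params.values())

    def regularization_loss(self) -> float:
        return 0.0


class Conv1D(Layer):
    """1D convolution, valid padding: out = floor((in - k)/s) + 1."""

    def __init__(self, filters: int, kernel: int, stride: int = 1) -> None:
        super().__init__()
        if filters < 1 or kernel < 1 or stride < 1:
            raise ValueError("filters, kernel and stride must be positive")
        self.filters, self.kernel, self.stride = filters, kernel, stride

    def build(self, input_shape, rng):
        length, cin = input_shape
        out_len = (length - self.kernel) // self.stride + 1
        if out_len < 1:
            raise ValueError(
                f"conv1d(k={self.kernel}, s={self.stride}) on length {length} "
                "yields empty output"
            )
        fan_in = self.kernel * cin
        self.params["W"] = _glorot_uniform(
            rng, (self.kernel, cin, self.filters), fan_in, self.filters
        )
        self.params["b"] = np.zeros(self.filters)
        self.input_shape = input_shape
        self.output_shape = (out_len, self.filters)
        return self.output_shape

    def forward(self, x, training=False):
        # frames: (B, out_len, cin, kernel)
        frames = sliding_window_view(x, self.kernel, axis=1)[:, :: self.stride]
        self._frames = frames
        return np.einsum("blck,kcf->blf", frames, self.params["W"]) + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] = np.einsum("blck,blf->kcf", self._frames, dy)
        self.grads["b"] = dy.sum(axis=(0, 1))
        B = dy.shape[0]
        length = self.input_shape[0]
        dx = np.zeros((B, length, W.shape[1]))
        out_len = dy.shape[1]
        pos = self.stride * np.arange(out_len)
        for j in range(self.kernel):
            # taps at fixed offset j hit distinct input positions
            dx[:, pos + j, :] += dy @ W[j].T
        return dx


class BatchNorm(Layer):
    """Batch normalization over batch (and length, for sequences).

    Normalizes each channel to zero mean, unit variance within the batch
    (eps 1e-5), then scales/offsets by learned gamma/beta.  Inference uses
    exponential moving statistics (momentum 0.99).  Counts 4 parameters per
    channel including the two moving statistics.
    """

    def __init__(self, eps: float = 1e-5, momentum: float = 0.99) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum

    def build(self, input_shape, rng):
        c = input_shape[-1]
        self.params["gamma"] = np.ones(c)
        self.params["beta"] = np.zeros(c)
        # Raw exponential moving sums; debiased on read so early-training
        # inference is unbiased (no cold start at high momentum).
        self._ema_mean = np.zeros(c)
        self._ema_var = np.zeros(c)
        self._ema_t = 0
        self.input_shape = input_shape
        self.output_shape = input_shape
        return input_shape

    @property
    def moving_mean(self) -> np.ndarray:
        if self._ema_t == 0:
            return np.zeros_like(self._ema_mean)
        return self._ema_mean / (1.0 - self.momentum**self._ema_t)

    @property
    def moving_var(self) -> np.ndarray:
        if self._ema_t == 0:
            return np.ones_like(self._ema_var)
        return self._ema_var / (1.0 - self.momentum**self._ema_t)

    def param_count(self) -> int:
        # gamma + beta + moving mean + moving variance
        return 4 * self.params["gamma"].size

    def forward(self, x, training=False):
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self._ema_mean = self.momentum * self._ema_mean + (1 - self.momentum) * mean
            self._ema_var = self.momentum * self._ema_var + (1 - self.momentum) * var
            self._ema_t += 1
        else:
            mean, var = self.moving_mean, self.moving_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean) * inv
        if training:
            self._xhat, self._inv, self._axes = xhat, inv, axes
            self._n = int(np.prod([x.shape[a] for a in axes]))
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dy):
        xhat, inv, axes, n = self._xhat, self._inv, self._axes, self._n
        self.grads["gamma"] = (dy * xhat).sum(axis=axes)
        self.grads["beta"] = dy.sum(axis=axes)
        g = self.params["gamma"]
        dx = (g * inv / n) * (
            n * dy - dy.sum(axis=axes) - xhat * (dy * xhat).sum(axis=axes)
        )
        return dx


class Activation(Layer):
    """Elementwise / row-wise activation: relu, sigmoid, tanh or softmax."""

    KINDS = ("relu", "sigmoid", "tanh", "softmax", "linear")

    def __init__(self, kind: str) -> None:
        super().__init__()
        if kind not in self.KINDS:
            raise ValueError(f"unknown activation {kind!r}")
        self.kind = kind

    def forward(self, x, training=False):
        if self.kind == "relu":
            y = np.maximum(x, 0.0)
        elif self.kind == "sigmoid":
            y = 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
        elif self.kind == "tanh":
            y = np.tanh(x)
        elif self.kind == "softmax":
            z = x - x.max(axis=-1, keepdims=True)
            e = np.exp(z)
            y = e / e.sum(axis=-1, keepdims=True)
        else:
            y = x
        self._x, self._y = x, y
        return y

    def backward(self, dy):
        if self.kind == "relu":
            return dy * (self._x > 0)
        if self.kind == "sigmoid":
            return dy * self._y * (1.0 - self._y)
        if self.kind == "tanh":
            return dy * (1.0 - self._y**2)
        if self.kind == "softmax":
            p = self._y
            return p * (dy - (dy * p).sum(axis=-1, keepdims=True))
        return dy


class MaxPool1D(Layer):
    """Max pooling, valid padding: out = floor((in - pool)/s) + 1."""

    def __init__(self, pool: int, stride: int) -> None:
        super().__init__()
        if pool < 1 or stride < 1:
            raise ValueError("pool and stride must be positive")
        self.pool, self.stride = pool, stride

    def build(self, input_shape, rng):
        length, c = input_shape
        out_len = (length - self.pool) // self.stride + 1
        if out_len < 1:
            raise ValueError(
                f"maxpool1d(p={self.pool}, s={self.stride}) on length {length} "
                "yields empty output"
            )
        self.input_shape = input_shape
        self.output_shape = (out_len, c)
        return self.output_shape

    def forward(self, x, training=False):
        frames = sliding_window_view(x, self.pool, axis=1)[:, :: self.stride]
        self._argmax = frames.argmax(axis=-1)  # (B, out_len, C)
        self._x_shape = x.shape
        return frames.max(axis=-1)

    def backward(self, dy):
        B, out_len, c = dy.shape
        dx = np.zeros(self._x_shape)
        starts = self.stride * np.arange(out_len)
        b_idx = np.arange(B)[:, None, None]
        l_idx = starts[None, :, None] + self._argmax
        c_idx = np.arange(c)[None, None, :]
        np.add.at(dx, (b_idx, l_idx, c_idx), dy)
        return dx


class LSTM(Layer):
    """Single LSTM layer returning the final hidden state.

    Gates follow the standard formulation (input, forget, cell, output;
    sigmoid gates, tanh cell), parameters W (features x 4U), R (U x 4U) and
    bias (4U): 4·((features + units)·units + units) parameters.
    """

    def __init__(self, units: int) -> None:
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.units = units

    def build(self, input_shape, rng):
        _, f = input_shape
        u = self.units
        self.params["W"] = _glorot_uniform(rng, (f, 4 * u), f, 4 * u)
        self.params["R"] = np.concatenate(
            [_orthogonal(rng, u, u) for _ in range(4)], axis=1
        )
        b = np.zeros(4 * u)
        b[u : 2 * u] = 1.0  # forget-gate bias
        self.params["b"] = b
        self.input_shape = input_shape
        self.output_shape = (u,)
        return self.output_shape

    def forward(self, x, training=False):
        B, T, _ = x.shape
        u = self.units
        W, R, b = self.params["W"], self.params["R"], self.params["b"]
        h = np.zeros((B, u))
        c = np.zeros((B, u))
        xw = x @ W + b  # (B, T, 4u) — input projection hoisted out of the loop
        zbuf = np.empty((B, 4 * u))
        if training:
            # per-gate activations cached as (T, B, u) stacks for BPTT —
            # time-major so each step reads/writes one contiguous slab
            cache = {k: np.empty((T, B, u)) for k in
                     ("i", "f", "g", "o", "c_prev", "tc", "h_prev")}
        for t in range(T):
            np.dot(h, R, out=zbuf)
            zbuf += xw[:, t]
            # sigmoid gates in place (i, f blocks and o block), tanh cell
            expit(zbuf[:, : 2 * u], out=zbuf[:, : 2 * u])
            expit(zbuf[:, 3 * u :], out=zbuf[:, 3 * u :])
            g = np.tanh(zbuf[:, 2 * u : 3 * u])
            i = zbuf[:, :u]
            f = zbuf[:, u : 2 * u]
            o = zbuf[:, 3 * u :]
            c_prev = c
            c = f * c_prev + i * g
            tc = np.tanh(c)
            h_prev = h
            h = o * tc
            if training:
                for k, v in (("i", i), ("f", f), ("g", g), ("o", o),
                             ("c_prev", c_prev), ("tc", tc), ("h_prev", h_prev)):
                    cache[k][t] = v
        if training:
            self._cache, self._x = cache, x
        return h

    def backward(self, dy):
        x, cache = self._x, self._cache
        B, T, f_in = x.shape
        u = self.units
        W, R = self.params["W"], self.params["R"]
        # The recurrent coupling forces a sequential loop, but only for the
        # elementwise gate derivatives and dh = dz @ R.T; the large GEMMs
        # (dW, dR, db, dx) batch over all timesteps afterwards.
        dz_all = np.empty((T, B, 4 * u))
        dh = dy
        dc = np.zeros((B, u))
        for t in range(T - 1, -1, -1):
            i = cache["i"][t]
            f = cache["f"][t]
            g = cache["g"][t]
            o = cache["o"][t]
            c_prev = cache["c_prev"][t]
            tc = cache["tc"][t]
            do = dh * tc
            dc = dc + dh * o * (1.0 - tc**2)
            dz = dz_all[t]
            dz[:, :u] = (dc * g) * i * (1.0 - i)
            dz[:, u : 2 * u] = (dc * c_prev) * f * (1.0 - f)
            dz[:, 2 * u : 3 * u] = (dc * i) * (1.0 - g**2)
            dz[:, 3 * u :] = do * o * (1.0 - o)
            dh = dz @ R.T
            dc = dc * f
        flat_dz = dz_all.reshape(T * B, 4 * u)
        xt = np.ascontiguousarray(x.transpose(1, 0, 2)).reshape(T * B, f_in)
        self.grads["W"] = xt.T @ flat_dz
        self.grads["R"] = cache["h_prev"].reshape(T * B, u).T @ flat_dz
        self.grads["b"] = flat_dz.sum(axis=0)
        return (dz_all @ W.T).transpose(1, 0, 2)


class Flatten(Layer):
    """Collapse all non-batch axes (a no-op after an LSTM's vector output)."""

    def build(self, input_shape, rng):
        self.input_shape = input_shape
        self.output_shape = (int(np.prod(input_shape)),)
        return self.output_shape

    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy):
        return dy.reshape(self._shape)


class Dense(Layer):
    """Fully connected layer with optional L2 weight penalty (l2·sum W²)."""

    def __init__(self, units: int, l2: float = 0.0) -> None:
        super().__init__()
        if units < 1:
            raise ValueError("units must be positive")
        self.units, self.l2 = units, l2

    def build(self, input_shape, rng):
        (f,) = input_shape
        self.params["W"] = _glorot_uniform(rng, (f, self.units), f, self.units)
        self.params["b"] = np.zeros(self.units)
        self.input_shape = input_shape
        self.output_shape = (self.units,)
        return self.output_shape

    def forward(self, x, training=False):
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dy):
        W = self.params["W"]
        self.grads["W"] = self._x.T @ dy
        if self.l2:
            self.grads["W"] = self.grads["W"] + 2.0 * self.l2 * W
        self.grads["b"] = dy.sum(axis=0)
        return dy @ W.T

    def regularization_loss(self) -> float:
        if not self.l2:
            return 0.0
        return float(self.l2 * np.sum(self.params["W"] ** 2))


class Dropout(Layer):
    """Inverted dropout: active only in training, identity at inference."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def build(self, input_shape, rng):
        if self.rng is None:
            self.rng = np.random.default_rng(rng.integers(2**31))
        self.input_shape = input_shape
        self.output_shape = input_shape
        return input_shape

    def forward(self, x, training=False):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep) / keep
        return x * self._mask

    def backward(self, dy):
        return dy if self._mask is None else dy * self._mask
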