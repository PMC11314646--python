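"""Differentiable layer primitives for the 1-D attention CNNs.

Everything here operates on arrays of shape ``(N, C, L)`` (batch, channels,
positions) and implements an explicit ``forward`` / ``backward`` pair; the
backward pass leaves parameter gradients on the layer and returns the
gradient with respect to the layer input.  The convolution follows the
neural-convolution convention ``y[n] = sum_m x[n-m] * w[M-1-m]`` with
zero padding on the left so that output length equals input length.
"""
from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def activation(kind: str, x: np.ndarray) -> np.ndarray:
    """Pointwise nonlinearity: ``relu``, ``swish`` (x*sigmoid(x)) or ``sine``."""
    x = np.asarray(x, dtype=np.float64)
    if kind == "relu":
        return np.maximum(0.0, x)
    if kind == "swish":
        return x * sigmoid(x)
    if kind == "sine":
        return np.sin(x)
    raise ValueError(f"unknown activation kind {kind!r}")


def activation_grad(kind: str, x: np.ndarray) -> np.ndarray:
    if kind == "relu":
        return (x > 0).astype(np.float64)
    if kind == "swish":
        s = sigmoid(x)
        return s * (1.0 + x * (1.0 - s))
    if kind == "sine":
        return np.cos(x)
    raise ValueError(f"unknown activation kind {kind!r}")


class Layer:
    """Base class: parameterless identity."""

    def params(self) -> dict[str, np.ndarray]:
        """Learnable arrays by name."""
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def buffers(self) -> dict[str, np.ndarray]:
        """Non-learnable state (e.g. batch-norm running statistics)."""
        return {}

    def n_params(self) -> int:
        return sum(int(a.size) for a in self.params().values())

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Conv1D(Layer):
    """1-D convolution with length-preserving (left) zero padding.

    ``y[o, n] = b[o] + sum_c sum_m x[c, n-m] w[o, c, M-1-m]`` — i.e. true
    convolution of each input channel with the stored kernel, summed over
    input channels.  Weight shape is ``(C_out, C_in, M)``.
    """

    def __init__(self, c_in: int, c_out: int, m: int, rng: np.random.Generator | None = None):
        if m < 1 or c_in < 1 or c_out < 1:
            raise ValueError("conv dimensions must be >= 1")
        self.c_in, self.c_out, self.m = c_in, c_out, m
        if rng is None:
            self.w = np.zeros((c_out, c_in, m))
        else:
            self.w = glorot_uniform(rng, (c_out, c_in, m), c_in * m, c_out * m)
        self.b = np.zeros(c_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, training=False):
        if x.shape[1] != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {x.shape[1]}")
        # y[n] = sum_j w[j] x[n - (M-1) + j]: left-pad M-1 zeros, then correlate
        xp = np.pad(x, ((0, 0), (0, 0), (self.m - 1, 0)))
        cols = sliding_window_view(xp, self.m, axis=2)  # (N, C_in, L, M)
        self._cols = cols
        self._xshape = x.shape
        return np.einsum("nclm,ocm->nol", cols, self.w, optimize=True) + self.b[None, :, None]

    def backward(self, dout):
        self.dw = np.einsum("nclm,nol->ocm", self._cols, dout, optimize=True)
        self.db = dout.sum(axis=(0, 2))
        n, _, L = self._xshape
        dxp = np.zeros((n, self.c_in, L + self.m - 1))
        for j in range(self.m):
            dxp[:, :, j : j + L] += np.einsum("nol,oc->ncl", dout, self.w[:, :, j], optimize=True)
        return dxp[:, :, self.m - 1 :]


class BatchNorm1D(Layer):
    """Per-channel batch normalization over (batch, positions).

    Training uses batch statistics and updates running statistics with
    exponential momentum; inference uses the running statistics.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.1):
        self.c = c
        self.eps = eps
        self.momentum = momentum
        self.gamma = np.ones(c)
        self.beta = np.zeros(c)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.dgamma = np.zeros(c)
        self.dbeta = np.zeros(c)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def forward(self, x, training=False):
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        self._training = training
        if training:
            mean = x.mean(axis=(0, 2))
            var = x.var(axis=(0, 2))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        self._inv_std = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mean[None, :, None]) * self._inv_std[None, :, None]
        return self.gamma[None, :, None] * self._xhat + self.beta[None, :, None]

    def backward(self, dout):
        xhat, inv_std = self._xhat, self._inv_std
        self.dgamma = (dout * xhat).sum(axis=(0, 2))
        self.dbeta = dout.sum(axis=(0, 2))
        g = self.gamma[None, :, None] * inv_std[None, :, None]
        if not self._training:
            return dout * g
        m = dout.shape[0] * dout.shape[2]
        dxhat_sum = dout.sum(axis=(0, 2))[None, :, None]
        dxhat_dot = (dout * xhat).sum(axis=(0, 2))[None, :, None]
        return g * (dout - dxhat_sum / m - xhat * dxhat_dot / m)


class Activation(Layer):
    def __init__(self, kind: str):
        if kind not in ("relu", "swish", "sine"):
            raise ValueError(f"unknown activation kind {kind!r}")
        self.kind = kind

    def forward(self, x, training=False):
        self._x = x
        return activation(self.kind, x)

    def backward(self, dout):
        return dout * activation_grad(self.kind, self._x)


class MaxPool1D(Layer):
    """Max pooling; a trailing position not filling a full window is dropped."""

    def __init__(self, size: int = 2, stride: int = 2):
        if size != stride:
            raise ValueError("only non-overlapping pooling is supported")
        self.size = size

    def forward(self, x, training=False):
        n, c, L = x.shape
        lo = L // self.size
        xt = x[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        self._argmax = xt.argmax(axis=3)
        self._in_len = L
        return xt.max(axis=3)

    def backward(self, dout):
        n, c, lo = dout.shape
        dx = np.zeros((n, c, self._in_len))
        dxt = dx[:, :, : lo * self.size].reshape(n, c, lo, self.size)
        np.put_along_axis(dxt, self._argmax[..., None], dout[..., None], axis=3)
        return dx


class Dropout(Layer):
    """Inverted dropout; identity at inference time."""

    def __init__(self, p: float = 0.5):
        if not 0 <= p < 1:
            raise ValueError("dropout rate must be in [0, 1)")
        self.p = p
        self.rng = np.random.default_rng(0)

    def forward(self, x, training=False):
        if not training or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask

    def backward(self, dout):
        return dout if self._mask is None else dout * self._mask


class Flatten(Layer):
    def forward(self, x, training=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        self.n_in, self.n_out = n_in, n_out
        if rng is None:
            self.w = np.zeros((n_out, n_in))
        else:
            self.w = glorot_uniform(rng, (n_out, n_in), n_in, n_out)
        self.b = np.zeros(n_out)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"w": self.w, "b": self.b}

    def grads(self):
        return {"w": self.dw, "b": self.db}

    def forward(self, x, training=False):
        if x.shape[1] != self.n_in:
            raise ValueError(f"expected {self.n_in} features, got {x.shape[1]}")
        self._x = x
        return x @ self.w.T + self.b

    def backward(self, dout):
        self.dw = dout.T @ self._x
        self.db = dout.sum(axis=0)
        return dout @ self.w


class SEAttention(Layer):
    """Squeeze–excitation channel attention.

    Global average pooling squeezes each feature map to a scalar; a two-layer
    bottleneck (C -> floor(C/r) with ReLU -> C with sigmoid, both layers with
    biases) produces one gate scalar per channel which rescales the map:
    ``out_c = s_c * x_c``.
    """

    def __init__(self, c: int, r: int, rng: np.random.Generator | None = None):
        if r < 1:
            raise ValueError("reduction ratio must be >= 1")
        self.c, self.r = c, r
        self.hidden = max(1, c // r)
        h = self.hidden
        if rng is None:
            self.w1 = np.zeros((h, c))
            self.w2 = np.zeros((c, h))
        else:
            self.w1 = glorot_uniform(rng, (h, c), c, h)
            self.w2 = glorot_uniform(rng, (c, h), h, c)
        self.b1 = np.zeros(h)
        self.b2 = np.zeros(c)
        self.dw1 = np.zeros_like(self.w1)
        self.db1 = np.zeros_like(self.b1)
        self.dw2 = np.zeros_like(self.w2)
        self.db2 = np.zeros_like(self.b2)
        self.last_scale: np.ndarray | None = None  # (N, C), for inspection

    def params(self):
        return {"w1": self.w1, "b1": self.b1, "w2": self.w2, "b2": self.b2}

    def grads(self):
        return {"w1": self.dw1, "b1": self.db1, "w2": self.dw2, "b2": self.db2}

    def forward(self, x, training=False):
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        self._x = x
        self._z = x.mean(axis=2)  # squeeze: (N, C)
        self._h_pre = self._z @ self.w1.T + self.b1
        self._h = np.maximum(0.0, self._h_pre)
        s_pre = self._h @ self.w2.T + self.b2
        self._s = sigmoid(s_pre)
        self.last_scale = self._s
        return x * self._s[:, :, None]

    def backward(self, dout):
        x, s, h = self._x, self._s, self._h
        L = x.shape[2]
        dx = dout * s[:, :, None]
        ds = (dout * x).sum(axis=2)
        ds_pre = ds * s * (1.0 - s)
        self.dw2 = ds_pre.T @ h
        self.db2 = ds_pre.sum(axis=0)
        dh = ds_pre @ self.w2
        dh_pre = dh * (self._h_pre > 0)
        self.dw1 = dh_pre.T @ self._z
        self.db1 = dh_pre.sum(axis=0)
        dz = dh_pre @ self.w1
        dx += dz[:, :, None] / L
        return dx


class ATACAttention(Layer):
    """Attention-as-activation gating module.

    Two point-wise (kernel length 1) convolutions with batch normalization —
    C -> floor(C/r) with ReLU, then floor(C/r) -> C — feed a sigmoid gate
    that multiplies the feature map elementwise.  Unlike squeeze–excitation
    the gate varies across positions, giving local channel attention.
    """

    def __init__(self, c: int, r: int, rng: np.random.Generator | None = None):
        if r < 1:
            raise ValueError("reduction ratio must be >= 1")
        self.c, self.r = c, r
        self.hidden = max(1, c // r)
        self.conv1 = Conv1D(c, self.hidden, 1, rng)
        self.bn1 = BatchNorm1D(self.hidden)
        self.conv2 = Conv1D(self.hidden, c, 1, rng)
        self.bn2 = BatchNorm1D(c)
        self.last_gate: np.ndarray | None = None  # (N, C, L)

    def params(self):
        out = {}
        for tag, sub in (("pw1", self.conv1), ("bn1", self.bn1), ("pw2", self.conv2), ("bn2", self.bn2)):
            for k, v in sub.params().items():
                out[f"{tag}.{k}"] = v
        return out

    def grads(self):
        out = {}
        for tag, sub in (("pw1", self.conv1), ("bn1", self.bn1), ("pw2", self.conv2), ("bn2", self.bn2)):
            for k, v in sub.grads().items():
                out[f"{tag}.{k}"] = v
        return out

    def buffers(self):
        out = {}
        for tag, sub in (("bn1", self.bn1), ("bn2", self.bn2)):
            for k, v in sub.buffers().items():
                out[f"{tag}.{k}"] = v
        return out

    def forward(self, x, training=False):
        if x.shape[1] != self.c:
            raise ValueError(f"expected {self.c} channels, got {x.shape[1]}")
        self._x = x
        a = self.conv1.forward(x, training)
        a = self.bn1.forward(a, training)
        self._relu_pre = a
        a = np.maximum(0.0, a)
        a = self.conv2.forward(a, training)
        a = self.bn2.forward(a, training)
        self._g = sigmoid(a)
        self.last_gate = self._g
        return x * self._g

    def backward(self, dout):
        g = self._g
        dx = dout * g
        dg = dout * self._x
        da = dg * g * (1.0 - g)
        da = self.bn2.backward(da)
        da = self.conv2.backward(da)
        da = da * (self._relu_pre > 0)
        da = self.bn1.backward(da)
        da = self.conv1.backward(da)
        return dx + da
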