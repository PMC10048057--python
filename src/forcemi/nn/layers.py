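"""Layers with explicit forward/backward passes.

Tensor layout is (batch, feature-channel, height, width) unless noted;
for EEG input height = electrodes N and width = time points M.  Each
layer stores parameters in ``self.params`` and accumulates gradients in
``self.grads`` during ``backward``.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


class Layer:
    """Base class: stateless layers only need forward/backward."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def parameters(self):
        for name in self.params:
            yield self, name

    def __call__(self, x, train=False):
        return self.forward(x, train)


class Sequential(Layer):
    def __init__(self, *layers: Layer) -> None:
        super().__init__()
        self.layers = list(layers)

    def forward(self, x, train=False):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def parameters(self):
        for layer in self.layers:
            yield from layer.parameters()


class Concat(Layer):
    """Run branches on the same input; concatenate along channel axis."""

    def __init__(self, *branches: Layer) -> None:
        super().__init__()
        self.branches = list(branches)
        self._splits: list[int] = []

    def forward(self, x, train=False):
        outs = [b.forward(x, train) for b in self.branches]
        self._splits = np.cumsum([o.shape[1] for o in outs])[:-1].tolist()
        return np.concatenate(outs, axis=1)

    def backward(self, dout):
        parts = np.split(dout, self._splits, axis=1)
        dx = None
        for branch, g in zip(self.branches, parts):
            gb = branch.backward(np.ascontiguousarray(g))
            dx = gb if dx is None else dx + gb
        return dx

    def parameters(self):
        for b in self.branches:
            yield from b.parameters()


class TemporalConv(Layer):
    """Convolution with a (1, S) kernel along the time axis, 'same' padding.

    Input (B, 1, N, M) -> output (B, F, N, M).  S must be odd so that the
    symmetric padding keeps the width exactly M.
    """

    def __init__(self, n_filters: int, kernel_width: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        if kernel_width % 2 == 0:
            raise ValueError("temporal kernel width must be odd")
        self.S = kernel_width
        scale = np.sqrt(2.0 / kernel_width)
        self.params = {
            "W": (rng.standard_normal((n_filters, kernel_width)) * scale).astype(dtype),
            "b": np.zeros(n_filters, dtype=dtype),
        }
        self._xp = None

    @staticmethod
    def _shift_stack(x3: np.ndarray, S: int) -> np.ndarray:
        """(B, N, M) -> contiguous (S, B*N*M) stack of S time shifts."""
        pad = (S - 1) // 2
        xp = np.pad(x3, ((0, 0), (0, 0), (pad, pad)))
        M = x3.shape[-1]
        win = sliding_window_view(xp, S, axis=-1)      # (B, N, M, S)
        return np.ascontiguousarray(np.moveaxis(win, -1, 0)).reshape(S, -1)

    def forward(self, x, train=False):
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (B, 1, N, M) input, got {x.shape}")
        self._in_shape = x.shape
        self._stack = self._shift_stack(x[:, 0], self.S)   # (S, B*N*M)
        B, _, N, M = x.shape
        out = (self.params["W"] @ self._stack).reshape(-1, B, N, M)
        return (np.moveaxis(out, 0, 1)
                + self.params["b"][None, :, None, None])

    def backward(self, dout):
        B, _, N, M = self._in_shape
        F = self.params["W"].shape[0]
        g = np.ascontiguousarray(np.moveaxis(dout, 1, 0)).reshape(F, -1)
        self.grads["W"] = g @ self._stack.T
        self.grads["b"] = dout.sum(axis=(0, 2, 3))
        # dx[j] = sum_s A_s[j - s + pad] with A_s = sum_f W[f,s] * dout[f]
        dstack = (self.params["W"].T @ g).reshape(self.S, B, N, M)
        pad = (self.S - 1) // 2
        dx = np.zeros((B, N, M), dtype=dout.dtype)
        for s in range(self.S):
            js, je = max(0, s - pad), min(M, M + s - pad)
            dx[:, :, js:je] += dstack[s][:, :, js - s + pad:je - s + pad]
        return dx[:, None]


class SpatialConv(Layer):
    """Convolution with an (N, 1) kernel collapsing the electrode axis.

    Input (B, C, N, M) -> output (B, G, 1, M): for every time point a
    learned linear map from all C x N input values to G feature channels.
    """

    def __init__(self, in_channels: int, out_channels: int, n_electrodes: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        fan_in = in_channels * n_electrodes
        scale = np.sqrt(2.0 / fan_in)
        self.params = {
            "W": (rng.standard_normal((out_channels, in_channels, n_electrodes))
                  * scale).astype(dtype),
            "b": np.zeros(out_channels, dtype=dtype),
        }
        self._x2 = None

    def forward(self, x, train=False):
        B, C, N, M = x.shape
        G = self.params["W"].shape[0]
        self._shape = (B, C, N, M)
        self._x2 = x.reshape(B, C * N, M)
        W2 = self.params["W"].reshape(G, C * N)
        out = np.matmul(W2[None], self._x2) + self.params["b"][None, :, None]
        return out[:, :, None, :]  # (B, G, 1, M)

    def backward(self, dout):
        B, C, N, M = self._shape
        G = self.params["W"].shape[0]
        g = dout[:, :, 0, :]  # (B, G, M)
        dW2 = np.matmul(g, self._x2.transpose(0, 2, 1)).sum(axis=0)
        self.grads["W"] = dW2.reshape(G, C, N)
        self.grads["b"] = g.sum(axis=(0, 2))
        W2 = self.params["W"].reshape(G, C * N)
        dx2 = np.matmul(W2.T[None], g)
        return dx2.reshape(B, C, N, M)


class BatchNorm(Layer):
    """Batch normalization per feature channel (axis 1)."""

    def __init__(self, n_channels: int, momentum: float = 0.1,
                 eps: float = 1e-5, dtype=np.float32) -> None:
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.params = {
            "gamma": np.ones(n_channels, dtype=dtype),
            "beta": np.zeros(n_channels, dtype=dtype),
        }
        self.running_mean = np.zeros(n_channels, dtype=np.float64)
        self.running_var = np.ones(n_channels, dtype=np.float64)

    def _bshape(self, x):
        return (1, -1) + (1,) * (x.ndim - 2)

    def forward(self, x, train=False):
        axes = (0,) + tuple(range(2, x.ndim))
        shape = self._bshape(x)
        if train:
            mean = x.mean(axis=axes, dtype=np.float64)
            var = x.var(axis=axes, dtype=np.float64)
            self.running_mean += self.momentum * (mean - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mean = self.running_mean
            var = self.running_var
        self._inv_std = (1.0 / np.sqrt(var + self.eps))
        self._mean = mean
        self._train = train
        self._axes = axes
        self._x = x
        # out = x * a + c with per-channel a = gamma/std, c = beta - mean*a
        a = (self.params["gamma"] * self._inv_std).astype(x.dtype)
        c = (self.params["beta"] - self._mean * a).astype(x.dtype)
        return x * a.reshape(shape) + c.reshape(shape)

    def backward(self, dout):
        shape = self._bshape(dout)
        axes = self._axes
        m = dout.size / dout.shape[1]
        sum_d = dout.sum(axis=axes, dtype=np.float64)
        sum_dx = (dout * self._x).sum(axis=axes, dtype=np.float64)
        # dgamma = sum(dout * xhat) expressed through raw-x sums
        self.grads["beta"] = sum_d.astype(dout.dtype)
        dgamma = (sum_dx - self._mean * sum_d) * self._inv_std
        self.grads["gamma"] = dgamma.astype(dout.dtype)
        gi = self.params["gamma"] * self._inv_std
        if not self._train:
            return dout * gi.astype(dout.dtype).reshape(shape)
        # dx = gi*(dout - sum_d/m - xhat*dgamma/m), xhat = (x-mean)*inv_std
        k1 = gi
        k2 = -gi * self._inv_std * dgamma / m
        k3 = -gi * (sum_d / m - self._mean * self._inv_std * dgamma / m)
        k1 = k1.astype(dout.dtype).reshape(shape)
        k2 = k2.astype(dout.dtype).reshape(shape)
        k3 = k3.astype(dout.dtype).reshape(shape)
        return dout * k1 + self._x * k2 + k3


class ELU(Layer):
    def __init__(self, alpha: float = 1.0) -> None:
        super().__init__()
        self.alpha = alpha

    def forward(self, x, train=False):
        self._pos = x > 0
        self._out = np.where(self._pos, x, self.alpha * np.expm1(x))
        return self._out

    def backward(self, dout):
        return dout * np.where(self._pos, 1.0, self._out + self.alpha)


class AvgPoolWidth(Layer):
    """Average pooling (1, K) with stride K along the width axis."""

    def __init__(self, pool_width: int) -> None:
        super().__init__()
        self.K = pool_width

    def forward(self, x, train=False):
        B, C, H, M = x.shape
        if M % self.K:
            raise ValueError(
                f"width {M} not divisible by pool width K={self.K}")
        self._M = M
        return x.reshape(B, C, H, M // self.K, self.K).mean(axis=-1)

    def backward(self, dout):
        return np.repeat(dout, self.K, axis=-1) / self.K


class Dropout(Layer):
    """Inverted dropout; active only in training mode."""

    def __init__(self, p: float, rng: np.random.Generator) -> None:
        super().__init__()
        if not 0 <= p < 1:
            raise ValueError("dropout rate must lie in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x, train=False):
        if not train or self.p == 0:
            self._mask = None
            return x
        self._mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * self._mask.astype(x.dtype)

    def backward(self, dout):
        if self._mask is None:
            return dout
        return dout * self._mask.astype(dout.dtype)


class ChannelAttention(Layer):
    """Channel-attention recalibration (shared-MLP avg+max squeeze).

    Per feature channel, global average- and max-pooled descriptors pass
    through a shared bias-free two-layer perceptron (C -> C/r -> C,
    rectifier in between); the two outputs are summed and squashed by a
    sigmoid into weights in (0, 1) that rescale the input channels.
    """

    def __init__(self, n_channels: int, reduction: int,
                 rng: np.random.Generator, dtype=np.float32) -> None:
        super().__init__()
        if n_channels % reduction:
            raise ValueError(
                f"feature channels C={n_channels} not divisible by reduction "
                f"r={reduction}; choose r dividing C")
        hidden = n_channels // reduction
        self.params = {
            "W0": (rng.standard_normal((hidden, n_channels))
                   * np.sqrt(2.0 / n_channels)).astype(dtype),
            "W1": (rng.standard_normal((n_channels, hidden))
                   * np.sqrt(1.0 / hidden)).astype(dtype),
        }

    def attention_weights(self, x: np.ndarray) -> np.ndarray:
        """Channel weights M_c in (0, 1), shape (B, C); caches for backward."""
        B, C = x.shape[:2]
        flat = x.reshape(B, C, -1)
        self._x = x
        self._p_avg = flat.mean(axis=2)                      # (B, C)
        self._argmax = flat.argmax(axis=2)
        self._p_max = np.take_along_axis(flat, self._argmax[:, :, None],
                                         axis=2)[:, :, 0]
        W0, W1 = self.params["W0"], self.params["W1"]
        self._u_avg = self._p_avg @ W0.T
        self._u_max = self._p_max @ W0.T
        self._r_avg = np.maximum(self._u_avg, 0)
        self._r_max = np.maximum(self._u_max, 0)
        z = (self._r_avg + self._r_max) @ W1.T
        self._a = 1.0 / (1.0 + np.exp(-z))
        return self._a

    def forward(self, x, train=False):
        a = self.attention_weights(x)
        return x * a.reshape(a.shape + (1,) * (x.ndim - 2))

    def backward(self, dout):
        x = self._x
        B, C = x.shape[:2]
        a_b = self._a.reshape((B, C) + (1,) * (x.ndim - 2))
        dx = dout * a_b
        da = (dout * x).reshape(B, C, -1).sum(axis=2)
        dz = da * self._a * (1.0 - self._a)
        W0, W1 = self.params["W0"], self.params["W1"]
        self.grads["W1"] = dz.T @ (self._r_avg + self._r_max)
        dr = dz @ W1                                         # (B, hidden)
        du_avg = dr * (self._u_avg > 0)
        du_max = dr * (self._u_max > 0)
        self.grads["W0"] = du_avg.T @ self._p_avg + du_max.T @ self._p_max
        dp_avg = du_avg @ W0
        dp_max = du_max @ W0
        n_spatial = int(np.prod(x.shape[2:]))
        dx_flat = dx.reshape(B, C, -1).copy()
        dx_flat += dp_avg[:, :, None] / n_spatial
        np.put_along_axis(
            dx_flat, self._argmax[:, :, None],
            np.take_along_axis(dx_flat, self._argmax[:, :, None], axis=2)
            + dp_max[:, :, None], axis=2)
        return dx_flat.reshape(x.shape)


class Flatten(Layer):
    def forward(self, x, train=False):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout):
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 dtype=np.float32) -> None:
        super().__init__()
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.params = {
            "W": (rng.standard_normal((n_out, n_in)) * scale).astype(dtype),
            "b": np.zeros(n_out, dtype=dtype),
        }

    def forward(self, x, train=False):
        self._x = x
        return x @ self.params["W"].T + self.params["b"]

    def backward(self, dout):
        self.grads["W"] = dout.T @ self._x
        self.grads["b"] = dout.sum(axis=0)
        return dout @ self.params["W"]
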