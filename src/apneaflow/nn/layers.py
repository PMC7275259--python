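"""Layers with explicit forward/backward passes.

All volumetric layers consume ``(N, H, W, T, C)`` float32 arrays.  Spatial
convolutions are stride-1 (matching the network definitions used here);
pooling supports arbitrary kernel/stride.  Convolution and pooling windows
are gathered with :func:`numpy.lib.stride_tricks.sliding_window_view` and
contracted with BLAS, which keeps desk-scale training tractable.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Layer",
    "Conv3D",
    "AvgPool3D",
    "MaxPool3D",
    "BatchNorm",
    "Dense",
    "Dropout",
    "Flatten",
    "GlobalAvgPool",
    "ReLU",
    "LeakyReLU",
    "Sigmoid",
]


def _triple(k) -> tuple[int, int, int]:
    if np.isscalar(k):
        return (int(k),) * 3
    k = tuple(int(v) for v in k)
    if len(k) != 3:
        raise ValueError(f"expected a 3-tuple kernel/stride, got {k!r}")
    return k


class Layer:
    """Base layer: stateless by default, trainable flag gates updates."""

    trainable: bool = True

    def initialize(self, rng: np.random.Generator) -> None:  # pragma: no cover
        pass

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[np.ndarray]:
        return []

    def grads(self) -> list[np.ndarray]:
        return []

    def state(self) -> list[np.ndarray]:
        """All arrays needed to snapshot/restore the layer (params + stats)."""
        return self.params()


class Conv3D(Layer):
    """Valid or 'same' stride-1 volumetric convolution.

    Weights are stored ``(kh, kw, kt, C_in, C_out)``; bias ``(C_out,)``.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel, padding: str = "valid"):
        self.in_channels = int(in_channels)
        self.out_channels = int(out_channels)
        self.kernel = _triple(kernel)
        if padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {padding!r}")
        self.padding = padding
        kh, kw, kt = self.kernel
        self.W = np.zeros((kh, kw, kt, self.in_channels, self.out_channels), dtype=np.float32)
        self.b = np.zeros(self.out_channels, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._x_padded: np.ndarray | None = None

    def initialize(self, rng: np.random.Generator) -> None:
        fan_in = np.prod(self.kernel) * self.in_channels
        std = np.sqrt(2.0 / fan_in)
        self.W[...] = rng.normal(0.0, std, size=self.W.shape).astype(np.float32)
        self.b[...] = 0.0

    def _pad(self, x: np.ndarray) -> tuple[np.ndarray, tuple]:
        if self.padding == "valid":
            return x, ((0, 0),) * 5
        kh, kw, kt = self.kernel
        pads = (
            (0, 0),
            ((kh - 1) // 2, kh // 2),
            ((kw - 1) // 2, kw // 2),
            ((kt - 1) // 2, kt // 2),
            (0, 0),
        )
        return np.pad(x, pads), pads

    def _offsets(self):
        kh, kw, kt = self.kernel
        return [(i, j, k) for i in range(kh) for j in range(kw) for k in range(kt)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # Stride-1 shift-and-GEMM: accumulate one skinny (M, C) @ (C, F)
        # product per kernel offset, avoiding a full im2col materialization.
        xp, pads = self._pad(np.ascontiguousarray(x, dtype=np.float32))
        self._xp, self._pads = xp, pads
        kh, kw, kt = self.kernel
        n, h, w, t, _ = xp.shape
        Hp, Wp, Tp = h - kh + 1, w - kw + 1, t - kt + 1
        self._out_spatial = (Hp, Wp, Tp)
        y = np.empty((n * Hp * Wp * Tp, self.out_channels), dtype=np.float32)
        y[...] = self.b
        for i, j, k in self._offsets():
            xs = np.ascontiguousarray(
                xp[:, i : i + Hp, j : j + Wp, k : k + Tp, :]
            ).reshape(-1, self.in_channels)
            y += xs @ self.W[i, j, k]
        return y.reshape(n, Hp, Wp, Tp, self.out_channels)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xp = self._xp
        Hp, Wp, Tp = self._out_spatial
        dy_mat = np.ascontiguousarray(dy).reshape(-1, self.out_channels)
        self.db[...] = dy_mat.sum(axis=0)
        dxp = np.zeros_like(xp)
        for i, j, k in self._offsets():
            xs = np.ascontiguousarray(
                xp[:, i : i + Hp, j : j + Wp, k : k + Tp, :]
            ).reshape(-1, self.in_channels)
            self.dW[i, j, k] = xs.T @ dy_mat
            dxp[:, i : i + Hp, j : j + Wp, k : k + Tp, :] += (
                dy_mat @ self.W[i, j, k].T
            ).reshape(dy.shape[0], Hp, Wp, Tp, self.in_channels)
        self._xp = None
        if self.padding == "same":
            (_, (pt, pb), (pl, pr), (pf, pk), _) = self._pads
            dxp = dxp[
                :,
                pt : dxp.shape[1] - pb or None,
                pl : dxp.shape[2] - pr or None,
                pf : dxp.shape[3] - pk or None,
                :,
            ]
        return dxp

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class _Pool3D(Layer):
    trainable = False

    def __init__(self, kernel, stride):
        self.kernel = _triple(kernel)
        self.stride = _triple(stride)

    def _windows(self, x: np.ndarray) -> np.ndarray:
        sh, sw, st = self.stride
        win = sliding_window_view(x, self.kernel, axis=(1, 2, 3))
        return win[:, ::sh, ::sw, ::st]


class AvgPool3D(_Pool3D):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        win = self._windows(np.ascontiguousarray(x, dtype=np.float32))
        self._out_shape = win.shape[:5]
        return np.ascontiguousarray(win.mean(axis=(5, 6, 7)), dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._x_shape, dtype=np.float32)
        kh, kw, kt = self.kernel
        sh, sw, st = self.stride
        Hp, Wp, Tp = dy.shape[1:4]
        share = dy / np.float32(kh * kw * kt)
        for i in range(kh):
            for j in range(kw):
                for k in range(kt):
                    dx[
                        :,
                        i : i + sh * Hp : sh,
                        j : j + sw * Wp : sw,
                        k : k + st * Tp : st,
                        :,
                    ] += share
        return dx


class MaxPool3D(_Pool3D):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x_shape = x.shape
        win = self._windows(np.ascontiguousarray(x, dtype=np.float32))
        N, Hp, Wp, Tp, C = win.shape[:5]
        flat = win.reshape(N, Hp, Wp, Tp, C, -1)
        self._argmax = flat.argmax(axis=-1)
        return np.ascontiguousarray(flat.max(axis=-1), dtype=np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._x_shape, dtype=np.float32)
        kh, kw, kt = self.kernel
        sh, sw, st = self.stride
        N, Hp, Wp, Tp, C = dy.shape
        di, rem = np.divmod(self._argmax, kw * kt)
        dj, dk = np.divmod(rem, kt)
        n, hi, wi, ti, c = np.indices((N, Hp, Wp, Tp, C), sparse=False)
        np.add.at(dx, (n, sh * hi + di, sw * wi + dj, st * ti + dk, c), dy)
        return dx


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W, T).

    ``gamma``/``beta`` are trainable; running mean/variance are the frozen
    statistics used in eval mode (and counted as non-trainable parameters).
    """

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.channels = int(channels)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.gamma = np.ones(channels, dtype=np.float32)
        self.beta = np.zeros(channels, dtype=np.float32)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean[...] = m * self.running_mean + (1 - m) * mean
            self.running_var[...] = m * self.running_var + (1 - m) * var
        else:
            mean, var = self.running_mean, self.running_var
        self._std = np.sqrt(var + self.eps).astype(np.float32)
        self._xhat = ((x - mean) / self._std).astype(np.float32)
        self._axes = axes
        self._m = x.size // x.shape[-1]
        self._train = train
        return (self.gamma * self._xhat + self.beta).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        axes = self._axes
        self.dgamma[...] = (dy * self._xhat).sum(axis=axes)
        self.dbeta[...] = dy.sum(axis=axes)
        if not self._train:
            return (dy * self.gamma / self._std).astype(np.float32)
        m = self._m
        dxhat = dy * self.gamma
        dx = (
            dxhat
            - dxhat.mean(axis=axes)
            - self._xhat * (dxhat * self._xhat).mean(axis=axes)
        ) / self._std
        return dx.astype(np.float32)

    def params(self) -> list[np.ndarray]:
        return [self.gamma, self.beta]

    def grads(self) -> list[np.ndarray]:
        return [self.dgamma, self.dbeta]

    def state(self) -> list[np.ndarray]:
        return [self.gamma, self.beta, self.running_mean, self.running_var]


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int):
        self.n_in, self.n_out = int(n_in), int(n_out)
        self.W = np.zeros((self.n_in, self.n_out), dtype=np.float32)
        self.b = np.zeros(self.n_out, dtype=np.float32)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def initialize(self, rng: np.random.Generator) -> None:
        std = np.sqrt(2.0 / self.n_in)
        self.W[...] = rng.normal(0.0, std, size=self.W.shape).astype(np.float32)
        self.b[...] = 0.0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.W + self.b

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dW[...] = self._x.T @ dy
        self.db[...] = dy.sum(axis=0)
        return (dy @ self.W.T).astype(np.float32)

    def params(self) -> list[np.ndarray]:
        return [self.W, self.b]

    def grads(self) -> list[np.ndarray]:
        return [self.dW, self.db]


class Dropout(Layer):
    trainable = False

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = float(rate)
        self.rng: np.random.Generator | None = None  # attached by the model

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


class Flatten(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return np.ascontiguousarray(x).reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)


class GlobalAvgPool(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(1, 2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        N, H, W, T, C = self._shape
        scale = 1.0 / (H * W * T)
        return np.broadcast_to(dy[:, None, None, None, :] * scale, self._shape).astype(
            np.float32
        )


class ReLU(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, 0.0).astype(np.float32)


class LeakyReLU(Layer):
    trainable = False

    def __init__(self, alpha: float = 0.01):
        self.alpha = float(alpha)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.alpha * x).astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dy, self.alpha * dy).astype(np.float32)


class Sigmoid(Layer):
    trainable = False

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._y = 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))
        return self._y.astype(np.float32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return (dy * self._y * (1.0 - self._y)).astype(np.float32)
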