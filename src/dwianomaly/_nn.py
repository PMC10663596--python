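"""Minimal CPU neural-network engine for small 3D volumes.

Implements exactly the layers the anomaly models need — strided 3D
convolution, transposed convolution, dense layers, affine-free instance
normalization, LeakyReLU/sigmoid and Adam — with explicit forward/backward
passes on float64 numpy arrays.  Convolutions use a gather (im2col) /
scatter (col2im) pair that share one index table, so the transposed
convolution is the exact adjoint of the convolution with the same geometry.

Array layout is channel-first: (N, C, X, Y, Z).  Everything is deterministic
given the caller's Generator; gradients are verified against finite
differences in the test suite.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

# ---------------------------------------------------------------------------
# global dtype
# ---------------------------------------------------------------------------

_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype) -> None:
    """Dtype for newly created layers (float32 default; float64 for checks)."""
    global _DEFAULT_DTYPE
    _DEFAULT_DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DEFAULT_DTYPE


# ---------------------------------------------------------------------------
# im2col / col2im with a shared, cached index table
# ---------------------------------------------------------------------------

_INDEX_CACHE: dict[tuple, tuple] = {}


def _conv_indices(spatial: Sequence[int], c: int, k: int, stride: int, pad: int):
    """Index table for gathering (window, channel·offset) feature vectors.

    Returns (idx, out_shape, padded_shape): idx has shape (n_windows, c·k³)
    and addresses the flattened zero-padded (c, *padded) grid, so a single
    fancy index yields GEMM-ready columns with no transpose copy.
    """
    key = (tuple(spatial), c, k, stride, pad)
    if key in _INDEX_CACHE:
        return _INDEX_CACHE[key]
    padded = tuple(s + 2 * pad for s in spatial)
    out = tuple((s + 2 * pad - k) // stride + 1 for s in spatial)
    starts = [np.arange(o) * stride for o in out]
    offs = np.arange(k)
    sx, sy, sz = np.meshgrid(*starts, indexing="ij")
    sx, sy, sz = sx.ravel(), sy.ravel(), sz.ravel()
    ox, oy, oz = np.meshgrid(offs, offs, offs, indexing="ij")
    ox, oy, oz = ox.ravel(), oy.ravel(), oz.ravel()
    py, pz = padded[1], padded[2]
    spatial_idx = (
        (sx[:, None] + ox[None, :]) * (py * pz)
        + (sy[:, None] + oy[None, :]) * pz
        + (sz[:, None] + oz[None, :])
    )  # (n_win, k³)
    pflat = int(np.prod(padded))
    idx = (
        np.arange(c, dtype=np.intp)[None, :, None] * pflat + spatial_idx[:, None, :]
    ).reshape(spatial_idx.shape[0], c * k**3)
    _INDEX_CACHE[key] = (idx, out, padded)
    return _INDEX_CACHE[key]


def _pad_spatial(x: np.ndarray, pad: int) -> np.ndarray:
    if not pad:
        return x
    n, c = x.shape[:2]
    padded = tuple(s + 2 * pad for s in x.shape[2:])
    xp = np.zeros((n, c) + padded, dtype=x.dtype)
    xp[:, :, pad:-pad, pad:-pad, pad:-pad] = x
    return xp


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> tuple[np.ndarray, tuple]:
    """(N, C, X, Y, Z) → columns (N, n_windows, C·k³), plus the output shape."""
    n, c = x.shape[:2]
    idx, out, _ = _conv_indices(x.shape[2:], c, k, stride, pad)
    flat = _pad_spatial(x, pad).reshape(n, -1)
    return flat[:, idx], out


def col2im(
    cols: np.ndarray, spatial: Sequence[int], c: int, k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of :func:`im2col`: scatter-add columns back onto the grid."""
    n = cols.shape[0]
    idx, out, padded = _conv_indices(spatial, c, k, stride, pad)
    flat_idx = idx.ravel()
    size = c * int(np.prod(padded))
    vals = np.ascontiguousarray(cols).reshape(n, -1)
    acc = np.empty((n, size), dtype=cols.dtype)
    for m in range(n):
        acc[m] = np.bincount(flat_idx, weights=vals[m], minlength=size)
    acc = acc.reshape((n, c) + padded)
    if pad:
        acc = acc[:, :, pad:-pad, pad:-pad, pad:-pad]
    return np.ascontiguousarray(acc)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Param:
    __slots__ = ("value", "grad")

    def __init__(self, value: np.ndarray):
        self.value = value
        self.grad = np.zeros_like(value)


class Layer:
    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DEFAULT_DTYPE)


class Conv3d(Layer):
    """k³ convolution, weight shape (C_in·k³, C_out).

    Keeps only a reference to the input; the column matrix is regathered in
    the backward pass (cheaper than holding it across the whole step).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 1, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        fan_in = c_in * k**3
        self.w = Param(_kaiming(rng, (fan_in, c_out), fan_in))
        self.b = Param(np.zeros(c_out, dtype=_DEFAULT_DTYPE))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.w.value.dtype)
        self._x = x
        cols, out = im2col(x, self.k, self.stride, self.pad)
        y = cols @ self.w.value + self.b.value
        n = x.shape[0]
        return np.ascontiguousarray(y.transpose(0, 2, 1)).reshape((n, self.c_out) + out)

    def backward(self, dout):
        n = dout.shape[0]
        dout = np.ascontiguousarray(dout, dtype=self.w.value.dtype)
        dy = np.ascontiguousarray(dout.reshape(n, self.c_out, -1).transpose(0, 2, 1))
        cols, _ = im2col(self._x, self.k, self.stride, self.pad)
        self.w.grad += np.tensordot(cols, dy, axes=([0, 1], [0, 1]))
        self.b.grad += dy.sum(axis=(0, 1))
        dcols = dy @ self.w.value.T
        return col2im(dcols, self._x.shape[2:], self.c_in, self.k, self.stride, self.pad)


class ConvTranspose3d(Layer):
    """Stride-s upsampling convolution: output spatial size = s × input size.

    Implemented as the adjoint of the matching Conv3d geometry; weight shape
    (C_in, C_out·k³).
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, stride: int = 2, pad: int | None = None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.c_in, self.c_out, self.k, self.stride = c_in, c_out, k, stride
        self.pad = (k - 1) // 2 if pad is None else pad
        self.w = Param(_kaiming(rng, (c_in, c_out * k**3), c_in * k**3 // stride**3))
        self.b = Param(np.zeros(c_out, dtype=_DEFAULT_DTYPE))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.ascontiguousarray(x, dtype=self.w.value.dtype)
        n, c, *small = x.shape
        self._small = tuple(small)
        out = tuple(s * self.stride for s in small)
        self._out = out
        _, n_out, _ = _conv_indices(out, self.c_out, self.k, self.stride, self.pad)
        if tuple(n_out) != tuple(small):
            raise ValueError(
                f"transposed-conv geometry mismatch: input {small}, output {out}"
            )
        xf = np.ascontiguousarray(x.reshape(n, c, -1).transpose(0, 2, 1))  # (N, n_win, C_in)
        self._xf = xf
        cols = xf @ self.w.value                      # (N, n_win, C_out·k³)
        y = col2im(cols, out, self.c_out, self.k, self.stride, self.pad)
        return y + self.b.value[None, :, None, None, None]

    def backward(self, dout):
        n = dout.shape[0]
        dout = np.ascontiguousarray(dout, dtype=self.w.value.dtype)
        dcols, _ = im2col(dout, self.k, self.stride, self.pad)  # (N, n_win, C_out·k³)
        self.w.grad += np.tensordot(self._xf, dcols, axes=([0, 1], [0, 1]))
        self.b.grad += dout.sum(axis=(0, 2, 3, 4))
        dxf = dcols @ self.w.value.T                  # (N, n_win, C_in)
        return np.ascontiguousarray(dxf.transpose(0, 2, 1)).reshape((n, self.c_in) + self._small)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_kaiming(rng, (n_in, n_out), n_in))
        self.b = Param(np.zeros(n_out, dtype=_DEFAULT_DTYPE))

    def params(self):
        return [self.w, self.b]

    def forward(self, x):
        x = np.asarray(x, dtype=self.w.value.dtype)
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout):
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T


class InstanceNorm3d(Layer):
    """Per-sample, per-channel normalization over space (no learned affine)."""

    def __init__(self, eps: float = 1e-5):
        self.eps = eps

    def forward(self, x):
        axes = (2, 3, 4)
        mean = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._std = np.sqrt(var + self.eps)
        self._y = (x - mean) / self._std
        return self._y

    def backward(self, dout):
        axes = (2, 3, 4)
        m = dout.mean(axis=axes, keepdims=True)
        my = (dout * self._y).mean(axis=axes, keepdims=True)
        return (dout - m - self._y * my) / self._std


class LeakyReLU(Layer):
    def __init__(self, negative_slope: float = 0.01):
        self.slope = negative_slope

    def forward(self, x):
        self._neg = x < 0
        return np.where(self._neg, self.slope * x, x)

    def backward(self, dout):
        return np.where(self._neg, self.slope * dout, dout)


class Sigmoid(Layer):
    def forward(self, x):
        self._y = sigmoid(x)
        return self._y

    def backward(self, dout):
        return dout * self._y * (1.0 - self._y)


class Identity(Layer):
    def forward(self, x):
        return x

    def backward(self, dout):
        return dout


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def params(self):
        return [p for layer in self.layers for p in layer.params()]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------------------
# numerics and optimization
# ---------------------------------------------------------------------------

def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class Adam:
    """Adam with a per-epoch exponential learning-rate decay lr₀·γ^epoch."""

    def __init__(self, params: list[Param], lr: float = 1e-4, betas=(0.9, 0.999),
                 eps: float = 1e-8, lr_decay: float = 1.0):
        self.params = params
        self.lr0 = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.lr_decay = lr_decay
        self.epoch = 0
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    @property
    def lr(self) -> float:
        return self.lr0 * self.lr_decay**self.epoch

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        lr = self.lr
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * p.grad
            v *= self.b2
            v += (1 - self.b2) * p.grad**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p.value -= lr * mhat / (np.sqrt(vhat) + self.eps)


def get_state(params: list[Param]) -> list[np.ndarray]:
    return [p.value.copy() for p in params]


def set_state(params: list[Param], state: list[np.ndarray]) -> None:
    for p, s in zip(params, state):
        p.value[...] = s


def pad_to_multiple(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[slice, ...]]:
    """Zero-pad trailing three spatial axes of (..., X, Y, Z) to a multiple.

    Returns the padded array and the slices recovering the original grid.
    """
    spatial = x.shape[-3:]
    target = [int(np.ceil(s / multiple) * multiple) for s in spatial]
    pads = [(0, 0)] * (x.ndim - 3) + [
        ((t - s) // 2, t - s - (t - s) // 2) for s, t in zip(spatial, target)
    ]
    xp = np.pad(x, pads)
    crop = tuple(
        slice(lo, lo + s) for (lo, _), s in zip(pads[-3:], spatial)
    )
    return xp, (Ellipsis,) + crop
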