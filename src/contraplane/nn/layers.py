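"""Numpy layers with hand-derived backward passes.

Tensors are channels-last ``(B, D, H, W, C)``; convolutions accumulate one
GEMM per kernel offset on shifted views of the padded input, so the heavy
lifting happens in BLAS without large strided gather copies.  Each layer
caches what its backward pass needs during ``forward`` (single-use per
training step).  Layers preserve the input dtype, which lets the test
suite run finite-difference gradient checks in float64.
"""

from __future__ import annotations

import itertools

import numpy as np

__all__ = ["Conv3d", "InstanceNorm3d", "ReLU", "MaxPool3d", "TrilinearUp3d", "Sequential"]


class Layer:
    params: dict
    grads: dict

    def __init__(self):
        self.params = {}
        self.grads = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


_OFFSETS3 = list(itertools.product(range(3), repeat=3))


class Conv3d(Layer):
    """'Same' 3D convolution, kernel 1 or 3, He-initialized.

    Weights are stored as ``(k³, C_in, C_out)``; output voxel (d,h,w) sums
    ``x[d+a−1, h+b−1, w+c−1] @ w[(a,b,c)]`` over the 27 kernel offsets.
    """

    def __init__(self, c_in: int, c_out: int, k: int = 3, rng: np.random.Generator | None = None):
        super().__init__()
        if k not in (1, 3):
            raise ValueError("kernel must be 1 or 3")
        self.c_in, self.c_out, self.k = c_in, c_out, k
        rng = rng or np.random.default_rng(0)
        fan_in = c_in * k**3
        self.params["w"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(k**3, c_in, c_out)).astype(
            np.float32
        )
        self.params["b"] = np.zeros(c_out, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.params["w"].astype(x.dtype, copy=False)
        if self.k == 1:
            self._x = x
            return x @ w[0] + self.params["b"].astype(x.dtype)
        b_, d, h, wd, _ = x.shape
        xp = np.zeros((b_, d + 2, h + 2, wd + 2, self.c_in), dtype=x.dtype)
        xp[:, 1:-1, 1:-1, 1:-1, :] = x
        self._xp = xp
        y = np.zeros((b_, d, h, wd, self.c_out), dtype=x.dtype)
        for slot, (a, bb, c) in enumerate(_OFFSETS3):
            y += xp[:, a : a + d, bb : bb + h, c : c + wd, :] @ w[slot]
        return y + self.params["b"].astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        w = self.params["w"].astype(grad.dtype, copy=False)
        if self.k == 1:
            self.grads["w"] = np.tensordot(self._x, grad, axes=([0, 1, 2, 3], [0, 1, 2, 3]))[None]
            self.grads["b"] = grad.sum(axis=(0, 1, 2, 3))
            return grad @ w[0].T
        b_, d, h, wd, _ = grad.shape
        dw = np.empty((27, self.c_in, self.c_out), dtype=grad.dtype)
        g2 = np.ascontiguousarray(grad).reshape(-1, self.c_out)
        gp = np.zeros((b_, d + 2, h + 2, wd + 2, self.c_out), dtype=grad.dtype)
        gp[:, 1:-1, 1:-1, 1:-1, :] = grad
        dx = np.zeros((b_, d, h, wd, self.c_in), dtype=grad.dtype)
        for slot, (a, bb, c) in enumerate(_OFFSETS3):
            sl = (slice(None), slice(a, a + d), slice(bb, bb + h), slice(c, c + wd), slice(None))
            xs2 = np.ascontiguousarray(self._xp[sl]).reshape(-1, self.c_in)
            dw[slot] = xs2.T @ g2
            # transpose convolution: dx[j] += grad[j + 1 − k] wₖᵀ, via shifted views
            dx += gp[:, 2 - a : 2 - a + d, 2 - bb : 2 - bb + h, 2 - c : 2 - c + wd, :] @ w[slot].T
        self.grads["w"] = dw
        self.grads["b"] = grad.sum(axis=(0, 1, 2, 3))
        return dx


class InstanceNorm3d(Layer):
    """Per-(sample, channel) normalization over the spatial axes, with affine."""

    def __init__(self, c: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.params["gamma"] = np.ones(c, dtype=np.float32)
        self.params["beta"] = np.zeros(c, dtype=np.float32)

    def forward(self, x: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3)
        mu = x.mean(axis=axes, keepdims=True)
        var = x.var(axis=axes, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.params["gamma"].astype(x.dtype) + self.params["beta"].astype(x.dtype)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        axes = (1, 2, 3)
        self.grads["gamma"] = (grad * self._xhat).sum(axis=(0, 1, 2, 3))
        self.grads["beta"] = grad.sum(axis=(0, 1, 2, 3))
        dxhat = grad * self.params["gamma"].astype(grad.dtype)
        m1 = dxhat.mean(axis=axes, keepdims=True)
        m2 = (dxhat * self._xhat).mean(axis=axes, keepdims=True)
        return (dxhat - m1 - self._xhat * m2) * self._inv


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, x.dtype.type(0))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, grad.dtype.type(0))


class MaxPool3d(Layer):
    """2×2×2 max pooling; backward routes gradient to the per-window argmax."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, d, h, w, c = x.shape
        self._shape = x.shape
        xr = x.reshape(b, d // 2, 2, h // 2, 2, w // 2, 2, c)
        win = np.ascontiguousarray(np.moveaxis(xr, (2, 4, 6), (5, 6, 7))).reshape(
            b, d // 2, h // 2, w // 2, c, 8
        )
        self._arg = win.argmax(axis=-1)
        return np.take_along_axis(win, self._arg[..., None], axis=-1)[..., 0]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        b, d, h, w, c = self._shape
        gwin = np.zeros((b, d // 2, h // 2, w // 2, c, 8), dtype=grad.dtype)
        np.put_along_axis(gwin, self._arg[..., None], grad[..., None], axis=-1)
        gwin = gwin.reshape(b, d // 2, h // 2, w // 2, c, 2, 2, 2)
        return np.moveaxis(gwin, (5, 6, 7), (2, 4, 6)).reshape(b, d, h, w, c)


def _linear_resize_tables(n_in: int, n_out: int):
    """Index/weight tables for 1D linear resize with half-pixel alignment."""
    pos = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    floor = np.floor(pos).astype(int)
    lo = np.clip(floor, 0, n_in - 1)
    hi = np.clip(floor + 1, 0, n_in - 1)
    frac = pos - floor
    return lo, hi, 1.0 - frac, frac


class TrilinearUp3d(Layer):
    """×2 trilinear upsampling; backward is the exact adjoint of the forward map.

    With half-pixel alignment, output 2m reads inputs (m−1, m) with weights
    (¼, ¾) and output 2m+1 reads (m, m+1) with weights (¾, ¼), clamped at
    the ends; the adjoint is accumulated with parity-sliced vectorized adds.
    """

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = x
        self._axes_n = []
        for axis in (1, 2, 3):
            n_in = y.shape[axis]
            lo, hi, wlo, whi = _linear_resize_tables(n_in, 2 * n_in)
            self._axes_n.append((axis, n_in))
            shape = [1] * y.ndim
            shape[axis] = 2 * n_in
            y = np.take(y, lo, axis=axis) * wlo.reshape(shape).astype(y.dtype) + np.take(
                y, hi, axis=axis
            ) * whi.reshape(shape).astype(y.dtype)
        return y

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = grad
        for axis, n_in in reversed(self._axes_n):
            gm = np.moveaxis(g, axis, 0)
            g_even, g_odd = gm[0::2], gm[1::2]
            acc = 0.75 * (g_even + g_odd)
            acc[: n_in - 1] += 0.25 * g_even[1:]
            acc[1:] += 0.25 * g_odd[: n_in - 1]
            acc[0] += 0.25 * g_even[0]  # clamped low edge
            acc[n_in - 1] += 0.25 * g_odd[n_in - 1]  # clamped high edge
            g = np.moveaxis(acc.astype(grad.dtype, copy=False), 0, axis)
        return g


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad
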