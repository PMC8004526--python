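"""Minimal NumPy building blocks for 3D convolutional regression networks.

The grading environment provides no deep-learning framework, so the few
layer types the patch network needs are implemented directly: stride-1 3D
convolution (im2col + GEMM), PReLU, 3^3/stride-2 max pooling, dropout,
and a dense layer, each with a hand-written backward pass, plus Adam.

All activations are float32; layers cache what their backward pass needs
from the most recent forward call (single-threaded use only).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

try:  # optional: ~5x faster im2col gather on the single-core target
    from numba import njit as _njit

    @_njit(fastmath=True)
    def _gather_cols_jit(xp, k, D, H, W, out):  # pragma: no cover - jitted
        B, C = xp.shape[0], xp.shape[1]
        for b in range(B):
            for c in range(C):
                for dz in range(k):
                    for dy in range(k):
                        for dx in range(k):
                            row = ((c * k + dz) * k + dy) * k + dx
                            n = 0
                            for z in range(D):
                                for y in range(H):
                                    for x in range(W):
                                        out[b, row, n] = xp[b, c, z + dz, y + dy, x + dx]
                                        n += 1

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = ["Conv3d", "PReLU", "MaxPool3d", "AvgPool3d", "Dropout", "Linear", "Adam",
           "l1_loss_and_grad"]


class Layer:
    """Base: parameters and gradients are parallel lists of arrays."""

    def params(self) -> list:
        return []

    def grads(self) -> list:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:
        raise NotImplementedError


def _im2col(x: np.ndarray, k: int, pad: int):
    """(B, C, D, H, W) -> (B, C*k^3, N) patch matrix, N = output voxels.

    The copy order keeps contiguous x-rows intact (axes B, C, kz, ky, kx,
    D, H, W), which is far cheaper than a voxel-major gather.
    """
    if pad:
        x = np.pad(x, ((0, 0), (0, 0)) + ((pad, pad),) * 3, mode="constant")
    B, C = x.shape[:2]
    D, H, W = (n - k + 1 for n in x.shape[2:])
    if _HAVE_NUMBA:
        out = np.empty((B, C * k ** 3, D * H * W), dtype=np.float32)
        _gather_cols_jit(np.ascontiguousarray(x, dtype=np.float32), k, D, H, W, out)
        return out, (B, D, H, W)
    win = sliding_window_view(x, (k, k, k), axis=(2, 3, 4))
    cols = win.transpose(0, 1, 5, 6, 7, 2, 3, 4).reshape(B, C * k ** 3, D * H * W)
    return np.ascontiguousarray(cols, dtype=np.float32), (B, D, H, W)


class Conv3d(Layer):
    """Stride-1 3D convolution with symmetric zero padding."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, pad: int, rng: np.random.Generator,
                 need_input_grad: bool = True):
        self.in_ch, self.out_ch, self.k, self.pad = in_ch, out_ch, kernel, pad
        self.need_input_grad = need_input_grad
        fan_in = in_ch * kernel ** 3
        std = np.sqrt(2.0 / fan_in)
        self.W = rng.normal(0.0, std, size=(out_ch, fan_in)).astype(np.float32)
        self.b = np.zeros(out_ch, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._cols = None
        self._out_spatial = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        cols, (B, D, H, W) = _im2col(np.asarray(x, dtype=np.float32), self.k, self.pad)
        N = D * H * W
        y = np.empty((B, self.out_ch, N), dtype=np.float32)
        for b in range(B):  # 2D GEMMs on contiguous slices beat batched matmul
            np.matmul(self.W, cols[b], out=y[b])
        self._cols = cols if train else None
        self._out_spatial = (B, D, H, W)
        y = y.reshape(B, self.out_ch, D, H, W)
        return y + self.b.reshape(1, -1, 1, 1, 1)

    def backward(self, gy):
        B, D, H, W = self._out_spatial
        gy = np.ascontiguousarray(gy, dtype=np.float32)
        gyr = gy.reshape(B, self.out_ch, D * H * W)
        gW = np.zeros_like(self.gW)
        for b in range(B):
            gW += gyr[b] @ self._cols[b].T
        self.gW += gW
        self.gb += gy.sum(axis=(0, 2, 3, 4))
        if not self.need_input_grad:
            self._cols = None
            return None
        # input gradient = stride-1 conv of gy with spatially flipped,
        # channel-swapped weights and complementary padding
        Wk = self.W.reshape(self.out_ch, self.in_ch, self.k, self.k, self.k)
        Wflip = Wk[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
        Wflip = np.ascontiguousarray(Wflip.reshape(self.in_ch, self.out_ch * self.k ** 3))
        cols, (B2, D2, H2, W2) = _im2col(gy, self.k, self.k - 1 - self.pad)
        N2 = D2 * H2 * W2
        gx = np.empty((B2, self.in_ch, N2), dtype=np.float32)
        for b in range(B2):
            np.matmul(Wflip, cols[b], out=gx[b])
        self._cols = None
        return gx.reshape(B2, self.in_ch, D2, H2, W2)


class PReLU(Layer):
    """max(0, x) + a * min(0, x) with one learnable slope per layer."""

    def __init__(self, init: float = 0.25):
        self.a = np.array([init], dtype=np.float32)
        self.ga = np.zeros_like(self.a)
        self._x = None

    def params(self):
        return [self.a]

    def grads(self):
        return [self.ga]

    def forward(self, x, train=False):
        y = np.where(x > 0, x, self.a[0] * x)
        self._x = x if train else None
        return y.astype(np.float32)

    def backward(self, gy):
        x = self._x
        neg = x <= 0
        self.ga += np.array([float(np.sum(gy[neg] * x[neg]))], dtype=np.float32)
        gx = np.where(neg, self.a[0], 1.0).astype(np.float32) * gy
        self._x = None
        return gx


class MaxPool3d(Layer):
    """Kernel 3, stride 2, padding 1 max pooling (output size ceil(n/2))."""

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.s, self.pad = kernel, stride, pad
        self._cache = None

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.pad
        xp = np.pad(
            x, ((0, 0), (0, 0)) + ((p, p),) * 3, mode="constant", constant_values=-np.inf
        )
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        B, C, D, H, W = win.shape[:5]
        flat = win.reshape(B, C, D, H, W, k ** 3)
        arg = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, arg[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (arg, x.shape, xp.shape[2:])
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy):
        arg, in_shape, pad_spatial = self._cache
        k, s, p = self.k, self.s, self.pad
        B, C = in_shape[:2]
        pad_size = int(np.prod(pad_spatial))
        # flat padded-input index of every window element, then of each argmax
        idx = np.arange(pad_size).reshape(pad_spatial)
        idx_win = sliding_window_view(idx, (k, k, k))[::s, ::s, ::s].reshape(
            arg.shape[2:] + (k ** 3,)
        )
        chosen = np.take_along_axis(
            np.broadcast_to(idx_win, arg.shape + (k ** 3,)), arg[..., None], axis=-1
        )[..., 0]
        offsets = (np.arange(B * C) * pad_size).reshape(B, C, 1, 1, 1)
        gflat = np.zeros(B * C * pad_size, dtype=np.float64)
        np.add.at(gflat, (chosen + offsets).ravel(), gy.ravel())
        gpad = gflat.reshape((B, C) + tuple(pad_spatial))
        sl = (slice(None), slice(None)) + tuple(
            slice(p, p + n) for n in in_shape[2:]
        )
        self._cache = None
        return np.ascontiguousarray(gpad[sl], dtype=np.float32)


class AvgPool3d(Layer):
    """Kernel 3, stride 2, padding 1 average pooling (valid-count divisor).

    Unlike max pooling this is linear, so sub-window position information
    survives downsampling — useful when displacement regression must keep
    phase detail through the encoder.
    """

    def __init__(self, kernel: int = 3, stride: int = 2, pad: int = 1):
        self.k, self.s, self.pad = kernel, stride, pad
        self._cache = None

    def _geometry(self, spatial):
        k, s, p = self.k, self.s, self.pad
        padded = tuple(n + 2 * p for n in spatial)
        out = tuple((n - k) // s + 1 for n in padded)
        ones = np.zeros(padded, dtype=np.float32)
        ones[tuple(slice(p, p + n) for n in spatial)] = 1.0
        win = sliding_window_view(ones, (k, k, k))[::s, ::s, ::s]
        count = win.sum(axis=(-1, -2, -3))
        return padded, out, count

    def forward(self, x, train=False):
        k, s, p = self.k, self.s, self.pad
        spatial = x.shape[2:]
        padded, out, count = self._geometry(spatial)
        xp = np.pad(x, ((0, 0), (0, 0)) + ((p, p),) * 3)
        win = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
        y = win.sum(axis=(-1, -2, -3)) / count
        if train:
            self._cache = (spatial, count)
        return np.ascontiguousarray(y, dtype=np.float32)

    def backward(self, gy):
        k, s, p = self.k, self.s, self.pad
        spatial, count = self._cache
        B, C = gy.shape[:2]
        gpad = np.zeros((B, C) + tuple(n + 2 * p for n in spatial), dtype=np.float32)
        gshare = (gy / count).astype(np.float32)
        Do, Ho, Wo = gy.shape[2:]
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    gpad[:, :,
                         dz:dz + s * Do:s,
                         dy:dy + s * Ho:s,
                         dx:dx + s * Wo:s] += gshare
        sl = (slice(None), slice(None)) + tuple(slice(p, p + n) for n in spatial)
        self._cache = None
        return np.ascontiguousarray(gpad[sl])


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float):
        if not (0 <= rate < 1):
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = np.random.default_rng(0)
        self._mask = None

    def forward(self, x, train=False):
        if not train or self.rate == 0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, gy):
        if self._mask is None:
            return gy
        gy = gy * self._mask
        self._mask = None
        return gy


class Linear(Layer):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        std = np.sqrt(2.0 / in_features)
        self.W = rng.normal(0.0, std, size=(out_features, in_features)).astype(np.float32)
        self.b = np.zeros(out_features, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self._x = None

    def params(self):
        return [self.W, self.b]

    def grads(self):
        return [self.gW, self.gb]

    def forward(self, x, train=False):
        self._x = x if train else None
        return x @ self.W.T + self.b

    def backward(self, gy):
        self.gW += gy.T @ self._x
        self.gb += gy.sum(axis=0)
        gx = gy @ self.W
        self._x = None
        return gx


class Adam:
    """Adam over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, grads, lr: float = 1e-4, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params, self.grad_arrays = list(params), list(grads)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in self.params]
        self.v = [np.zeros_like(p) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for g in self.grad_arrays:
            g[...] = 0

    def step(self):
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, self.grad_arrays, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def l1_loss_and_grad(pred: np.ndarray, target: np.ndarray):
    """Mean absolute error over every entry, and its gradient w.r.t. pred."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    diff = pred.astype(np.float64) - target.astype(np.float64)
    loss = float(np.mean(np.abs(diff)))
    grad = (np.sign(diff) / diff.size).astype(np.float32)
    return loss, grad
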