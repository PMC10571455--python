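"""Minimal seeded NumPy neural-network engine.

Provides the layers the grading networks need — 3x3 same-padding
convolution (im2col + GEMM), 2x2/stride-2 max pooling, channel
concatenation, batch normalization, dense layers, ReLU and a softmax /
sigmoid cross-entropy head — together with an Adam optimizer. All
computation is float32, single-threaded-deterministic, and every source
of randomness flows through an explicit ``numpy.random.Generator``.

Layers follow the usual forward/backward contract: ``forward(x, train)``
caches what backward needs; ``backward(dy)`` returns the input gradient
and accumulates parameter gradients in ``grads`` aligned with
``params``.
"""

from __future__ import annotations

import ctypes
import ctypes.util
import glob

import numpy as np
from numpy.lib.stride_tricks import as_strided, sliding_window_view

F32 = np.float32


def _load_cblas():
    """Locate a CBLAS sgemm for the zero-copy convolution path.

    The convolution kernels below run GEMMs directly on strided window
    views of the padded activation buffer, which needs explicit
    leading-dimension control that the numpy API does not expose.
    Returns None when no CBLAS library is available; the layers then
    fall back to an im2col + numpy matmul path.
    """
    candidates = []
    for pattern in ("libcblas.so*", "libopenblas*.so*", "libblas.so*"):
        candidates += sorted(glob.glob(f"/opt/conda/envs/*/lib/{pattern}"))
        candidates += sorted(glob.glob(f"/usr/lib/x86_64-linux-gnu/{pattern}"))
    found = ctypes.util.find_library("cblas") or ctypes.util.find_library("openblas")
    if found:
        candidates.append(found)
    for path in candidates:
        try:
            lib = ctypes.CDLL(path)
            fn = lib.cblas_sgemm
        except (OSError, AttributeError):
            continue
        fn.restype = None
        fn.argtypes = [ctypes.c_int] * 3 + [ctypes.c_int] * 3 + [
            ctypes.c_float, ctypes.c_void_p, ctypes.c_int,
            ctypes.c_void_p, ctypes.c_int,
            ctypes.c_float, ctypes.c_void_p, ctypes.c_int,
        ]
        return fn
    return None


_CBLAS_SGEMM = _load_cblas()
_ROW_MAJOR, _NO_TRANS, _TRANS = 101, 111, 112


def _sgemm(trans_a: bool, m: int, n: int, k: int, a_ptr: int, lda: int,
           b_ptr: int, ldb: int, c_ptr: int, ldc: int, beta: float):
    _CBLAS_SGEMM(_ROW_MAJOR, _TRANS if trans_a else _NO_TRANS, _NO_TRANS,
                 m, n, k, 1.0, a_ptr, lda, b_ptr, ldb, beta, c_ptr, ldc)


class Layer:
    params: list
    grads: list

    def __init__(self):
        self.params = []
        self.grads = []

    def forward(self, x, train: bool):  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy):  # pragma: no cover - interface
        raise NotImplementedError


class Conv3x3(Layer):
    """3x3 convolution, stride 1, same padding. x: (N, H, W, C).

    When CBLAS is available, the convolution runs as GEMMs directly on
    overlapping window views of the padded activations (one GEMM per
    vertical/horizontal tap with an offset base pointer), avoiding the
    9x im2col inflation that otherwise dominates runtime. Otherwise an
    im2col + matmul fallback computes identical results.
    """

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / (9 * c_in))
        self.w = (rng.standard_normal((3, 3, c_in, c_out)) * scale).astype(F32)
        self.b = np.zeros(c_out, dtype=F32)
        self.c_in, self.c_out = c_in, c_out
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]
        #: network input layers set this; their input gradient is never used
        self.skip_input_grad = False

    def forward(self, x, train):
        n, h, w, c = x.shape
        if c != self.c_in:
            raise ValueError(f"expected {self.c_in} input channels, got {c}")
        # the zero-copy GEMM path pays off on large feature maps; small
        # maps with many channels are faster through a single im2col GEMM
        self._used_im2col = _CBLAS_SGEMM is None or h * w <= 400
        if self._used_im2col:
            return self._forward_im2col(x)
        f = self.c_out
        xp = np.pad(np.asarray(x, dtype=F32), ((0, 0), (1, 1), (1, 1), (0, 0)))
        wp = w + 2
        rows = n * h * wp          # flattened (case, row) x padded width
        m = rows - 2               # number of sliding windows
        o = np.zeros((rows, f), dtype=F32)
        blocks = []
        for di in range(3):
            a = np.ascontiguousarray(xp[:, di:di + h]).reshape(rows, c)
            wk = np.ascontiguousarray(self.w[di])  # (3, C, F)
            for j in range(3):
                _sgemm(False, m, f, c,
                       a.ctypes.data + j * c * 4, c,
                       wk.ctypes.data + j * c * f * 4, f,
                       o.ctypes.data, f, 1.0)
            blocks.append(a)
        self._cache = (blocks, o.shape, x.shape)
        fs = o.strides[1]
        y = as_strided(o, (n, h, w, f), (h * wp * f * fs, wp * f * fs, f * fs, fs))
        return y + self.b

    def backward(self, dy):
        if self._used_im2col:
            return self._backward_im2col(dy)
        blocks, oshape, (n, h, w, c) = self._cache
        f = self.c_out
        wp = w + 2
        rows = n * h * wp
        m = rows - 2
        dy = np.ascontiguousarray(dy, dtype=F32)
        self.grads[1][...] = dy.sum(axis=(0, 1, 2))
        dof = np.zeros((rows, f), dtype=F32)
        fs = dof.strides[1]
        as_strided(dof, (n, h, w, f), (h * wp * f * fs, wp * f * fs, f * fs, fs))[...] = dy
        dxp = None if self.skip_input_grad else np.zeros((n, h + 2, wp, c), dtype=F32)
        dw = self.grads[0]
        dbuf = None if self.skip_input_grad else np.empty((m, 3 * c), dtype=F32)
        for di in range(3):
            a = blocks[di]
            wk = np.ascontiguousarray(self.w[di])  # (3, C, F)
            dwk = np.zeros_like(wk)
            for j in range(3):
                _sgemm(True, c, f, m,
                       a.ctypes.data + j * c * 4, c,
                       dof.ctypes.data, f,
                       dwk.ctypes.data + j * c * f * 4, f, 0.0)
            dw[di] = dwk
            if self.skip_input_grad:
                continue
            # d(window rows) = dO @ w[di]^T, then shift-add back to buffer rows
            np.matmul(dof[:m], wk.reshape(3 * c, f).T, out=dbuf)
            dslab = np.zeros((rows, c), dtype=F32)
            for j in range(3):
                dslab[j:j + m] += dbuf[:, j * c:(j + 1) * c]
            dxp[:, di:di + h] += dslab.reshape(n, h, wp, c)
        return None if self.skip_input_grad else dxp[:, 1:-1, 1:-1, :]

    # -- im2col fallback (identical arithmetic) --------------------------------
    def _forward_im2col(self, x):
        n, h, w, c = x.shape
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        cols = sliding_window_view(xp, (3, 3), axis=(1, 2))   # N,H,W,C,3,3
        cols = np.ascontiguousarray(cols.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * w, 9 * c)
        y = cols @ self.w.reshape(9 * c, self.c_out) + self.b
        self._cache = (cols, x.shape)
        return y.reshape(n, h, w, self.c_out)

    def _backward_im2col(self, dy):
        cols, xshape = self._cache
        n, h, w, c = xshape
        dym = dy.reshape(n * h * w, self.c_out)
        wmat = self.w.reshape(9 * c, self.c_out)
        self.grads[0][...] = (cols.T @ dym).reshape(self.w.shape)
        self.grads[1][...] = dym.sum(axis=0)
        if self.skip_input_grad:
            return None
        dcols = (dym @ wmat.T).reshape(n, h, w, 3, 3, c)
        dxp = np.zeros((n, h + 2, w + 2, c), dtype=F32)
        for di in range(3):
            for dj in range(3):
                dxp[:, di:di + h, dj:dj + w, :] += dcols[:, :, :, di, dj, :]
        return dxp[:, 1:-1, 1:-1, :]


class MaxPool2x2(Layer):
    """2x2 max pooling with stride 2."""

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        xr = xr.reshape(n, h // 2, w // 2, 4, c)
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (n, h, w, c) = self._cache
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=F32)
        np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)


class ReLU(Layer):
    def forward(self, x, train):
        self._mask = x > 0
        return np.maximum(x, 0, out=x)  # fresh conv/dense output: safe in-place

    def backward(self, dy):
        dy *= self._mask
        return dy


class BatchNorm(Layer):
    """Per-channel batch normalization over (N, H, W)."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        super().__init__()
        self.gamma = np.ones(channels, dtype=F32)
        self.beta = np.zeros(channels, dtype=F32)
        self.running_mean = np.zeros(channels, dtype=F32)
        self.running_var = np.ones(channels, dtype=F32)
        self.momentum, self.eps = momentum, eps
        self.params = [self.gamma, self.beta]
        self.grads = [np.zeros_like(self.gamma), np.zeros_like(self.beta)]
        self._collect = None

    def begin_calibration(self):
        """Start replacing running stats with exact full-pass moments."""
        self._collect = [0, np.zeros_like(self.running_mean, dtype=np.float64),
                         np.zeros_like(self.running_var, dtype=np.float64)]

    def end_calibration(self):
        count, s, ss = self._collect
        self._collect = None
        if count:
            mean = s / count
            self.running_mean[...] = mean.astype(F32)
            self.running_var[...] = (ss / count - mean ** 2).astype(F32)

    def forward(self, x, train):
        axes = tuple(range(x.ndim - 1))
        if self._collect is not None:
            cnt = int(np.prod([x.shape[a] for a in axes]))
            self._collect[0] += cnt
            self._collect[1] += x.sum(axis=axes, dtype=np.float64)
            self._collect[2] += (x.astype(np.float64) ** 2).sum(axis=axes)
            mean, var = x.mean(axis=axes), x.var(axis=axes)
            xhat = (x - mean) / np.sqrt(var + self.eps)
            return (self.gamma * xhat + self.beta).astype(F32)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean[...] = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var[...] = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        xhat = (x - mean) / np.sqrt(var + self.eps)
        self._cache = (xhat, var, axes, x.shape)
        return (self.gamma * xhat + self.beta).astype(F32)

    def backward(self, dy):
        xhat, var, axes, shape = self._cache
        m = np.prod([shape[a] for a in axes])
        self.grads[0][...] = np.sum(dy * xhat, axis=axes)
        self.grads[1][...] = np.sum(dy, axis=axes)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        dxhat = dy * self.gamma
        dx = (dxhat - dxhat.mean(axis=axes) - xhat * (dxhat * xhat).mean(axis=axes)) * inv_std
        return dx.astype(F32)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(F32)
        self.b = np.zeros(n_out, dtype=F32)
        self.params = [self.w, self.b]
        self.grads = [np.zeros_like(self.w), np.zeros_like(self.b)]

    def forward(self, x, train):
        self._x = x
        return x @ self.w + self.b

    def backward(self, dy):
        self.grads[0][...] = self._x.T @ dy
        self.grads[1][...] = dy.sum(axis=0)
        return dy @ self.w.T


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_xent_grad(logits: np.ndarray, labels: np.ndarray) -> tuple:
    """Mean cross-entropy loss and gradient w.r.t. logits."""
    p = softmax(logits)
    n = len(labels)
    loss = float(-np.log(np.clip(p[np.arange(n), labels], 1e-12, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return loss, (dlogits / n).astype(F32)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))


class Adam:
    def __init__(self, params: list, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list):
        self.t += 1
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m[...] = self.b1 * m + (1 - self.b1) * g
            v[...] = self.b2 * v + (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)
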