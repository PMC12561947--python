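"""Dense, convolutional, pooling and normalization layers.

Convolution uses im2col (one strided-view copy, then a BLAS matmul); its
backward scatters gradients with a kernel-position loop over strided slices,
which avoids per-element indexed accumulation.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .core import Module, Parameter

try:  # fast scatter kernel for the convolution backward pass
    import numba

    @numba.njit(cache=True)
    def _col2im_add(dcols, dxp, stride):
        # dcols: (B, oH, oW, C, k, k); dxp: (B, C, Hp, Wp)
        B, oH, oW, C, k, _ = dcols.shape
        for b in range(B):
            for i in range(oH):
                for j in range(oW):
                    for c in range(C):
                        for ki in range(k):
                            for kj in range(k):
                                dxp[b, c, i * stride + ki, j * stride + kj] += (
                                    dcols[b, i, j, c, ki, kj]
                                )

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    _HAVE_NUMBA = False


class Linear(Module):
    """Affine map on the last axis; scaled-uniform init."""

    def __init__(self, in_features, out_features, rng, bias=True, dtype=np.float32):
        super().__init__()
        bound = 1.0 / np.sqrt(in_features)
        self.w = Parameter(
            rng.uniform(-bound, bound, size=(in_features, out_features)).astype(dtype)
        )
        self.b = Parameter(np.zeros(out_features, dtype=dtype)) if bias else None
        self.in_features = in_features
        self.out_features = out_features

    def forward(self, x):
        self._x = x
        y = x @ self.w.value
        if self.b is not None:
            y = y + self.b.value
        return y

    def backward(self, grad):
        xm = self._x.reshape(-1, self.in_features)
        gm = grad.reshape(-1, self.out_features)
        self.w.grad += xm.T @ gm
        if self.b is not None:
            self.b.grad += gm.sum(axis=0)
        return (grad @ self.w.value.T).reshape(self._x.shape)


class ReLU(Module):
    def forward(self, x):
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, grad):
        return np.where(self._mask, grad, 0)


class Conv2d(Module):
    """2-D convolution (cross-correlation) on NCHW tensors, He-normal init."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1, padding=0,
                 bias=False, rng=None, dtype=np.float32):
        super().__init__()
        k = kernel_size
        fan_in = in_channels * k * k
        std = np.sqrt(2.0 / fan_in)
        rng = rng if rng is not None else np.random.default_rng(0)
        self.w = Parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, k, k)).astype(dtype)
        )
        self.b = Parameter(np.zeros(out_channels, dtype=dtype)) if bias else None
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k
        self.stride = stride
        self.padding = padding

    def _out_hw(self, H, W):
        k, s, p = self.kernel_size, self.stride, self.padding
        return (H + 2 * p - k) // s + 1, (W + 2 * p - k) // s + 1

    def forward(self, x):
        B, C, H, W = x.shape
        if C != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, got {C}")
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        oH, oW = self._out_hw(H, W)
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            B * oH * oW, C * k * k
        )
        wmat = self.w.value.reshape(self.out_channels, -1)
        y = cols @ wmat.T
        if self.b is not None:
            y = y + self.b.value
        self._cache = (cols, x.shape, (oH, oW))
        return y.reshape(B, oH, oW, self.out_channels).transpose(0, 3, 1, 2)

    def backward(self, grad):
        cols, (B, C, H, W), (oH, oW) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        g2 = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(
            -1, self.out_channels
        )
        self.w.grad += (g2.T @ cols).reshape(self.w.value.shape)
        if self.b is not None:
            self.b.grad += g2.sum(axis=0)
        wmat = self.w.value.reshape(self.out_channels, -1)
        dcols = (g2 @ wmat).reshape(B, oH, oW, C, k, k)
        dxp = np.zeros((B, C, H + 2 * p, W + 2 * p), dtype=grad.dtype)
        if _HAVE_NUMBA:
            _col2im_add(dcols, dxp, s)
        else:
            dc = dcols.transpose(0, 3, 1, 2, 4, 5)
            for ki in range(k):
                for kj in range(k):
                    dxp[:, :, ki:ki + s * oH:s, kj:kj + s * oW:s] += dc[:, :, :, :, ki, kj]
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with running statistics."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(num_features, dtype=dtype))
        self.beta = Parameter(np.zeros(num_features, dtype=dtype))
        self.running_mean = np.zeros(num_features, dtype=dtype)
        self.running_var = np.ones(num_features, dtype=dtype)
        self.eps = eps
        self.momentum = momentum
        self.num_features = num_features

    def forward(self, x):
        if self.training:
            mu = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mu).astype(
                self.running_mean.dtype
            )
            self.running_var = ((1 - m) * self.running_var + m * var).astype(
                self.running_var.dtype
            )
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu[None, :, None, None]) * inv_std[None, :, None, None]
        self._cache = (xhat, inv_std)
        return self.gamma.value[None, :, None, None] * xhat + self.beta.value[
            None, :, None, None
        ]

    def backward(self, grad):
        xhat, inv_std = self._cache
        axes = (0, 2, 3)
        self.gamma.grad += (grad * xhat).sum(axis=axes)
        self.beta.grad += grad.sum(axis=axes)
        dxhat = grad * self.gamma.value[None, :, None, None]
        if not self.training:
            return dxhat * inv_std[None, :, None, None]
        n = grad.shape[0] * grad.shape[2] * grad.shape[3]
        mean_dxhat = dxhat.mean(axis=axes)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=axes)
        dx = (
            dxhat
            - mean_dxhat[None, :, None, None]
            - xhat * mean_dxhat_xhat[None, :, None, None]
        ) * inv_std[None, :, None, None]
        return dx


class MaxPool2d(Module):
    def __init__(self, kernel_size=3, stride=2, padding=1):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        B, C, H, W = x.shape
        k, s, p = self.kernel_size, self.stride, self.padding
        fill = np.finfo(x.dtype).min if np.issubdtype(x.dtype, np.floating) else 0
        xp = (
            np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=fill)
            if p
            else x
        )
        win = sliding_window_view(xp, (k, k), axis=(2, 3))[:, :, ::s, ::s]
        oH, oW = win.shape[2], win.shape[3]
        flat = win.reshape(B, C, oH, oW, k * k)
        idx = flat.argmax(axis=-1)
        y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
        self._cache = (idx, x.shape, xp.shape, (oH, oW))
        return y

    def backward(self, grad):
        idx, (B, C, H, W), (_, _, Hp, Wp), (oH, oW) = self._cache
        k, s, p = self.kernel_size, self.stride, self.padding
        rows = (np.arange(oH)[None, None, :, None] * s) + idx // k
        cols = (np.arange(oW)[None, None, None, :] * s) + idx % k
        b_idx = np.arange(B)[:, None, None, None]
        c_idx = np.arange(C)[None, :, None, None]
        flat_idx = ((b_idx * C + c_idx) * Hp + rows) * Wp + cols
        acc = np.bincount(
            flat_idx.ravel(),
            weights=grad.ravel().astype(np.float64),
            minlength=B * C * Hp * Wp,
        ).reshape(B, C, Hp, Wp)
        dxp = acc.astype(grad.dtype)
        return dxp[:, :, p:p + H, p:p + W] if p else dxp


class GlobalAvgPool2d(Module):
    """NCHW -> NC mean over the spatial axes."""

    def forward(self, x):
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad):
        B, C, H, W = self._shape
        return np.broadcast_to(
            grad[:, :, None, None] / (H * W), self._shape
        ).astype(grad.dtype)


class LayerNorm(Module):
    """Normalization over the last axis with learnable scale/shift."""

    def __init__(self, dim, eps=1e-5, dtype=np.float32):
        super().__init__()
        self.gamma = Parameter(np.ones(dim, dtype=dtype))
        self.beta = Parameter(np.zeros(dim, dtype=dtype))
        self.eps = eps
        self.dim = dim

    def forward(self, x):
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        self._cache = (xhat, inv_std)
        return self.gamma.value * xhat + self.beta.value

    def backward(self, grad):
        xhat, inv_std = self._cache
        red = tuple(range(grad.ndim - 1))
        self.gamma.grad += (grad * xhat).sum(axis=red)
        self.beta.grad += grad.sum(axis=red)
        dxhat = grad * self.gamma.value
        mean_dxhat = dxhat.mean(axis=-1, keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=-1, keepdims=True)
        return (dxhat - mean_dxhat - xhat * mean_dxhat_xhat) * inv_std
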