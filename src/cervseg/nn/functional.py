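"""Spatial operations (convolutions, pooling, resizing) with hand-written
backward passes. Convolutions use im2col so the heavy lifting is a matmul."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, _accumulate, _ensure, _make, grad_enabled


def _out_size(size: int, k: int, stride: int, dilation: int, pad: int) -> int:
    return (size + 2 * pad - dilation * (k - 1) - 1) // stride + 1


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int, dilation: int, pad: int):
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    oh = _out_size(h, kh, stride, dilation, pad)
    ow = _out_size(w, kw, stride, dilation, pad)
    cols = np.empty((n, c, kh, kw, oh, ow), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dilation, j * dilation
            cols[:, :, i, j] = xp[:, :, ii:ii + oh * stride:stride, jj:jj + ow * stride:stride]
    return cols, oh, ow, xp.shape


def _col2im(cols: np.ndarray, xp_shape, kh, kw, stride, dilation, pad, h, w):
    xp = np.zeros(xp_shape, dtype=cols.dtype)
    oh, ow = cols.shape[-2:]
    for i in range(kh):
        for j in range(kw):
            ii, jj = i * dilation, j * dilation
            xp[:, :, ii:ii + oh * stride:stride, jj:jj + ow * stride:stride] += cols[:, :, i, j]
    return xp[:, :, pad:pad + h, pad:pad + w] if pad else xp


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, *, stride: int = 1,
           padding: int = 0, dilation: int = 1) -> Tensor:
    """Cross-correlation with an (O, C, kh, kw) kernel."""
    x, w = _ensure(x), _ensure(w)
    n, c, h, wid = x.shape
    o, ci, kh, kw = w.shape
    if ci != c:
        raise ValueError(f"conv2d channel mismatch: input {c}, kernel {ci}")
    cols, oh, ow, xp_shape = _im2col(x.data, kh, kw, stride, dilation, padding)
    cols2 = cols.reshape(n, c * kh * kw, oh * ow)
    w2 = w.data.reshape(o, c * kh * kw)
    y = np.matmul(w2, cols2).reshape(n, o, oh, ow)
    if b is not None:
        y = y + b.data.reshape(1, o, 1, 1)
    if not grad_enabled():
        return Tensor(y)

    def bwd(g):
        g2 = g.reshape(n, o, oh * ow)
        gw = np.tensordot(g2, cols2, axes=([0, 2], [0, 2])).reshape(w.shape)
        _accumulate(w, gw.astype(w.data.dtype))
        gcols = np.matmul(w2.T, g2).reshape(n, c, kh, kw, oh, ow)
        gx = _col2im(gcols, xp_shape, kh, kw, stride, dilation, padding, h, wid)
        _accumulate(x, gx)
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)).astype(b.data.dtype))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, bwd)


def depthwise_conv2d(x: Tensor, w: Tensor, *, stride: int = 1, padding: int = 0,
                     dilation: int = 1) -> Tensor:
    """Per-channel convolution; kernel shape (C, kh, kw)."""
    x, w = _ensure(x), _ensure(w)
    n, c, h, wid = x.shape
    cw, kh, kw = w.shape
    if cw != c:
        raise ValueError(f"depthwise_conv2d channel mismatch: input {c}, kernel {cw}")
    cols, oh, ow, xp_shape = _im2col(x.data, kh, kw, stride, dilation, padding)
    y = np.einsum("nckluv,ckl->ncuv", cols, w.data, optimize=True)
    if not grad_enabled():
        return Tensor(y)

    def bwd(g):
        gw = np.einsum("ncuv,nckluv->ckl", g, cols, optimize=True)
        _accumulate(w, gw.astype(w.data.dtype))
        gcols = np.einsum("ncuv,ckl->nckluv", g, w.data, optimize=True)
        gx = _col2im(gcols, xp_shape, kh, kw, stride, dilation, padding, h, wid)
        _accumulate(x, gx)

    return _make(y, (x, w), bwd)


def conv_transpose2x2(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Transposed convolution, kernel 2, stride 2 (exact x2 upsampling).

    Kernel shape (C_in, C_out, 2, 2); each input pixel paints a 2x2 block.
    """
    x, w = _ensure(x), _ensure(w)
    n, c, h, wid = x.shape
    ci, o, kh, kw = w.shape
    if ci != c or (kh, kw) != (2, 2):
        raise ValueError("conv_transpose2x2 expects kernel (C_in, C_out, 2, 2)")
    y6 = np.einsum("ncij,coab->noiajb", x.data, w.data, optimize=True)
    y = y6.reshape(n, o, 2 * h, 2 * wid)
    if b is not None:
        y = y + b.data.reshape(1, o, 1, 1)
    if not grad_enabled():
        return Tensor(y)

    def bwd(g):
        g6 = g.reshape(n, o, h, 2, wid, 2)
        gw = np.einsum("ncij,noiajb->coab", x.data, g6, optimize=True)
        _accumulate(w, gw.astype(w.data.dtype))
        gx = np.einsum("noiajb,coab->ncij", g6, w.data, optimize=True)
        _accumulate(x, gx)
        if b is not None:
            _accumulate(b, g.sum(axis=(0, 2, 3)).astype(b.data.dtype))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, bwd)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C, 1, 1) spatial mean."""
    x = _ensure(x)
    n, c, h, w = x.shape
    y = x.data.mean(axis=(2, 3), keepdims=True)

    def bwd(g):
        _accumulate(x, np.broadcast_to(g / (h * w), x.shape).astype(x.data.dtype))

    return _make(y, (x,), bwd)


def _interp_matrix(out_size: int, in_size: int, dtype) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (half-pixel centers)."""
    a = np.zeros((out_size, in_size), dtype=dtype)
    if in_size == 1:
        a[:, 0] = 1.0
        return a
    src = (np.arange(out_size) + 0.5) * in_size / out_size - 0.5
    src = np.clip(src, 0, in_size - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, in_size - 1)
    frac = src - lo
    a[np.arange(out_size), lo] += 1.0 - frac
    a[np.arange(out_size), hi] += frac
    return a


def resize_bilinear(x: Tensor, oh: int, ow: int) -> Tensor:
    """Differentiable bilinear resize of an (N, C, H, W) map."""
    x = _ensure(x)
    n, c, h, w = x.shape
    if (h, w) == (oh, ow):
        return x
    ah = _interp_matrix(oh, h, x.data.dtype)
    aw = _interp_matrix(ow, w, x.data.dtype)
    y = np.einsum("oh,nchw,pw->ncop", ah, x.data, aw, optimize=True)

    def bwd(g):
        gx = np.einsum("oh,ncop,pw->nchw", ah, g, aw, optimize=True)
        _accumulate(x, gx)

    return _make(y, (x,), bwd)


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor, running_mean: np.ndarray,
                 running_var: np.ndarray, *, training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    """Batch normalization over (N, H, W) per channel; updates running stats
    in place when training."""
    x = _ensure(x)
    n, c, h, w = x.shape
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mean
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mean, var = running_mean, running_var
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean.reshape(1, c, 1, 1)) * invstd.reshape(1, c, 1, 1)
    y = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)
    if not grad_enabled():
        return Tensor(y)

    def bwd(g):
        _accumulate(gamma, (g * xhat).sum(axis=(0, 2, 3)).astype(gamma.data.dtype))
        _accumulate(beta, g.sum(axis=(0, 2, 3)).astype(beta.data.dtype))
        ghat = g * gamma.data.reshape(1, c, 1, 1)
        if training:
            m = n * h * w
            s1 = ghat.sum(axis=(0, 2, 3), keepdims=True)
            s2 = (ghat * xhat).sum(axis=(0, 2, 3), keepdims=True)
            gx = (ghat - s1 / m - xhat * s2 / m) * invstd.reshape(1, c, 1, 1)
        else:
            gx = ghat * invstd.reshape(1, c, 1, 1)
        _accumulate(x, gx.astype(x.data.dtype))

    return _make(y, (x, gamma, beta), bwd)


def linear(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """x @ w.T + b for (N, F_in) inputs; w is (F_out, F_in)."""
    x, w = _ensure(x), _ensure(w)
    y = x.data @ w.data.T
    if b is not None:
        y = y + b.data

    def bwd(g):
        _accumulate(w, (g.T @ x.data).astype(w.data.dtype))
        _accumulate(x, g @ w.data)
        if b is not None:
            _accumulate(b, g.sum(axis=0).astype(b.data.dtype))

    parents = (x, w) if b is None else (x, w, b)
    return _make(y, parents, bwd)
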