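"""Differentiable building-block operations: convolution, interpolation,
softmax/cross-entropy.  All functions take and return :class:`Tensor`."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .tensor import Tensor, count_macs


def _windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """Strided view (B, C, OH, OW, KH, KW) over the padded input."""
    sw = sliding_window_view(xp, (kh, kw), axis=(2, 3))
    if stride > 1:
        sw = sw[:, :, ::stride, ::stride]
    return sw


def _conv1x1(x: Tensor, w: Tensor, b: Tensor | None, stride: int) -> Tensor:
    """Fast path: a 1x1 convolution is a channel-mixing matrix product."""
    xd = x.data if stride == 1 else x.data[:, :, ::stride, ::stride]
    B, cin, oh, ow = xd.shape
    cout = w.data.shape[0]
    w2 = w.data.reshape(cout, cin)
    out = np.tensordot(w2, xd, axes=([1], [1])).transpose(1, 0, 2, 3)
    out = np.ascontiguousarray(out)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)
    count_macs(B * cout * oh * ow * cin)

    def backward(g):
        if w.requires_grad:
            dw = np.tensordot(g, xd, axes=([0, 2, 3], [0, 2, 3]))
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxs = np.tensordot(w2, g, axes=([0], [1])).transpose(1, 0, 2, 3)
            if stride == 1:
                x._accum(np.ascontiguousarray(dxs))
            else:
                dx = np.zeros_like(x.data)
                dx[:, :, ::stride, ::stride] = dxs
                x._accum(dx)

    return Tensor._make(out, (x, w) + ((b,) if b is not None else ()), backward)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           padding: int = 0, groups: int = 1) -> Tensor:
    """2-D cross-correlation.  ``groups`` must be 1 (dense) or ``Cin``
    (depthwise); those are the only forms the network uses."""
    B, cin, H, W = x.data.shape
    cout, cin_g, kh, kw = w.data.shape
    if kh == kw == 1 and groups == 1 and padding == 0:
        return _conv1x1(x, w, b, stride)
    if padding:
        xp = np.pad(x.data, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = x.data
    sw = _windows(xp, kh, kw, stride)
    oh, ow = sw.shape[2], sw.shape[3]
    depthwise = groups == cin and cout == cin and cin_g == 1
    if not depthwise and groups != 1:
        raise NotImplementedError("conv2d supports groups=1 or depthwise only")

    if depthwise:
        out = np.einsum("bcxykl,ckl->bcxy", sw, w.data[:, 0], optimize=True)
    else:
        out = np.tensordot(sw, w.data, axes=([1, 4, 5], [1, 2, 3]))  # (B,OH,OW,Cout)
        out = out.transpose(0, 3, 1, 2)
    out = np.ascontiguousarray(out)
    if b is not None:
        out += b.data.reshape(1, -1, 1, 1)
    count_macs(B * cout * oh * ow * cin_g * kh * kw)

    def backward(g):
        if w.requires_grad:
            if depthwise:
                dw = np.einsum("bcxy,bcxykl->ckl", g, sw, optimize=True)[:, None]
            else:
                dw = np.tensordot(g, sw, axes=([0, 2, 3], [0, 2, 3]))
            w._accum(dw.reshape(w.data.shape))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dxp = np.zeros_like(xp)
            for k in range(kh):
                for l in range(kw):
                    if depthwise:
                        t = g * w.data[:, 0, k, l].reshape(1, -1, 1, 1)
                    else:
                        t = np.tensordot(g, w.data[:, :, k, l], axes=([1], [0]))
                        t = t.transpose(0, 3, 1, 2)
                    dxp[:, :, k:k + oh * stride:stride, l:l + ow * stride:stride] += t
            if padding:
                dxp = dxp[:, :, padding:-padding, padding:-padding]
            x._accum(dxp)

    return Tensor._make(out, (x, w) + ((b,) if b is not None else ()), backward)


@lru_cache(maxsize=256)
def _interp_matrix(n_in: int, n_out: int, dtype: str) -> np.ndarray:
    """Row-interpolation matrix for bilinear resize, half-pixel centres
    (the corner-alignment-off convention, applied everywhere)."""
    m = np.zeros((n_out, n_in), dtype=np.float64)
    if n_in == 1:
        m[:, 0] = 1.0
        return m.astype(dtype)
    src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
    src = np.clip(src, 0, n_in - 1)
    lo = np.floor(src).astype(int)
    hi = np.minimum(lo + 1, n_in - 1)
    frac = src - lo
    m[np.arange(n_out), lo] += 1 - frac
    m[np.arange(n_out), hi] += frac
    return m.astype(dtype)


def interpolate_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    """Resize (B, C, H, W) to ``size`` with separable bilinear weights.

    Interpolation is linear, so the backward pass is the transposed
    weighting; it is excluded from MAC counts by convention.
    """
    B, C, H, W = x.data.shape
    oh, ow = size
    if (oh, ow) == (H, W):
        return x
    dt = str(x.data.dtype)
    mh = _interp_matrix(H, oh, dt)
    mw = _interp_matrix(W, ow, dt)
    out = np.einsum("ij,bcjk,lk->bcil", mh, x.data, mw, optimize=True)

    def backward(g):
        if x.requires_grad:
            x._accum(np.einsum("ij,bcik,kl->bcjl", mh, g, mw, optimize=True))

    return Tensor._make(out, (x,), backward)


def flip_w(x: Tensor) -> Tensor:
    """Horizontal flip of (B, C, H, W), differentiable."""
    out = x.data[:, :, :, ::-1].copy()

    def backward(g):
        if x.requires_grad:
            x._accum(g[:, :, :, ::-1])

    return Tensor._make(out, (x,), backward)


def rotate_bilinear(x: Tensor, angles_deg: np.ndarray) -> Tensor:
    """Per-image rotation of (B, C, H, W) about the centre, bilinear
    resampling with edge clamping; differentiable in ``x``.

    Used to map an augmented view's probability map back into the original
    frame, so ``angles_deg[b]`` is the angle that *undoes* image b's
    augmentation.
    """
    B, C, H, W = x.data.shape
    angles = np.atleast_1d(np.asarray(angles_deg, dtype=np.float64))
    out = np.empty_like(x.data)
    gathers = []
    yy, xx = np.mgrid[0:H, 0:W].astype(np.float64)
    cy, cx = (H - 1) / 2.0, (W - 1) / 2.0
    for b in range(B):
        # skimage/PIL convention: positive angle rotates counter-clockwise;
        # sample the source at the inverse rotation of each target pixel
        th = np.deg2rad(angles[b])
        sy = cy + (yy - cy) * np.cos(th) - (xx - cx) * np.sin(th)
        sx = cx + (yy - cy) * np.sin(th) + (xx - cx) * np.cos(th)
        sy = np.clip(sy, 0, H - 1)
        sx = np.clip(sx, 0, W - 1)
        y0 = np.floor(sy).astype(int)
        x0 = np.floor(sx).astype(int)
        y1 = np.minimum(y0 + 1, H - 1)
        x1 = np.minimum(x0 + 1, W - 1)
        fy = (sy - y0).astype(x.data.dtype)
        fx = (sx - x0).astype(x.data.dtype)
        idx = [(y0 * W + x0).ravel(), (y0 * W + x1).ravel(),
               (y1 * W + x0).ravel(), (y1 * W + x1).ravel()]
        wts = [((1 - fy) * (1 - fx)).ravel(), ((1 - fy) * fx).ravel(),
               (fy * (1 - fx)).ravel(), (fy * fx).ravel()]
        flat = x.data[b].reshape(C, H * W)
        acc = np.zeros((C, H * W), dtype=x.data.dtype)
        for i, w_ in zip(idx, wts):
            acc += flat[:, i] * w_
        out[b] = acc.reshape(C, H, W)
        gathers.append((idx, wts))

    def backward(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.data)
        for b, (idx, wts) in enumerate(gathers):
            gflat = g[b].reshape(C, H * W)
            dflat = dx[b].reshape(C, H * W)
            for i, w_ in zip(idx, wts):
                np.add.at(dflat.T, i, (gflat * w_).T)
        x._accum(dx)

    return Tensor._make(out, (x,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor,
               mean: np.ndarray, var: np.ndarray, eps: float,
               batch_stats: bool) -> Tensor:
    """Fused normalisation over (B, H, W) per channel.

    ``mean``/``var`` are the statistics to normalise with (batch statistics
    during training, running statistics in evaluation); ``batch_stats``
    selects the full backward (statistics depend on x) vs the affine-only
    backward.
    """
    mu = mean.reshape(1, -1, 1, 1)
    inv = 1.0 / np.sqrt(var.reshape(1, -1, 1, 1) + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data.reshape(1, -1, 1, 1) + beta.data.reshape(1, -1, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gi = g * (gamma.data.reshape(1, -1, 1, 1) * inv)
            if batch_stats:
                n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
                m1 = gi.sum(axis=(0, 2, 3), keepdims=True) / n
                m2 = (gi * xhat).sum(axis=(0, 2, 3), keepdims=True) / n
                x._accum(gi - m1 - xhat * m2)
            else:
                x._accum(gi)

    return Tensor._make(out, (x, gamma, beta), backward)


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float) -> Tensor:
    """Fused normalisation over the last dimension."""
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).reshape(-1, x.data.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accum(g.reshape(-1, x.data.shape[-1]).sum(axis=0))
        if x.requires_grad:
            gi = g * gamma.data
            n = x.data.shape[-1]
            m1 = gi.mean(axis=-1, keepdims=True)
            m2 = (gi * xhat).mean(axis=-1, keepdims=True)
            x._accum(inv * (gi - m1 - xhat * m2))

    return Tensor._make(out, (x, gamma, beta), backward)


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    e = (x - m).exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = 1) -> Tensor:
    m = x.data.max(axis=axis, keepdims=True)
    z = x - m
    return z - z.exp().sum(axis=axis, keepdims=True).log()


def cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean per-pixel cross-entropy.  ``logits`` is (B, C, *spatial) or
    (N, C); ``target`` holds integer class indices of the matching spatial
    shape.  Fused forward/backward for speed and stability."""
    x = logits.data
    if x.ndim > 2:
        xm = np.moveaxis(x, 1, -1)
        flat = xm.reshape(-1, x.shape[1])
    else:
        flat = x
    t = np.asarray(target).reshape(-1).astype(np.int64)
    n, c = flat.shape
    if t.min() < 0 or t.max() >= c:
        raise ValueError(f"target labels must lie in [0, {c - 1}]")
    m = flat.max(axis=1, keepdims=True)
    z = flat - m
    lse = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - lse
    loss = -logp[np.arange(n), t].mean()

    def backward(g):
        if logits.requires_grad:
            p = np.exp(logp)
            p[np.arange(n), t] -= 1.0
            dx = (g / n) * p
            if x.ndim > 2:
                dx = np.moveaxis(dx.reshape(xm.shape), -1, 1)
            logits._accum(dx.astype(x.dtype))

    return Tensor._make(np.asarray(loss, dtype=x.dtype), (logits,), backward)
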