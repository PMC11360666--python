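"""Spatial differentiable primitives: convolution, pooling, normalization,
nearest resize and the linear state-space scan behind SS2D.

All feature maps are (B, C, H, W) float32. Convolutions use an im2col /
col2im pair built from k*k strided slices (cheap for the 1x1/3x3/5x5
kernels this network uses); the state-space recurrence is evaluated with
``scipy.signal.lfilter`` per channel, with a hand-derived backward pass
through the recursion.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from . import flops
from .autodiff import Tensor, astensor


# -- im2col / col2im -------------------------------------------------------

def _pad_hw(x: np.ndarray, ph: int, pw: int, value: float = 0.0) -> np.ndarray:
    if ph == 0 and pw == 0:
        return x
    return np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)),
                  mode="constant", constant_values=value)


def _out_size(h: int, k: int, s: int, p: int) -> int:
    return (h + 2 * p - k) // s + 1


def _im2col(xp: np.ndarray, k: int, s: int, ho: int, wo: int) -> np.ndarray:
    """xp already padded -> (B, C, k, k, ho, wo)."""
    b, c = xp.shape[:2]
    cols = np.empty((b, c, k, k, ho, wo), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            cols[:, :, i, j] = xp[:, :, i:i + s * ho:s, j:j + s * wo:s]
    return cols


def _col2im(gcols: np.ndarray, h: int, w: int, k: int, s: int, p: int) -> np.ndarray:
    """(B, C, k, k, ho, wo) -> (B, C, H, W), summing overlaps."""
    b, c = gcols.shape[:2]
    ho, wo = gcols.shape[-2:]
    gx = np.zeros((b, c, h + 2 * p, w + 2 * p), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            gx[:, :, i:i + s * ho:s, j:j + s * wo:s] += gcols[:, :, i, j]
    if p:
        gx = gx[:, :, p:-p, p:-p]
    return gx


# -- convolution ------------------------------------------------------------

def conv2d(x, weight, bias=None, stride: int = 1, padding: int = 0,
           groups: int = 1):
    """2-D convolution. weight: (O, C/groups, k, k); groups is 1 or C
    (dense or depthwise)."""
    x, weight = astensor(x), astensor(weight)
    b_t = astensor(bias) if bias is not None else None
    xd, wd = x.data, weight.data
    B, C, H, W = xd.shape
    O, Cg, kh, kw = wd.shape
    assert kh == kw, "square kernels only"
    k, s, p = kh, stride, padding
    ho, wo = _out_size(H, k, s, p), _out_size(W, k, s, p)
    if ho < 1 or wo < 1:
        raise ValueError(f"conv output collapsed: input {H}x{W}, k={k}, s={s}, p={p}")

    if groups == 1:
        assert Cg == C, f"weight expects {Cg} channels, input has {C}"
        if k == 1 and s == 1 and p == 0:
            cols2 = xd.reshape(B, C, H * W)
        else:
            cols = _im2col(_pad_hw(xd, p, p), k, s, ho, wo)
            cols2 = cols.reshape(B, C * k * k, ho * wo)
        w2 = wd.reshape(O, C * k * k)
        out = np.matmul(w2, cols2).reshape(B, O, ho, wo)
        flops.add_macs(B * O * C * k * k * ho * wo)

        def backward(g):
            g2 = g.reshape(B, O, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("bol,bkl->ok", g2, cols2, optimize=True)
                weight._accumulate(gw.reshape(wd.shape))
            if x.requires_grad:
                gcols2 = np.matmul(w2.T, g2)
                if k == 1 and s == 1 and p == 0:
                    gx = gcols2.reshape(B, C, H, W)
                else:
                    gx = _col2im(gcols2.reshape(B, C, k, k, ho, wo), H, W, k, s, p)
                x._accumulate(gx)
            if b_t is not None and b_t.requires_grad:
                b_t._accumulate(g.sum(axis=(0, 2, 3)))

    elif groups == C and O == C and Cg == 1:
        # depthwise
        cols = _im2col(_pad_hw(xd, p, p), k, s, ho, wo)  # (B,C,k,k,ho,wo)
        wdw = wd.reshape(C, k * k)
        out = np.einsum("bckl,ck->bcl", cols.reshape(B, C, k * k, ho * wo),
                        wdw, optimize=True).reshape(B, C, ho, wo)
        flops.add_macs(B * C * k * k * ho * wo)

        def backward(g):
            g2 = g.reshape(B, C, ho * wo)
            if weight.requires_grad:
                gw = np.einsum("bcl,bckl->ck", g2,
                               cols.reshape(B, C, k * k, ho * wo), optimize=True)
                weight._accumulate(gw.reshape(wd.shape))
            if x.requires_grad:
                gcols = np.einsum("bcl,ck->bckl", g2, wdw, optimize=True)
                gx = _col2im(gcols.reshape(B, C, k, k, ho, wo), H, W, k, s, p)
                x._accumulate(gx)
            if b_t is not None and b_t.requires_grad:
                b_t._accumulate(g.sum(axis=(0, 2, 3)))

    else:
        raise NotImplementedError("only dense (groups=1) or depthwise convs")

    if b_t is not None:
        out = out + b_t.data.reshape(1, O, 1, 1)
    parents = (x, weight) if b_t is None else (x, weight, b_t)
    return Tensor._result(out, parents, backward)


# -- pooling ----------------------------------------------------------------

def maxpool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    x = astensor(x)
    xd = x.data
    B, C, H, W = xd.shape
    k, s, p = kernel, stride, padding
    ho, wo = _out_size(H, k, s, p), _out_size(W, k, s, p)
    xp = _pad_hw(xd, p, p, value=-np.inf) if p else xd
    cols = _im2col(xp, k, s, ho, wo).reshape(B, C, k * k, ho, wo)
    arg = cols.argmax(axis=2)  # first maximal element on ties
    out = np.take_along_axis(cols, arg[:, :, None], axis=2)[:, :, 0]

    def backward(g):
        if x.requires_grad:
            gcols = np.zeros((B, C, k * k, ho, wo), dtype=np.float32)
            np.put_along_axis(gcols, arg[:, :, None], g[:, :, None], axis=2)
            x._accumulate(_col2im(gcols.reshape(B, C, k, k, ho, wo), H, W, k, s, p))

    return Tensor._result(out, (x,), backward)


def avgpool2d(x, kernel: int, stride: int = 1, padding: int = 0):
    x = astensor(x)
    xd = x.data
    B, C, H, W = xd.shape
    k, s, p = kernel, stride, padding
    ho, wo = _out_size(H, k, s, p), _out_size(W, k, s, p)
    cols = _im2col(_pad_hw(xd, p, p), k, s, ho, wo)
    out = cols.mean(axis=(2, 3))

    def backward(g):
        if x.requires_grad:
            gcols = np.broadcast_to(g[:, :, None, None] / (k * k),
                                    (B, C, k, k, ho, wo)).astype(np.float32)
            x._accumulate(_col2im(gcols, H, W, k, s, p))

    return Tensor._result(out, (x,), backward)


# -- resize -----------------------------------------------------------------

def upsample_nearest(x, scale: int = 2):
    x = astensor(x)
    xd = x.data
    B, C, H, W = xd.shape
    out = xd.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        if x.requires_grad:
            gx = g.reshape(B, C, H, scale, W, scale).sum(axis=(3, 5))
            x._accumulate(gx)

    return Tensor._result(out, (x,), backward)


def resize_nearest(x, out_h: int, out_w: int):
    """Nearest-neighbor resize to an arbitrary target (used by CBFuse)."""
    x = astensor(x)
    xd = x.data
    B, C, H, W = xd.shape
    if (out_h, out_w) == (H, W):
        return x
    ri = np.floor(np.arange(out_h) * (H / out_h)).astype(np.int64)
    ci = np.floor(np.arange(out_w) * (W / out_w)).astype(np.int64)
    out = xd[:, :, ri][:, :, :, ci]

    def backward(g):
        if x.requires_grad:
            tmp = np.zeros((B, C, H, out_w), dtype=np.float32)
            np.add.at(tmp, (slice(None), slice(None), ri), g)
            gx = np.zeros((B, C, H, W), dtype=np.float32)
            np.add.at(gx, (slice(None), slice(None), slice(None), ci), tmp)
            x._accumulate(gx)

    return Tensor._result(out, (x,), backward)


def flip(x, axis: int):
    x = astensor(x)
    out = np.flip(x.data, axis=axis).copy()

    def backward(g):
        if x.requires_grad:
            x._accumulate(np.flip(g, axis=axis))

    return Tensor._result(out, (x,), backward)


# -- normalization ----------------------------------------------------------

def batchnorm2d(x, gamma, beta, running_mean, running_var,
                training: bool, momentum: float = 0.1, eps: float = 1e-5):
    """Per-channel batch normalization on (B, C, H, W).

    running_mean / running_var are plain ndarrays updated in place in
    training mode.
    """
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    xd = x.data
    C = xd.shape[1]
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        n = xd.size / C
        running_mean *= (1 - momentum)
        running_mean += momentum * mu
        running_var *= (1 - momentum)
        running_var += momentum * var * (n / max(n - 1, 1))
    else:
        mu, var = running_mean, running_var
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu.reshape(1, C, 1, 1)) * inv.reshape(1, C, 1, 1)
    out = gamma.data.reshape(1, C, 1, 1) * xhat + beta.data.reshape(1, C, 1, 1)

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gs = gamma.data.reshape(1, C, 1, 1) * inv.reshape(1, C, 1, 1)
            if training:
                m = g.mean(axis=(0, 2, 3), keepdims=True)
                mx = (g * xhat).mean(axis=(0, 2, 3), keepdims=True)
                x._accumulate(gs * (g - m - xhat * mx))
            else:
                x._accumulate(gs * g)

    return Tensor._result(out.astype(np.float32), (x, gamma, beta), backward)


def layernorm(x, gamma, beta, eps: float = 1e-6):
    """Layer normalization over the last axis (per-token channel norm)."""
    x, gamma, beta = astensor(x), astensor(gamma), astensor(beta)
    xd = x.data
    mu = xd.mean(axis=-1, keepdims=True)
    var = xd.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv
    out = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).reshape(-1, xd.shape[-1]).sum(axis=0))
        if beta.requires_grad:
            beta._accumulate(g.reshape(-1, xd.shape[-1]).sum(axis=0))
        if x.requires_grad:
            gg = g * gamma.data
            m = gg.mean(axis=-1, keepdims=True)
            mx = (gg * xhat).mean(axis=-1, keepdims=True)
            x._accumulate(inv * (gg - m - xhat * mx))

    return Tensor._result(out.astype(np.float32), (x, gamma, beta), backward)


# -- linear state-space scan -------------------------------------------------

def ssm_scan(x, a, b_in, c_out, d_skip, delta):
    """Diagonal linear time-invariant state-space recurrence along the last
    axis of x (B, C, L):

        h_t = exp(delta*a) * h_{t-1} + delta*b_in * x_t,   h_0 = 0
        y_t = c_out * h_t + d_skip * x_t

    All parameters are per-channel vectors (C,). delta must be positive and
    a negative so the discretized transition is a contraction.
    """
    x = astensor(x)
    a, b_in = astensor(a), astensor(b_in)
    c_out, d_skip, delta = astensor(c_out), astensor(d_skip), astensor(delta)
    if np.any(delta.data <= 0):
        raise ValueError("delta must be positive")
    xd = x.data
    B, C, L = xd.shape
    lam = np.exp(delta.data * a.data)  # (C,)
    inp = delta.data * b_in.data
    h = np.empty_like(xd)
    for c in range(C):
        h[:, c, :] = lfilter([inp[c]], [1.0, -lam[c]], xd[:, c, :], axis=-1)
    out = c_out.data[None, :, None] * h + d_skip.data[None, :, None] * xd
    flops.add_macs(2 * xd.size)  # 2 MACs/token for the recurrence + readout

    def backward(g):
        gy = g
        gh = c_out.data[None, :, None] * gy
        ghat = np.empty_like(gh)
        for c in range(C):
            ghat[:, c, ::-1] = lfilter([1.0], [1.0, -lam[c]], gh[:, c, ::-1], axis=-1)
        if x.requires_grad:
            x._accumulate(inp[None, :, None] * ghat + d_skip.data[None, :, None] * gy)
        if c_out.requires_grad:
            c_out._accumulate((gy * h).sum(axis=(0, 2)))
        if d_skip.requires_grad:
            d_skip._accumulate((gy * xd).sum(axis=(0, 2)))
        hprev = np.concatenate([np.zeros((B, C, 1), np.float32), h[:, :, :-1]], axis=2)
        dlam = (ghat * hprev).sum(axis=(0, 2))
        dinp = (ghat * xd).sum(axis=(0, 2))
        if a.requires_grad:
            a._accumulate(dlam * delta.data * lam)
        if b_in.requires_grad:
            b_in._accumulate(dinp * delta.data)
        if delta.requires_grad:
            delta._accumulate(dlam * a.data * lam + dinp * b_in.data)

    return Tensor._result(out, (x, a, b_in, c_out, d_skip, delta), backward)


def ssm_scan_reference(x: np.ndarray, a, b_in, c_out, d_skip, delta) -> np.ndarray:
    """Naive per-token recurrence (forward only) — the oracle the vectorized
    scan is tested against."""
    x = np.asarray(x, dtype=np.float64)
    B, C, L = x.shape
    lam = np.exp(np.asarray(delta, np.float64) * np.asarray(a, np.float64))
    inp = np.asarray(delta, np.float64) * np.asarray(b_in, np.float64)
    h = np.zeros((B, C), dtype=np.float64)
    y = np.empty_like(x)
    for t in range(L):
        h = lam[None, :] * h + inp[None, :] * x[:, :, t]
        y[:, :, t] = np.asarray(c_out)[None, :] * h + np.asarray(d_skip)[None, :] * x[:, :, t]
    return y
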