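"""Bi-Level Routing Attention (BRA).

Attention in two stages: the map is partitioned into an S x S grid of
contiguous regions; region-level descriptors (mean query/key per region)
build a region-to-region affinity whose row-wise top-k picks, for every
query region, the k regions worth attending to; token-to-token attention
then runs only over the gathered keys/values, and a local context
enhancement (depthwise 5x5 convolution of V) is added to the output.

With k = S^2 the routing is exhaustive and the operator equals dense
attention plus LCE — the equivalence the tests exercise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from . import nnops
from .autodiff import Tensor, astensor
from .modules import ConvBN, Module, Parameter, kaiming


@dataclass
class BRAConfig:
    S: int = 8              # regions per axis
    k: int = 4              # routed regions per query region
    num_heads: int = 1
    scale: float | None = None  # None -> 1/sqrt(head_dim); set 1.0 for the literal form

    def __post_init__(self):
        if self.S < 1:
            raise ValueError("S must be >= 1")
        if not (1 <= self.k <= self.S ** 2):
            raise ValueError(f"k must be in [1, S^2], got k={self.k}, S={self.S}")


@dataclass
class BRATrace:
    x_regions: np.ndarray
    q: np.ndarray
    k_: np.ndarray
    v: np.ndarray
    q_r: np.ndarray
    k_r: np.ndarray
    a_r: np.ndarray
    i_r: np.ndarray
    k_g: np.ndarray
    v_g: np.ndarray
    a: np.ndarray
    o: np.ndarray


def patchify(x, S: int):
    """(B, C, H, W) -> (B, S^2, H*W/S^2, C); each region a contiguous
    (H/S)x(W/S) tile, tokens row-major within the tile."""
    x = astensor(x)
    b, c, h, w = x.shape
    if h % S or w % S:
        raise ValueError(f"spatial dims {h}x{w} not divisible by region grid S={S}")
    rh, rw = h // S, w // S
    y = ad.reshape(x, (b, c, S, rh, S, rw))
    y = ad.transpose(y, (0, 2, 4, 3, 5, 1))       # b, Sh, Sw, rh, rw, c
    return ad.reshape(y, (b, S * S, rh * rw, c))


def unpatchify(x, S: int, h: int, w: int):
    """Inverse of :func:`patchify` back to (B, C, H, W)."""
    x = astensor(x)
    b, r2, n, c = x.shape
    rh, rw = h // S, w // S
    y = ad.reshape(x, (b, S, S, rh, rw, c))
    y = ad.transpose(y, (0, 5, 1, 3, 2, 4))
    return ad.reshape(y, (b, c, h, w))


def region_routing(q, k_, cfg: BRAConfig):
    """Region means -> affinity -> row-wise top-k.

    Returns (a_r Tensor (B, S^2, S^2), i_r ndarray (B, S^2, k)); indices are
    sorted by descending affinity, ties broken toward the lower region index.
    """
    q, k_ = astensor(q), astensor(k_)
    if cfg.k > q.shape[1]:
        raise ValueError(f"k={cfg.k} exceeds number of regions {q.shape[1]}")
    q_r = ad.mean(q, axis=2)                       # (B, R, C)
    k_r = ad.mean(k_, axis=2)
    a_r = ad.matmul(q_r, ad.transpose(k_r, (0, 2, 1)))
    order = np.argsort(-a_r.data, axis=-1, kind="stable")
    i_r = order[:, :, :cfg.k]
    return a_r, i_r, q_r, k_r


def lce(v, kernel):
    """Local context enhancement: shape-preserving depthwise convolution."""
    kernel = astensor(kernel)
    ksz = kernel.shape[-1]
    if ksz % 2 == 0:
        raise ValueError("LCE kernel must be odd-sized")
    return nnops.conv2d(v, kernel, None, stride=1, padding=(ksz - 1) // 2,
                        groups=kernel.shape[0])


class BRA(Module):
    """The routing-attention operator with learnable Q/K/V projections and
    a depthwise 5x5 LCE kernel."""

    def __init__(self, rng, channels: int, cfg: BRAConfig | None = None,
                 lce_kernel_size: int = 5):
        super().__init__()
        self.channels = channels
        self.cfg = cfg or BRAConfig()
        if channels % self.cfg.num_heads:
            raise ValueError("channels must divide num_heads")
        self.wq = Parameter(kaiming(rng, (channels, channels), channels))
        self.wk = Parameter(kaiming(rng, (channels, channels), channels))
        self.wv = Parameter(kaiming(rng, (channels, channels), channels))
        self.lce_kernel = Parameter(
            kaiming(rng, (channels, 1, lce_kernel_size, lce_kernel_size),
                    lce_kernel_size ** 2))

    def forward(self, x, return_trace: bool = False):
        x = astensor(x)
        b, c, h, w = x.shape
        cfg = self.cfg
        S, k, nh = cfg.S, cfg.k, cfg.num_heads
        xr = patchify(x, S)                       # (B, R, N, C)
        r2, n = xr.shape[1], xr.shape[2]
        q = ad.matmul(xr, self.wq)
        k_ = ad.matmul(xr, self.wk)
        v = ad.matmul(xr, self.wv)
        a_r, i_r, _, _ = region_routing(q, k_, cfg)

        bidx = np.arange(b)[:, None, None]
        k_g = k_[bidx, i_r]                       # (B, R, k, N, C)
        v_g = v[bidx, i_r]
        k_g = ad.reshape(k_g, (b, r2, k * n, c))
        v_g = ad.reshape(v_g, (b, r2, k * n, c))

        hd = c // nh
        scale = cfg.scale if cfg.scale is not None else 1.0 / np.sqrt(hd)

        def heads(t, length):
            t = ad.reshape(t, (b, r2, length, nh, hd))
            return ad.transpose(t, (0, 1, 3, 2, 4))  # (B, R, h, L, hd)

        qh, kh, vh = heads(q, n), heads(k_g, k * n), heads(v_g, k * n)
        logits = ad.matmul(qh, ad.transpose(kh, (0, 1, 2, 4, 3))) * scale
        attn = ad.softmax(logits, axis=-1)
        oh = ad.matmul(attn, vh)                  # (B, R, h, N, hd)
        o_attn = ad.reshape(ad.transpose(oh, (0, 1, 3, 2, 4)), (b, r2, n, c))

        v_map = unpatchify(v, S, h, w)
        lce_map = lce(v_map, self.lce_kernel)
        o = o_attn + patchify(lce_map, S)         # Eq form: O = Attn + LCE(V)
        out = unpatchify(o, S, h, w)
        if not return_trace:
            return out
        trace = BRATrace(
            x_regions=xr.data, q=q.data, k_=k_.data, v=v.data,
            q_r=q.data.mean(axis=2), k_r=k_.data.mean(axis=2),
            a_r=a_r.data, i_r=i_r, k_g=k_g.data, v_g=v_g.data,
            a=attn.data, o=o.data)
        return out, trace


def dense_attention_reference(x: np.ndarray, wq, wk, wv, lce_kernel,
                              scale: float | None = None) -> np.ndarray:
    """Brute-force full attention over all H*W tokens + LCE — the oracle for
    the k = S^2 equivalence (single head)."""
    b, c, h, w = x.shape
    tokens = x.transpose(0, 2, 3, 1).reshape(b, h * w, c).astype(np.float64)
    q = tokens @ np.asarray(wq, np.float64)
    k = tokens @ np.asarray(wk, np.float64)
    v = tokens @ np.asarray(wv, np.float64)
    s = 1.0 / np.sqrt(c) if scale is None else scale
    logits = s * (q @ k.transpose(0, 2, 1))
    logits -= logits.max(axis=-1, keepdims=True)
    e = np.exp(logits)
    attn = e / e.sum(axis=-1, keepdims=True)
    o = attn @ v
    o_map = o.reshape(b, h, w, c).transpose(0, 3, 1, 2)
    # direct sliding-window depthwise conv
    ksz = lce_kernel.shape[-1]
    p = (ksz - 1) // 2
    v_map = v.reshape(b, h, w, c).transpose(0, 3, 1, 2)
    vp = np.pad(v_map, ((0, 0), (0, 0), (p, p), (p, p)))
    lce_out = np.zeros_like(v_map)
    for i in range(ksz):
        for j in range(ksz):
            lce_out += lce_kernel[:, 0, i, j][None, :, None, None] * \
                vp[:, :, i:i + h, j:j + w]
    return (o_map + lce_out).astype(np.float64)
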