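"""Visual state-space (VSS) block and the C2f_VSS aggregation wrapper.

The spatial mixer is SS2D: the feature map is flattened into four
directional token sequences (row-major, row-major reversed, column-major,
column-major reversed), a diagonal linear time-invariant state-space
recurrence runs along each, and the four un-scanned outputs are summed.
A literal shifted-depthwise-convolution variant is available behind
``variant="shift_conv"``; the selective-scan form is the default.

The VSS block embeds the input linearly into two paths: path A runs
depthwise conv -> SiLU -> SS2D -> layer norm; path B is a SiLU gate; the
elementwise product is projected back and added to the input residually.
The literal stage ordering LN -> SS2D -> DWConv -> projection is exposed
via ``order="eq"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nnops
from .autodiff import Tensor, astensor
from .modules import ConvBN, LayerNorm, Linear, Module, Parameter, kaiming


@dataclass
class SS2DParams:
    """Raw scan parameters (all per-channel vectors of length C)."""
    a: np.ndarray        # diagonal state transition, negative
    b_in: np.ndarray
    c_out: np.ndarray
    d_skip: np.ndarray
    delta: np.ndarray    # positive step size

    def __post_init__(self):
        if np.any(self.delta <= 0):
            raise ValueError("delta must be positive")
        if np.any(np.exp(self.delta * self.a) >= 1.0):
            raise ValueError("discretized transition must be a contraction")


def _directional_sequences(x):
    """(B, C, H, W) -> four (B, C, L) sequences."""
    b, c, h, w = x.shape
    row = ad.reshape(x, (b, c, h * w))
    col = ad.reshape(ad.transpose(x, (0, 1, 3, 2)), (b, c, h * w))
    return [row, nnops.flip(row, 2), col, nnops.flip(col, 2)], (b, c, h, w)


def _merge_directions(ys, shape):
    b, c, h, w = shape
    y0 = ys[0]
    y1 = nnops.flip(ys[1], 2)
    y2 = ys[2]
    y3 = nnops.flip(ys[3], 2)
    out = ad.reshape(y0 + y1, (b, c, h, w))
    out_col = ad.reshape(y2 + y3, (b, c, w, h))
    return out + ad.transpose(out_col, (0, 1, 3, 2))


def ss2d_forward(x, p: SS2DParams):
    """Functional four-directional scan with raw parameter vectors.

    Computed in double precision so it can serve as an oracle-grade
    reference path; the in-network :class:`SS2D` module runs in float32.
    """
    x = astensor(x)
    x = Tensor(x.data.astype(np.float64))
    seqs, shape = _directional_sequences(x)
    as64 = lambda v: Tensor(np.asarray(v, np.float64))
    a, b_in = as64(p.a), as64(p.b_in)
    c_out, d_skip, delta = as64(p.c_out), as64(p.d_skip), as64(p.delta)
    ys = [nnops.ssm_scan(s, a, b_in, c_out, d_skip, delta) for s in seqs]
    return _merge_directions(ys, shape)


def ss2d_reference(x: np.ndarray, p: SS2DParams) -> np.ndarray:
    """Naive per-token recurrent loop over all four directions (oracle)."""
    b, c, h, w = x.shape
    row = x.reshape(b, c, h * w)
    col = x.transpose(0, 1, 3, 2).reshape(b, c, h * w)
    args = (p.a, p.b_in, p.c_out, p.d_skip, p.delta)
    y0 = nnops.ssm_scan_reference(row, *args)
    y1 = nnops.ssm_scan_reference(row[:, :, ::-1], *args)[:, :, ::-1]
    y2 = nnops.ssm_scan_reference(col, *args)
    y3 = nnops.ssm_scan_reference(col[:, :, ::-1], *args)[:, :, ::-1]
    out = (y0 + y1).reshape(b, c, h, w)
    out += (y2 + y3).reshape(b, c, w, h).transpose(0, 1, 3, 2)
    return out


class SS2D(Module):
    """Learnable SS2D operator. The transition is parameterized as
    a = -exp(a_log) and delta = exp(log_delta) so the contraction invariant
    holds throughout training."""

    def __init__(self, rng, channels: int, variant: str = "selective_scan"):
        super().__init__()
        if variant not in ("selective_scan", "shift_conv"):
            raise ValueError(f"unknown SS2D variant {variant!r}")
        self.variant = variant
        self.channels = channels
        if variant == "selective_scan":
            self.a_log = Parameter(np.log(rng.uniform(0.5, 1.5, channels))
                                   .astype(np.float32))
            self.log_delta = Parameter(np.log(rng.uniform(0.1, 0.5, channels))
                                       .astype(np.float32))
            self.b_in = Parameter(rng.standard_normal(channels).astype(np.float32))
            self.c_out = Parameter(rng.standard_normal(channels).astype(np.float32))
            self.d_skip = Parameter(np.ones(channels, np.float32))
        else:
            self.shift = ConvBN(rng, channels, channels, 3, groups=channels,
                                activation="identity", use_norm=False)

    def params(self) -> SS2DParams:
        return SS2DParams(a=-np.exp(self.a_log.data), b_in=self.b_in.data,
                          c_out=self.c_out.data, d_skip=self.d_skip.data,
                          delta=np.exp(self.log_delta.data))

    def forward(self, x):
        if self.variant == "shift_conv":
            return self.shift(x)
        x = astensor(x)
        a = -ad.exp(self.a_log)
        delta = ad.exp(self.log_delta)
        seqs, shape = _directional_sequences(x)
        ys = [nnops.ssm_scan(s, a, self.b_in, self.c_out, self.d_skip, delta)
              for s in seqs]
        return _merge_directions(ys, shape)


@dataclass
class VSSTrace:
    h_prime: np.ndarray
    x_prime: np.ndarray
    h_ln: np.ndarray
    h_ss2d: np.ndarray
    h_dwconv: np.ndarray
    h_linear: np.ndarray
    y: np.ndarray


class VSSBlock(Module):
    def __init__(self, rng, channels: int, hidden: int | None = None,
                 order: str = "fig", ss2d_variant: str = "selective_scan"):
        super().__init__()
        if order not in ("fig", "eq"):
            raise ValueError("order must be 'fig' or 'eq'")
        self.order = order
        d = channels if hidden is None else hidden
        self.channels, self.hidden = channels, d
        self.embed_a = Linear(rng, channels, d)   # W1, b1
        self.embed_b = Linear(rng, channels, d)   # W2, b2
        self.dw = ConvBN(rng, d, d, 3, groups=d, activation="identity",
                         use_norm=False)
        self.ln = LayerNorm(d)
        self.ss2d = SS2D(rng, d, ss2d_variant)
        self.proj = Linear(rng, d, channels)      # W3, b3

    def _tokens(self, x):
        b, c, h, w = x.shape
        return ad.transpose(ad.reshape(x, (b, c, h * w)), (0, 2, 1)), (b, h, w)

    def _maps(self, t, meta, d):
        b, h, w = meta
        return ad.reshape(ad.transpose(t, (0, 2, 1)), (b, d, h, w))

    def forward(self, x, return_trace: bool = False):
        x = astensor(x)
        tok, meta = self._tokens(x)
        h_prime = self.embed_a(tok)
        x_prime = self.embed_b(tok)
        d = self.hidden
        if self.order == "fig":
            hm = self._maps(h_prime, meta, d)
            h_dw = self.dw(hm)
            h_act = ad.silu(h_dw)
            h_ss = self.ss2d(h_act)
            h_ln = self.ln(self._tokens(h_ss)[0])
            path_a = h_ln
            tr_ln, tr_ss, tr_dw = h_ln, h_ss, h_dw
        else:  # literal equation ordering LN -> SS2D -> DWConv
            h_ln = self.ln(h_prime)
            h_ss = self.ss2d(self._maps(h_ln, meta, d))
            h_dw = ad.silu(self.dw(h_ss))
            path_a = self._tokens(h_dw)[0]
            tr_ln, tr_ss, tr_dw = h_ln, h_ss, h_dw
        gate = ad.silu(x_prime)
        fused = path_a * gate
        h_linear = self.proj(fused)
        out = x + self._maps(h_linear, meta, self.channels)
        if not return_trace:
            return out
        def _d(t):
            return t.data
        trace = VSSTrace(h_prime=_d(h_prime), x_prime=_d(x_prime),
                         h_ln=_d(tr_ln), h_ss2d=_d(tr_ss), h_dwconv=_d(tr_dw),
                         h_linear=_d(h_linear), y=_d(h_linear))
        return out, trace


class C2fVSS(Module):
    """1x1 conv -> split halves -> chain of VSS blocks on the second half
    (every intermediate retained) -> concat all -> 1x1 conv."""

    def __init__(self, rng, in_ch: int, out_ch: int, n_blocks: int = 1,
                 hidden: int | None = None, activation: str = "silu",
                 ss2d_variant: str = "selective_scan"):
        super().__init__()
        hidden = out_ch if hidden is None else hidden
        if hidden % 2:
            raise ValueError("hidden width must be even")
        self.cv1 = ConvBN(rng, in_ch, hidden, 1, activation=activation)
        h2 = hidden // 2
        self.blocks = [VSSBlock(rng, h2, ss2d_variant=ss2d_variant)
                       for _ in range(n_blocks)]
        self.cv2 = ConvBN(rng, (2 + n_blocks) * h2, out_ch, 1,
                          activation=activation)

    def forward(self, x):
        y = self.cv1(x)
        y1, y2 = ad.split(y, [y.shape[1] // 2] * 2, axis=1)
        feats = [y1, y2]
        cur = y2
        for blk in self.blocks:
            cur = blk(cur)
            feats.append(cur)
        return self.cv2(ad.concat(feats, axis=1))
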