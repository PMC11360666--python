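"""Backbone/neck building blocks.

The RepVGG block here is the split-branch-shuffle variant: the input is
split in half along channels, the second half runs through parallel 3x3 /
1x1 / identity branches (each batch-normalized) whose outputs are summed,
the halves are re-concatenated and channel-shuffled. The parallel branches
exist only during training; :meth:`RepVGGBlock.reparameterize` folds each
branch's normalization into its convolution, zero-pads the 1x1 kernel,
expresses the identity as a centered one-hot kernel and sums all three
into a single 3x3 convolution with bias.

Also here: RepNCSPELAN4 (1x1 -> split -> two 3x3 convs on one half ->
concat -> 1x1), ADown (pool/split/conv downsampling), SPPELAN (parallel
5/9/13 max-pool pyramid), Silence, CBLinear and CBFuse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nnops
from .autodiff import Tensor, astensor
from .modules import ConvBN, Module, Parameter, fuse_conv_bn


# -- functional ops ---------------------------------------------------------

def channel_split(x):
    """Split a (B, C, H, W) map into front/back halves along channels."""
    x = astensor(x)
    c = x.shape[1]
    if c % 2:
        raise ValueError(f"channel_split needs an even channel count, got {c}")
    return tuple(ad.split(x, [c // 2, c // 2], axis=1))


def channel_shuffle(x, groups: int):
    """Interleave channel groups: reshape(groups, C/groups) -> transpose -> flatten."""
    x = astensor(x)
    b, c, h, w = x.shape
    if c % groups:
        raise ValueError(f"channels ({c}) not divisible by groups ({groups})")
    y = ad.reshape(x, (b, groups, c // groups, h, w))
    y = ad.transpose(y, (0, 2, 1, 3, 4))
    return ad.reshape(y, (b, c, h, w))


def shuffle_permutation(channels: int, groups: int) -> np.ndarray:
    """The explicit channel permutation channel_shuffle applies."""
    return np.arange(channels).reshape(groups, channels // groups).T.ravel()


def silence(x):
    """Identity placeholder at the network entry."""
    return astensor(x)


# -- RepVGG ------------------------------------------------------------------

@dataclass
class RepVGGTrace:
    x_left: np.ndarray
    x_right: np.ndarray
    y_3x3: np.ndarray
    y_1x1: np.ndarray
    y_id: np.ndarray
    y_repvgg: np.ndarray
    y_concat: np.ndarray
    y_shuffle: np.ndarray


class RepVGGBlock(Module):
    """Split-branch-shuffle RepVGG block (shape preserving, even C required).

    The activation is applied to the summed branch output (required for the
    merged single-conv form to be exactly equivalent); set
    activation="identity" for the algebraic identities.
    """

    def __init__(self, rng, channels: int, activation: str = "silu",
                 shuffle_groups: int = 2):
        super().__init__()
        if channels % 2:
            raise ValueError(f"RepVGG block needs even channels, got {channels}")
        self.channels = channels
        self.act_name = activation
        self.shuffle_groups = shuffle_groups
        c = channels // 2
        self.conv3 = ConvBN(rng, c, c, 3, activation="identity")
        self.conv1 = ConvBN(rng, c, c, 1, activation="identity")
        from .modules import BatchNorm2d
        self.id_bn = BatchNorm2d(c)
        self.merged: ConvBN | None = None

    def forward(self, x, return_trace: bool = False):
        x = astensor(x)
        x_left, x_right = channel_split(x)
        if self.merged is not None:
            y_pre = nnops.conv2d(x_right, self.merged.weight, self.merged.bias,
                                 stride=1, padding=1)
            y3 = y1 = yid = None
        else:
            y3 = self.conv3(x_right)
            y1 = self.conv1(x_right)
            yid = self.id_bn(x_right)
            y_pre = y3 + y1 + yid
        from .modules import _act
        y_act = _act(self.act_name)(y_pre)
        y_concat = ad.concat([x_left, y_act], axis=1)
        out = channel_shuffle(y_concat, self.shuffle_groups)
        if not return_trace:
            return out
        trace = RepVGGTrace(
            x_left=x_left.data, x_right=x_right.data,
            y_3x3=None if y3 is None else y3.data,
            y_1x1=None if y1 is None else y1.data,
            y_id=None if yid is None else yid.data,
            y_repvgg=y_pre.data, y_concat=y_concat.data, y_shuffle=out.data)
        return out, trace

    def merged_kernel(self) -> tuple[np.ndarray, np.ndarray]:
        """Fold norms and sum the three branches into one 3x3 kernel + bias."""
        w3, b3 = fuse_conv_bn(self.conv3.weight.data, None, self.conv3.bn)
        w1, b1 = fuse_conv_bn(self.conv1.weight.data, None, self.conv1.bn)
        w1p = np.zeros_like(w3)
        w1p[:, :, 1:2, 1:2] = w1
        c = self.channels // 2
        wid = np.zeros((c, c, 3, 3), np.float32)
        wid[np.arange(c), np.arange(c), 1, 1] = 1.0
        wid, bid = fuse_conv_bn(wid, None, self.id_bn)
        return w3 + w1p + wid, b3 + b1 + bid

    def reparameterize(self) -> "RepVGGBlock":
        """Return a merged copy running a single 3x3 conv on the right half."""
        rng = np.random.default_rng(0)
        out = RepVGGBlock(rng, self.channels, self.act_name, self.shuffle_groups)
        w, b = self.merged_kernel()
        merged = ConvBN(rng, self.channels // 2, self.channels // 2, 3,
                        activation=self.act_name, use_norm=False)
        merged.weight.data = w
        merged.bias.data = b
        out.merged = merged
        out.conv3 = out.conv1 = out.id_bn = None
        return out


class RepVGGStage(Module):
    """Network-level RepVGG node: a strided 3x3 conv-BN-act providing the
    channel change and /2 downsampling, followed by the split-branch-shuffle
    block. The block itself is stride-1 by construction (the untouched half
    must re-concatenate), while the 80/40/20 head grid requires the early
    stages to downsample — hence the paired form."""

    def __init__(self, rng, in_ch: int, out_ch: int, stride: int = 2,
                 activation: str = "silu"):
        super().__init__()
        self.down = ConvBN(rng, in_ch, out_ch, 3, stride=stride, activation=activation)
        self.block = RepVGGBlock(rng, out_ch, activation=activation)

    def forward(self, x):
        return self.block(self.down(x))

    def reparameterize(self) -> "RepVGGStage":
        rng = np.random.default_rng(0)
        out = RepVGGStage.__new__(RepVGGStage)
        Module.__init__(out)
        out.down = self.down.fuse()
        out.block = self.block.reparameterize()
        return out


# -- RepNCSPELAN4 -------------------------------------------------------------

class RepNCSPELAN4(Module):
    def __init__(self, rng, in_ch: int, out_ch: int, hidden: int | None = None,
                 activation: str = "silu", final_activation: str | None = None):
        super().__init__()
        hidden = out_ch if hidden is None else hidden
        if hidden % 2:
            raise ValueError("hidden width must be even")
        self.cv1 = ConvBN(rng, in_ch, hidden, 1, activation=activation)
        h2 = hidden // 2
        self.b2a = ConvBN(rng, h2, h2, 3, activation=activation)
        self.b2b = ConvBN(rng, h2, h2, 3, activation=activation)
        self.cv2 = ConvBN(rng, hidden, out_ch, 1,
                          activation=final_activation or activation)

    def forward(self, x):
        y = self.cv1(x)
        y1, y2 = channel_split(y)
        y2 = self.b2b(self.b2a(y2))
        return self.cv2(ad.concat([y1, y2], axis=1))


# -- ADown --------------------------------------------------------------------

class ADown(Module):
    """Pool -> split -> per-branch conv -> concat downsampling (/2)."""

    def __init__(self, rng, in_ch: int, out_ch: int, activation: str = "silu"):
        super().__init__()
        if in_ch % 2 or out_ch % 2:
            raise ValueError("ADown needs even channel counts")
        self.cv1 = ConvBN(rng, in_ch // 2, out_ch // 2, 3, stride=2,
                          activation=activation)
        self.cv2 = ConvBN(rng, in_ch // 2, out_ch // 2, 1, activation=activation)

    def forward(self, x):
        x = astensor(x)
        _, _, h, w = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"ADown needs even spatial dims, got {h}x{w}")
        x = nnops.avgpool2d(x, 2, stride=1, padding=0)
        x1, x2 = channel_split(x)
        y1 = self.cv1(x1)
        y2 = self.cv2(nnops.maxpool2d(x2, 3, stride=2, padding=1))
        return ad.concat([y1, y2], axis=1)


# -- SPPELAN ------------------------------------------------------------------

class SPPELAN(Module):
    """Spatial pyramid: 1x1 transform, then parallel {1x1 conv, max-pool
    k=5/9/13 (stride 1)} branches, concat, 1x1 projection."""

    def __init__(self, rng, in_ch: int, out_ch: int, hidden: int | None = None,
                 activation: str = "silu"):
        super().__init__()
        hidden = out_ch // 2 if hidden is None else hidden
        self.cv1 = ConvBN(rng, in_ch, hidden, 1, activation=activation)
        self.cv2 = ConvBN(rng, hidden, hidden, 1, activation=activation)
        self.cv5 = ConvBN(rng, 4 * hidden, out_ch, 1, activation=activation)

    def forward(self, x):
        xt = self.cv1(x)
        branches = [self.cv2(xt),
                    nnops.maxpool2d(xt, 5, 1, 2),
                    nnops.maxpool2d(xt, 9, 1, 4),
                    nnops.maxpool2d(xt, 13, 1, 6)]
        return self.cv5(ad.concat(branches, axis=1))


class Silence(Module):
    def forward(self, x):
        return silence(x)


# -- CBLinear / CBFuse --------------------------------------------------------

class CBLinear(Module):
    """One 1x1 linear projection (bias, no norm/activation) split into the
    listed channel sizes — the auxiliary branch's backbone taps."""

    def __init__(self, rng, in_ch: int, out_channel_list):
        super().__init__()
        if not out_channel_list:
            raise ValueError("out_channel_list must be non-empty")
        self.out_list = list(out_channel_list)
        self.conv = ConvBN(rng, in_ch, sum(self.out_list), 1,
                           activation="identity", use_norm=False)

    def forward(self, x):
        y = self.conv(x)
        return ad.split(y, self.out_list, axis=1)


class CBFuse(Module):
    """Nearest-resize every input to the target size and sum elementwise."""

    def forward(self, inputs, target_size=None):
        inputs = [astensor(t) for t in inputs]
        chans = {t.shape[1] for t in inputs}
        if len(chans) != 1:
            raise ValueError(f"CBFuse channel mismatch: {sorted(chans)}")
        if target_size is None:
            target_size = inputs[-1].shape[2:]
        th, tw = target_size
        out = None
        for t in inputs:
            r = nnops.resize_nearest(t, th, tw)
            out = r if out is None else out + r
        return out


def cbfuse(inputs, target_size=None):
    return CBFuse().forward(inputs, target_size)
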