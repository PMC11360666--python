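"""Parameter/module containers and the shared conv-BN-activation unit.

Every module takes a ``numpy.random.Generator`` at construction so weight
initialization is fully seeded; there is no global RNG state anywhere in
the network.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from . import nnops
from .autodiff import Tensor


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data)
        self.requires_grad = True


class Module:
    def __init__(self):
        self.training = True
        self._buffers: dict[str, np.ndarray] = {}

    # -- registration ------------------------------------------------------
    def register_buffer(self, name: str, arr: np.ndarray):
        self._buffers[name] = arr
        setattr(self, name, arr)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Parameter):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, arr in self._buffers.items():
            yield prefix + name, arr
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- serialization -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, arr in self.named_buffers():
            state["buffer:" + name] = arr
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = dict(self.named_parameters())
        for name, p in params.items():
            if p.data.shape != state[name].shape:
                raise ValueError(f"shape mismatch for {name}")
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for name, arr in self.named_buffers():
            arr[...] = state["buffer:" + name]

    def n_params(self) -> int:
        return int(sum(p.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def kaiming(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))
        self.register_buffer("running_mean", np.zeros(channels, np.float32))
        self.register_buffer("running_var", np.ones(channels, np.float32))

    def forward(self, x):
        return nnops.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                                 self.running_var, self.training and ad.grad_enabled(),
                                 self.momentum, self.eps)


def _act(name: str):
    if name == "silu":
        return ad.silu
    if name == "identity":
        return lambda t: t
    raise ValueError(f"unknown activation {name!r}")


class ConvBN(Module):
    """Conv2d (no bias) + BatchNorm + activation; the workhorse unit.

    With use_norm=False the conv carries a bias instead (post-fusion form).
    """

    def __init__(self, rng, in_ch: int, out_ch: int, kernel: int = 1,
                 stride: int = 1, padding: int | None = None,
                 activation: str = "silu", use_norm: bool = True,
                 groups: int = 1):
        super().__init__()
        if padding is None:
            padding = (kernel - 1) // 2
        self.in_ch, self.out_ch = in_ch, out_ch
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.groups = groups
        self.act_name = activation
        cg = in_ch // groups
        self.weight = Parameter(kaiming(rng, (out_ch, cg, kernel, kernel),
                                        cg * kernel * kernel))
        self.use_norm = use_norm
        if use_norm:
            self.bn = BatchNorm2d(out_ch)
            self.bias = None
        else:
            self.bn = None
            self.bias = Parameter(np.zeros(out_ch, np.float32))

    def forward(self, x):
        y = nnops.conv2d(x, self.weight, self.bias, self.stride, self.padding,
                         self.groups)
        if self.bn is not None:
            y = self.bn(y)
        return _act(self.act_name)(y)

    def fuse(self) -> "ConvBN":
        """Fold the batch norm into the conv, returning a bias-carrying copy."""
        rng = np.random.default_rng(0)  # weights overwritten below
        fused = ConvBN(rng, self.in_ch, self.out_ch, self.kernel, self.stride,
                       self.padding, self.act_name, use_norm=False,
                       groups=self.groups)
        if self.bn is None:
            fused.weight.data = self.weight.data.copy()
            fused.bias.data = self.bias.data.copy()
            return fused
        w, b = fuse_conv_bn(self.weight.data, None, self.bn)
        fused.weight.data = w
        fused.bias.data = b
        return fused


def fuse_conv_bn(weight: np.ndarray, bias: np.ndarray | None, bn: BatchNorm2d):
    """w' = w * gamma/sqrt(var+eps); b' = beta - mean*gamma/sqrt(var+eps) (+ folded bias)."""
    scale = bn.gamma.data / np.sqrt(bn.running_var + bn.eps)
    w = weight * scale[:, None, None, None]
    b0 = bias if bias is not None else np.zeros(weight.shape[0], np.float32)
    b = bn.beta.data + (b0 - bn.running_mean) * scale
    return w.astype(np.float32), b.astype(np.float32)


class Linear(Module):
    def __init__(self, rng, in_f: int, out_f: int, bias: bool = True):
        super().__init__()
        self.weight = Parameter(kaiming(rng, (in_f, out_f), in_f))
        self.bias = Parameter(np.zeros(out_f, np.float32)) if bias else None

    def forward(self, x):
        y = ad.matmul(x, self.weight)
        if self.bias is not None:
            y = y + self.bias
        return y


class LayerNorm(Module):
    def __init__(self, channels: int, eps: float = 1e-6):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, np.float32))
        self.beta = Parameter(np.zeros(channels, np.float32))

    def forward(self, x):
        return nnops.layernorm(x, self.gamma, self.beta, self.eps)
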