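"""Whole-network assembly: the step graph (backbone 1-11, neck 12-26,
auxiliary branch 27-42, detection heads), forward execution, and
deployment-time reparameterization.

The graph is data: a list of :class:`LayerNode` (step id, kind, kind
arguments, input step ids). The default graph yields the 80x80x256 /
40x40x512 / 20x20x512 head inputs at 640 px —
backbone stages 64-128-256-512-512 with three ADown halvings and
BRA after the second and third backbone RepNCSPELAN4, a PAN-style neck
with C2f_VSS on both top-down fusions, and a CBLinear/CBFuse auxiliary
branch that mirrors the backbone and is dropped at inference.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from . import nnops
from .attention import BRA, BRAConfig
from .autodiff import Tensor, no_grad
from .blocks import (ADown, CBFuse, CBLinear, RepNCSPELAN4, RepVGGStage,
                     SPPELAN, Silence)
from .heads import DetectHead
from .modules import Module
from .vss import C2fVSS

KINDS = {"silence", "repvgg", "repncspelan4", "adown", "bra", "sppelan",
         "upsample", "concat", "c2f_vss", "cblinear", "cbfuse", "detect_head"}


@dataclass
class LayerNode:
    step: int
    kind: str
    args: dict = field(default_factory=dict)
    inputs: list = field(default_factory=list)  # ints or (step, slot) pairs


@dataclass
class TrainConfig:
    batch_size: int = 4
    epochs: int = 200
    learning_rate: float = 0.001
    optimizer: str = "adam"
    seed: int = 0
    aux_loss_weight: float = 0.25

    def __post_init__(self):
        if min(self.batch_size, self.epochs) < 1 or self.learning_rate <= 0:
            raise ValueError("train config values must be positive")


@dataclass
class ModelConfig:
    num_classes: int = 4
    input_size: int = 640
    width_multiple: float = 1.0
    reg_max: int = 16
    activation: str = "silu"
    bra_k: int = 4
    bra_heads: int = 1
    vss_n: int = 1
    ss2d_variant: str = "selective_scan"
    graph: list = None

    def __post_init__(self):
        if self.width_multiple <= 0:
            raise ValueError("width_multiple must be positive")
        if self.graph is None:
            self.graph = default_graph()
        self.graph = [n if isinstance(n, LayerNode) else LayerNode(**n)
                      for n in self.graph]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["graph"] = [asdict(n) for n in self.graph]
        return d


def default_graph() -> list[LayerNode]:
    """Backbone/neck/aux step graph with base (width_multiple = 1) widths."""
    N = LayerNode
    g = [
        N(0, "silence"),
        # backbone
        N(1, "repvgg", {"c": 64, "stride": 2}, [0]),
        N(2, "repvgg", {"c": 128, "stride": 2}, [1]),
        N(3, "repncspelan4", {"c": 256}, [2]),
        N(4, "adown", {"c": 256}, [3]),
        N(5, "repncspelan4", {"c": 512}, [4]),
        N(6, "bra", {"S": 8}, [5]),
        N(7, "adown", {"c": 512}, [6]),
        N(8, "repncspelan4", {"c": 512}, [7]),
        N(9, "bra", {"S": 4}, [8]),
        N(10, "adown", {"c": 512}, [9]),
        N(11, "repncspelan4", {"c": 512}, [10]),
        # neck
        N(12, "sppelan", {"c": 512}, [11]),
        N(13, "upsample", {}, [12]),
        N(14, "concat", {}, [13, 9]),
        N(15, "c2f_vss", {"c": 512}, [14]),
        N(16, "repncspelan4", {"c": 512}, [15]),
        N(17, "upsample", {}, [16]),
        N(18, "concat", {}, [17, 6]),
        N(19, "c2f_vss", {"c": 256}, [18]),
        N(20, "repncspelan4", {"c": 256}, [19]),        # P3 (80x80x256)
        N(21, "adown", {"c": 256}, [20]),
        N(22, "concat", {}, [21, 16]),
        N(23, "repncspelan4", {"c": 512}, [22]),        # P4 (40x40x512)
        N(24, "adown", {"c": 512}, [23]),
        N(25, "concat", {}, [24, 12]),
        N(26, "repncspelan4", {"c": 512}, [25]),        # P5 (20x20x512)
        # auxiliary branch
        N(27, "cblinear", {"cs": [256]}, [5]),
        N(28, "cblinear", {"cs": [256, 512]}, [8]),
        N(29, "cblinear", {"cs": [256, 512, 512]}, [11]),
        N(30, "repvgg", {"c": 64, "stride": 2}, [0]),
        N(31, "repvgg", {"c": 128, "stride": 2}, [30]),
        N(32, "repncspelan4", {"c": 256}, [31]),
        N(33, "adown", {"c": 256}, [32]),
        N(34, "cbfuse", {}, [(27, 0), (28, 0), (29, 0), 33]),
        N(35, "repncspelan4", {"c": 256}, [34]),        # A3
        N(36, "adown", {"c": 512}, [35]),
        N(37, "cbfuse", {}, [(28, 1), (29, 1), 36]),
        N(38, "repncspelan4", {"c": 512}, [37]),        # A4
        N(39, "adown", {"c": 512}, [38]),
        N(40, "cbfuse", {}, [(29, 2), 39]),
        N(41, "repncspelan4", {"c": 512}, [40]),        # A5
        N(42, "detect_head", {"role": "aux"}, [35, 38, 41]),
        N(43, "detect_head", {"role": "main"}, [20, 23, 26]),
    ]
    return g


class GraphError(ValueError):
    pass


def _scale_width(c: int, wm: float) -> int:
    if wm == 1.0:
        return c
    return max(8, int(round(c * wm / 8)) * 8)


def _src_step(ref) -> int:
    return ref[0] if isinstance(ref, (tuple, list)) else ref


class Model(Module):
    """Executable network built from a :class:`ModelConfig` step graph."""

    def __init__(self, cfg: ModelConfig, seed: int = 0,
                 _rng: np.random.Generator | None = None):
        super().__init__()
        self.cfg = cfg
        rng = _rng if _rng is not None else np.random.default_rng(seed)
        wm = cfg.width_multiple
        self.nodes: dict[int, LayerNode] = {}
        self.mods: dict[int, Module | None] = {}
        self.out_ch: dict[int, object] = {}
        self.out_stride: dict[int, int] = {}
        self.main_head_step = None
        self.aux_head_step = None
        act = cfg.activation

        for node in sorted(cfg.graph, key=lambda n: n.step):
            s = node.step
            if node.kind not in KINDS:
                raise GraphError(f"step {s}: unknown kind {node.kind!r}")
            if s in self.nodes:
                raise GraphError(f"duplicate step id {s}")
            for ref in node.inputs:
                src = _src_step(ref)
                if src not in self.nodes:
                    raise GraphError(
                        f"step {s}: input {src} does not reference an earlier step")
            self.nodes[s] = node

            def ch(ref):
                src = _src_step(ref)
                c = self.out_ch[src]
                if isinstance(ref, (tuple, list)):
                    return c[ref[1]]
                if isinstance(c, (tuple, list)):
                    raise GraphError(f"step {s}: input {src} needs a slot index")
                return c

            def st(ref):
                return self.out_stride[_src_step(ref)]

            kind, a = node.kind, node.args
            if kind == "silence":
                self.mods[s] = Silence()
                self.out_ch[s], self.out_stride[s] = 3, 1
            elif kind == "repvgg":
                c = _scale_width(a["c"], wm)
                self.mods[s] = RepVGGStage(rng, ch(node.inputs[0]), c,
                                           a.get("stride", 2), act)
                self.out_ch[s] = c
                self.out_stride[s] = st(node.inputs[0]) * a.get("stride", 2)
            elif kind == "repncspelan4":
                c = _scale_width(a["c"], wm)
                self.mods[s] = RepNCSPELAN4(rng, ch(node.inputs[0]), c,
                                            activation=act)
                self.out_ch[s], self.out_stride[s] = c, st(node.inputs[0])
            elif kind == "adown":
                c = _scale_width(a["c"], wm)
                self.mods[s] = ADown(rng, ch(node.inputs[0]), c, act)
                self.out_ch[s], self.out_stride[s] = c, st(node.inputs[0]) * 2
            elif kind == "bra":
                c = ch(node.inputs[0])
                bcfg = BRAConfig(S=a["S"], k=min(cfg.bra_k, a["S"] ** 2),
                                 num_heads=cfg.bra_heads)
                self.mods[s] = BRA(rng, c, bcfg)
                self.out_ch[s], self.out_stride[s] = c, st(node.inputs[0])
            elif kind == "sppelan":
                c = _scale_width(a["c"], wm)
                self.mods[s] = SPPELAN(rng, ch(node.inputs[0]), c,
                                       activation=act)
                self.out_ch[s], self.out_stride[s] = c, st(node.inputs[0])
            elif kind == "upsample":
                self.mods[s] = None
                self.out_ch[s] = ch(node.inputs[0])
                self.out_stride[s] = st(node.inputs[0]) // 2
            elif kind == "concat":
                if len(node.inputs) < 2:
                    raise GraphError(f"step {s}: concat needs >= 2 inputs")
                self.mods[s] = None
                self.out_ch[s] = sum(ch(r) for r in node.inputs)
                self.out_stride[s] = st(node.inputs[0])
            elif kind == "c2f_vss":
                c = _scale_width(a["c"], wm)
                self.mods[s] = C2fVSS(rng, ch(node.inputs[0]), c,
                                      n_blocks=cfg.vss_n, activation=act,
                                      ss2d_variant=cfg.ss2d_variant)
                self.out_ch[s], self.out_stride[s] = c, st(node.inputs[0])
            elif kind == "cblinear":
                cs = [_scale_width(c, wm) for c in a["cs"]]
                self.mods[s] = CBLinear(rng, ch(node.inputs[0]), cs)
                self.out_ch[s] = tuple(cs)
                self.out_stride[s] = st(node.inputs[0])
            elif kind == "cbfuse":
                if len(node.inputs) < 1:
                    raise GraphError(f"step {s}: cbfuse needs >= 1 input")
                cs = {ch(r) for r in node.inputs}
                if len(cs) != 1:
                    raise GraphError(f"step {s}: cbfuse channel mismatch {cs}")
                self.mods[s] = CBFuse()
                self.out_ch[s] = cs.pop()
                self.out_stride[s] = st(node.inputs[-1])
            elif kind == "detect_head":
                in_ch = [ch(r) for r in node.inputs]
                strides = tuple(st(r) for r in node.inputs)
                if a.get("role", "main") == "main":
                    if strides != (8, 16, 32) or len(node.inputs) != 3:
                        raise GraphError(
                            f"step {s}: main head needs 3 inputs at strides 8/16/32,"
                            f" got {strides}")
                    self.main_head_step = s
                else:
                    self.aux_head_step = s
                head = DetectHead(rng, in_ch, cfg.num_classes, cfg.reg_max)
                self.mods[s] = head
                self.out_ch[s], self.out_stride[s] = None, None
        if self.main_head_step is None:
            raise GraphError("graph has no main detect_head")
        self.head_in_ch = [self.out_ch[_src_step(r)]
                           for r in self.nodes[self.main_head_step].inputs]

    # registration of the per-step modules for parameters/buffers
    def _children(self):
        for s, m in self.mods.items():
            if m is not None:
                yield f"step{s}", m

    # -- execution ---------------------------------------------------------
    def forward(self, x, with_aux: bool | None = None, capture=()):
        """Run the graph. Returns a dict with keys:
        'features' (main-head input maps), 'main' (per-scale (cls, reg)),
        'aux' (same, or None), 'captured' ({step: map}).
        """
        x = x if isinstance(x, Tensor) else Tensor(x)
        b, c, h, w = x.shape
        if c != 3 or h % 32 or w % 32:
            raise ValueError(f"input must be (B, 3, H, W) with H, W divisible "
                             f"by 32, got {x.shape}")
        if self.training and (h != self.cfg.input_size or w != self.cfg.input_size):
            raise ValueError(f"training input must be {self.cfg.input_size}px, "
                             f"got {h}x{w}")
        if with_aux is None:
            with_aux = self.training
        with_aux = with_aux and self.aux_head_step is not None

        skip = set()
        if not with_aux:
            skip = self._aux_only_steps()
        # consumer counts for freeing intermediates
        need = {}
        for s, node in self.nodes.items():
            if s in skip:
                continue
            for ref in node.inputs:
                need[_src_step(ref)] = need.get(_src_step(ref), 0) + 1
        for s in capture:
            if s not in self.nodes:
                raise KeyError(f"capture step {s} not in graph")
            need[s] = need.get(s, 0) + 1

        cache: dict[int, object] = {}
        out = {"features": None, "main": None, "aux": None, "captured": {}}
        for s in sorted(self.nodes):
            if s in skip:
                continue
            node, mod = self.nodes[s], self.mods[s]

            def fetch(ref):
                src = _src_step(ref)
                val = cache[src]
                if isinstance(ref, (tuple, list)):
                    val = val[ref[1]]
                need[src] -= 1
                if need[src] == 0:
                    del cache[src]
                return val

            kind = node.kind
            if kind == "silence":
                y = mod(x)
            elif kind == "upsample":
                y = nnops.upsample_nearest(fetch(node.inputs[0]), 2)
            elif kind == "concat":
                y = ad.concat([fetch(r) for r in node.inputs], axis=1)
            elif kind == "cbfuse":
                y = mod([fetch(r) for r in node.inputs])
            elif kind == "detect_head":
                feats = [fetch(r) for r in node.inputs]
                preds = mod(feats)
                if node.args.get("role", "main") == "main":
                    out["features"] = feats
                    out["main"] = preds
                else:
                    out["aux"] = preds
                continue
            else:
                y = mod(fetch(node.inputs[0]))
            if s in capture:
                dat = y.data if isinstance(y, Tensor) else y
                out["captured"][s] = dat
                need[s] -= 1
            if need.get(s, 0) > 0:
                cache[s] = y
        return out

    def _aux_only_steps(self) -> set:
        """Steps reachable only from the auxiliary head."""
        keep = set()
        stack = [self.main_head_step]
        while stack:
            s = stack.pop()
            if s in keep:
                continue
            keep.add(s)
            stack.extend(_src_step(r) for r in self.nodes[s].inputs)
        return set(self.nodes) - keep

    def predict(self, x):
        """Inference forward: main head predictions only."""
        with no_grad():
            return self.forward(x, with_aux=False)

    # -- deployment ---------------------------------------------------------
    def reparameterize(self) -> "Model":
        """Merged single-branch copy: RepVGG branches folded into one 3x3
        conv each, auxiliary-only steps removed."""
        aux_only = self._aux_only_steps()
        new = Model.__new__(Model)
        Module.__init__(new)
        new.cfg = self.cfg
        new.nodes = {s: n for s, n in self.nodes.items() if s not in aux_only}
        new.mods = {}
        import copy
        for s in new.nodes:
            m = self.mods[s]
            if isinstance(m, RepVGGStage):
                new.mods[s] = m.reparameterize()
            else:
                new.mods[s] = copy.deepcopy(m)
        new.out_ch = {s: c for s, c in self.out_ch.items() if s not in aux_only}
        new.out_stride = {s: c for s, c in self.out_stride.items()
                          if s not in aux_only}
        new.main_head_step = self.main_head_step
        new.aux_head_step = None
        new.head_in_ch = self.head_in_ch
        new.eval()
        return new
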