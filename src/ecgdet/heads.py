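"""Anchor-free decoupled detection heads, box decoding and NMS.

Each scale gets separate classification and regression branches; box edges
are regressed as discrete distributions over ``reg_max`` bins (distribution
focal representation) whose softmax expectation gives the left/top/right/
bottom distances from the cell center, in units of the scale's stride.
Boxes are pixel, 0-based, half-open (x1, y1, x2, y2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from . import nnops
from .autodiff import Tensor
from .modules import ConvBN, Module


@dataclass
class Detection:
    class_id: int
    confidence: float
    box: tuple[float, float, float, float]  # x1, y1, x2, y2 pixels


class DetectHead(Module):
    """Decoupled cls/reg head over three feature maps (strides 8/16/32)."""

    def __init__(self, rng, in_channels, num_classes: int, reg_max: int = 16):
        super().__init__()
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.strides = (8, 16, 32)
        self.cls_branches = []
        self.reg_branches = []
        for c in in_channels:
            c2 = max(16, c // 4, reg_max * 4)
            c3 = max(16, c // 2)
            self.reg_branches.append([
                ConvBN(rng, c, c2, 3),
                ConvBN(rng, c2, c2, 3),
                ConvBN(rng, c2, 4 * reg_max, 1, activation="identity",
                       use_norm=False)])
            self.cls_branches.append([
                ConvBN(rng, c, c3, 3),
                ConvBN(rng, c3, c3, 3),
                ConvBN(rng, c3, num_classes, 1, activation="identity",
                       use_norm=False)])
        for branch in self.cls_branches:
            # rare-positive prior: start with low class confidence everywhere
            branch[-1].bias.data[:] = -np.log((1 - 0.01) / 0.01)

    def _children(self):
        yield from super()._children()
        for i, branch in enumerate(self.cls_branches):
            for j, m in enumerate(branch):
                yield f"cls_branches.{i}.{j}", m
        for i, branch in enumerate(self.reg_branches):
            for j, m in enumerate(branch):
                yield f"reg_branches.{i}.{j}", m

    def forward(self, feats):
        outs = []
        for x, cb, rb in zip(feats, self.cls_branches, self.reg_branches):
            c = x
            for m in cb:
                c = m(c)
            r = x
            for m in rb:
                r = m(r)
            outs.append((c, r))
        return outs


def make_anchors(input_size: int, strides=(8, 16, 32)):
    """Cell-center anchor points (pixels) and per-anchor stride, all scales
    concatenated in scale order."""
    pts, sts = [], []
    for s in strides:
        g = input_size // s
        xs = (np.arange(g) + 0.5) * s
        xx, yy = np.meshgrid(xs, xs)
        pts.append(np.stack([xx.ravel(), yy.ravel()], axis=1))
        sts.append(np.full(g * g, s, np.float32))
    return np.concatenate(pts).astype(np.float32), np.concatenate(sts)


def dfl_expectation(reg, reg_max: int):
    """(..., 4, reg_max) logits -> (..., 4) expected distances (cell units)."""
    p = ad.softmax(reg, axis=-1)
    bins = Tensor(np.arange(reg_max, dtype=np.float32).reshape(reg_max, 1))
    return ad.reshape(ad.matmul(p, bins), p.shape[:-1])


def decode_boxes(dist, anchors: np.ndarray, strides: np.ndarray):
    """ltrb distances (A, 4) in cell units -> xyxy pixel boxes.

    `dist` may be a Tensor (gradient flows through for the box loss) or a
    plain array."""
    scale = strides.reshape(-1, 1).astype(np.float32)
    if isinstance(dist, Tensor):
        d = dist * Tensor(scale)
        lt, rb = ad.split(d, [2, 2], axis=1)
        x1y1 = Tensor(anchors) - lt
        x2y2 = Tensor(anchors) + rb
        return ad.concat([x1y1, x2y2], axis=1)
    d = dist * scale
    return np.concatenate([anchors - d[:, :2], anchors + d[:, 2:]], axis=1)


def box_iou(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between (N,4) and (M,4) xyxy boxes."""
    a, b = np.asarray(a, np.float64), np.asarray(b, np.float64)
    ix1 = np.maximum(a[:, None, 0], b[None, :, 0])
    iy1 = np.maximum(a[:, None, 1], b[None, :, 1])
    ix2 = np.minimum(a[:, None, 2], b[None, :, 2])
    iy2 = np.minimum(a[:, None, 3], b[None, :, 3])
    inter = np.clip(ix2 - ix1, 0, None) * np.clip(iy2 - iy1, 0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    return np.where(union > 0, inter / union, 0.0)


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thr: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, by descending
    score (stable under score ties)."""
    order = np.argsort(-scores, kind="stable")
    keep = []
    suppressed = np.zeros(len(boxes), bool)
    for i in order:
        if suppressed[i]:
            continue
        keep.append(i)
        ious = box_iou(boxes[i:i + 1], boxes[order]).ravel()
        suppressed[order[ious > iou_thr]] = True
        suppressed[i] = True
    return np.array(keep, dtype=np.int64)


def decode_predictions(preds, input_size: int, conf_thr: float = 0.25,
                       iou_thr: float = 0.45, reg_max: int = 16,
                       max_det: int = 300) -> list[list[Detection]]:
    """Head outputs -> per-image detection lists (class-wise NMS, sorted by
    descending confidence)."""
    if not (0 < conf_thr < 1 and 0 < iou_thr < 1):
        raise ValueError("thresholds must lie in (0, 1)")
    batch = preds[0][0].shape[0]
    all_scores, all_cls, all_boxes = [], [], []
    for (cls_t, reg_t), stride in zip(preds, (8, 16, 32)):
        cls = cls_t.data if isinstance(cls_t, Tensor) else cls_t
        reg = reg_t.data if isinstance(reg_t, Tensor) else reg_t
        b, nc, h, w = cls.shape
        scores = 1.0 / (1.0 + np.exp(-cls.reshape(b, nc, h * w).transpose(0, 2, 1)))
        regs = reg.reshape(b, 4, reg_max, h * w).transpose(0, 3, 1, 2)
        e = np.exp(regs - regs.max(axis=-1, keepdims=True))
        p = e / e.sum(axis=-1, keepdims=True)
        dist = (p * np.arange(reg_max)).sum(axis=-1) * stride
        xs = (np.arange(w) + 0.5) * stride
        ys = (np.arange(h) + 0.5) * stride
        xx, yy = np.meshgrid(xs, ys)
        anchors = np.stack([xx.ravel(), yy.ravel()], axis=1)
        boxes = np.concatenate([anchors - dist[:, :, :2],
                                anchors + dist[:, :, 2:]], axis=2)
        all_scores.append(scores)
        all_boxes.append(boxes)
    results = []
    for i in range(batch):
        scores = np.concatenate([s[i] for s in all_scores])   # (A, nc)
        boxes = np.concatenate([b[i] for b in all_boxes])     # (A, 4)
        cls_id = scores.argmax(axis=1)
        conf = scores[np.arange(len(scores)), cls_id]
        m = conf >= conf_thr
        boxes, cls_id, conf = boxes[m], cls_id[m], conf[m]
        dets: list[Detection] = []
        for c in np.unique(cls_id):
            cm = cls_id == c
            keep = nms(boxes[cm], conf[cm], iou_thr)
            for j in keep:
                bx = boxes[cm][j]
                if bx[2] <= bx[0] or bx[3] <= bx[1]:
                    continue
                dets.append(Detection(int(c), float(conf[cm][j]),
                                      (float(bx[0]), float(bx[1]),
                                       float(bx[2]), float(bx[3]))))
        dets.sort(key=lambda d: -d.confidence)
        results.append(dets[:max_det])
    return results
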