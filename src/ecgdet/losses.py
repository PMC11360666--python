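"""Detection loss: binary cross-entropy classification, complete-IoU box
regression and distribution-focal edge regression, with center-based
positive assignment.

An anchor (cell center) is positive for a ground-truth box when it lies
inside the box and within ``center_radius`` strides of the box center; an
anchor claimed by several boxes goes to the smallest one. Auxiliary-head
predictions are supervised with the same loss scaled by ``aux_weight``.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .heads import decode_boxes, dfl_expectation, make_anchors

BOX_W, CLS_W, DFL_W = 7.5, 0.5, 1.5
CENTER_RADIUS = 2.5


def validate_targets(targets):
    """targets: list per image of (classes (M,), boxes_xyxy px (M, 4))."""
    for classes, boxes in targets:
        boxes = np.asarray(boxes, np.float32).reshape(-1, 4)
        if len(boxes) and (np.any(boxes[:, 2] - boxes[:, 0] <= 0)
                           or np.any(boxes[:, 3] - boxes[:, 1] <= 0)):
            raise ValueError("degenerate target box (zero width or height)")


def assign_anchors(anchors: np.ndarray, strides: np.ndarray,
                   boxes: np.ndarray, radius: float = CENTER_RADIUS):
    """Returns (fg_idx, gt_idx): indices of positive anchors and the box each
    one regresses to."""
    if len(boxes) == 0:
        return np.empty(0, np.int64), np.empty(0, np.int64)
    ax, ay = anchors[:, 0:1], anchors[:, 1:2]
    inside = ((ax > boxes[None, :, 0]) & (ax < boxes[None, :, 2]) &
              (ay > boxes[None, :, 1]) & (ay < boxes[None, :, 3]))
    cx = (boxes[:, 0] + boxes[:, 2]) / 2
    cy = (boxes[:, 1] + boxes[:, 3]) / 2
    near = ((np.abs(ax - cx[None]) < radius * strides[:, None]) &
            (np.abs(ay - cy[None]) < radius * strides[:, None]))
    pos = inside & near                                  # (A, M)
    areas = (boxes[:, 2] - boxes[:, 0]) * (boxes[:, 3] - boxes[:, 1])
    cost = np.where(pos, areas[None, :], np.inf)
    gt_idx = cost.argmin(axis=1)
    fg = pos.any(axis=1)
    return np.nonzero(fg)[0], gt_idx[fg]


def ciou_loss(pred: Tensor, gt: np.ndarray) -> Tensor:
    """1 - CIoU per row for (N, 4) xyxy boxes (pred a Tensor)."""
    gt = np.asarray(gt, np.float32)
    px1, py1, px2, py2 = (pred[:, i] for i in range(4))
    gx1, gy1, gx2, gy2 = (gt[:, i] for i in range(4))
    ix1 = ad.maximum(px1, gx1)
    iy1 = ad.maximum(py1, gy1)
    ix2 = -ad.maximum(-px2, -gx2)
    iy2 = -ad.maximum(-py2, -gy2)
    inter = ad.maximum(ix2 - ix1, 0.0) * ad.maximum(iy2 - iy1, 0.0)
    pw, ph = px2 - px1, py2 - py1
    gw, gh = gx2 - gx1, gy2 - gy1
    union = pw * ph + gw * gh - inter + 1e-7
    iou = inter / union
    # enclosing box diagonal and center distance
    ex1 = -ad.maximum(-px1, -gx1)
    ey1 = -ad.maximum(-py1, -gy1)
    ex2 = ad.maximum(px2, gx2)
    ey2 = ad.maximum(py2, gy2)
    c2 = (ex2 - ex1) ** 2 + (ey2 - ey1) ** 2 + 1e-7
    rho2 = ((px1 + px2 - gx1 - gx2) ** 2 + (py1 + py2 - gy1 - gy2) ** 2) * 0.25
    v = (4.0 / np.pi ** 2) * (ad.atan(gw / gh) - ad.atan(pw / (ph + 1e-7))) ** 2
    alpha = v.data / (1.0 - iou.data + v.data + 1e-7)    # detached, per CIoU
    return 1.0 - iou + rho2 / c2 + Tensor(alpha) * v


def dfl_loss(reg_logits: Tensor, target_dist: np.ndarray, reg_max: int) -> Tensor:
    """Distribution focal cross-entropy on (N, 4, reg_max) logits with
    continuous targets in cell units, split over the two adjacent bins."""
    t = np.clip(target_dist, 0, reg_max - 1 - 1e-3)
    tl = np.floor(t).astype(np.int64)
    tr = tl + 1
    wl = (tr - t).astype(np.float32)
    wr = (t - tl).astype(np.float32)
    p = ad.softmax(reg_logits, axis=-1)
    n, f = t.shape[0], 4
    ii = np.arange(n)[:, None].repeat(f, 1)
    jj = np.arange(f)[None, :].repeat(n, 0)
    pl = p[ii, jj, tl]
    pr = p[ii, jj, np.minimum(tr, reg_max - 1)]
    return -(Tensor(wl) * ad.log(pl + 1e-9) + Tensor(wr) * ad.log(pr + 1e-9))


def _flatten_preds(preds, num_classes: int, reg_max: int):
    """Head outputs -> (cls (B, A, nc), reg (B, A, 4, reg_max)) Tensors."""
    cls_all, reg_all = [], []
    for cls_t, reg_t in preds:
        b, nc, h, w = cls_t.shape
        cls_all.append(ad.transpose(ad.reshape(cls_t, (b, nc, h * w)), (0, 2, 1)))
        reg_all.append(ad.transpose(
            ad.reshape(reg_t, (b, 4, reg_max, h * w)), (0, 3, 1, 2)))
    return ad.concat(cls_all, axis=1), ad.concat(reg_all, axis=1)


def detection_loss(preds, targets, input_size: int, num_classes: int,
                   reg_max: int = 16, strides=(8, 16, 32)):
    """Loss for one head set. Returns (total Tensor, components dict)."""
    validate_targets(targets)
    anchors, astr = make_anchors(input_size, strides)
    cls_p, reg_p = _flatten_preds(preds, num_classes, reg_max)
    b, a = cls_p.shape[0], cls_p.shape[1]
    cls_target = np.zeros((b, a, num_classes), np.float32)

    fg_b, fg_a, fg_gt_boxes, fg_dist = [], [], [], []
    for i, (classes, boxes) in enumerate(targets):
        boxes = np.asarray(boxes, np.float32).reshape(-1, 4)
        classes = np.asarray(classes, np.int64).reshape(-1)
        fg_idx, gt_idx = assign_anchors(anchors, astr, boxes)
        if len(fg_idx) == 0:
            continue
        cls_target[i, fg_idx, classes[gt_idx]] = 1.0
        gtb = boxes[gt_idx]
        d = np.stack([anchors[fg_idx, 0] - gtb[:, 0],
                      anchors[fg_idx, 1] - gtb[:, 1],
                      gtb[:, 2] - anchors[fg_idx, 0],
                      gtb[:, 3] - anchors[fg_idx, 1]], axis=1)
        fg_b.append(np.full(len(fg_idx), i))
        fg_a.append(fg_idx)
        fg_gt_boxes.append(gtb)
        fg_dist.append(d / astr[fg_idx, None])
    n_pos = int(sum(len(x) for x in fg_a))

    cls_loss = ad.bce_with_logits(cls_p, cls_target).sum() * (1.0 / max(n_pos, 1))
    if n_pos == 0:
        zero = Tensor(np.float32(0.0))
        total = CLS_W * cls_loss
        return total, {"cls": float(cls_loss.item()), "box": 0.0, "dfl": 0.0,
                       "n_pos": 0}
    fb = np.concatenate(fg_b)
    fa = np.concatenate(fg_a)
    gtb = np.concatenate(fg_gt_boxes)
    tdist = np.concatenate(fg_dist)

    reg_pos = reg_p[fb, fa]                       # (N, 4, reg_max)
    dist = dfl_expectation(reg_pos, reg_max)      # (N, 4) cell units
    pboxes = decode_boxes(dist, anchors[fa], astr[fa])
    box_l = ciou_loss(pboxes, gtb).sum() * (1.0 / n_pos)
    dfl_l = dfl_loss(reg_pos, tdist, reg_max).sum() * (1.0 / n_pos)
    total = CLS_W * cls_loss + BOX_W * box_l + DFL_W * dfl_l
    return total, {"cls": float(cls_loss.item()), "box": float(box_l.item()),
                   "dfl": float(dfl_l.item()), "n_pos": n_pos}


def compute_loss(main_preds, aux_preds, targets, input_size: int,
                 num_classes: int, aux_weight: float = 0.25, reg_max: int = 16):
    """Main + weighted auxiliary detection loss."""
    total, comps = detection_loss(main_preds, targets, input_size,
                                  num_classes, reg_max)
    if aux_preds is not None and aux_weight > 0:
        aux_total, aux_comps = detection_loss(aux_preds, targets, input_size,
                                              num_classes, reg_max)
        total = total + aux_weight * aux_total
        comps = {**comps, **{f"aux_{k}": v for k, v in aux_comps.items()}}
    comps["total"] = float(total.item())
    return total, comps
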