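"""Loss components, target assignment, decoding and NMS."""

import numpy as np
import pytest

from ecgdet import autodiff as ad
from ecgdet.autodiff import Tensor
from ecgdet.heads import (Detection, box_iou, decode_predictions, make_anchors,
                          nms)
from ecgdet.losses import (assign_anchors, ciou_loss, compute_loss,
                           detection_loss, validate_targets)


def _fake_preds(rng, b=1, nc=4, reg_max=16, size=64):
    preds = []
    for s in (8, 16, 32):
        g = size // s
        cls = Tensor(rng.standard_normal((b, nc, g, g)).astype(np.float32))
        reg = Tensor(rng.standard_normal((b, 4 * reg_max, g, g)).astype(np.float32))
        preds.append((cls, reg))
    return preds


class TestNMS:
    def test_identical_boxes_one_survivor(self):
        boxes = np.array([[0, 0, 10, 10], [0, 0, 10, 10]], float)
        keep = nms(boxes, np.array([0.9, 0.8]), 0.45)
        assert keep.tolist() == [0]

    def test_matches_brute_force_oracle(self, rng):
        boxes = rng.uniform(0, 80, (20, 2))
        boxes = np.concatenate([boxes, boxes + rng.uniform(5, 30, (20, 2))],
                               axis=1)
        scores = rng.random(20)
        keep = set(nms(boxes, scores, 0.5).tolist())
        # O(n^2) reference: repeatedly take the best, drop overlaps
        alive = set(range(20))
        ref = set()
        while alive:
            best = max(alive, key=lambda i: scores[i])
            ref.add(best)
            alive.discard(best)
            for j in list(alive):
                if box_iou(boxes[best:best + 1], boxes[j:j + 1])[0, 0] > 0.5:
                    alive.discard(j)
        assert keep == ref


class TestDecode:
    def test_all_below_threshold_empty(self, rng):
        preds = _fake_preds(rng)
        for cls, _ in preds:
            cls.data[:] = -20.0
        dets = decode_predictions(preds, 64, conf_thr=0.25)
        assert dets == [[]]

    def test_thresholds_validated(self, rng):
        with pytest.raises(ValueError):
            decode_predictions(_fake_preds(rng), 64, conf_thr=0.0)

    def test_sorted_by_confidence(self, rng):
        dets = decode_predictions(_fake_preds(rng), 64, conf_thr=0.01)[0]
        confs = [d.confidence for d in dets]
        assert confs == sorted(confs, reverse=True)
        for d in dets:
            x1, y1, x2, y2 = d.box
            assert x2 > x1 and y2 > y1 and 0 <= d.confidence <= 1


class TestAssignment:
    def test_anchor_inside_and_near_center(self):
        anchors, strides = make_anchors(64)
        box = np.array([[8.0, 8.0, 40.0, 40.0]])
        fg, gt = assign_anchors(anchors, strides, box)
        assert len(fg) > 0
        assert np.all(gt == 0)
        ax, ay = anchors[fg, 0], anchors[fg, 1]
        assert np.all((ax > 8) & (ax < 40) & (ay > 8) & (ay < 40))

    def test_smaller_box_wins_overlap(self):
        anchors, strides = make_anchors(64)
        boxes = np.array([[0.0, 0.0, 64.0, 64.0], [24.0, 24.0, 40.0, 40.0]])
        fg, gt = assign_anchors(anchors, strides, boxes)
        center = (anchors[fg, 0] > 24) & (anchors[fg, 0] < 40) & \
                 (anchors[fg, 1] > 24) & (anchors[fg, 1] < 40)
        assert np.all(gt[center] == 1)


class TestCIoU:
    def test_zero_at_perfect_overlap(self, rng):
        gt = np.array([[4.0, 6.0, 30.0, 22.0], [0.0, 0.0, 10.0, 10.0]])
        pred = Tensor(gt.astype(np.float32))
        loss = ciou_loss(pred, gt)
        assert np.allclose(loss.data, 0, atol=1e-5)

    def test_positive_and_decreasing_with_overlap(self, rng):
        gt = np.array([[0.0, 0.0, 10.0, 10.0]])
        near = ciou_loss(Tensor(np.array([[1., 1., 11., 11.]], np.float32)), gt)
        far = ciou_loss(Tensor(np.array([[20., 20., 30., 30.]], np.float32)), gt)
        assert 0 < near.data[0] < far.data[0]


class TestLoss:
    def test_empty_targets_only_cls(self, rng):
        preds = _fake_preds(rng)
        targets = [(np.empty(0, np.int64), np.empty((0, 4), np.float32))]
        total, comps = detection_loss(preds, targets, 64, 4)
        assert comps["box"] == 0.0 and comps["dfl"] == 0.0
        assert comps["cls"] > 0
        assert total.item() >= 0

    def test_degenerate_box_rejected(self, rng):
        preds = _fake_preds(rng)
        targets = [(np.array([0]), np.array([[5.0, 5.0, 5.0, 20.0]]))]
        with pytest.raises(ValueError, match="degenerate"):
            detection_loss(preds, targets, 64, 4)

    def test_finite_on_random_batches(self, rng):
        for _ in range(100):
            preds = _fake_preds(rng)
            n = int(rng.integers(0, 4))
            xy = rng.uniform(0, 40, (n, 2))
            wh = rng.uniform(4, 24, (n, 2))
            boxes = np.concatenate([xy, xy + wh], axis=1).clip(0, 64)
            boxes[:, 2:] = np.maximum(boxes[:, 2:], boxes[:, :2] + 1)
            targets = [(rng.integers(0, 4, n), boxes)]
            total, comps = detection_loss(preds, targets, 64, 4)
            assert np.isfinite(total.item()) and total.item() >= 0

    def test_perfect_single_target_box_loss_zero(self, rng):
        """One-hot regression logits that decode exactly to the target box
        give zero box loss (IoU = 1)."""
        nc, reg_max, size = 4, 16, 64
        preds = _fake_preds(rng, nc=nc, reg_max=reg_max, size=size)
        anchors, strides = make_anchors(size)
        # target centered so integer cell distances exist at stride 8
        box = np.array([[4.0, 4.0, 36.0, 36.0]])
        targets = [(np.array([2]), box)]
        fg, _ = assign_anchors(anchors, strides, box)
        # write sharp two-bin logits whose expectation decodes to the exact
        # (possibly fractional) cell distances at every positive anchor
        for (cls, reg), s in zip(preds, (8, 16, 32)):
            g = size // s
            reg.data[:] = -30.0
            cls.data[:] = -30.0
            for a in fg:
                if strides[a] != s:
                    continue
                local = a - {8: 0, 16: (size // 8) ** 2,
                             32: (size // 8) ** 2 + (size // 16) ** 2}[s]
                iy, ix = divmod(int(local), g)
                d = np.array([anchors[a, 0] - box[0, 0], anchors[a, 1] - box[0, 1],
                              box[0, 2] - anchors[a, 0], box[0, 3] - anchors[a, 1]])
                dcells = d / s
                for e in range(4):
                    tl = int(np.floor(dcells[e]))
                    frac = dcells[e] - tl
                    reg.data[0, e * reg_max + tl, iy, ix] = \
                        30.0 + np.log(max(1 - frac, 1e-9))
                    if frac > 0:
                        reg.data[0, e * reg_max + tl + 1, iy, ix] = \
                            30.0 + np.log(frac)
                cls.data[0, 2, iy, ix] = 30.0
        total, comps = detection_loss(preds, targets, size, nc)
        assert comps["box"] < 1e-3

    def test_compute_loss_adds_weighted_aux(self, rng):
        main = _fake_preds(rng)
        aux = _fake_preds(rng)
        targets = [(np.array([1]), np.array([[8.0, 8.0, 40.0, 40.0]]))]
        t_main, _ = detection_loss(main, targets, 64, 4)
        total, comps = compute_loss(main, aux, targets, 64, 4, aux_weight=0.25)
        t_aux, _ = detection_loss(aux, targets, 64, 4)
        assert np.isclose(total.item(),
                          t_main.item() + 0.25 * t_aux.item(), rtol=1e-5)
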