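"""Detection evaluation: greedy matching, 101-point interpolated AP,
mAP@0.5 / mAP@0.5:0.95, PR curves, rank-statistic ROC/AUC, parameter and
FLOP counting, and feature heatmaps.

FLOPs follow the 2 x MAC convention (multiply and add counted separately)
over conv/linear/attention/scan operators; elementwise and normalization
work is excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

from .autodiff import no_grad
from .flops import flop_counter
from .heads import Detection, box_iou

IOU_GRID = np.arange(0.50, 0.96, 0.05)
RECALL_GRID = np.linspace(0, 1, 101)


def match_detections(dets, gt_classes, gt_boxes, iou_thr: float) -> np.ndarray:
    """Greedy TP/FP flags for one image.

    dets must be sorted by descending confidence; each detection matches the
    highest-IoU not-yet-matched ground truth of its class with IoU >= thr.
    """
    gt_boxes = np.asarray(gt_boxes, np.float64).reshape(-1, 4)
    gt_classes = np.asarray(gt_classes, np.int64).reshape(-1)
    flags = np.zeros(len(dets), bool)
    used = np.zeros(len(gt_boxes), bool)
    if len(dets) == 0:
        return flags
    confs = [d.confidence for d in dets]
    if any(confs[i] < confs[i + 1] for i in range(len(confs) - 1)):
        raise ValueError("detections must be sorted by descending confidence")
    boxes = np.array([d.box for d in dets], np.float64)
    ious = box_iou(boxes, gt_boxes) if len(gt_boxes) else np.zeros((len(dets), 0))
    for i, d in enumerate(dets):
        cand = np.nonzero((gt_classes == d.class_id) & ~used)[0]
        if len(cand) == 0:
            continue
        j = cand[np.argmax(ious[i, cand])]
        if ious[i, j] >= iou_thr:
            flags[i] = True
            used[j] = True
    return flags


def average_precision(flags, confidences, n_gt: int):
    """101-point interpolated AP. Returns None (undefined) when there are no
    ground truths and no detections; 0 when detections exist without GT."""
    flags = np.asarray(flags, bool)
    confidences = np.asarray(confidences, float)
    if n_gt == 0:
        return None if len(flags) == 0 else 0.0
    order = np.argsort(-confidences, kind="stable")
    flags = flags[order]
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope: max precision at recall >= r
    ap = 0.0
    for r in RECALL_GRID:
        m = recall >= r - 1e-12
        ap += precision[m].max() if m.any() else 0.0
    return ap / len(RECALL_GRID)


def _pr_curve(flags, confidences, n_gt: int):
    order = np.argsort(-np.asarray(confidences, float), kind="stable")
    f = np.asarray(flags, bool)[order]
    tp = np.cumsum(f)
    fp = np.cumsum(~f)
    recall = tp / max(n_gt, 1)
    precision = tp / np.maximum(tp + fp, 1)
    return recall, precision, np.asarray(confidences, float)[order]


@dataclass
class MetricsReport:
    per_class_precision: dict
    per_class_recall: dict
    per_class_ap50: dict
    per_class_ap50_95: dict
    precision: float
    recall: float
    ap50: float
    ap50_95: float
    pr_curves: dict = field(default_factory=dict)
    auc: dict = field(default_factory=dict)
    macro_auc: float | None = None

    def to_dict(self) -> dict:
        return {"precision": self.precision, "recall": self.recall,
                "mAP@0.5": self.ap50, "mAP@0.5:0.95": self.ap50_95,
                "per_class": {c: {"precision": self.per_class_precision[c],
                                  "recall": self.per_class_recall[c],
                                  "ap50": self.per_class_ap50[c],
                                  "ap50_95": self.per_class_ap50_95[c]}
                              for c in self.per_class_ap50},
                "auc": self.auc, "macro_auc": self.macro_auc}


def map_metrics(all_dets, all_gts, num_classes: int) -> MetricsReport:
    """all_dets: per-image lists of Detection; all_gts: per-image
    (classes, boxes_xyxy). Precision/recall are reported at the confidence
    maximizing F1 on the IoU-0.5 PR curve; aggregates are unweighted class
    means over classes with defined AP."""
    pc_p, pc_r, pc_ap50, pc_ap = {}, {}, {}, {}
    pr_curves = {}
    for c in range(num_classes):
        n_gt = sum(int((np.asarray(g[0]) == c).sum()) for g in all_gts)
        aps = []
        flags50, confs = None, None
        for thr in IOU_GRID:
            flags_all, conf_all = [], []
            for dets, (gcls, gbox) in zip(all_dets, all_gts):
                cdets = [d for d in dets if d.class_id == c]
                gsel = np.asarray(gcls) == c
                f = match_detections(cdets, np.asarray(gcls)[gsel],
                                     np.asarray(gbox).reshape(-1, 4)[gsel],
                                     float(thr))
                flags_all.extend(f.tolist())
                conf_all.extend(d.confidence for d in cdets)
            ap = average_precision(flags_all, conf_all, n_gt)
            aps.append(ap)
            if abs(thr - 0.5) < 1e-9:
                flags50, confs = np.asarray(flags_all, bool), np.asarray(conf_all)
        if all(a is None for a in aps):
            continue
        pc_ap50[c] = aps[0] if aps[0] is not None else 0.0
        pc_ap[c] = float(np.mean([a if a is not None else 0.0 for a in aps]))
        if len(flags50):
            recall, precision, sconf = _pr_curve(flags50, confs, n_gt)
            f1 = 2 * precision * recall / np.maximum(precision + recall, 1e-12)
            i = int(np.argmax(f1))
            pc_p[c], pc_r[c] = float(precision[i]), float(recall[i])
            pr_curves[c] = (recall, precision)
        else:
            pc_p[c], pc_r[c] = 0.0, 0.0
            pr_curves[c] = (np.zeros(0), np.zeros(0))
    classes = sorted(pc_ap50)
    agg = lambda d: float(np.mean([d[c] for c in classes])) if classes else 0.0
    return MetricsReport(pc_p, pc_r, pc_ap50, pc_ap,
                         agg(pc_p), agg(pc_r), agg(pc_ap50), agg(pc_ap),
                         pr_curves)


def roc_auc(scores, binary_labels) -> float:
    """AUC via the rank (Mann-Whitney) statistic; ties count one half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(binary_labels, bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: need both classes present")
    ranks = rankdata(scores)  # average ranks on ties
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def image_class_scores(dets_per_image, num_classes: int) -> np.ndarray:
    """Image-level score per class = max detection confidence of that class
    (0 when the class is absent) — the one-vs-rest ROC construction."""
    out = np.zeros((len(dets_per_image), num_classes))
    for i, dets in enumerate(dets_per_image):
        for d in dets:
            out[i, d.class_id] = max(out[i, d.class_id], d.confidence)
    return out


def detector_auc(dets_per_image, image_classes, num_classes: int):
    """Per-class one-vs-rest AUC + macro mean over defined classes."""
    scores = image_class_scores(dets_per_image, num_classes)
    image_classes = np.asarray(image_classes)
    aucs = {}
    for c in range(num_classes):
        y = image_classes == c
        if y.all() or not y.any():
            continue
        aucs[c] = roc_auc(scores[:, c], y)
    macro = float(np.mean(list(aucs.values()))) if aucs else None
    return aucs, macro


# -- model statistics ---------------------------------------------------------

@dataclass
class ModelStats:
    n_params: int
    gflops: float
    input_size: int
    with_aux: bool


def count_params(model, with_aux: bool = True) -> int:
    if with_aux:
        return model.n_params()
    aux_only = model._aux_only_steps()
    total = 0
    for s, m in model.mods.items():
        if m is not None and s not in aux_only:
            total += m.n_params()
    return total


def count_flops(model, input_size: int | None = None,
                with_aux: bool = False) -> ModelStats:
    """FLOPs (2 x MACs) of one batch-1 forward at the given input size."""
    size = input_size or model.cfg.input_size
    x = np.zeros((1, 3, size, size), np.float32)
    was_training = model.training
    model.eval()
    with no_grad(), flop_counter() as fc:
        model.forward(x, with_aux=with_aux)
    model.train(was_training)
    return ModelStats(count_params(model, with_aux), fc[0] / 1e9, size, with_aux)


def save_report(report: MetricsReport, out_dir, class_names=None):
    """Emit a report as JSON + CSV, with PR (and ROC-ready AUC) artifacts;
    PR curves are rendered to PNG when curves are present."""
    import csv
    import json
    from pathlib import Path
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics.json").write_text(json.dumps(report.to_dict(), indent=2))
    with open(out / "metrics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class", "precision", "recall", "ap50", "ap50_95"])
        for c in sorted(report.per_class_ap50):
            name = class_names[c] if class_names else c
            w.writerow([name, report.per_class_precision[c],
                        report.per_class_recall[c], report.per_class_ap50[c],
                        report.per_class_ap50_95[c]])
        w.writerow(["all", report.precision, report.recall, report.ap50,
                    report.ap50_95])
    if report.pr_curves:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(5, 4))
        for c, (rec, prec) in sorted(report.pr_curves.items()):
            name = class_names[c] if class_names else f"class {c}"
            ax.plot(rec, prec, label=str(name))
        ax.set_xlabel("recall")
        ax.set_ylabel("precision")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1.05)
        ax.legend(fontsize=7)
        fig.tight_layout()
        fig.savefig(out / "pr_curves.png", dpi=120)
        plt.close(fig)


def feature_heatmap(model, image: np.ndarray, step_id: int) -> np.ndarray:
    """Channel-mean absolute activation at a step, min-max normalized,
    nearest-resized to the input resolution and colormapped over the image.
    Returns (H, W, 3) float in [0, 1]."""
    if step_id not in model.nodes:
        raise KeyError(f"step {step_id} not in graph")
    x = image[None] if image.ndim == 3 else image
    with no_grad():
        out = model.forward(x.astype(np.float32), with_aux=True,
                            capture=(step_id,))
    fmap = out["captured"][step_id]
    if isinstance(fmap, (list, tuple)):
        fmap = fmap[0]
    act = np.abs(fmap[0]).mean(axis=0)
    lo, hi = act.min(), act.max()
    norm = (act - lo) / (hi - lo) if hi > lo else np.zeros_like(act)
    h, w = x.shape[-2:]
    ri = np.floor(np.arange(h) * (norm.shape[0] / h)).astype(int)
    ci = np.floor(np.arange(w) * (norm.shape[1] / w)).astype(int)
    up = norm[ri][:, ci]
    import matplotlib
    cmap = matplotlib.colormaps["jet"]
    heat = cmap(up)[..., :3]
    base = x[0].transpose(1, 2, 0)
    return np.clip(0.5 * base + 0.5 * heat, 0, 1)
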