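"""Training loop, checkpointing and evaluation driver.

A dataset item is ``(image, labels)`` with image either a path or a
(3, S, S) float array and labels a list of :class:`BoxLabel`. Training is
single-threaded and fully seeded: the seed fixes weight init, data order
and augmentation, so a rerun reproduces the loss curve bit for bit.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .data import AugmentConfig, BoxLabel, augment, load_image, read_yolo_labels
from .heads import decode_predictions
from .losses import compute_loss
from .metrics import map_metrics
from .network import Model, ModelConfig, TrainConfig
from .optim import Adam


def load_dataset(pairs, input_size: int):
    """Materialize (image array, labels) items from (image, label) path pairs."""
    items = []
    for img, lab in pairs:
        arr = img if isinstance(img, np.ndarray) else load_image(img, input_size)
        labels = lab if isinstance(lab, list) else read_yolo_labels(lab)
        items.append((arr, labels))
    return items


def _targets(labels, size: int):
    if not labels:
        return np.empty(0, np.int64), np.empty((0, 4), np.float32)
    cls = np.array([l.class_id for l in labels], np.int64)
    boxes = np.array([l.xyxy(size) for l in labels], np.float32)
    return cls, boxes


def run_training(model: Model, dataset, cfg: TrainConfig,
                 aug: AugmentConfig | None = None, log=print):
    """Adam training with per-epoch structured logging.

    Returns a history list of dicts (epoch, mean losses, lr, seconds).
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    size = model.cfg.input_size
    items = load_dataset(dataset, size)
    rng = np.random.default_rng(cfg.seed)
    if cfg.optimizer.lower() != "adam":
        raise ValueError(f"unsupported optimizer {cfg.optimizer!r}")
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    model.train()
    history = []
    step = 0
    for epoch in range(cfg.epochs):
        t0 = time.time()
        order = rng.permutation(len(items))
        sums, n_batches = {}, 0
        for lo in range(0, len(order), cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            imgs, tgts = [], []
            for j in idx:
                img, labels = items[j]
                if aug is not None:
                    img, labels = augment(img, labels, aug,
                                          int(rng.integers(0, 2 ** 31 - 1)))
                imgs.append(img)
                tgts.append(_targets(labels, size))
            x = np.stack(imgs).astype(np.float32)
            out = model.forward(x)
            loss, comps = compute_loss(out["main"], out["aux"], tgts, size,
                                       model.cfg.num_classes,
                                       aux_weight=cfg.aux_loss_weight,
                                       reg_max=model.cfg.reg_max)
            opt.zero_grad()
            loss.backward()
            opt.step()
            step += 1
            for k, v in comps.items():
                sums[k] = sums.get(k, 0.0) + v
            n_batches += 1
        rec = {"epoch": epoch, "lr": cfg.learning_rate,
               "seconds": round(time.time() - t0, 3),
               **{k: sums[k] / n_batches for k in sorted(sums)}}
        history.append(rec)
        if log is not None:
            log(f"epoch {epoch:3d} loss {rec['total']:.4f} "
                f"cls {rec['cls']:.3f} box {rec['box']:.3f} "
                f"dfl {rec['dfl']:.3f} ({rec['seconds']:.1f}s)")
    return history


def evaluate(model: Model, dataset, conf_thr: float = 0.25,
             iou_thr: float = 0.45, input_size: int | None = None):
    """Decode predictions on a dataset and score them."""
    size = input_size or model.cfg.input_size
    items = load_dataset(dataset, size)
    was_training = model.training
    model.eval()
    all_dets, all_gts = [], []
    for img, labels in items:
        out = model.predict(img[None].astype(np.float32))
        dets = decode_predictions(out["main"], size, conf_thr, iou_thr,
                                  model.cfg.reg_max)[0]
        all_dets.append(dets)
        all_gts.append(_targets(labels, size))
    model.train(was_training)
    return map_metrics(all_dets, all_gts, model.cfg.num_classes), all_dets, all_gts


# -- checkpointing -------------------------------------------------------------

def _is_merged(model: Model) -> bool:
    from ecgdet.blocks import RepVGGStage
    return any(isinstance(m, RepVGGStage) and m.block.merged is not None
               for m in model.mods.values())


def save_checkpoint(path, model: Model):
    state = model.state_dict()
    arrays = {f"param::{k}": v for k, v in state.items()}
    meta = {"config": model.cfg.to_dict(),
            "structure": "merged" if _is_merged(model) else "train"}
    arrays["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> Model:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        cfg = ModelConfig(**meta["config"])
        model = Model(cfg, seed=0)
        if meta["structure"] == "merged":
            model = model.reparameterize()
        state = {k[len("param::"):]: z[k] for k in z.files if k.startswith("param::")}
    model.load_state_dict(state)
    return model
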