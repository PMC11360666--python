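"""YOLO-format labels, image loading and deterministic augmentation.

A label file holds one ``class cx cy w h`` line per object, coordinates
normalized to [0, 1] relative to the full frame. Images are resized
directly to the square working resolution (no letterboxing — the
normalized labels refer to the full frame, so a direct resize keeps them
valid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from PIL import Image, ImageOps


@dataclass
class BoxLabel:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        eps = 1e-6
        if self.class_id < 0:
            raise ValueError(f"negative class id {self.class_id}")
        if not (0 < self.w <= 1 and 0 < self.h <= 1):
            raise ValueError(f"box size out of (0, 1]: w={self.w}, h={self.h}")
        for lo, hi in ((self.cx - self.w / 2, self.cx + self.w / 2),
                       (self.cy - self.h / 2, self.cy + self.h / 2)):
            if lo < -eps or hi > 1 + eps:
                raise ValueError("box extends outside the unit square")

    def xyxy(self, size: float) -> tuple[float, float, float, float]:
        return ((self.cx - self.w / 2) * size, (self.cy - self.h / 2) * size,
                (self.cx + self.w / 2) * size, (self.cy + self.h / 2) * size)


def read_yolo_labels(path) -> list[BoxLabel]:
    labels = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        try:
            cls = int(parts[0])
            cx, cy, w, h = (float(p) for p in parts[1:])
            labels.append(BoxLabel(cls, cx, cy, w, h))
        except ValueError as e:
            raise ValueError(f"{path}:{ln}: {e}") from None
    return labels


def write_yolo_labels(path, labels):
    lines = [f"{l.class_id} {l.cx:.6f} {l.cy:.6f} {l.w:.6f} {l.h:.6f}"
             for l in labels]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


DEFAULT_CLASSES = ["ECG HB", "history-MI", "MI-ECG", "normal-ECG"]


@dataclass
class DatasetManifest:
    class_names: list = field(default_factory=lambda: list(DEFAULT_CLASSES))
    splits: dict = field(default_factory=dict)  # name -> list of (img, label)

    def save(self, path):
        """Paths are stored relative to the manifest location when possible,
        so a generated tree is relocatable (and byte-reproducible)."""
        base = Path(path).resolve().parent

        def rel(p):
            p = Path(p).resolve()
            try:
                return p.relative_to(base).as_posix()
            except ValueError:
                return str(p)

        data = {"class_names": self.class_names,
                "splits": {k: [[rel(i), rel(l)] for i, l in v]
                           for k, v in self.splits.items()}}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load(cls, path):
        base = Path(path).resolve().parent
        data = yaml.safe_load(Path(path).read_text())

        def absolute(p):
            q = Path(p)
            return str(q if q.is_absolute() else base / q)

        return cls(class_names=data["class_names"],
                   splits={k: [(absolute(i), absolute(l)) for i, l in v]
                           for k, v in data["splits"].items()})

    def validate(self):
        nc = len(self.class_names)
        for name, pairs in self.splits.items():
            for img, lab in pairs:
                if not Path(img).exists() or not Path(lab).exists():
                    raise FileNotFoundError(f"{name}: missing pair {img}, {lab}")
                for l in read_yolo_labels(lab):
                    if l.class_id >= nc:
                        raise ValueError(f"{lab}: class id {l.class_id} >= {nc}")


def load_image(path, size: int = 640) -> np.ndarray:
    """Read PNG/JPEG -> (3, size, size) float32 in [0, 1]; embedded
    orientation metadata is applied; grayscale is replicated to 3 channels."""
    img = Image.open(path)
    img = ImageOps.exif_transpose(img)
    img = img.convert("RGB")
    if img.size != (size, size):
        img = img.resize((size, size), Image.BILINEAR)
    arr = np.asarray(img, dtype=np.float32) / 255.0
    return arr.transpose(2, 0, 1)


@dataclass
class AugmentConfig:
    p_hflip: float = 0.5
    p_affine: float = 0.5
    max_rotate: float = 5.0        # degrees
    max_translate: float = 0.10    # fraction of frame
    scale_range: tuple = (0.9, 1.1)
    p_crop: float = 0.3
    crop_scale: tuple = (0.8, 1.0)
    p_jitter: float = 0.5
    brightness: float = 0.2
    contrast: float = 0.2
    min_area_frac: float = 0.10    # drop boxes keeping less area than this

    @classmethod
    def identity(cls):
        return cls(p_hflip=0, p_affine=0, p_crop=0, p_jitter=0)


def _transform_boxes(labels, mat, size, min_area_frac):
    """Apply a forward 2x3 pixel map to boxes, AABB, clip, drop slivers."""
    out = []
    for l in labels:
        x1, y1, x2, y2 = l.xyxy(size)
        corners = np.array([[x1, y1], [x2, y1], [x1, y2], [x2, y2]], np.float64)
        pts = corners @ mat[:, :2].T + mat[:, 2]
        nx1, ny1 = pts.min(axis=0)
        nx2, ny2 = pts.max(axis=0)
        full = (nx2 - nx1) * (ny2 - ny1)
        cx1, cy1 = max(nx1, 0.0), max(ny1, 0.0)
        cx2, cy2 = min(nx2, size), min(ny2, size)
        if cx2 <= cx1 or cy2 <= cy1 or full <= 0:
            continue
        if (cx2 - cx1) * (cy2 - cy1) / full < min_area_frac:
            continue
        out.append(BoxLabel(l.class_id, (cx1 + cx2) / 2 / size,
                            (cy1 + cy2) / 2 / size,
                            (cx2 - cx1) / size, (cy2 - cy1) / size))
    return out


def _apply_affine_image(image, mat, size):
    """image (3, S, S) float; mat maps input px -> output px (forward)."""
    a = np.vstack([mat, [0, 0, 1]])
    inv = np.linalg.inv(a)
    img8 = Image.fromarray(
        (np.clip(image, 0, 1) * 255).round().astype(np.uint8).transpose(1, 2, 0))
    out = img8.transform((size, size), Image.AFFINE,
                         data=inv[:2].ravel().tolist(),
                         resample=Image.BILINEAR, fillcolor=(255, 255, 255))
    return np.asarray(out, np.float32).transpose(2, 0, 1) / 255.0


def augment(image: np.ndarray, labels, cfg: AugmentConfig, seed: int):
    """Seeded composition of horizontal flip, small affine, crop-and-pad and
    brightness/contrast jitter; labels transformed consistently."""
    rng = np.random.default_rng(seed)
    size = image.shape[-1]
    img = image
    labs = list(labels)

    if rng.random() < cfg.p_hflip:
        img = img[:, :, ::-1].copy()
        labs = [BoxLabel(l.class_id, 1.0 - l.cx, l.cy, l.w, l.h) for l in labs]

    if rng.random() < cfg.p_affine:
        th = math.radians(rng.uniform(-cfg.max_rotate, cfg.max_rotate))
        sc = rng.uniform(*cfg.scale_range)
        tx = rng.uniform(-cfg.max_translate, cfg.max_translate) * size
        ty = rng.uniform(-cfg.max_translate, cfg.max_translate) * size
        c = size / 2
        cos, sin = math.cos(th) * sc, math.sin(th) * sc
        # p' = sR(p - c) + c + t
        mat = np.array([[cos, -sin, c + tx - cos * c + sin * c],
                        [sin, cos, c + ty - sin * c - cos * c]], np.float64)
        img = _apply_affine_image(img, mat, size)
        labs = _transform_boxes(labs, mat, size, cfg.min_area_frac)

    if rng.random() < cfg.p_crop:
        f = rng.uniform(*cfg.crop_scale)
        cw = int(round(f * size))
        ox = rng.integers(0, size - cw + 1)
        oy = rng.integers(0, size - cw + 1)
        s = size / cw
        mat = np.array([[s, 0, -ox * s], [0, s, -oy * s]], np.float64)
        img = _apply_affine_image(img, mat, size)
        labs = _transform_boxes(labs, mat, size, cfg.min_area_frac)

    if rng.random() < cfg.p_jitter:
        alpha = 1.0 + rng.uniform(-cfg.contrast, cfg.contrast)
        beta = rng.uniform(-cfg.brightness, cfg.brightness)
        img = np.clip(alpha * (img - 0.5) + 0.5 + beta, 0, 1).astype(np.float32)

    return img, labs
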