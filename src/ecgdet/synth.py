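"""Seeded synthetic ECG-sheet generator.

Produces class-conditional 640x640 grid-paper images with one trace per
row and a YOLO box tightly enclosing each drawn trace, emulating a
four-class ECG photograph dataset (abnormal heartbeat, history of
myocardial infarction, acute myocardial infarction, normal). Each beat is
a five-bump Gaussian mixture (P, Q, R, S, T) — a visually plausible,
learnable class signal, not a physiological simulator:

* normal-ECG (3): regular RR (coefficient of variation < 2%), baseline ST;
* ECG HB (0): RR intervals jittered so the RR CV is >= 20%;
* MI-ECG (2): ST segment elevated by >= 0.2 of the R amplitude;
* history-MI (1): pathological Q waves (depth >= 25% of R), normal ST.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from .data import BoxLabel, DatasetManifest, write_yolo_labels

CLASS_HB, CLASS_HIST_MI, CLASS_MI, CLASS_NORMAL = 0, 1, 2, 3


@dataclass
class SynthConfig:
    n_images: int = 100
    class_mix: tuple = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    image_size: int = 640
    rows: int = 3                   # traces per sheet
    minor_grid: int = 8             # px
    major_grid: int = 40            # px
    amplitude_range: tuple = (0.85, 1.15)
    beats_range: tuple = (5, 8)     # inclusive
    noise: float = 0.01             # additive noise, fraction of R amplitude
    samples_per_beat: int = 96
    multi_class_sheets: bool = False

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")


# beat morphology: (offset, width) as fractions of the RR interval,
# amplitude relative to R
_BUMPS = {"P": (-0.28, 0.045, 0.15), "Q": (-0.045, 0.012, -0.10),
          "R": (0.0, 0.016, 1.0), "S": (0.045, 0.014, -0.22),
          "T": (0.32, 0.07, 0.32)}
_ST_WINDOW = (0.08, 0.24)   # fraction of RR after R where the ST segment sits


def waveform_with_meta(class_id: int, seed: int, n_beats: int = 6,
                       samples_per_beat: int = 96, noise: float = 0.0) -> dict:
    """Waveform plus construction metadata (RR intervals, R sample indices,
    ST windows)."""
    if class_id not in (CLASS_HB, CLASS_HIST_MI, CLASS_MI, CLASS_NORMAL):
        raise ValueError(f"unknown class id {class_id}")
    rng = np.random.default_rng(seed)
    jitter = 0.45 if class_id == CLASS_HB else 0.01
    rr = 1.0 + rng.uniform(-jitter, jitter, n_beats)
    q_amp = -0.35 if class_id == CLASS_HIST_MI else _BUMPS["Q"][2]
    st_lift = 0.25 if class_id == CLASS_MI else 0.0

    n = int(round(n_beats * samples_per_beat))
    t = np.arange(n) / samples_per_beat        # time in nominal beats
    y = np.zeros(n)
    r_times = np.concatenate([[rr[0] * 0.5], rr]).cumsum()[:-1]
    st_windows = []
    for i, rt in enumerate(r_times):
        beat_rr = rr[i]
        for name, (off, width, amp) in _BUMPS.items():
            if name == "Q":
                amp = q_amp
            center = rt + off * beat_rr
            y += amp * np.exp(-0.5 * ((t - center) / (width * beat_rr)) ** 2)
        lo = rt + _ST_WINDOW[0] * beat_rr
        hi = rt + _ST_WINDOW[1] * beat_rr
        st_windows.append((lo, hi))
        if st_lift:
            # raised-cosine plateau over the ST segment
            win = (t >= lo - 0.03 * beat_rr) & (t <= hi + 0.03 * beat_rr)
            phase = np.clip((t[win] - (lo - 0.03 * beat_rr)) /
                            (hi - lo + 0.06 * beat_rr), 0, 1)
            y[win] += st_lift * 0.5 * (1 - np.cos(2 * np.pi * phase))
    if noise:
        y = y + rng.normal(0, noise, n)
    r_idx = np.clip((r_times * samples_per_beat).round().astype(int), 0, n - 1)
    return {"trace": y, "rr": rr, "r_times": r_times, "r_idx": r_idx,
            "st_windows": st_windows, "t": t}


def synth_waveform(class_id: int, seed: int, n_beats: int = 6,
                   samples_per_beat: int = 96, noise: float = 0.0) -> np.ndarray:
    """Class-conditional 1-D trace (R amplitude = 1)."""
    return waveform_with_meta(class_id, seed, n_beats, samples_per_beat,
                              noise)["trace"]


def st_level(meta: dict) -> float:
    """Mean trace level over the ST windows (relative to R amplitude)."""
    t, y = meta["t"], meta["trace"]
    vals = []
    for lo, hi in meta["st_windows"]:
        m = (t >= lo) & (t <= hi)
        if m.any():
            vals.append(y[m].mean())
    return float(np.mean(vals))


def _draw_grid(cfg: SynthConfig) -> np.ndarray:
    s = cfg.image_size
    img = np.full((s, s, 3), 252, np.uint8)
    img[::cfg.minor_grid, :] = (255, 205, 205)
    img[:, ::cfg.minor_grid] = (255, 205, 205)
    img[::cfg.major_grid, :] = (250, 160, 160)
    img[:, ::cfg.major_grid] = (250, 160, 160)
    return img


MIN_BOX_PX = 6


def render_sheet(traces, cfg: SynthConfig):
    """Plot traces on grid paper; one tight BoxLabel per trace.

    traces: list of (class_id, 1-D array). Returns (image uint8 (S, S, 3),
    labels list[BoxLabel])."""
    if not traces:
        raise ValueError("render_sheet needs at least one trace")
    s = cfg.image_size
    img = _draw_grid(cfg)
    rows = len(traces)
    margin = s // 16
    labels = []
    color = np.array([40, 40, 70], np.uint8)
    for r, (class_id, trace) in enumerate(traces):
        yc = int((r + 0.5) * s / rows)
        amp_px = 0.30 * s / rows
        n_cols = s - 2 * margin
        xi = np.linspace(0, len(trace) - 1, n_cols)
        yv = np.interp(xi, np.arange(len(trace)), trace)
        ypix = np.clip(np.round(yc - amp_px * yv).astype(int), 0, s - 1)
        ymin, ymax = s, -1
        for i in range(n_cols):
            x = margin + i
            y0 = ypix[i - 1] if i else ypix[i]
            lo, hi = (y0, ypix[i]) if y0 <= ypix[i] else (ypix[i], y0)
            img[lo:hi + 1, x] = color
            img[min(lo + 1, s - 1):hi + 2, x] = color  # 2 px stroke
            ymin, ymax = min(ymin, lo), max(ymax, hi + 1)
        x1, x2 = margin, margin + n_cols - 1
        if ymax - ymin < MIN_BOX_PX:        # flat trace: clamp box height
            mid = (ymin + ymax) // 2
            ymin, ymax = mid - MIN_BOX_PX // 2, mid + MIN_BOX_PX // 2
        x1, y1 = max(x1 - 2, 0), max(ymin - 2, 0)
        x2, y2 = min(x2 + 2, s - 1), min(ymax + 2, s - 1)
        labels.append(BoxLabel(class_id, (x1 + x2 + 1) / 2 / s,
                               (y1 + y2 + 1) / 2 / s,
                               (x2 - x1 + 1) / s, (y2 - y1 + 1) / s))
    return img, labels


def generate_sheet(cfg: SynthConfig, class_ids, seed: int):
    """Build one sheet for the given per-row class ids."""
    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss)
    traces = []
    for class_id in class_ids:
        n_beats = int(rng.integers(cfg.beats_range[0], cfg.beats_range[1] + 1))
        amp = rng.uniform(*cfg.amplitude_range)
        w_seed = int(rng.integers(0, 2 ** 31 - 1))
        tr = amp * synth_waveform(class_id, w_seed, n_beats,
                                  cfg.samples_per_beat, cfg.noise)
        traces.append((class_id, tr))
    return render_sheet(traces, cfg)


def generate_dataset(cfg: SynthConfig, out_dir) -> DatasetManifest:
    """Write n_images PNG/label pairs plus a manifest with an 80/10/10
    train/val/test split; byte-identical for a fixed (config, seed)."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "labels").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed))
    pairs = []
    for i in range(cfg.n_images):
        sheet_class = int(rng.choice(4, p=cfg.class_mix))
        if cfg.multi_class_sheets:
            class_ids = [int(rng.choice(4, p=cfg.class_mix))
                         for _ in range(cfg.rows)]
        else:
            class_ids = [sheet_class] * cfg.rows
        sheet_seed = int(rng.integers(0, 2 ** 31 - 1))
        img, labels = generate_sheet(cfg, class_ids, sheet_seed)
        ip = out / "images" / f"ecg_{i:05d}.png"
        lp = out / "labels" / f"ecg_{i:05d}.txt"
        Image.fromarray(img).save(ip)
        write_yolo_labels(lp, labels)
        pairs.append((str(ip), str(lp)))
    n = len(pairs)
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    manifest = DatasetManifest(splits={
        "train": pairs[:n_train],
        "val": pairs[n_train:n_train + n_val],
        "test": pairs[n_train + n_val:]})
    manifest.save(out / "manifest.yaml")
    return manifest
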