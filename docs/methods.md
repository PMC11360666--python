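# Methods

## Network

The detector is a 44-node directed acyclic graph (`ecgdet.network.default_graph`)
executed in step order; every node consumes earlier steps only.

**Backbone** (strides in parentheses): Silence → RepVGG stage 3→64 (/2) →
RepVGG stage 64→128 (/4) → RepNCSPELAN4 →256 → ADown (/8) → RepNCSPELAN4
→512 → BRA(S=8) → ADown (/16) → RepNCSPELAN4 →512 → BRA(S=4) → ADown
(/32) → RepNCSPELAN4 →512.

**Neck**: SPPELAN at /32, then a PAN: upsample + concat with the /16
backbone tap → C2f_VSS →512 → RepNCSPELAN4; upsample + concat with the /8
tap → C2f_VSS →256 → RepNCSPELAN4 (P3, 80×80×256 at 640 input); ADown +
concat → RepNCSPELAN4 (P4, 40×40×512); ADown + concat with the SPPELAN
output → RepNCSPELAN4 (P5, 20×20×512).

**Auxiliary branch** (training only): CBLinear taps on the three backbone
RepNCSPELAN4 outputs produce channel chunks `[256]`, `[256,512]`,
`[256,512,512]`; a parallel stem (two RepVGG stages, RepNCSPELAN4, ADown)
is fused with those chunks by CBFuse (nearest-resize + sum) at /8, /16,
/32, yielding mirror head inputs supervised with weight 0.25.
`Model.reparameterize()` drops every step reachable only from the
auxiliary head and merges all RepVGG branches; tests assert the merged
network's inference outputs match within 1e-4 relative (measured ~1e-6).

### Block-level choices

* **RepVGG activation placement.** The split-branch block applies the
  activation to the *sum* of the three normalized branches. Applying a
  nonlinearity inside each branch would make the exact single-conv merge
  impossible, and deployment-time merging is the block's purpose. With
  `activation="identity"` the block reduces to the pure algebraic form
  used in the equation-level tests. Branch traces expose the
  pre-activation outputs, so the sum identity Y = Y₃ₓ₃+Y₁ₓ₁+Y_id is
  directly assertable.
* **RepVGG stages in the graph.** The split-branch block is stride-1 by
  construction (the untouched half must re-concatenate), but the first two
  backbone steps must downsample 640→160 for the 80/40/20 head grid. Each
  network-level `repvgg` node therefore pairs a strided 3×3 conv-BN-SiLU
  (channel change, /2) with the block.
* **RepNCSPELAN4** is the shallow two-branch form: 1×1 conv to the hidden
  width (default = out_channels), split halves, two 3×3 convs on the
  second half, concat, 1×1 conv out. This is deliberately lighter than the
  four-subblock aggregation the name suggests elsewhere; parameter/GFLOP
  totals of the default configuration (35.6 M / 192 GFLOPs with the
  auxiliary branch at 640 px) are accordingly lower than detectors built
  on the deeper variant.
* **ADown**: 2×2 stride-1 average pool, channel split, then per half a
  3×3 stride-2 conv and a 3×3 stride-2 max pool + 1×1 conv, concatenated.
  Even spatial dims are required; there is no implicit padding.
* **SPPELAN**: 1×1 transform, parallel {1×1 conv, max-pool k=5/9/13 all
  stride 1}, concat, 1×1 projection. Hidden width defaults to half the
  output width.
* **BRA**: single head by default (multi-head splits channels evenly);
  attention scale defaults to 1/√d for numerical stability, with
  `scale=1.0` available for the literal unscaled form. Top-k ties break
  toward the lower region index (stable argsort), making routing
  deterministic. LCE is a depthwise 5×5 convolution of V (size
  configurable). The two BRA sites have independent parameters. In the
  graph the node computes `x + BRA(x)`; the residual keeps early training
  stable while the operator itself (and all its oracle tests) remains the
  pure attention form.
* **SS2D** is the four-directional selective scan: row-major, reversed
  row-major, column-major, reversed column-major sequences, a diagonal
  linear time-invariant recurrence per channel (scalar state), outputs
  un-scanned and summed. Parameters are stored as a = −exp(a_log),
  Δ = exp(log_delta) so the discretized transition e^{Δa} stays a
  contraction throughout training. An input-independent (LTI) recurrence
  is the default because it is exactly checkable against a per-token
  reference loop; a literal shifted-depthwise-convolution reading is
  available as `ss2d_variant="shift_conv"`. The functional
  `ss2d_forward` computes in float64 (oracle-grade); the in-network
  module runs in float32.
* **VSS block** order: linear embeddings W₁,W₂ into two paths; path A =
  DWConv → SiLU → SS2D → LayerNorm, path B = SiLU gate; elementwise
  product, output projection W₃, residual add. The alternative literal
  ordering LN → SS2D → DWConv is exposed via `order="eq"`; the two are
  never silently mixed. LayerNorm is per-token over channels, ε = 1e-6.
  No positional embeddings.
* **C2f_VSS**: 1×1 conv → split halves → chain of `vss_n` VSS blocks on
  the second half with *every* intermediate retained → concat → 1×1 conv
  (dense aggregation). Default `vss_n = 1`.

### Heads, loss, decoding

Decoupled anchor-free heads at strides 8/16/32; box edges are discrete
distributions over 16 bins (distribution-focal representation) whose
softmax expectation gives left/top/right/bottom distances in stride units.
Positive assignment is center-based: a cell is positive for a box when its
center lies inside the box and within 2.5 strides of the box center;
contested cells go to the smallest box. Loss = 0.5·BCE(cls) +
7.5·(1−CIoU) + 1.5·DFL, each normalized by the positive count; auxiliary
heads add the same loss × 0.25. Classification conv biases start at
−log(99) (1% prior) so early training is not swamped by negatives.
Decoding takes the per-cell argmax class, thresholds at confidence 0.25
and applies class-wise greedy NMS at IoU 0.45. Boxes are pixel, 0-based,
half-open; YOLO-normalized coordinates exist only at the file boundary.

### Numerical substrate

No deep-learning framework is used: `ecgdet.autodiff` is a tape-based
reverse-mode engine over float32 numpy arrays (float64 is preserved where
supplied, for oracle paths), with convolution via an im2col/col2im pair,
pooling/normalization/resize primitives with hand-derived gradients, and
the state-space recurrence evaluated by `scipy.signal.lfilter` per channel
(backward pass runs the reversed recurrence). All primitives are verified
against central finite differences in the test suite. Training is
single-threaded; determinism (identical loss curves and checkpoints for a
fixed seed) is a tested contract. Batch norm: ε = 1e-5, momentum 0.1;
max-pool ties break toward the first maximal element.

FLOPs are reported as 2 × multiply-accumulates over conv/linear/attention/
scan operators, elementwise and normalization work excluded — the common
detector-reporting convention; the counter is exercised against closed
forms per layer.

## Synthetic data

The generator emulates a four-class photographed ECG-sheet dataset: 640×640
grid-paper images, by default three traces per sheet, one class per sheet,
one tight whole-trace box per trace (a per-beat box mode exists but is not
default). Each beat is a five-bump Gaussian mixture (P, Q, R, S, T
at fixed fractions of the RR interval, R amplitude 1). Class conditioning:
normal — RR coefficient of variation < 2%, baseline ST; abnormal heartbeat
— RR jittered uniformly ±45% (CV ≈ 26%); acute MI — raised-cosine ST
plateau of 0.25 R-amplitude; history of MI — Q deepened to 35% of R with
normal ST. Additive Gaussian noise of 0.01 R-amplitude; per-sheet beat
count 5–8 and amplitude 0.85–1.15 drawn from a seeded generator; datasets
are byte-reproducible and split 80/10/10.

What it does **not** emulate: 12-lead layouts, scanner/photography
artifacts, perspective distortion, handwriting/stamps, physiologic
waveform variability beyond the four class signatures. Tests passing on
these sheets demonstrate that the architecture and training stack can
learn real class-discriminating morphology at desk scale; they say nothing
about clinical-grade accuracy on photographed ECGs.

## Problem sizes

Desk-scale experiments use `width_multiple = 0.25` (channels 16–128) and
128 px inputs — the smallest size at which the default region grids (S=8
at /8, S=4 at /16) divide the feature maps. The learnability experiment
trains on 64 generated sheets (generator seed 7) for 50 epochs, batch 4,
Adam at lr 0.001; full-width statistics (parameters, GFLOPs, head shapes)
are computed at the native 640 px. The full-scale training schedule the
defaults encode (batch 4, 200 epochs, lr 0.001, Adam) is not run in the
test suite.

## Known limitations

* The equation-literal shallow blocks make the default model lighter
  (35.6 M params / 192 GFLOPs with aux at 640 px) than detectors using the
  deeper four-subblock aggregations; widths are configurable if heavier
  variants are wanted.
* The scan is LTI by default; input-dependent (selective) Δ is not the
  tested path.
* Augmentation magnitudes (rotation ≤ 5°, translation ≤ 10%, scale
  0.9–1.1, crop 0.8–1.0, brightness/contrast ± 0.2, 10% surviving-area
  drop threshold) are conservative defaults, all configurable.
* Single-process CPU training only; multi-worker determinism is not
  promised, and no mixed precision or export formats.
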