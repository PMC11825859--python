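# Methods

## Model

CGS-Net is a dual-encoder, single-decoder segmentation network for binary
cancer segmentation of whole-slide image (WSI) patches. Its inputs are two
224×224×3 RGB patches sharing a center pixel: the *detail* patch from
pyramid level 2 and the *context* patch from level 3. Levels 2 and 3 are a
factor 2 apart in linear resolution (3.89 → 7.8 µm/px), so the context
patch covers twice the physical extent at half the resolution. Annotation
coordinates live at level 0; level-2 pixel coordinates are level-0 / 4 and
level-3 coordinates are level-0 / 8.

Two encoder families are implemented from their published stage recipes:

- **MiT** (mix transformer): overlapped patch merging (stride-4 stem with a
  7×7 conv, then 3×3 stride-2 merges), efficient self-attention with
  per-stage sequence-reduction ratios (8, 4, 2, 1), and a mix feed-forward
  whose hidden layer contains a 3×3 depthwise convolution. B1 = depths
  (2,2,2,2), B2 = (3,4,6,3), dims (64,128,320,512), heads (1,2,5,8).
- **SwinV2**: 4×4 patch embedding, windowed attention (window 7) with
  scaled cosine similarity and a per-head learnable logit scale, a
  continuous relative position bias generated by a 2→512→heads MLP on
  log-spaced coordinates, residual post-normalization, and patch-merging
  downsampling. Tiny = depths (2,2,6,2), Small = (2,2,18,2), dims
  (96,192,384,768), heads (3,6,12,24).

Both produce four feature maps at strides 4/8/16/32. In the dual model each
stage is fused by a **multi-cross attention (MCA)** block: layer-normalized
context tokens form the queries and layer-normalized detail tokens the keys
and values of a single-head attention with full d×d projections
(`softmax(QKᵀ/√d_k)V` followed by a projection), a residual connection that
adds the raw detail tokens back, and a small bottleneck feed-forward
refinement whose output layer starts at zero. Single-head attention is
deliberate: the identity initialization of the key/value/projection maps
requires square matrices, which multi-head splitting would break.

Initialization: `W_Q = 0`, `W_K = W_V = W_P = I`, all biases zero, FFN
output layer zero. Softmax of the all-zero score matrix is the uniform
row-stochastic matrix (entries 1/n), so each attention output row is the
mean detail token and — crucially — *no* context information reaches the
output. The whole dual model is therefore an exact function of the detail
input at initialization (verified to 0 in the tests), while the gradient
with respect to `W_Q` is generically nonzero, so the context pathway is
trainable. The residual keeps the detail features themselves (not just
their mean) flowing to the decoder at initialization; the non-residual form
is retained for the closed-form oracle tests.

The decoder is a U-Net decoder over the four stage maps extended by two
extra transposed-convolution stages, so the output probability map has the
full input resolution — the ground truth is never downsampled, because
cancer pixels are rare and decimating them would discard most of the
positive class. Each decoder stage is ConvTranspose(2×2, stride 2) +
double 3×3 conv (BatchNorm + ReLU); a 1×1 conv + sigmoid head emits the
probability map. 2-D dropout (default 15% during regularized training) sits
after the skip-merging stages and in the MCA blocks.

### Parameter budgets

The published parameter table pins the architecture. With the encoder
recipes above, the implemented encoders count 13,151,424 (MiT-B1),
24,196,288 (MiT-B2), 27,578,154 (SwinV2-Tiny) and 48,959,418
(SwinV2-Small) trainable scalars; the *differences* between sizes within a
family match the published single-model differences to within rounding,
which confirms the recipes. The decoder head widths and the MCA bottleneck
widths are then calibrated, once per family, so that all eight single/dual
totals reproduce the published column at two-decimal (million) precision:

| component | MiT | SwinV2 |
|---|---|---|
| decoder head widths | (192, 80, 48, 24, 16) | Tiny (164, 88, 32, 24, 16); Small (162, 80, 48, 24, 16) |
| MCA FFN hidden widths | (20, 40, 100, 160) | (32, 64, 128, 256) |

A `test_tiny` variant of each family (depth 1 per stage, dims 16–128) is a
first-class configuration used by every training test so the whole pipeline
runs on one CPU.

### Tensor backend

Models, losses and training run on `cgsnet.nn`, a compact reverse-mode
autodiff engine over numpy (im2col convolutions, transposed convolution as
the exact adjoint, layer/batch norm, attention primitives, Adam,
reduce-on-plateau scheduling). Gradients of every primitive are verified
against central finite differences in float64; the functional MCA API
operates at float64 for the 1e-12 closed-form checks. Float32 is the
training precision.

## Masks and patch extraction

The tissue mask thresholds HSV saturation at a per-slide Otsu threshold
(256-bin histogram), then applies morphological closing (disk radius 4 px
at level 2) and removes holes and objects smaller than 16 px² (halved at
level 3). The defaults are our choice; the operations themselves are fixed.
Constant-saturation images yield an all-background mask with a warning.
Masks are computed independently per level rather than rescaled, avoiding
interpolation artifacts. The cancer mask is rasterized from the annotation
polygons — a pixel is cancer iff its center lies inside the polygon under
the even-odd rule — and is *not* gated by the tissue mask, so fat-tissue
holes inside an annotation stay cancer. Non-cancer = tissue ∧ ¬cancer.

Patch extraction proposes level-2 center pixels per category and audits the
224×224 window (half-open, [c−112, c+112)) against the masks:

- *cancer*: centers drawn from cancer-mask pixels; pass 1 (attempts
  1–10,000) requires tissue > 75% and cancer ≥ 75%, pass 2 (to 25,000)
  relaxes cancer to ≥ 45%.
- *cancer boundary* and *non-cancer island boundary*: centers within a
  112 px Chebyshev band of the annotation (or island) edge; pass 1 cancer
  40–75% with tissue > 75%, pass 2 (after 10,000 attempts) cancer 20–75%
  with tissue ≥ 50%, pass 3 (attempts 22,000–25,000, our reading of "the
  final few thousand") cancer 10–90% with tissue ≥ 25%.
- *non-cancer* (both slide types): uniform centers, single pass, tissue
  > 75% and zero cancer pixels.

Any two accepted windows on a slide must overlap by less than 50% of one
window's area, across categories. Per-slide quotas are 50 non-cancer + 25
cancer + 50 cancer-boundary + 25 island-boundary patches per cancer slide
and 25 non-cancer patches per non-cancer slide; a category's unmet quota
moves to its closest neighbour (cancer-boundary ↔ island-boundary,
cancer → cancer-boundary). On small-tumor ("cancer unique") slides ten
annotation vertices seed the boundary category. Boundary/cancer candidates
that fail only the tissue rule in the final pass are accepted when their
window touches an annotation edge lying within 112 px of background (glass
boundary); such records carry a `glass_exempt` flag so audits remain
re-checkable. Cancer slides that still hold fewer than 80 cancer-containing
patches are topped up from annotation vertices with all quality control and
overlap rules waived — deliberate oversampling of small lesions, and those
records are marked `fallback`. Whether island-boundary patches count toward
the 80-floor is unstated in the source material; we count every record with
a positive cancer fraction.

Slides are split 60/20/20 at the slide level (largest-remainder allocation)
stratified over {non-cancer, cancer, cancer-unique}; all patches inherit
their slide's split, so no patch-level leakage is possible.

## Training

The loss is `0.95·focal + 0.05·dice` with γ = 2, optional α balancing, and
soft-dice smoothing ε = 1e−6 (the exact focal/dice variant of the cited
recipe is not reprinted in the source; these are the standard forms, all
exposed in `LossConfig`). Augmentation applies one shared geometric draw
(transpose, flips, 90° rotations, small affine) to the detail image,
context image and both masks, and color-only transforms (hard HSV jitter,
Gaussian blur, coarse dropout) to the images; masks stay binary.

Stages: each single model trains with its encoder frozen for the first 600
of 1000 epochs (defaults; tests and the desk-scale study use scaled-down
schedules, the schedule is fully configurable). The dual model receives the
detail encoder from the level-2 single, the context encoder from the
level-3 single and the decoder from the level-2 single; MCA blocks keep
their zero/identity initialization. Four Adam groups (detail encoder,
context encoder, decoder, MCA) with three reduce-on-plateau schedulers
(encoders / decoder / MCA) drive training; encoders and decoder stay frozen
for the first 300 epochs (MCA-only phase), then everything is unfrozen for
300 more. After selection, the model is retrained from scratch on
train + validation for exactly the best-validation epoch count, re-applying
the same (truncated) freeze schedule. L1/L2 penalties apply only to
components that were neither pre-trained nor frozen at the start of the
phase. Learning rates (6e−5 encoders, 6e−4 decoder/MCA), batch size
(default 16, tests use 4) and scheduler type are our defaults — the source
states the optimizer and scheduler counts but not their hyperparameters.

## Evaluation

Every pixel of every evaluated patch enters one flat pool; oversampled
cancer patches contribute each occurrence. AUC is the trapezoidal area
under the pooled ROC with midrank ties (cross-checked in tests against the
O(n²) pairwise concordance statistic), and the cancer Dice is the pooled
(micro) `2TP/(2TP+FP+FN)` at the fixed threshold 0.5; an empty
positive-and-predicted set is defined as Dice 1.0 and logged. A streaming
implementation reduces chunks to per-distinct-probability counts and is
exactly equal to the in-memory pool. Repeated runs aggregate as mean ±
sample standard deviation (ddof = 1; run count configurable, default 3).
The MCA weight summary reports the plain entrywise mean of each stage's
query/key/value matrices next to the 0/1/1 init-convention row; note that
the entrywise mean of an identity matrix is 1/d, so freshly initialized
stages report 1/d in the key/value columns — the published near-zero
post-training averages are consistent with entrywise means of large
matrices, but the exact averaged quantity there is not specified.

## Synthetic slides and the context-benefit study

The generator emulates: bright glass background, pink eosin-like tissue
blobs, purple cancer cores, polygonal level-0 annotations, a two-level
pyramid where level 3 is the exact 2×2 integer box-mean of level 2, and
exact per-level ground-truth masks (the rasterization is the oracle). It
does **not** emulate nuclear texture, stain variability, scanner artifacts
or tissue deformation — so passing tests demonstrate algorithmic
correctness and the architectural context mechanism, not clinical
performance.

The context-benefit study renders an *ambiguous band* around each cancer
boundary: tissue within 180 px inside and 250 px outside the boundary is
drawn from one shared color distribution, so its label is undecidable from
local appearance. Because 180 px exceeds the detail patch's 112 px
half-field-of-view, a boundary-centred detail window sees neither the
cancer core nor unambiguous normal tissue, while the co-centred context
window (224 px half-FOV at level-2 scale) sees both. The benchmark cohort
(fixed geometry; 2 train cancer + 1 train non-cancer, 1 validation and 2
test cancer slides of 1024² px with ~318 px tumors) is held constant;
five repetitions vary only the training seed. Detail-only and dual models
(`test_tiny`, 24-epoch scaled schedules, inputs downsampled 7× to 32×32 —
the pairing geometry is scale-invariant) are compared by held-out pooled
AUC over an evaluation pool that emphasizes boundary patches. The dual
model consistently exceeds the single model by ≥ 0.05 AUC (typical margins
0.15–0.25).

## Numerical and degenerate-input conventions

Coordinates are 0-based; windows half-open; level-3 centers use floor
division; context windows are edge-padded at slide borders. Softmax
subtracts the row maximum (exact for the all-zero case). The box
downsample uses integer floor division after summing 2×2 blocks; odd axes
are edge-padded. Slides must be ≥ 672 px per axis at level 2 (three
non-overlapping patches per axis). Sampling determinism comes from
`numpy.random.default_rng` seeded per slide with a stable hash of the
slide id, so manifests are byte-reproducible for a given cohort and seed.

## Known limitations

- SwinV2 shifted windows are disabled at resolutions not divisible by the
  window size (inputs are then zero-padded for the window partition); the
  published 224-px path uses shifts exactly as specified.
- ImageNet pre-training is supported only through `pretrained_source`
  weight archives supplied by the user; nothing is downloaded, and the
  truncated-normal fallback initialization is the tested path.
- The CPU backend is single-threaded numpy; full-size (B1/B2/Tiny/Small)
  models are built and counted in tests but trained only at `test_tiny`
  scale.
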