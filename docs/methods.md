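# Methods

## The model

`exemplarnet` implements a two-stage image-classification pipeline for
biomedical images (MRI slices, blood-cell micrographs, histopathology tiles
and the like): a lightweight convolutional backbone trained end-to-end with a
softmax head, followed by a patch-based deep-feature-engineering stage that
usually outperforms the softmax head itself.

### LiteNeXt backbone

LiteNeXt is a ConvNeXt-style network reduced to ~7.4 M parameters:

* **Patchify stem** — 4×4 convolution, stride 4, 96 filters, batch norm, GELU.
  A 224×224×3 input becomes 56×56×96.
* **Four stages of dual-shortcut blocks** at widths 96/192/384/768. Each block
  holds two residual sub-units; a sub-unit is pre-LN → 3×3 depth-wise
  convolution with a 4× channel multiplier (inverted bottleneck) → GELU → 1×1
  point-wise projection back to the stage width → batch norm, with an additive
  shortcut around the whole sub-unit. Two shortcuts per block (rather than
  ConvNeXt's one) help gradient flow in small, shallow networks.
* **Grouped patchify downsampling** between stages: 2×2 convolution, stride 2,
  one input channel and two output filters per group, so the spatial side
  halves and the channel count doubles (96→192→384→768), followed by channel
  layer norm and GELU. No pooling anywhere.
* **Output block** — 1×1 convolution widening 768→1280, layer norm, GELU,
  batch norm, global average pooling (GAP) to a 1280-vector, and a fully
  connected softmax head.

Exact accounting for the default schedule: each stage of width C costs
8C² + 90C parameters (two sub-units of 4C² + 45C), the three downsamples
14·C_in each, the stem 4896, the output convolution 768·1280 + 1280, the two
output-block norms 2·2·1280, and the 4-class head 1280·4 + 4 — in total
7,405,348 trainable scalars, i.e. 7.4 M, or 28.2 MiB at four bytes per weight.

The layer set (grouped convolution, batch/layer norm, GELU, linear, GAP) is
implemented directly in NumPy with explicit backward passes
(`exemplarnet.nn`); convolutions are computed as sums of strided-slice
contractions over kernel offsets, which keeps the backward pass free of
scatter operations. Training uses SGD with classical momentum 0.9 (no weight
decay), learning rate 0.01, batch size 32, cross-entropy on logits, and a
stratified 70:30 train/validation split. Weights initialise from a clipped
normal (σ = 0.02, ±2σ); norm scales start at one, shifts and biases at zero.
Every stochastic choice (init, split, shuffling) flows from explicit seeds, so
identical seeds reproduce identical weights bit for bit.

Input sides must be multiples of 4 (the stem is an exact patchify); multiples
of 32 give exact halving at every stage, other sides floor on odd dimensions
(e.g. 112 → 28, 14, 7, 3). Pixels are scaled to [0, 1]; images are resized
bilinearly; grayscale inputs are channel-replicated.

### Exemplar feature engineering

For each image resized to the network side S:

1. divide it into nine overlapping patches of side S/2 with stride S/4
   (112/56 at S = 224) — a 3×3 grid whose corners are covered once and whose
   central square is covered four times;
2. extract the GAP feature vector of the full image and of every patch with
   the *pretrained, frozen* backbone (patches are bilinearly upscaled to S by
   default; a `native` mode runs them at their own resolution through the
   fully convolutional trunk);
3. concatenate the ten blocks: block t holds input t (t = 1 the full image,
   t = k+1 patch k), giving 10 × 1280 = 12,800 features by default.

The patch blocks are what lets the pipeline pick up class signal confined to
a sub-region that full-image GAP averages away.

### INCA feature selection

Selection is fitted on **training features only**; the chosen column indices
are then transferred to the test matrix unchanged.

1. Columns are standardised to train-set mean 0 / SD 1 (zero-variance columns
   map to 0; test rows reuse the train statistics). Standardisation is the
   default and switchable — distance-based ranking needs comparable scales.
2. NCA feature weighting learns a relevance w_r² per feature by maximising the
   anchor-averaged soft leave-one-out nearest-neighbour objective
   (1/N)·Σᵢ Σⱼ p_ij·1[yᵢ = yⱼ] − λ·Σ w_r², with p_ij ∝ exp(−Σ_r w_r²|x_ir −
   x_jr|), by stochastic gradient ascent from w = 1: ⌊N/2⌋ passes over all
   anchors in random order, λ = 1/N. The returned weights are the
   Polyak–Ruppert average of the iterates over the last half of the passes —
   the standard variance-reduction companion of decaying-step SGD — which
   stabilises the ranking of weakly informative features without changing the
   objective or the iteration budget (switchable via `iterate_averaging`).
3. Features are ranked by decreasing w_r² (stable sort, lower index wins
   ties), and every nested prefix of size a ∈ [iv, fv] (100..1000 by default,
   901 candidates) is scored by the stratified 10-fold cross-validated error
   of a 1-NN classifier under the L1 metric. The pairwise distance matrix is
   grown one ranked column at a time, so the sweep costs O((fv−iv)·N²) rather
   than O(Σ a·N²). The smallest size attaining the minimum error wins.

**Step size.** The ascent step is α_t = step_size/√t per pass with
`step_size = 3.0` by default. The scale matters: with standardised features
and thousands of columns the soft-neighbour distribution is extremely peaked
(distances are sums over all features), so per-anchor gradients have magnitude
~10⁻³; steps of order 0.1 leave the weights essentially at their
initialisation after ⌊N/2⌋ passes, while unit-to-few steps let clearly
informative columns (per-feature t-statistics ≈ 4) separate from noise within
the fixed iteration budget. Convergence is observable in `objective_trace`;
the default was chosen as the smallest scale at which the trace plateaus
within the budget on representative fixtures, and it remains stable (no
divergence) up to at least 10×.

**Iterations.** "Half the number of images" is read as ⌊N/2⌋ *passes* over
the data (one gradient step per anchor per pass), the iteration unit used by
stochastic solvers in the reference numerical environment. Read as single
anchor steps the optimizer cannot leave its initialisation on realistic
problems, and the selector degenerates to near-random ranking.

### Shallow classification and evaluation

The selected features feed three fixed classifiers: 1-NN with L1 distance
(all ties — equal distances, equal votes — resolve to the lowest training
index, making predictions deterministic), an SVM with the cubic polynomial
kernel (x·z + 1)³, C = 1, one-vs-one coding, and LDA with shared covariance,
no shrinkage and empirical priors (the SVD solver absorbs singular pooled
covariance). Reported numbers are train→test: classifiers fit on all
training rows and predict the held-out split; 10-fold CV is used inside the
selector and for validation-style figures.

Metrics: accuracy, UAR/UAP (macro recall/precision), overall F1 as the
harmonic mean of UAR and UAP (a `macro_f1` flag switches to the mean of
per-class F1 — the two are numerically indistinguishable on near-diagonal
matrices), per-class sensitivity/specificity/precision/F1 with unweighted
macro averages, Wilson 95 % score intervals for accuracies, and McNemar
χ²(1) tests on discordant pairs with continuity correction by default.
Percentages print at two decimals with half-up rounding.

## Synthetic data

No real dataset ships with the package; two seeded generators create inputs
with exactly the statistical structure the pipeline assumes.

**Images.** Each class combines (i) a *global* low-frequency signal — a
smooth 2-D cosine surface with class-specific frequency, orientation and
phase — and (ii) a *local* motif — a high-frequency checkerboard with
class-specific cell geometry, confined to the central half of one
class-specific cell of the 3×3 patch grid — plus i.i.d. pixel noise, clipped
to [0, 1] and written as 8-bit PNGs. Defaults: 3 classes, 40 train + 15 test
images per class, side 224 (tests use 64 or 32: cosines and checkerboards
survive downscaling), global amplitude 0.35, motif amplitude 0.5, noise σ
0.05. Setting the global amplitude to zero makes the class signal local-only,
the regime where patch features must beat full-image features. What this
emulates — and all it emulates — is multi-scale class-discriminative
structure; it does not reproduce the acquisition physics, artefacts, or
intra-class variability of real MRI/microscopy/histology, so green tests
certify the pipeline's mechanics, not clinical performance.

**Feature fixtures.** Labeled matrices with a known informative column subset:
informative columns receive class-dependent mean offsets (adjacent classes
separated by `effect_size` noise-SD units, random sign per column), all other
columns are N(0, 1) noise, classes balanced. The selector-recovery fixture
uses 1,500 features with 120 informative, n = 360, and *twelve* classes at
adjacent-class separation 0.5 SD. The many-class, modest-separation regime is
what keeps the recovery question meaningful: each feature carries clear
aggregate structure (NCA ranks it reliably), yet the 1-NN CV error stays well
off its floor at 100 columns and keeps declining as further informative
columns accumulate, so the sweep's optimum genuinely spans the informative
set. With few classes or stronger effects, ~100 columns already saturate the
oracle at zero error and the smallest-minimum rule correctly stops the sweep
at the range start; that is a property of the task, not of the selector.

## Numerical and design choices

* Patch order is row-major over (row, col) offsets; block layout is
  `[image, patch1..patch9]`.
* Downsample channel doubling is enforced by the spec validator (the grouped
  2×2 convolution pairs each input channel with two output filters).
* The fold planner reduces the fold count with a warning when the smallest
  class has fewer samples than folds; it refuses folds > N.
* The sweep requires iv ≥ 1, iv ≤ fv ≤ d; the CLI clamps fv to the actual
  column count before selection.
* Degenerate inputs: empty folders, single-class training sets, zero-variance
  columns, zero-row matrices, and b + c = 0 McNemar tables all have explicit,
  tested behaviours (typed errors or flagged degenerate results).
* Model archives embed the architecture spec; loading validates stored-vs-
  expected shapes and reports the diff. The FP32 payload is 4 bytes per
  parameter (28.2 MiB for the default network).
* One global pipeline seed fans out to per-stage seeds via CRC32 of
  "seed:stage", keeping every stage independently reproducible.

## Problem sizes used in tests and the acceptance script

Architecture anchors (parameter count, shape traces, feature lengths, patch
counts) run at full size — they are seconds of compute. Everything involving
training or selection runs scaled down by design: networks with filter
schedule (8, 16, 32, 64, 48) at input sides 32–64, datasets of 36–165 images,
5 training epochs, and the recovery fixture above. These sizes were chosen so
the full suite exercises every pipeline path at desk scale. Benchmark-scale
experiments (tens of thousands of images, 100 training epochs) are out of
scope, and no published benchmark accuracies are claimed or reproduced here.

## Known limitations

* The NumPy backbone is CPU-only and unoptimised relative to GPU frameworks;
  it is sized for method correctness and small experiments, not large-scale
  training.
* NCA feature weighting is stochastic; different seeds give slightly
  different rankings near the informative/noise boundary.
* `native` patch mode requires patch sides that survive the stem and three
  downsamples (multiples of 4, ≥ 32 in practice).
* Repetition counts > 1 per stage are supported (extra dual-shortcut blocks
  before the stage's downsample) but are an experimental extension beyond the
  recommended single-repetition schedule.
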