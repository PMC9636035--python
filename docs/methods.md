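# Methods

## The model

A patient's TMB status is treated as a binary latent variable (high/low)
expressed in tissue morphology. Slides are tiled into square patches at a
working magnification; every patch inherits its patient's label; a
convolutional classifier produces per-patch probabilities of TMB-high; the
patient-level PITER score is the median of those probabilities over all
tumor patches of all of the patient's slides (a multiple-instance "bag"
aggregation). A binary biomarker call thresholds the score at the cutoff
that maximizes the Youden index on the training cohort.

The central methodological problem is confounding. Patch labels are
constant within a slide, so anything that identifies the slide — staining
chemistry, scanner colour response — is a perfectly valid predictor of the
training labels and a useless one on new material. Adversarial confounder
suppression (AdvCS) addresses this: a confounder head classifies the
source slide ID from the shared representation through a gradient-reversal
layer (identity forward, gradient × −λ backward), so the head descends its
cross-entropy while the backbone ascends it, driving the representation
towards slide-invariance. The total objective is
`CE_task + α · CE_confounder`.

## AdvCS at desk scale: design choices

The adversarial game as naively formulated is unstable, and several
choices here are deliberate:

* **Mixed-slide confounder batches.** Task batches contain patches of a
  single slide (32 at a time). A head trained on such batches sees one
  class at a time and never learns; the confounder branch therefore draws
  its own batches across all training slides, unaugmented (it must measure
  decodability of the representation as deployed).
* **A near-optimal adversary.** The head is refit each step by
  warm-started multinomial logistic regression (lbfgs, C = 10, 60
  iterations) on a replay buffer of the most recent ~960 representations.
  A weak, lagging head underestimates slide decodability and the backbone
  only suppresses what the head can see; the refit head tracks what any
  post-hoc linear probe would find.
* **Conditional suppression.** The reversed gradient uses a softmax
  restricted to slides sharing the sample's task label. Labels are
  slide-constant, so the global slide partition *contains* the label
  partition: an unconditional adversary provably attacks the task signal
  itself (we observed inverted validation AUCs). Restricting the game to
  within-label-group decodability — staining idiosyncrasies, scanner hue —
  protects the label structurally.
* **Chance-level gating.** Pressure is applied only while the head beats
  within-group chance ln(N_y), with a linear ramp to zero over the last
  0.1 nats. The goal is a chance-level head; pushing beyond it has no
  information-theoretic meaning and empirically diverges (confounder CE
  growing without bound through representation-norm games).
* **α = 3, λ = 1, no warm-up.** α and λ are not identifiable separately in
  this formulation (both scale the reversed gradient); λ stays at 1 and α
  sets the pressure. The value 3 makes suppression decisive within a
  10-epoch desk-scale budget. A linear λ warm-up is available
  (`lambda_warmup_frac`) but off by default: early suppression prevents
  the shortcut from entrenching.

## Optimization recipe

Adam (β₁ = 0.9, β₂ = 0.999) with decoupled weight decay 0.01 on weight
matrices; cosine learning-rate schedule
`lr(t) = lr_min + ½(lr_max − lr_min)(1 + cos πt)` from 6·10⁻⁴ to 6·10⁻⁶
across the run (20 epochs at production scale; shorter in the bundled
benchmarks); batches of 32 patches sampled with replacement from one
slide; augmentation by k·90° rotation (k uniform) then horizontal flip
with probability 0.5. An "epoch" is a pass over the training slides with
⌈patches/32⌉ batches per slide — a schedule unit, not an exact data pass,
since sampling is with replacement. The checkpoint with the best
validation patient-level AUC is kept. One RNG stream per concern
(sampling, augmentation, initialization), all derived from the config
seed, makes single-threaded runs bit-reproducible.

## The bundled backbone

No deep-learning runtime is a dependency: the classifier stack is a
compact CNN implemented directly on numpy arrays with explicit
forward/backward passes — three 3×3 stride-2 convolutions (8, 16, 32
channels, im2col with index-precomputed scatter for the backward pass),
global average pooling, and a dense layer to a 32-dimensional
representation feeding the task and confounder heads. It trains in
seconds per epoch on CPU at 64 px patches. A production-scale backbone
(e.g. an EfficientNet-class network) would slot in behind the same
`BackboneSpec` interface; nothing in the pipeline logic depends on the
backbone's size.

## Preprocessing

* Foreground: HSV saturation after a 3-px box blur, threshold 0.07 —
  stained tissue is strongly saturated, glass is not.
* Resampling: area averaging for integer magnification ratios, anti-aliased
  bilinear otherwise; `microns_per_pixel` scales with the ratio.
* Tiling: non-overlapping by default (stride = patch size), row-major,
  0-based (x, y) top-left coordinates, partial edge tiles dropped, tiles
  kept when mask coverage ≥ 0.5.
* Stain normalization: Macenko. Optical density OD = −ln((I+1)/256); pixels
  with ‖OD‖ > 0.15 are projected onto their top-2 principal plane; the 1st
  and 99th percentile angular directions give the two stain vectors
  (hematoxylin = the blue-heavier column); concentrations come from a
  non-negative least-squares deconvolution and are rescaled by the ratio of
  99th-percentile maxima before recomposition in the target basis. A
  Reinhard LAB-statistics matcher is included as a lighter alternative.

## Biomarker and statistics

* TMB ground truth: high iff raw value ≥ cutoff; 206 in exome-count mode,
  10 mut/Mb in panel mode. The boundary is inclusive in both modes.
* Tumor filter: keep a patch iff (1 − p_normal) ≥ τ (default 0.5) **and**
  its argmax class matches the slide's histology.
* Aggregation: plain median (even counts: mean of the central pair); all
  tumor patches of a patient's slides pooled into one bag. A
  slide-then-patient median is a trivial variant but pooling is the
  default.
* Youden cutoff: candidates are midpoints between adjacent distinct scores
  plus ∓∞ sentinels; ties break towards the larger cutoff (higher
  specificity); patients at or above the cutoff are called high.
* Bootstrap: percentile intervals, resampling patients (score and label
  jointly); endpoints are nearest-rank order statistics — with B replicates
  and tail mass a, the lower endpoint is replicate ⌈aB⌉ and the upper
  ⌈(1−a)B⌉ (1-based). Replicates on which the statistic is undefined
  (e.g. one-class AUC) are redrawn and counted.
* Survival: Kaplan–Meier product-limit curves per PITER group and the
  two-group log-rank test (the standard companion of KM stratification),
  both via lifelines. Multivariable Cox adjustment is deliberately left to
  standard survival packages and is not part of the tested core.
* Heatmaps: grid cell (y/patch, x/patch) holds the mean TMB-high
  probability of the patches that land there (overlaps averaged with a
  warning); missing cells are NaN; rendered with the viridis map so
  high-probability regions appear yellow.

## The synthetic cohort generator

The generator emulates exactly the structure the method needs and nothing
more:

* **Texture signal** — nuclei as Gaussian-profile ellipses on a noisy pink
  background. TMB-high patients get up to +150% nucleus density and +50%
  radius at `signal_strength` = 1, making the morphological signal
  genuinely informative at the single-patch level (connected-component
  counting gives an independent oracle for its presence).
* **Confound** — one additive RGB shift per slide: a signed base direction
  whose sign correlates with the patient label at `confound_label_corr`
  (configurable per split), plus per-slide random jitter. Mean patch
  colour therefore identifies the slide — the shortcut AdvCS must remove.
* **Structure** — patients carry latent labels at `tmb_prevalence`
  (optionally exactly balanced, with label-stratified splits); multiple
  slides per patient; optional exponential survival times tied to the
  label; deterministic, bit-identical output for a fixed config and seed.

What it does **not** emulate: real nuclear morphology and texture
heterogeneity, within-slide staining gradients, scanner optics, tissue
artefacts (folds, pen marks), or any LUSC-specific morphology. Passing
benchmarks here demonstrates that the pipeline's mechanics are correct —
that adversarial suppression removes a slide-level colour confound and
recovers a genuine texture signal — not that the full-scale clinical
performance of a production system would be reproduced.

### Why the sign of the confound limits what AdvCS can do

With the sign construction, the confound contains a slide-level *binary*
partition that is 90%-aligned with the label partition at correlation 0.9.
Slide-ID suppression cannot distinguish that bit from the label bit — both
are slide-constant binary partitions — so the mechanism can only shift the
model to morphology if morphology is at least as informative per patch as
the sign. The generator's texture effect is sized accordingly, and the
conditional adversary concentrates suppression on what *is* removable: the
graded, slide-specific component (jitter and magnitude) that enables slide
memorization.

## Benchmark problem sizes

The bundled benchmarks are sized for a single CPU core: the mechanism
experiment uses 10 training patients (20 slides × 50 patches of 64 px,
confound–label correlation 0.9 in training, 0 in validation) with a
40-patient balanced validation arm for a stable AUC readout, 10 epochs;
signal recovery uses 80 patients (half validation), one slide each, 30
patches, no confound. Bootstrap calibration uses B = 2,000 over 500
simulations. These sizes are the package's reference conditions; all are
plain configuration parameters.

## Known limitations

* The numpy backbone is intentionally small; it demonstrates mechanism,
  not state-of-the-art patch accuracy.
* The adversary is linear (as is the probe that audits it); a nonlinear
  confounder readout could in principle survive suppression.
* Best-checkpoint selection needs a validation split with both classes;
  without one the final model is simply the last epoch's.
* The generator's confound is purely additive in RGB; multiplicative or
  spatially varying stain effects are not modelled (stain normalization
  addresses those upstream on real slides).
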