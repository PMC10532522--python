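# Methods

## Overview

`cardioseg` treats heart-enlargement segmentation as per-pixel
classification on frozen convolutional features. The pipeline has four
stages: (1) canonicalize images to 224×224×3 in [0,1]; (2) apply a fixed
bank of 64 3×3×3 kernels (stride 1, zero same-padding, rectifier) to get
a 224×224×64 feature map; (3) classify each pixel's 64-vector with a
three-member voting ensemble into {0 background, 1 heart tissue,
2 enlarged region}; (4) post-process class 2 into a binary mask, an
overlay, and a subject-level diagnosis. Nothing in the feature extractor
is trained — only the pixel classifiers are fit — which is what keeps the
model CPU-friendly and fully deterministic.

## Feature extraction

"Convolution" is implemented as cross-correlation (no kernel flip), the
convention of the networks the filter bank mimics; for seeded random
kernels the two conventions are statistically indistinguishable. The
canonical filter bank is `seeded_random` (default seed 42): kernel
entries drawn from N(0, 1/fan_in) with fan_in = 27, biases zero. A
`pretrained_vgg_block1` provenance loads the first convolutional layer of
a VGG-16 from a local `.npz` file (`kernels` 3×3×3×64, `biases` 64); no
network access is ever performed by the library. Random features through
a rectifier are a standard random-projection representation: they
preserve local intensity/edge structure, which is all the intensity-coded
phantom classes need. Features stay at full 224×224 resolution so the
classifier output is directly a segmentation; the 8×8 frame tiling is a
lossless partition of that map used to assemble training batches, not a
downsampling step.

## Ensemble members and voting

* **Gaussian NB** (hand-written): per class/feature mean and *population*
  standard deviation (divisor n), priors = class frequencies. Standard
  deviations are clamped to `sd_floor` (default 1e-6) so constant
  features cannot produce degenerate densities. Posteriors are evaluated
  in log space and normalized with log-sum-exp; a direct product oracle
  and scikit-learn's GaussianNB serve as cross-checks in the tests.
* **Random forest** (scikit-learn backed): bootstrap sampling,
  `⌊log2 M⌋+1` features per split (7 for M=64), probabilities = mean of
  per-tree class responses. Default 25 trees.
* **Boosted trees** (xgboost backed, `tree_method="hist"`, one thread):
  logistic loss with second-order updates, leaf weight `−G/(H+λ)`,
  defaults λ=1, γ=0, 30 rounds, learning rate 0.3, depth ≤ 6, base score
  0.5. With three classes the softmax multi-class objective is used — the
  same regularized tree machinery, chosen over a one-vs-rest scheme
  because it is the canonical multi-class form of this booster. The
  closed-form single-leaf weight and the monotone decrease of the
  training loss over rounds are asserted in the tests.

Voting supports `hard` (mode), `weighted` (argmax of weighted indicator
sums) and `soft` (argmax of the weighted mean of member probabilities).
Soft with uniform weights is the default: all three members expose
calibrated-ish probabilities, and soft voting uses them without needing a
tie-break among three discrete votes in most cases. All ties break to the
lowest class index in the fixed class order. A fourth member slot is
deliberately not populated.

## Synthetic phantom cohort

The generator emulates a chest-CT cohort in which the cardiothoracic
ratio (CTR = heart width / thorax width) separates diagnoses at 0.5. Each
subject is a mid-gray thorax ellipse (intensity 0.45 on a 0.10
background) containing a bright heart ellipse (0.80) whose horizontal
extent is CTR × the thorax extent; enlarged subjects (CTR ≥ 0.5,
default draw U[0.55, 0.70]) additionally carry a brighter central core
(0.95) labelled class 2 at 70 % of the heart's semi-axes, while healthy
subjects (CTR drawn U[0.35, 0.45]) contain no class-2 pixels at all.
The distinct core intensity is a deliberate design choice: it makes the
enlarged class separable from heart tissue by local pixel evidence, so
the pipeline's *correctness* is testable end to end. Additive Gaussian
intensity noise (default sd 0.02, clipped to [0,1]) is the only
stochastic image component; every phantom is bit-reproducible from its
seed, and cohorts derive per-subject seeds and CTRs from a single master
seed. The default cohort is 20 subjects, 11 enlarged / 9 healthy.

What the phantoms do **not** emulate: anatomical texture, partial-volume
effects, scanner artifacts, inter-subject anatomy variation, or labels
with annotator noise. Passing the recovery experiment therefore shows the
machinery is implemented correctly and recovers a signal it can represent
— it says nothing about clinical accuracy on real CT, which would require
real data and labels.

## Pipeline and evaluation choices

* Train/test splits are always by subject, never by pixel, to avoid
  leakage; `stratified_split` keeps both diagnoses represented in the
  test set.
* Flip augmentation (horizontal + vertical, image and mask in lockstep)
  is applied to training subjects only. The two flips are kept as
  separate augmentations; a combined 180° rotation is not added.
* Training pixels are subsampled per subject (default 4 000, stratified
  by class across the three augmented variants) — the phantom classes are
  large and homogeneous, so a few thousand pixels per subject saturate
  the members while keeping training fast on one CPU.
* The binary mask is the class-2 indicator with 4-connected components
  smaller than `min_region_px` (default 25) removed; a subject is
  diagnosed enlarged iff any pixel survives. Raising `min_region_px`
  can only remove pixels (monotonicity is tested).
* Pixel-level sensitivity/specificity use class 2 as the positive class.
  For subjects whose truth contains no class-2 pixels, sensitivity is
  undefined and reported as NaN; cohort summaries average over the
  subjects where a metric is defined (plain unweighted means otherwise).
* Dice: binary mode scores the class-1 sets of two-class masks; macro
  mode averages per-class binary Dice over the classes present in either
  mask, so healthy subjects are not penalized for an absent enlarged
  class. Empty-vs-empty Dice is defined as 1.0 (predicting "nothing"
  for a subject with nothing is correct).
* ROC curves sweep every unique score as a threshold (ties grouped);
  AUC is the trapezoidal area, which equals the Mann–Whitney pairwise
  statistic — the identity is asserted in the tests.
* Mask PNGs use the gray dialect {0, 128, 255} (three-class) or
  {0, 255} (two-class) with a ±32 decoding tolerance band; images are
  resized bilinearly, masks with nearest-neighbor so labels survive.
  DICOM reading applies RescaleSlope/Intercept when present and then
  per-image min-max scaling; no Hounsfield windowing is applied.
  Overlays paint the enlarged region opaque red.

## Determinism and numerics

Every stochastic component (phantom noise, CTR draws, pixel subsampling,
the random filter bank, forest bootstraps, booster) is seeded from the
configuration; the forest and booster run single-threaded, so two runs
with the same config produce bit-identical masks, reports and model
archives (tested). NB posteriors are stable down to ~1e-300 likelihoods
thanks to the log-space evaluation; the only guarded degeneracies are
constant features (`sd_floor`), empty masks (Dice = 1 for empty-vs-empty)
and undefined metric denominators (explicit errors or NaN, never silent
zeros).

## Problem sizes

The recovery experiment used in the tests and in
`scripts/acceptance.py` — 20 subjects (≈ 1 M labeled pixels, subsampled
to ≈ 48 k training rows), train 12 / test 8 — is the package's chosen
desk-scale study: it is large enough that all three members see every
class in every intensity regime, and small enough to run in well under a
minute on one CPU. Unit tests use 4–6-subject cohorts and reduced member
sizes for speed.

## Known limitations

* Random frozen features are weaker than pretrained ones on real CT;
  the pretrained provenance exists but ships without weights.
* The phantom geometry is two ellipses; no claim of anatomical realism.
* Member probabilities are not calibrated; soft voting treats them as
  comparable.
* Multi-frame DICOM series and Hounsfield windowing are out of scope.
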