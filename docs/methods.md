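# Methods

`noisyvision` is a desk-scale pipeline for stress-testing visual recognition
systems with noisy object images. Everything runs on a single CPU in minutes,
on synthetic inputs with known ground truth, so that every analysis stage can
be validated by parameter-recovery and closed-form oracles before it is
pointed at real data.

## SSNR stimuli

Noisy stimuli are parameterised by the signal-to-signal-plus-noise ratio
(SSNR) `w ∈ [0, 1]`:

    T = w·S + (1 − w)·N

where `S` is the source image and `N` a noise field. Unlike conventional
SNR, SSNR is bounded: `w = 0` is pure noise, `w = 1` the clean image.

Two noise families are implemented.

* **Pixelated Gaussian noise**: each pixel i.i.d. `Normal(127.5, 255/6)`, so
  the 0–255 intensity range spans ±3 SD. Fields are generated unclipped;
  intensities are clipped into [0, 255] once, *after* blending. Clipping is
  modest (≈0.3% of pixels at `w = 0`).
* **Fourier phase-scrambled noise**: a target amplitude spectrum (by default
  the mean spectrum of the image set, close to 1/f) is combined with random
  phases. Phases are taken from the Fourier transform of a real white-noise
  carrier, which guarantees Hermitian symmetry — including real-valued
  Nyquist bins on even-sized canvases — so the inverse transform is real to
  machine precision. The DC phase is fixed at 0 and the real part is shifted
  to mean 127.5 with no variance rescaling: the off-DC amplitude spectrum of
  the output equals the input exactly, and intensity scale is carried
  entirely by the supplied spectrum.

A useful closed form for validation: for independent, equal-variance `S` and
`N`, the correlation between the blend and the signal is
`r(w) = w / sqrt(w² + (1−w)²)`, which crosses 0.5 at `w = 1/(1+√3) ≈ 0.366`.
The susceptibility analyses must reproduce this number on an identity
"network", and do (test suite and acceptance script).

## Synthetic data generators

The generators define the study conditions; their defaults are fixed and the
recovery tests are run against them.

* **Images** (`generate_image_dataset`): K parametric shape families (blob,
  bars, ring, cross, wedge, checker) drawn on a 64×64 canvas with jittered
  position (±5% of canvas), size (22–30% of canvas), orientation (0–30°),
  foreground/background intensity, and mild pixel texture. Jitter is kept
  modest so that raw pixels remain linearly informative (a logistic
  regression on clean pixels exceeds 80% at K = 4 — a floor guaranteeing the
  categories are separable at all). Every image carries its foreground mask,
  from which ground-truth diagnostic maps are derived (mask eroded to its
  core, smoothed with a 15-pixel-diameter disc emulating the thick
  annotation pen).
* **Observers** (`ObserverModel`): accuracy follows a 4-parameter psychometric
  law with guess rate 1/K, lapse rate 0.02, slope 20 (SSNR⁻¹ units), and a
  per-image midpoint `t_img`. Errors are drawn from a two-cluster
  confusability matrix (within-cluster confusions 1.5× as likely),
  emulating the animate/inanimate confusion structure of real observers. In
  the ascending design the ramp stops at the first step-grid level above
  `t_img` plus Gaussian decision noise (SD 0.05 SSNR, configurable) — the
  simplest stopping rule that yields threshold-correlated stop levels. Its
  expectation has a known form (quantisation bias ≈ half a step plus the
  truncated-Gaussian term), which the tests integrate numerically.
* **Voxel patterns** (`simulate_voxel_patterns`): responses are a fixed random
  linear readout of a chosen network layer, standardized, scaled by `snr`,
  plus unit-SD run-specific Gaussian noise; every run contains every
  stimulus exactly once. The readout is centered per voxel across stimuli —
  amplitudes are deviations from each voxel's baseline — which also keeps the
  optional synthetic time series (baseline 100, boxcar over the response
  window, 4 s stimulus + 6 s rest at TR 2 s) consistent with the direct
  path: percent signal change is computed relative to the run mean, so any
  per-voxel mean response would otherwise leak into the baseline. The
  dual-path consistency test exploits this: amplitudes extracted from the
  time series match the directly generated ones to a few percent after
  per-run centering.

## Network and training

The vision model is a small configurable CNN in numpy: B conv(3×3)+ReLU
blocks each followed by 2×2 max-pooling (default channels 8-16-16-32, canvas
64), two fully connected layers, and a softmax output. The early pooling
stage means representations from block 2 onward pool over space, preserving
the layer taxonomy the analyses address (conv after rectification → FC →
softmax). Implementing the network in numpy keeps the forward, backward, and
relevance-propagation passes under one roof and makes the LRP rules exact
rather than wrapped around an autodiff framework.

Training is minibatch SGD with momentum 0.9, weight decay 5e-4, batch 24
under the multinomial logistic loss. `TrainConfig.paper_protocol()` exposes
the fine-tuning schedule (learning rate 0.001, 20 epochs) appropriate when
starting from pretrained weights; the from-scratch default uses learning
rate 0.01, and the directional analyses train for 30 epochs because the
mixed clean/noise stream halves the effective number of clean samples and
20 epochs leaves that condition short of its clean-accuracy plateau.

The augmentation pipeline crops a random rectangle covering 87.5% of the
image's linear extent with aspect ratio uniform in [2/3, 3/2], resizes to
the canvas, and adds a per-image intensity offset `Normal(0, 3)`. SSNR
blending is applied after augmentation. Input standardisation (mean and SD
of the augmented, blended training stream, estimated once from 200 stream
samples and frozen) happens last. Standardising by SD as well as mean is a
deliberate departure from mean-only subtraction: a network trained from
random initialisation needs unit-scale inputs, whereas mean-only subtraction
presumes a model already trained at raw intensity scale.

Noise-mix specifications are per-sample stochastic: each training sample
draws its condition (clean / Gaussian / phase-scrambled) from the stated
proportions and, for noisy conditions, an SSNR level uniformly from the
stated range (0.2–0.99 for the standard noise-training recipe) or level set.

## Psychometrics

Accuracy- (or correlation-) by-SSNR curves are fitted with a 4-parameter
logistic `f(w) = L + (U−L)/(1+exp(−k(w−m)))` by bounded nonlinear least
squares on the per-level values (not a binomial likelihood), with 5
multi-start initialisations from a fixed restart seed and tolerances 1e-10.
The lower asymptote is bounded to [0, 1/K + 0.2] when the guess rate is
known. Thresholds are the analytic inversion of the fitted curve at the
stated criterion (50% for aggregate curves, 90% for per-image model
thresholds, r = 0.5 for layer susceptibility); a threshold is invalid when
the criterion lies outside (L, U) or the crossing falls outside [0, 1] —
this implements the exclusion of images whose curve never reaches the
criterion. Per-image analyses additionally exclude images of the category
the model gives as its modal response to pure noise.

Split-half reliability repeatedly halves the observer set (10,000 splits by
default), correlates per-image mean thresholds between halves, and reports
the mean and SD; with additive i.i.d. observer noise the expected value is
the Spearman–Brown form `σ_s²/(σ_s² + 2σ_n²/n)`, which the tests verify.
Two independent correlations are compared by the Fisher z statistic
`z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))` with a two-sided normal
p-value; the type-I error of this test is calibrated by simulation.

## Layer analyses

*Correlation-based susceptibility*: per layer, the Pearson correlation
between activation patterns for a clean image and the same image at SSNR `w`,
averaged over images and noise draws per level. Curves whose floor at
SSNR ≈ 0 is above zero are linearly rescaled to span [0, 1] before the
logistic fit (levels should therefore include values near 0 and 1). Layers
above 50,000 units are subsampled with a fixed seed; Pearson r is stable
under coordinate subsampling, and thresholds are invariant to per-layer
affine rescaling of activations.

*Classification-based susceptibility*: a linear one-vs-one SVM (C = 1)
per layer, trained on clean-image activations standardized by the clean
training statistics, tested at each SSNR level; threshold at 50% accuracy.

*Slopes*: OLS of threshold against 1-based layer index over valid layers;
flat profiles return slope 0 with p = 1 and a zero-variance flag.

*Weight CCA*: a layer's weights are reshaped to (units × flattened incoming
weights); canonical correlations are computed with units as the canonical
variables and incoming-weight coordinates as observations, making the
similarity invariant to any invertible mixing of the unit axis (the
transformations that leave a network's function unchanged up to relabeling).
Whitening is done in the SVD basis with an `rcond` singular-value cutoff
rather than a ridge: this is exact for full-rank weight matrices (self- and
unit-mixed similarity equal 1 to machine precision) and degrades gracefully
to min(rank_a, rank_b) components when rank-deficient. The null level for
independent weights scales like √(units/features), so the measure is most
informative when a layer has more incoming weights than units — true for
all conv layers past the first in practice.

## Relevance propagation

Relevance is seeded at the softmax unit of the target class and propagated
backward. For a linear step `z_j = Σ_i x_i w_ij (+ b_j)` the basic rule
assigns `R_i = Σ_j (x_i w_ij / z_j) R_j`; the composite schedule uses, with
depth: z-beta at the input layer (relevance respects the feasible input
range [l, h] of the standardized input, by default the model's own (0−μ)/σ
and (255−μ)/σ), gamma (positively boosted weights `w + γ·max(w,0)`, γ = 0.05)
in the first ≈40% of remaining layers, epsilon (sign-matched stabiliser
`z + ε·sign(z)`, ε = 0.25) in the next ≈35%, and the basic rule in the final
≈25%. At depth 19 this fractional mapping reproduces the composite
assignment published for VGG-19 exactly (z-beta 1, gamma 2–8, epsilon 9–14,
basic 15–19). Convolutions are handled as linear maps over im2col patches
with relevance scattered back through the patch adjoint; max-pooling routes
relevance to the pooling winner; rectification is pass-through. Biases enter
the denominator but receive no back-distributed relevance, so conservation
(sum of input relevances = seeded relevance) is exact only on bias-free
networks — verified to 1e-5 there, and the vectorised implementation matches
an explicit per-unit double loop to 1e-6. Negative pixel relevances are
zeroed and the map rescaled to [0, 1] only at the very end, which also makes
maps invariant to positive rescaling of the seed.

Model maps are compared to (ground-truth or human-style) diagnostic maps by
spatial Pearson correlation and intersection-over-union overlap after
binarisation (0.5 for the thick-penned human-style maps, 0.2 for model maps,
which are first blurred with a σ = 3 px Gaussian to compensate for pen
thickness). The binned comparison samples one image per category per bin,
without replacement across bins while images last.

## Neural analyses

Voxel time series are converted to percent signal change relative to the run
mean per voxel; the stimulus amplitude is the mean of TRs 3–5 post-onset
(1-based inclusive, i.e. array offsets +2…+4 from the onset TR), and
amplitudes are then z-normalized per run (overall mean 0, SD 1). Decoding is
a linear one-vs-one SVM (C = 1) under leave-one-run-out cross-validation;
training uses only the training condition's trials from held-in runs — strict
run separation even when training and testing conditions differ — and folds
whose training set misses a category are skipped. Subjects are included when
mean V1 accuracy across the three viewing conditions reaches 20% (chance
12.5% at 8 categories); the boundary case 0.20 includes.

RDMs are pairwise Pearson correlations between row patterns (zero-variance
patterns flagged NaN); two RDMs are compared by the Pearson correlation of
their off-diagonal upper triangles, reported with its Fisher z. Group
statistics Fisher-z-transform per-subject RSA correlations and run two-sided
one-sample (or paired) t tests per layer, flagging p < 0.01 uncorrected;
zero-variance layers are flagged instead of producing infinite t.

Chance calibration of permuted-label decoding uses labels drawn i.i.d.
uniform. A global permutation of the label vector is deliberately *not*
used: sampling without replacement makes the held-out run's labels
anti-correlated with the training majority and biases the "null" accuracy
below 1/K.

## Study conditions for the directional suite

The headline noise-training effects are replicated directionally at desk
scale on synthetic shapes: 6 categories, 50 training and 25 test images per
category, canvas 64, 30 epochs. Six categories (rather than the unit-test
default of 4) keep the discrimination fine-grained: with too few, easily
separable categories even a clean-trained network's deep layers encode a
noise-robust decision variable and the layer-susceptibility contrast between
standard and noise-trained networks has no room to express itself, exactly
as near-ceiling performance would mask the effect in a behavioural
experiment. Under these conditions:

* a network trained on the clean + Gaussian-noise mix (SSNR 0.2–0.99) has a
  much lower 50% SSNR threshold than its clean-trained twin;
* training *only* at SSNR 0.2 collapses clean-image accuracy, while the
  clean + SSNR-0.2 mix preserves it and improves accuracy at SSNR 0.2;
* the noise-trained network's layer-susceptibility slope is negative
  (denoising across depth) while the clean-trained slope is near zero or
  positive, and the threshold gap between the two is larger in the deepest
  third of layers than the first third.

Layer-level slope and gap statements are evaluated on the mean over three
independently trained model pairs: at this scale the direction holds for
most but not every individual training run (~3 in 4 in our scans), and the
claims concern the training procedure, not one lucky initialisation. The
accuracy and threshold effects are large enough to assert per run.

## What passing tests do and do not show

The generators emulate the *structure* of the real inputs — psychometric
trial tables, run-structured voxel matrices, diagnostic maps — not their
content: parametric shapes are far easier than ImageNet photographs, the
simulated observer has no attention lapses beyond a constant rate, voxel
noise is Gaussian and run-homogeneous with no spatial autocorrelation or
drift, and the "neural" patterns are by construction linear readouts of a
network layer. Passing the recovery suites therefore shows the analysis
stages are correct and calibrated, and that the training effects replicate
directionally at small scale; it does not certify the absolute thresholds,
slopes, or RSA values that full-scale photographic stimuli, human observers,
and 7 T recordings would produce.

Known limitations: the SmallCNN is far shallower than the networks whose
layer taxonomy it mirrors (7 analysis layers vs 19); phase-scrambled and
Gaussian noise are not contrast-matched (by design); the 4PL fit on
proportion-correct data ignores binomial heteroscedasticity; and weight CCA
on the first conv layer has few observations per unit (9 incoming weights),
so its null is weak there.
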