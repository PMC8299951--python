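# Methods

This note documents the models, algorithms and design choices behind
`habitat-tex`: a pipeline that partitions a breast lesion on dynamic
contrast-enhanced (DCE) MRI into kinetic habitats, extracts masked texture
features from each habitat, and asks whether habitat-restricted radiomic
models discriminate benign from malignant lesions better than a
whole-tumor model.

## The analysis protocol

Each patient contributes a single-slice dynamic series: one pre-contrast
frame `I(·, t0)` and eight post-contrast frames `I(·, t)`, `t = 1..8`.
The pipeline runs six stages.

**1. Subtraction.** Eight subtraction images `post_t − pre` isolate
enhancement. All later image processing happens on the 4th-phase
subtraction image, the phase at which both early- and late-peaking tissue
is substantially enhanced.

**2. ROI normalization and quantization.** The operator's region of
interest (in the synthetic pipeline: the truth bounding box dilated by
10 px, standing in for a hand-drawn ROI) is normalized to the window
μ ± 3σ of its gray levels, mapped linearly onto [0, 255] and rounded
half-up to 8-bit integers. The recorded (μ, σ) reproduce the mapping
exactly; a zero-spread ROI is a hard error.

**3. Lesion segmentation.** A spatial fuzzy C-means clustering of the
quantized gray levels delineates the lesion: standard FCM updates
(fuzziness m = 2, two clusters, centroids initialized at 64 and 192),
with each membership map smoothed by a 3×3 mean filter per iteration;
convergence when the largest membership change falls below 1e−5 (cap 100
iterations, warning on non-convergence). The lesion is the
brightest-centroid cluster, refined by keeping the largest 4-connected
component, filling holes and opening with a 3×3 cross. The deterministic
initialization removes run-to-run variance; any published spatial-FCM
variant would satisfy the same contract.

**4. Kinetic habitat partition.** Pixelwise relative enhancement

    H(m, n, t) = (I(m, n, t) − I(m, n, t0)) / max(I(m, n, t0), 1)

(the 1-gray-level floor keeps the ratio finite near zero baseline) and
time to peak `TTP(m, n) = argmin{t : H is maximal}` (earliest phase on
ties, keeping "time to peak" minimal). Lesion pixels with TTP in phases
1–4 form the *early* habitat, 5–6 *moderate*, 7–8 *late*; the three zones
partition the mask exactly and may be empty.

**5. Texture extraction — 467 features per region.** For each of the
four regions (whole lesion + three habitats), on the quantized phase-4
subtraction patch:

| family    | layout                                                        | count |
|-----------|---------------------------------------------------------------|------|
| histogram | mean, variance, skewness, kurtosis (population moments)       | 4    |
| GLCM      | 19 statistics × (4 angles × 4 distances + 4 angle-averaged)   | 380  |
| GRLM      | 11 run-length statistics × 4 angles, distance 1               | 44   |
| DWT       | 3 wavelets × (4 scales × 3 orientations + scale-4 approx.)    | 39   |

Co-occurrence pairs count only when both pixels lie in the region mask
(symmetric, normalized); runs truncate at mask boundaries. Gray levels
default to the full 256 quantized values (configurable). The 19 GLCM
statistics are the standard Haralick/Soh/Clausi set with 1-based gray
values, natural-log entropies and 0·log 0 ≡ 0; the GLCM block counts
both the 16 directional matrices and the angle-averaged matrix at each
distance (19 × 20 = 380 — the only enumeration consistent with the
canonical four angles, four distances and a 380 total). Run-length
low/high gray emphasis uses value+1 to keep level 0 finite; "fraction of
image in runs" is the run count divided by region pixels. Wavelet
features are the mean absolute coefficient of each detail subband of a
4-level decomposition (Haar, Daubechies-2, Symlet-4; symmetric extension)
on the mean-filled, zero-padded bounding-box patch, plus the scale-4
approximation subband. An empty habitat yields an all-NaN vector flagged
as missing.

**6. Modeling and evaluation.** Per region, on training-cohort rows
only: zero-variance and pairwise-correlated features (|Pearson r| > 0.95;
the later feature in canonical order drops) are removed; an L1-penalized
logistic path selects features at the penalty minimizing 10-fold
cross-validated deviance (CV-minimum, not 1-SE — consistent with
moderately sized selected sets); a CART tree (Gini, cost-complexity
pruning chosen by inner 10-fold CV) and an RBF-kernel SVM (C ∈ {0.1, 1,
10, 100}, γ ∈ {1/p, 0.01, 0.1, 1}, inner 10-fold CV) are tuned and refit
on all training rows. Continuous scores are leaf class-1 probability
(tree) and signed decision values (SVM). Training ROC is reported both
from pooled out-of-fold CV scores and from refit-on-train scores,
labeled; the operating threshold maximizes the Youden index on training
refit scores and is carried unchanged to validation (the leakage-free
choice). AUCs carry DeLong standard errors and normal 95% CIs; paired
model comparisons use the two-sided DeLong z-test on common patients;
selected features get a Lilliefors-corrected Kolmogorov–Smirnov normality
screen deciding mean±SD vs median±IQR summaries. No multiple-testing
correction is applied (flagged as a caveat in the report). ICC(2,1)
(two-way random effects, absolute agreement, single measures) is provided
for inter-reader feature reproducibility.

Patients with an empty habitat are excluded from that habitat's model
only; features undefined for any training patient of a region (e.g. no
valid co-occurrence pair at a long offset inside a small zone) are
dropped from that region's model, and validation patients still carrying
undefined values are excluded from that zone's evaluation. All exclusions
are bookkept in the report.

## The synthetic cohort generator

No public imaging accompanies the underlying clinical protocol, so the
package ships a generator whose defaults define the study conditions.
Lesions are irregular noise-perturbed ellipses (1–25% of a 128×128
frame, single 4-connected component). Each lesion pixel receives a true
TTP phase drawn iid from a class-conditional mixture, then follows a
piecewise-linear rise to its peak relative enhancement exactly at that
phase and geometric washout after it — the simplest curve family that
makes the argmax identifiable. Background tissue is a smooth baseline
with no systematic enhancement; all frames carry additive Gaussian noise
(SD 8 gray levels). With zero noise the computed TTP equals the injected
TTP on every lesion pixel, which the tests assert exactly.

Two class differences are planted:

* **kinetics** — malignant mixtures lean early (phase 1–4 mass 0.59 vs
  0.43) and wash out faster (rate 0.16 vs 0.12);
* **texture** — a Gaussian random field modulates each pixel's peak
  enhancement, with *correlation length* as the class knob in the early
  and late habitats (malignant ≈ 1 px vs benign ≈ 2.2 px) and amplitude
  identical across classes and zones, so the signal is spatial structure
  rather than gray-level spread.

Between-patient heterogeneity keeps the classes overlapping the way a
clinical cohort does: per-patient Dirichlet jitter of the TTP mixture
(concentration 14), truncated-normal washout jitter (SD 0.04), mild
lognormal jitter of the early/late correlation lengths, and — crucially —
a strongly variable moderate-zone correlation length with *identical*
distribution in both classes. Whole-tumor statistics mix this nuisance
with the habitat signal, while zone-restricted features do not; this is
the mechanism by which habitat models outperform the whole-tumor model,
and the moderate-habitat model is weakest — the qualitative structure
the analysis is designed to detect. Scenario presets: `default` (above),
`strong` (larger texture contrast), `null` (identical classes; every
downstream model must sit at chance). The validation cohort is generated
with a 1.08 global intensity gain as a scanner surrogate; cohort
membership is by tag, never random.

What the generator does **not** emulate: spatially contiguous habitats
(iid TTP assignment gives speckled zones, chosen so class-conditional TTP
histograms are exactly multinomial and testable by χ² goodness of fit),
MR acquisition physics (coil profiles, k-space artifacts), 3D anatomy,
rim-enhancement morphology, and washout-type curve taxonomies. Passing
tests therefore show the pipeline recovers planted kinetic/textural
structure under realistic noise and nuisance variation — not that it
reproduces clinical effect sizes, which depend on unavailable patient
data.

## Numerical and reproducibility choices

* Rounding in quantization is half-up, fixed for bit-exact tests.
* Entropies: natural log, 0·log 0 ≡ 0. Degenerate zero-variance GLCM
  reports correlation 1 (a single repeated pair is perfectly
  correlated); zero-variance regions report skewness = kurtosis = 0.
* Youden ties resolve to the lowest threshold; a constant score vector
  degenerates to calling everything positive.
* DeLong: structural-components variance; identical score vectors give
  p = 1; CIs clip to [0, 1]. Its type-I error at α = 0.05 is verified by
  Monte-Carlo (2000 null replicates) to lie in [0.035, 0.065].
* Every random draw descends from one config seed through named
  `SeedSequence` substreams (cohorts, folds, solvers); the report hash is
  identical across runs, and NPZ cohort bundles are byte-identical.
* An empty LASSO selection is legal (flagged): the model emits a constant
  score, i.e. chance-level ROC, keeping the 8-model report complete under
  the null scenario.

## Problem sizes

The shipped configuration mirrors a two-scanner clinical layout: 84
benign + 125 malignant training and 40 + 50 validation patients on
128×128 frames, 256 gray levels, 10-fold CV. The test suite and the
acceptance script run this end to end (several minutes on one core);
sub-sampled configurations used in unit tests keep the same structure at
smaller n and fold counts.

## Known limitations

* Speckled (non-contiguous) habitats under-populate long-offset
  co-occurrence pairs in small zones; the affected features are dropped
  per-region rather than imputed.
* The 380-feature GLCM enumeration is a reconstruction from the canonical
  angle/distance sets and the printed family total; other enumerations
  (e.g. distance-averaged) would be defensible.
* Training-cohort ROC from pooled CV scores and from refit scores differ
  (the refit is optimistic); both are reported and labeled rather than
  adjudicated.
* The DeLong normal approximation is asymptotic; at very small cohort
  sizes its CIs are approximate.
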