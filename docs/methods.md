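# Methods

`stromaquant` re-creates, on fully synthetic data, the analysis chain that
turns hematoxylin–eosin whole-slide images into a prognostic biomarker:
tile-level tissue classification, quantification of the mixed
tumor–stroma ratio (MTSR), and the downstream survival-evaluation stack.
This note documents the models, the choices that were genuinely open, and
what the synthetic benchmark does and does not demonstrate.

## Synthetic imagery

Real bladder-cancer slides are access-restricted and orders of magnitude
too large for a test suite, so slides and patches are fabricated with
exact ground truth.

**Texture palette.** Ten classes — background plus nine tissue types
(adipose, burn/deformation, inflammatory, mixed tumor–stroma, muscle,
necrosis, stroma, tumor, vessel) — each defined by a base RGB color
chosen to evoke H&E morphology, a deterministic pattern family (stripes,
blobs, checker, speckle, plain), a pattern scale in pixels, and additive
Gaussian color noise (sd 8 intensity levels). A single `difficulty` knob
in [0, 1] interpolates every base color toward the palette's grand mean
and damps pattern contrast: at 0 the per-patch mean color alone
identifies the class; at 1 the classes are nearly indistinguishable. The
benchmark runs at difficulty 0.3, where classes remain visually separable
but a trained classifier is still required to exceed the accuracy bounds.

**Slides.** A slide is a Voronoi tessellation: `region_count` seed points
scattered over the tissue area (an optional background frame stays
empty), each cell assigned one of the nine tissue classes drawn from a
weight vector, each class rendered with its texture. The class-area
fractions (`true_ratios`) are re-tallied from the final pixel label map,
never from the weights, so they are exact by construction and serve as
the oracle for ratio recovery. Region growth by Voronoi cells rather than
a Potts-style sampler keeps the ground truth exact and the region count
controllable.

What this emulates — and what it does not: the generator reproduces the
*geometry* of the quantification problem (contiguous tissue regions,
blank background, known class areas) but none of the optics of real
histology (stain variation beyond affine color shifts, focus artifacts,
pen marks, tissue folds). Passing the benchmark therefore demonstrates
that the pipeline machinery is correct, not that the compact network
would classify real H&E tissue.

## Preprocessing

Slides are cut into non-overlapping square tiles (default 64 px at
synthetic working resolution; 224 px is the full-scale convention),
row-major, 0-based, half-open windows; residual margins are dropped.
Tiles with less than 2% Canny edge pixels after BT.601 grayscale
conversion are discarded as non-tissue. The Canny hysteresis thresholds
default to 10/25 on the 8-bit scale with a σ = 1 Gaussian pre-smooth;
these were chosen once so that flat background (noise sd 8) yields < 2%
edge pixels and every tissue texture yields more — note that scikit-image
gradients live on a much smaller numeric scale than OpenCV Sobel
magnitudes, so OpenCV-style 50/150 thresholds would detect nothing here.
Both thresholds are exposed in the API.

Color is standardized by Reinhard transfer in the decorrelated log color
space lαβ (RGB → LMS → log10 → opponent axes): each channel is shifted
and scaled so its mean and standard deviation match a reference, then
back-transformed and clipped to [0, 255]. The reference is always an
explicit input (fit from designated tiles), never hard-coded. An
ε = 1e-6 guard covers log(0) and zero-variance channels, which map to the
reference mean.

Ground-truth patch labels follow the 90% rule: "tumor" when tumor
exceeds 90% of the patch area; "mixed tumor–stroma" when tumor is present
at or below that bound and stroma is also present; otherwise the majority
pixel class with ties broken by the fixed class order. The majority
fallback for tumor-minority patches without stroma is this package's
extension of the rule, which does not address that case.

## Patch classifier

The `compact` preset is a small CNN trained from scratch: three 3×3
convolution blocks (8, 16, 32 channels), each followed by batch
normalization, ReLU, and 2×2 max pooling; global average pooling; and a
linear softmax head over the 10 classes. Input is 64×64 RGB scaled to
[−0.5, 0.5]. Training is mini-batch SGD (batch 160, momentum 0.9,
initial learning rate 0.01) under a per-batch exponential learning-rate
decay (0.9999), with categorical cross-entropy loss. Before the final
epoch the batch-norm running statistics are replaced by exact full-pass
moments over the training set and then frozen, so the last epoch trains
under the same normalization used at inference. Without this step the
network can exploit per-batch statistics and lose held-out accuracy on
the closest class pairs once evaluated with population statistics. The
implementation is plain numpy with im2col convolutions, so all heavy
operations are BLAS matrix products and training is bit-reproducible for
a fixed seed on one machine.

The benchmark trains for 4 epochs on 600 patches per class — enough for
convergence at this scale, as the loss plateaus within the first two
epochs. A `backbone-transfer` preset name (224-px input over a pretrained
backbone, matching the full-scale recipe) is reserved as an extension
point; no pretrained backbone ships with the package.

Evaluation reports the 10×10 confusion matrix, row-normalized per-class
accuracies, and Cohen's κ = (p_o − p_e)/(1 − p_e) with chance agreement
from marginal products; κ is reported as undefined (NaN) when both
margins collapse to one class. Argmax ties resolve to the lowest class
index. Embeddings are the global-average-pool activations (32-d).

## Quantification and agreement

Segmentation composes tile → edge filter → optional normalization →
classify. Every kept tile contributes one unit of area; the tissue-class
ratio is tiles-of-class / kept-tissue-tiles × 100%, with
background-predicted tiles excluded from the denominator, computed with
exact rational arithmetic before the percent conversion. MTSR is the
"mixed tumor–stroma" entry. Sub-tile mixtures are deliberately not
re-weighted — area is the tile count, matching patch-level segmentation.
The tile-quantization error of oracle-labeled tiles is bounded by the
fraction of impure tiles (those touching a region boundary or the
background frame) and shrinks as tiles shrink; the acceptance suite
verifies both facts on 20 slides.

Patient-level MTSR defaults to the tile-weighted mean over slides
(weights = kept-tile counts), which equals pooling the raw tile counts;
"mean" and "max" rules are available and the rule used is recorded in
the output.

Agreement between two measurement series uses Pearson r, ICC(2,1)
(two-way random effects, absolute agreement, single measure, computed
from the subject × rater mean squares, with the McGraw–Wong F-based
confidence interval), and Bland–Altman statistics: mean difference
(predicted − reference), limits of agreement at ±1.96 sd, and a
t-distribution CI (n − 1 df) for the mean difference.

## Survival stack

- **Cox models** delegate to lifelines with Efron tie handling. Wald 95%
  intervals use z = 1.96 throughout. Monotone-likelihood fits are retried
  with a tiny ridge penalty and flagged `converged=False` rather than
  returned silently.
- **Cutpoints**: maximally selected rank statistics — every distinct
  covariate value inside the (0.10, 0.90) quantile range is a candidate;
  the standardized two-group log-rank statistic is maximized over
  candidates; the selection-adjusted p-value comes from permuting the
  covariate (seeded, default 199 permutations) and comparing maxima. A
  permutation null is exact by simulation and simpler to verify than the
  Lausen–Schumacher approximation. A median split is available as the
  alternative strategy for combined-cohort stratification.
- **KM/log-rank**: lifelines product-limit curves and the 1-df log-rank
  test; an internal vectorized standardized log-rank statistic (O−E over
  hypergeometric variance) drives the cutpoint scan.
- **C-index**: Harrell's concordance over usable pairs (earlier-censored
  pairs excluded, risk ties count one half), via lifelines; the test
  suite checks exhaustive pair enumeration on every fixture ≤ 20 records.
- **Time-dependent AUC**: cumulative-case/dynamic-control estimator with
  inverse-probability-of-censoring weights (scikit-survival). Horizons
  default to 1/3/5 time units; horizons beyond follow-up are reported as
  NaN.
- **Nomogram**: per-covariate points are β_j·(x_j − ref_j) scaled so the
  widest contribution spans 0–100, with ref_j the covariate value that
  zeroes the contribution (min for β > 0, max otherwise). Predicted
  survival is S₀(t)^exp(lp − mean lp) with the Breslow baseline at the
  training covariate means; the points mapping is lossless by
  construction and the suite verifies agreement with the direct Cox
  survival function to 1e-9.
- **Calibration**: deciles of predicted survival vs. KM-observed survival
  per horizon. The apparent calibration slope is 1 by construction; the
  bootstrap-corrected slope refits the model on resamples and fits a
  one-covariate Cox model of the original data on each bootstrap linear
  predictor (default 1000 resamples in the op contract, scaled to 200 in
  the pipeline default and less in tests). `n_boot = 0` returns the
  apparent curve flagged as such.
- **Decision curves**: NB(p_t) = TP/N − FP/N · p_t/(1 − p_t), with event
  status by the horizon estimated by Kaplan–Meier inside the treated
  subset so censored subjects are handled rather than dropped; treat-all
  and treat-none references included.
- **Proportional hazards**: Grambsch–Therneau test on Schoenfeld
  residuals against the event-time rank transform, one χ² per covariate
  plus a global χ² (df = number of covariates). The per-covariate null
  rejection rate is verified at its nominal 5% level over 500
  constant-hazard simulations, and the statistics were checked against
  `survival::cox.zph(transform = "rank")` in R on a fixture.

## Meta-analysis

Stage one fits a Cox model per cohort; stage two pools the log-HRs by
inverse variance. Cochran's Q, I² = max(0, (Q − df)/Q), and the
DerSimonian–Laird moment estimator τ² = max(0, (Q − df)/(Σw − Σw²/Σw))
quantify heterogeneity; the gate selects fixed effects iff I² < 25% and
the Q-test p exceeds 0.05, otherwise DerSimonian–Laird random effects.
Both estimates are always computed and reported. τ² is truncated at zero
(statsmodels' DL keeps negative values; the truncated convention is used
here, and the cross-check test uses a heterogeneous fixture where the two
agree). Egger's test regresses θ_i/SE_i on 1/SE_i and t-tests the
intercept with k − 2 df; it requires k ≥ 3.

## Survival simulation and parameter recovery

Cohorts draw MTSR from a truncated normal on [0, 100] (default mean 10%,
sd 8%, roughly the dispersion a heavily right-skewed clinical MTSR
distribution shows after truncation), nodal stage as Bernoulli(0.3), and
event times as exponential with subject hazard
baseline · exp(β_mtsr·MTSR + β_N·N); censoring is an independent
exponential clock, and between-cohort heterogeneity perturbs β_mtsr by
N(0, τ²). Default study conditions: 6 cohorts (one discovery + five
external), 300 subjects each, baseline hazard 0.05/unit time, censoring
0.03/unit time (≈ 60–75% events), planted β_mtsr = log(1.5)/10 per
percentage point (HR 1.5 per 10 pp), β_N = log(1.8).

Parameter-recovery experiments plant **no** nodal-stage effect: the
stage-1 Cox model is univariate on MTSR, and a marginal Cox coefficient
is attenuated when an independent prognostic covariate is omitted
(non-collapsibility), so "the pooled CI covers the planted value" is
only a well-posed frequentist claim when MTSR is the sole hazard driver.
The full prognostic study keeps the nodal-stage effect because the
multivariate model, nomogram, and decision curves need a second
independent predictor.

## Feature-model surrogate

The imaging-feature arm replaces real MRI radiomics with synthetic
tables: informative columns shifted by a standardized effect size between
classes, redundant columns correlated ρ with informative parents, and
independent noise columns. The chain is ICC(2,1) screening across two
measurement repeats (retain ≥ 0.75), column z-scoring, greedy mRMR
selection of 10 features, and a random forest tuned by exhaustive
cross-validated grid search within the canonical bounds (trees 5–150,
depth 1–10, min split 2–10, min leaf 1–6; the default grid subsamples
those ranges), ties preferring fewer trees then shallower depth.

mRMR scoring: relevance is the one-way ANOVA F-statistic mapped to the
explained-variance share R² = F/(F + n − 2); redundancy is the mean
absolute Pearson correlation with the already-selected set; the step
score is their difference. The R² mapping is strictly monotone in F, so
the first pick is always the most relevant feature, and it puts relevance
on the same [0, 1] scale as the correlation penalty — with a raw
F-statistic a perfect duplicate of a strong feature would out-score an
independent noise feature despite its redundancy, defeating the purpose
of the penalty.

Metrics: confusion panel at a 0.5 probability threshold (accuracy,
sensitivity, specificity, PPV, NPV), rank-based AUC, and a stratified
bootstrap 95% CI for the AUC (2000 resamples, seeded). DeLong intervals
are a possible alternative backend; bootstrap was chosen for uniformity
with the calibration machinery.

## Orchestration and reproducibility

`pipeline.run_benchmark` and `pipeline.run_prognostic_study` wire the
stages together. One master seed is fanned out to named per-stage seeds
via `numpy.random.SeedSequence.spawn`, and every report carries a
manifest (package version, full config, all derived seeds), so a single
integer reproduces an entire run and any stage can be reproduced in
isolation. The numbered scripts under `analysis/` are thin drivers over
these functions and write their tables and figures under `results/`.

## Problem sizes

The shipped configurations are desk-scale choices: the patch benchmark
uses 600 training and 200 held-out patches per class at 64 px (4 epochs);
ratio recovery uses 20 slides of 512×512 px with 30 regions; coverage
experiments use 100 replicates; permutation and bootstrap counts default
to 199 and 200 in the pipeline (1000 remains the op-contract default for
calibration). These sizes make every result reproducible in minutes on a
single CPU while leaving the statistical machinery identical to a
full-scale run.

## Known limitations

- The texture generator cannot demonstrate anything about real H&E
  generalization; it validates machinery, not histology.
- The compact CNN is not a transfer-learned backbone; its accuracy bounds
  hold on synthetic textures only.
- Exponential event and censoring times satisfy proportional hazards by
  construction; the PH diagnostics are validated under the null, not
  against realistic violations.
- The maxstat permutation p-value is exact only up to Monte-Carlo error
  at the configured permutation count.
- ICC confidence bounds assume the balanced two-rater design generated
  here.
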