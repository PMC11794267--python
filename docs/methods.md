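# Methods

## Problem and pipeline

`emgsel` implements an offline movement-classification pipeline for
multi-channel surface electromyography (sEMG), of the kind used to prototype
myoelectric control of prostheses and assistive robots.  The pipeline is:

1. **Preprocess** raw recordings: 50 Hz notch (quality factor 30), 20–500 Hz
   fourth-order Butterworth bandpass, both applied forward–backward (zero
   phase), then overlapping 250 ms windows with 50 % overlap cut strictly
   inside annotated movement intervals.
2. **Extract** a catalog of 41 window features (34 time-domain, 6
   frequency-domain, plus plain MAV) per channel.
3. **Rank** each feature by the cross-validated accuracy of an ANN given only
   that feature's channels, and eliminate features below a threshold
   (default 0.85; 0.80 also supported — both thresholds circulate in the
   sEMG literature and reports record which was used).
4. **Reduce** the retained table with one of six methods — PCA, LDA, PPCA,
   GPLVM, ReliefF, Lasso — or none, and compare cross-validated accuracy and
   wall-clock cost.
5. **Search** all k-feature subsets (k = 2…5) of the retained set
   exhaustively with the same ANN and fold assignment, and compare subset
   sizes with one-way ANOVA over the top-10 accuracies.

The classifier everywhere is a feed-forward network with three hidden layers
of 20 ReLU units, trained with Adam (learning rate 1e-3, batch = min(128, n),
early stopping disabled) for a fixed epoch budget: 1000 epochs in the `paper`
profile, 150 in the `fast` desk-scale profile.  Cross-validation is
stratified 5-fold; the column z-scorer and any reduction method are fit on
training folds only.

## Synthetic data generator

Real multi-subject sEMG is large and external, so the package ships a seeded
generator that reproduces the statistical structure the pipeline depends on:

* carrier: Gaussian white noise bandpassed to 20–450 Hz and variance
  normalized — sEMG is well modeled as a bandlimited stochastic process, and
  the catalog's amplitude and spectral features respond to modulation of
  such a carrier;
* protocol: six movement classes, repetitions of 5 s separated by 3 s rest,
  2 kHz sampling, 12 channels (all configurable);
* activation: a per-(movement, channel) gain matrix scales the carrier under
  a trapezoidal envelope with 0.5 s ramps (ramps avoid discontinuities that
  would degenerate the difference-based features).  By default each movement
  has two dominant channels at gain 3 and supporting channels cycled through
  0.5/0.75/1.0; the cyclic phase is chosen so every movement's gain row is
  distinct even when movements share a dominant pair (few channels);
* noise: baseline bandlimited noise of configurable SD everywhere, plus an
  optional 50 Hz sinusoid emulating powerline pickup.

Classes are therefore *amplitude-coded*: movement identity is carried by the
channel pattern of carrier amplitude, not by spectral shape or waveform
asymmetry.  Passing tests consequently show that the pipeline recovers
amplitude-pattern structure; they do not certify behavior on features real
sEMG might additionally modulate (spectral compression under fatigue,
motor-unit synchronization, electrode shift, inter-subject variability).
Amplitude units are arbitrary and all thresholds downstream are defined
relative to window statistics.

A second generator, `planted_feature_matrix`, produces small Gaussian
class-conditional feature tables with known ground truth (a jointly — but
not individually — informative feature pair, or graded per-feature signal
strengths).  It drives the wrapper-search tests where the right answer must
be known exactly.

## Feature catalog conventions

The literature names these features but rarely fixes conventions; the
catalog pins one formula each (see the table in `features.py`).  Notable
choices:

* thresholded counts (ZC dead-band, SSC, Wilson amplitude) use
  window-relative thresholds since units are arbitrary; WAMP's default
  threshold is 0.1 × window SD.  SSC and WAMP use strict inequalities so a
  constant window scores 0 even at a zero threshold;
* V-order uses v = 3 (v = 2 would duplicate RMS); the log detector,
  LDAMV and LCOV use natural logs, maximum fractal length uses log10 (the
  common convention for that feature); skewness/kurtosis are Fisher/excess
  with biased central moments;
* approximate entropy: m = 2, r = 0.2 × window SD, Chebyshev distance,
  self-matches included; cardinality quantizes at 0.01 × window SD;
* spectral features use the one-sided density periodogram of the (mean
  removed) window restricted to 20–500 Hz — 500-sample windows are too short
  for Welch averaging at useful resolution.  The frequency-ratio split is
  250 Hz, low band inclusive of the boundary bin;
* all logs and divisions are floored at 1e-12, so no feature returns
  NaN/Inf on degenerate windows;
* IAV = iEMG, AAC = DAMV, STD = √VAR and AvgEnergy = SSI/N are intentional
  catalog duplicates (they are listed separately in common usage); the
  redundancy is exactly what LDA's singular-scatter detection and the
  clustering of feature scatter plots reflect.

## Reduction methods

* **PCA** wraps the standard SVD solution.  **LDA** solves the generalized
  eigenproblem S_b v = λ S_w v directly and *refuses* to run when
  cond(S_w) > 1e12, raising `SingularScatterError` that names zero-variance
  and pairwise-collinear columns — with catalog duplicates present this is
  the expected outcome, and it is reported rather than silently ridged
  (an explicit `ridge` parameter exists for users who want the rescue).
* **PPCA** is fit by EM in the sample-covariance form; the marginal
  log-likelihood is recorded every iteration and checked non-decreasing.
  Convergence is |Δ log L| < 1e-6 within 500 iterations; non-convergence
  returns the current fit with a warning flag.  Out-of-sample rows map to
  latent posterior means.
* **GPLVM** minimizes the negative GP marginal log-likelihood
  `D/2 log|K| + ½ tr(K⁻¹ Y Yᵀ)` jointly over latent coordinates and kernel
  hyperparameters (RBF variance, lengthscale, noise) with analytic
  gradients and L-BFGS, initialized from PCA.  These are MAP point
  estimates, not Bayesian inference over the mapping.  L-BFGS line search
  guarantees the recorded objective trace is non-increasing and the solution
  never exceeds its PCA-init value.  A linear kernel is available; on
  linear-factor data its latent space agrees with PCA, which is the
  cross-check used in tests.  New rows are projected by per-point
  optimization of the GP predictive likelihood (analytic gradients,
  nearest-training-latent initialization).  Dense kernel algebra is guarded
  at 3000 rows.
* **ReliefF** uses k = 10 nearest hits and per-class nearest misses with
  prior weighting and range-normalized differences.
* **Lasso** fits one-vs-rest L1 logistic regressions over a penalty grid,
  picks the penalty by internal cross-validated accuracy (ties prefer the
  sparser model), and selects the union of nonzero-coefficient columns; an
  all-zero selection falls back to the weakest penalty with a warning.
  One-vs-rest (rather than multinomial) was chosen because it makes the
  per-class sparsity patterns directly interpretable.

**Component-count defaults.** PCA and PPCA keep the components covering 99 %
of training-fold variance.  A 95 % cut was evaluated first and discarded: on
amplitude-coded sEMG feature tables the dominant variance direction is the
common amplitude mode (envelope ramps and carrier-level fluctuations shared
by all channels), while the class-discriminative channel *contrasts* are
lower-variance; at 95 % the kept subspace can collapse to 3 of 48 columns
and costs 10–19 accuracy points versus the unreduced table, whereas 99 %
restores parity.  GPLVM defaults to d = 10; ReliefF selects 25 % of columns.
All are configurable per call.

## Exhaustive search and statistics

Subsets are enumerated in lexicographic order over the retained-feature
ordering; a subset always includes all channels of each chosen feature.  One
stratified fold assignment, derived from the run seed, is shared by every
subset so accuracies are comparable; ties in the ranking are broken
lexicographically.  A JSON-lines checkpoint makes an interrupted search
resume to an identical report.  Subset sizes are compared by one-way ANOVA
on the top-10 accuracy vectors (per-fold/per-seed accuracies are the
replicate unit; no post-hoc tests).

## Problem sizes used in tests and the acceptance script

The shipped verification runs use desk-scale versions of the study
conditions: recordings of 1–2 repetitions per movement (protocol timing,
channel counts and noise structure unchanged), the 150-epoch `fast` ANN
profile, planted feature tables of 120 rows, a 12-feature ranking catalog,
and wrapper searches over 7–8 retained features.  Wall-clock times are
recorded in reports but never asserted — they are hardware-dependent.

## Known limitations

* The generator does not model motor-unit physiology, electrode placement,
  force levels, or inter-subject variability; "subjects" differ only by
  seed.
* LDA's singularity detection flags exact collinearity and near-collinear
  pairs via correlations; more intricate rank deficiencies are reported
  with the condition number but without a column diagnosis.
* GPLVM optimization is non-convex; different seeds can reach different
  local optima (the descent and PCA-consistency contracts still hold).
* The Ninapro-style MAT reader is a stub interface only; real-data ingestion
  is out of scope for the shipped tests.
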