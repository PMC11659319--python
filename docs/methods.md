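# Methods

This note documents the statistical models, the synthetic-data calibration,
the numerical choices, and what the tests do and do not establish.

## Analysis model

**ABR features.** Raw acquisition yields single-sweep epochs (sweeps ×
samples, µV, stimulus onset at t = 0, 10.66 ms window). Sweeps whose
maximum absolute voltage exceeds 23.8 µV are rejected; accepted sweeps are
averaged and bandpass filtered 100–3000 Hz. The filter is a 4th-order
Butterworth applied forward–backward (`scipy.signal.sosfiltfilt`), i.e.
zero-phase, so peak latencies are not shifted (the effective magnitude
response is the squared 4th-order response). Averaging and linear
filtering commute; the implementation filters the mean. Wave I is the
maximum in 1.3–2.3 ms, wave V in 5.1–6.4 ms; amplitude is peak minus the
following trough, defined as the first local minimum within 2 ms after
the peak, falling back to the minimum over that horizon. Automated picking
replaces manual confirmation: a pick at a window boundary, a flat window,
or a missing trough sets a QC flag (`boundary-peak` / `no-peak` /
`no-trough`), and non-clean records are meant to be excluded from
analysis (the flags are returned; exclusion is the caller's policy).
Derived features: I–V latency difference and the natural-log V/I amplitude
ratio (log because the raw ratio is strongly right-skewed); the ratio is
missing when either amplitude is zero (below 1e−9 µV numerically).

**Scoring.** PTA is the mean audiometric threshold at 0.5/1/2/4 kHz per
ear; the better ear has the smaller PTA (ties go to the right ear, with a
log note). Each of the ten cognitive measures is z-scored against the
analyzed sample (n−1 SD) and sign-flipped for the three time-based
measures (trail making A/B, four-mountains reaction time), so higher z
always means better. The composite is the mean of available z-scores; a
participant with fewer than all-but-two measures available (8 of 10 for
the default battery) is excluded from the composite. z-scoring uses the
full analyzed sample; subgroup analyses reuse full-sample z units rather
than re-standardizing within groups.

**Association models.** Ordinary least squares with t-based 95% CIs and
two-sided p-values. Units follow the reporting convention: cognition in
composite-z, age in years, PTA in dB HL, ABR predictors z-scored — so the
age slope reads "z per year" and ABR slopes "z per z". Age adjustment adds
age as a covariate; by the Frisch–Waugh theorem the adjusted slope equals
the residual-on-residual slope, which the tests verify to 1e−10. Models
require ≥ 10 observations per independent variable. Diagnostics
(Jarque–Bera normality, White heteroscedasticity, Ramsey RESET linearity,
variance inflation factors) are reported with pass/warn status at p = 0.05
/ VIF = 10 but never auto-reject a model. Age-group contrasts use a
one-way GLM F-test plus pooled-variance pairwise t-tests with Bonferroni
correction. No multiple-testing correction is applied across the
association suite's many models.

**Percentile ROC sweep.** For percentile p ∈ {1..99}, the good-performer
cutoff is the linear-interpolation empirical quantile of the composite
(numpy default); participants with composite ≥ cutoff are "good". The AUC
is the empirical Mann–Whitney probability that a random good performer
out-scores a random poor one on the oriented biomarker, ties counted 1/2,
computed via midranks. Orientations are fixed a priori (amplitude up =
good, latency up = poor) rather than taking max(AUC, 1−AUC), which would
bias every point upward. The Youden cutoff maximizes sensitivity +
specificity − 1 over midpoints between adjacent sorted unique scores plus
±∞; ties break toward higher specificity, then the lower cutoff; the
cutoff is mapped back to original units with its decision direction. The
age-adjusted variant residualizes the composite on age (OLS, intercept
included) before labeling; predictors stay raw. The chance band replaces
the biomarker with seeded i.i.d. standard-normal draws (1000 replicates by
default): because AUC is invariant under strictly increasing transforms of
the scores, any continuous null distribution gives the same band, so
normal draws lose no generality. The band's spread is reported two ways —
between replicate grid-means (~0.047 at n=118) and across percentiles of
the replicate-averaged curve (~0.002) — because "the SD of the chance
band" is ambiguous between the two; a curve averaged over a handful of
replicates lands between them. Adjusted-vs-unadjusted curve comparisons
use a paired t-test across grid points, with the explicit caveat that the
99 points are strongly dependent (nested labelings of one cohort), so that
p-value is descriptive only.

**Cross-validated LDA.** One seeded random (non-stratified) partition of
the cohort into k folds (sizes differing by at most 1) is reused across
all percentiles; k ∈ {2, 5, 10} unless explicitly overridden. Per
percentile and fold, a one-feature linear discriminant (pooled variance,
empirical priors; scikit-learn) is trained on k−1 folds and its
discriminant score evaluated on the held-out fold by empirical AUC. A fold
is excluded when its validation labels are single-class (sensitivity/
specificity undefined) *or* its training labels are (the discriminant is
undefined); both counts are kept. With one feature the discriminant score
is affine in the feature, so each retained fold's AUC equals the
raw-feature AUC oriented by the sign of the learned coefficient — an
exact oracle the tests check to 1e−10. Percentiles with zero retained
folds are reported missing, not as failures.

## Synthetic cohort generator

The generator emulates a cross-sectional adult cohort in three age groups
(sizes 26/26/66; ranges 18–30 / 31–59 / 60–92 years). Defaults:

| quantity | model | default |
|---|---|---|
| age | uniform within group range | — |
| PTA (dB HL) | −9.2 + 0.44·age + N(0, 8²), clipped to [−10, 120] | group means ≈ 1.4 / 10.6 / 24 |
| wave V latency (ms) | 5.871 + 0.0033·age + N(0, 0.28²) | group means ≈ 5.95 / 6.01 / 6.11 |
| wave V amplitude (µV) | 0.355 − 0.0023·age + N(0, 0.095²) | group means ≈ 0.30 / 0.25 / 0.18 |
| wave I latency (ms) | N(1.80, 0.26²), age-independent | — |
| wave I amplitude (µV) | lognormal, moment-matched mean 0.10 / SD 0.09 | stays positive |
| composite age slope | −0.021 z/year | — |
| age-adjusted wave V couplings | −0.101 / +0.110 z per z | — |

Ages are uniform within each group's range (the simplest distribution
respecting the published bounds). Wave I is simulated age-independent and
uncoupled from cognition. Wave V amplitude is left unclipped (rare tail
draws ≤ 0 match an observed range minimum of 0.00 µV); clipping it would
break the noiseless-limit and slope-recovery closed forms.

**Cognition calibration.** The slopes above describe the *recomputed*
composite — the mean of ten sample-z-scored measures — so the generator
works on the z scale directly. A shared latent factor is built as

    C = −0.021·(age − μ_age) + b_lat·η_lat + b_amp·η_amp + N(0, σ_u²)

where η are the standard-normal residuals of the wave V features and
b = (target slope)·(residual/marginal SD ratio of the feature), which
makes the fitted age-adjusted per-z slopes converge to the targets
(−0.101 / +0.110). Each measure's latent value is C plus unique noise of
SD w = 0.810, and σ_u is solved in closed form so the composite SD is
≈ 0.64 — equivalently a mean inter-measure correlation of ≈ 0.34, the
value a 10-measure composite of that SD implies. Measures are mapped to
raw units by fixed affine anchors (realistic means/SDs per instrument),
inverted for the time measures, and clipped to instrument bounds
(e.g. recall ≤ 10, recognition ≤ 20), reproducing the ceiling effects real
batteries show. Clipping attenuates the recovered age slope by ~1.5%,
well inside every stated tolerance. Scores are left continuous rather
than integer-rounded; rounding would only add quantization noise to the
z-scores without changing any tested property. An optional missingness
rate (default 0) blanks measures completely at random.

**A note on CI coverage.** Because every measure is z-scored against the
sample, the composite is self-normalizing: a cohort that happens to
realize a steeper age slope also realizes larger measure SDs, which
shrinks the fitted slope back. Measured over 200 cohorts, the fitted age
slope's spread is ~0.78× its model-based SE, so its 95% CI covers the
generating value ~99% of the time — above nominal, structurally, for any
calibration. Parameter-recovery coverage is therefore evaluated by
refitting the generating model (latent composite on age), which is
model-true OLS with nominal coverage; the pipeline composite is separately
required to recover the slope to ±0.002 at n = 2000. Any real study using
sample-standardized composites inherits the same over-coverage.

**Epoch simulation.** Each wave is a biphasic wavelet — a positive
Gaussian lobe (FWHM = configured width) plus a delayed (2×width), wider
(1.5σ), 0.6-scaled negative lobe — rescaled so the clean template's
peak-to-following-trough equals the configured amplitude exactly; that
value is the planted truth. The 100–3000 Hz zero-phase filter moves the
template's peak by 0 samples and changes its peak-to-trough by < 2%
(verified numerically), so planted-value recovery is well-posed. Single
sweeps add white Gaussian noise (default 5 µV — after averaging ~2300
sweeps and filtering, a ~0.05 µV residual floor, comparable to real
averaged recordings); a Bernoulli fraction of sweeps (default 5%) receives
a ±40 µV square pulse of 2 ms at a random position, guaranteeing rejection
at 23.8 µV. The artifact mask, clean template and planted features are
recorded in the epoch set's metadata as oracles. Sampling rate defaults to
24 kHz so the 3 kHz filter corner has ample margin.

**What the generator does not emulate.** Linear age trends with Gaussian
residuals only (no cohort heteroscedasticity, no nonlinear aging, no
tail-specific ABR–cognition coupling); a single shared factor across
measures (no domain-specific correlation structure, so the real-data
pattern of language-dependent associations cannot emerge); no
sex/education effects; missingness completely at random; stylized wave
shapes and artifact pulses. Passing tests therefore establish that the
*pipeline* recovers what its assumed generating model plants — including
the directional percentile-sweep asymmetry only insofar as the planted
couplings imply it — not that real recordings satisfy those assumptions.
In particular the empirical finding that latency is most informative at
the low-performance extreme and amplitude at the high extreme is a
property of real data that the symmetric generator reproduces only by
sampling accident; verifying it requires the reproduction run on deposited
per-participant data.

## Numerical and policy choices

- Quantile definition: linear interpolation between order statistics; any
  other convention shifts extreme-percentile labelings by at most one
  participant.
- Sample SDs use the n−1 denominator throughout.
- Sweep percentiles where a class is empty are recorded as missing points.
- Degenerate inputs raise typed errors (`DegenerateInputError`,
  `ParameterError`, ...) naming the offending field; the association suite
  records per-row errors and continues.
- Below-minimum sweep counts (< 2000 accepted) warn rather than fail so
  small epoch sets remain processable.
- The pipeline writes a manifest (seed, versions, SHA-256 of every output)
  and is byte-reproducible given (config, seed).
- Problem sizes in the test-suite simulations (e.g. 200 replicate cohorts,
  100 epoch sets of 2000 sweeps, 1000 chance replicates) were chosen so
  Monte-Carlo error sits comfortably below each asserted tolerance.

## Known limitations

- Only waves I and V are modeled; no latency-intensity functions, no
  electrode-montage or stimulus-level modeling.
- The reproduction path (deposited workbook → canonical schema) requires a
  user-supplied column map; the workbook's internal layout is not assumed.
- AUC confidence intervals (e.g. bootstrap bands per percentile) are not
  implemented; the chance band is the only uncertainty reference for the
  sweep.
- The paired test comparing adjusted and unadjusted AUC curves ignores the
  dependence between grid points, as noted above.
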