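# abrcog

Auditory brainstem response (ABR) wave features as a biomarker for
cognitive performance: a tested Python pipeline for simulating, extracting
and evaluating the association between subcortical evoked potentials and a
composite measure of cognition in aging adult cohorts.

## The problem

Age-related cognitive decline lacks cheap, non-invasive biomarkers. The ABR
— the scalp potential evoked in the first ~10 ms after a click — is
routine in audiology, and its wave V (lateral lemniscus / inferior
colliculus) carries information about subcortical neural health: peak
latency reflects conduction and synaptic delay, peak-to-trough amplitude
reflects the number and synchrony of responding neurons. This package
implements the full analysis linking those features to cognition:

1. **ABR feature extraction** — artifact rejection (|V| > 23.8 µV),
   averaging, zero-phase 100–3000 Hz bandpass, windowed peak picking
   (wave I: 1.3–2.3 ms, wave V: 5.1–6.4 ms), I–V latency difference and
   log V/I amplitude ratio, with QC flags replacing manual confirmation.
2. **Scoring** — pure-tone average (0.5/1/2/4 kHz, better ear), ten
   cognitive measures z-scored and direction-adjusted, averaged into a
   composite z; age groups (18–30 / 31–59 / ≥60 y) and hearing-loss
   category (PTA ≥ 20 dB HL).
3. **Association suite** — OLS with t-based 95% CIs: cognition on age
   (z/year), hearing (z/dB) and z-scored ABR features, univariate and
   age-adjusted, full-sample and per age group, with
   normality/heteroscedasticity/linearity/VIF diagnostics.
4. **Percentile ROC sweep** — for every percentile criterion 1–99 of the
   composite, good/poor labels, the empirical (Mann–Whitney) AUC of the
   oriented biomarker, the Youden-optimal cutoff in original units, and a
   chance band from seeded random predictors (AUC = 0.5 by construction,
   since AUC is invariant to monotone transforms).
5. **Cross-validation** — k-fold (k ∈ {2, 5, 10}) single-feature linear
   discriminant analysis per percentile, with degenerate (single-class)
   folds excluded and counted.
6. **Synthetic cohorts** — a first-class generator producing cohort tables
   and raw ABR epoch matrices with known ground truth, so every stage has
   a recoverable target without any data download.

## Worked example

```bash
python examples/03_association_suite.py
```

```
composite ~ age (z/year)            B=-0.022  95% CI [-0.025, -0.019]  p=0.0000  n=118
composite ~ PTA (z/dB)              B=-0.033  95% CI [-0.041, -0.026]  p=0.0000  n=118
composite ~ wave V latency (z/z)    B=-0.266  95% CI [-0.377, -0.156]  p=0.0000  n=118
  ... age-adjusted                  B=-0.118  95% CI [-0.195, -0.041]  p=0.0030  n=118
composite ~ wave V amplitude (z/z)  B=+0.341  95% CI [+0.238, +0.444]  p=0.0000  n=118
  ... age-adjusted                  B=+0.116  95% CI [+0.031, +0.201]  p=0.0079  n=118
```

This simulates a 118-participant cohort at the default calibration
(composite declining 0.021 z per year of age; age-adjusted wave V
couplings −0.101 z per z of latency and +0.110 z per z of amplitude) and
refits the association models: the univariate wave V slopes are roughly
halved by age adjustment but remain away from zero, because the generator
plants an age-independent component in the coupling. `examples/04_roc_sweep.py`
continues the same cohort into the percentile sweep:

```
wave_v_latency: mean AUC 0.71 +/- 0.05 (range 0.58-0.88)
  best at percentile 7: AUC 0.88, cutoff 6.18 (above_cutoff_poor), sens 0.65 / spec 1.00
wave_v_amplitude: mean AUC 0.77 +/- 0.05 (range 0.68-0.94)
  best at percentile 97: AUC 0.94, cutoff 0.34 (above_cutoff_good), sens 1.00 / spec 0.89
chance band: mean AUC 0.501, ...
```

i.e. a wave V latency above ~6.2 ms flags poor performers and an amplitude
above ~0.34 µV flags good ones, while an uninformative predictor pins to
AUC 0.5. The other examples cover simulation (01), raw-epoch feature
extraction (02) and cross-validation (05).

A thin CLI wraps the same pipeline (`abrcog simulate|score|associate|
sweep|crossval|report|reproduce`, with `--seed`, `--outdir`, `--config`);
`abrcog reproduce --source-data <workbook.xlsx>` runs the whole analysis
on a deposited per-participant table mapped onto the canonical cohort
schema via an editable YAML column map (`abrcog export-column-map`).

## Layout

```
src/abrcog/      synthetic, abr, scoring, association, roc, crossval, io, pipeline, cli
examples/        one narrative script per capability
tests/           unit + property tests, plus end-to-end acceptance checks
docs/methods.md  models, calibration, numerical choices, limitations
```
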