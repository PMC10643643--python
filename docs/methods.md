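# Methods

## The problem and the model

Fetal heart rate (or equivalently the fetal RR interval, fRRI = 60000/fHR in
ms) is the primary non-invasive window on fetal well-being, but measuring it
requires Doppler ultrasound or fetal ECG extraction. Maternal and fetal heart
rhythms are physiologically coupled (shared circulation, respiration,
autonomic state), which motivates predicting the *average* fRRI of a
pregnancy from maternal factors alone. The pipeline regresses mean fRRI on a
13-dimensional maternal feature vector

```
x = (age, weight, SDNN, SDHR, VLF, LF, HF, VHF, RWVLF, RWLF, RWHF, RWVHF, RRI)
```

using two standard learners — linear ε-insensitive support-vector regression
(SVR) and a random forest (RF) — evaluated by leave-one-out cross-validation
(LOO-CV), and attributes the fitted predictions to features with
interventional Shapley values. Nothing in the model encodes mechanism; it is
a purely statistical association screen, and the Shapley summary is its
interpretive output.

## Signal processing

* **High-pass filter.** 4th-order Butterworth at 5 Hz, applied
  forward–backward (`sosfiltfilt`). Zero phase matters: any phase lag would
  bias R-peak times and hence every RRI-derived feature. At 0.3 Hz
  (baseline/respiration drift) the squared 4th-order response attenuates by
  far more than the 20 dB the pipeline's contract requires; at 15 Hz (QRS
  band) throughput exceeds 99 %.
* **Normalization.** Division by the signal maximum, so the tallest R peak
  maps to 1 and peak-height thresholds are scale-free. A lead whose largest
  excursion is negative-going triggers an inversion warning rather than an
  error.
* **R-peak detection.** `scipy.signal.find_peaks` with a height threshold
  (default 0.4 normalized) and a refractory distance (default 300 ms
  maternal ≈ 200 bpm ceiling, 200 ms fetal ≈ 300 bpm). Each detected maximum
  is refined to sub-sample precision with a least-squares parabola over
  ±10 ms; this averages broadband noise across the peak and keeps timing
  error well below 1 ms at the simulator's default noise. Setting
  `refine_window_ms=0` recovers raw argmax positions. No ectopic/artifact
  interval rejection is applied by default — the interval series is used as
  detected.
* **Segmentation.** Consecutive half-open windows `[k·300 s, (k+1)·300 s)`
  from the record start, two per subject by default. Five minutes is the
  minimum window for which the VLF band (lower edge 0.0033 Hz) is
  assessable. A record supporting fewer windows yields the available ones
  plus a `SegmentShortfall` warning, mirroring real cohorts where only one
  window is extractable for some subjects.

## Spectral features

Band powers are computed directly on the *unevenly sampled* beat-indexed
series (RRI against later-beat time; R-wave amplitude against peak time)
with the Lomb–Scargle periodogram — the estimator of choice for uneven
sampling, avoiding interpolation artifacts that resampling would inject into
the HF/VHF bands. Choices that matter:

* Series are mean-centered only; no polynomial detrending (it would distort
  VLF).
* Frequency grid from `max(1/T, 0.0033 Hz)` to 0.9 Hz with spacing
  `1/(4T)` (oversampling factor 4).
* The raw periodogram is converted to one-sided PSD scale by `2·P·T/N`,
  which reproduces the FFT periodogram density exactly on even sampling;
  band values are trapezoid integrals over half-open bands `[low, high)`
  (half-open to avoid double counting at the shared edges 0.04/0.15/0.4 Hz).
  The canonical feature is therefore **integrated band power** (ms² for RRI,
  normalized-amplitude² for RWAV). Cohort tables that report band densities
  (ms²/Hz) differ by the bandwidth factor; rank-based analyses are
  unaffected.
* SD features use the sample (n−1) denominator, conventional for SDNN.

The suite checks oracle equivalence (Lomb–Scargle total power within 5 % of
the FFT periodogram on even grids), offset invariance, quadratic scaling
with modulation depth, and correct band assignment of injected tones in all
four bands.

## Models

* **SVR**: linear kernel, ε = IQR(y)/13.49, C = IQR(y)/1.349 —
  dispersion-scaled defaults in the convention of the common commercial
  regression toolboxes — with feature z-scoring. Both constants are
  overridable in `ModelConfig`.
* **RF**: 100 trees, minimum leaf 5, bootstrap on, one third of the 13
  features per split (the regression convention), seeded.
* **LOO protocol**: standardization statistics are recomputed inside every
  fold, so the held-out subject leaks nothing into its own prediction; a
  dedicated test corrupts a held-out target and verifies its prediction is
  unchanged. Predictions are returned in input order; a feature matrix with
  zero variance everywhere falls back to an intercept-only model with a
  warning.

## Evaluation

Per subject, `Error(%) = 100·|predicted − actual| / actual`, with ≤ 5 %
deemed acceptable (threshold inclusive). Aggregates: RMSE; Spearman rank
correlation (average ranks on ties, two-sided t-approximation p, 0.05
significance, optional permutation p); Bland–Altman with differences
**predicted − actual** (a negative mean therefore reads as underestimation),
limits mean ± 1.96·SD (sample SD), coverage counted strictly inside the
limits; and the Spearman correlation of error % against gestational age, a
drift check across gestation. Reported error percentages are rounded to one
decimal below 10 % and to integers above, matching clinical reporting
practice; CSV outputs keep full precision.

## Shapley attribution

Interventional (marginal-expectation) values: coalition value
`v(S) = mean over background rows b of f(x_S, b_{S̄})`. The default
estimator samples feature permutations (seeded; 1024 coalition evaluations
per subject ≈ 79 permutations of 13 features) with the full background
averaged at every step, so each permutation chain telescopes and the
efficiency axiom `Σ_j φ_j = f(x) − mean_b f(b)` holds exactly, not just in
expectation. An exact mode enumerates all 2¹³ coalitions with the Shapley
kernel weights for cross-checks on small backgrounds. The default background
is the cohort being explained (the natural choice when explaining a model on
its training set). Summaries take the **absolute mean** across subjects —
negative and positive contributions are equally "important" for a magnitude
ranking, and discarding negatives would bias the mean — with a
normal-approximation 95 % CI of the mean of |φ| (bootstrap is unnecessary at
cohort sizes ≥ 50; with one subject the CI is degenerate and flagged). For a
linear model the estimator reproduces the closed form
`φ_j = w_j (x_j − x̄_j)` to machine precision, which the tests assert.

## Synthetic data: what it emulates and what it does not

`generate_ecg` uses **integral pulse frequency modulation**: the prescribed
instantaneous interval `RRI(t) = mean + Σ a_k sin(2π f_k t + φ_k)` (seeded
random phases avoid degenerate phase alignment) drives an integrate-and-fire
beat emitter, the standard mechanism for placing beats with controlled RRI
spectral content. Beats start half an interval into the record and keep a
template-width margin from both edges so every ground-truth QRS is a
detectable interior maximum. Each beat stamps a Gaussian QRS (default FWHM
30 ms — only the R peak matters downstream, so morphology is deliberately
minimal); R-wave amplitude is `1 + Σ` respiration-style sinusoids; additive
baseline wander (0.3 Hz default) and white Gaussian noise complete the
waveform. Defaults mirror the recording protocol the pipeline targets:
20 min at 1 kHz, maternal mean RRI 763 ms, fetal 412 ms.

`generate_cohort` draws the 13 features from independent Gaussians with
means/SDs typical of mid-gestation cohorts (e.g. RRI 763 ± 114 ms, SDNN
34 ± 14 ms, age 34 ± 5.3 y), clipped at physiological floors (band powers at
0, RRI at 1 ms), and computes `fRRI = intercept + w·x + N(0, σ)`. The
default map puts weight on maternal RRI (0.15 ms/ms), age (1 ms/y), SDHR
(3 ms/bpm) and HF (0.02 ms per ms²), with intercept chosen so fRRI ≈
412 ± 22 ms; default σ = 10 ms gives a realistic signal-to-noise for
recovery tests. Identical spec + seed is bitwise reproducible.

**Limitations of the emulation** — and hence of what green tests prove about
real recordings: features are independent Gaussians (real HRV features are
correlated and skewed); the feature→fRRI map is linear and static (no
gestational-age interaction, no maternal–fetal coupling dynamics); noise is
white (no muscle artifact, electrode motion, or fetal-extraction residues);
QRS morphology is a single Gaussian (no P/T waves, so the detector is not
stressed by T-wave overcounting). Passing the recovery suite shows the
pipeline is *correct*, not that the published cohort-level accuracy
transfers to any particular dataset; the study's dataset-level statistics
are data-dependent and not reproducible without the original recordings.

## Problem sizes and numerical choices

The test and acceptance workloads use 5-min (detection) and 10-min
(feature-extraction) simulated records, LOO over cohorts of 150–200, ten
seeded replicate cohorts for the noise-floor check (RMSE pooled over all
1500 LOO residuals, since per-seed RMSE fluctuates by ~0.6 ms around the
10.4 ms expectation), and 60-subject Shapley runs at 1024 coalition samples.
Float CSVs are written with `%.17g` and read with round-trip parsing so
cohort tables survive I/O bit-exactly; every JSON report embeds the seed and
a config hash. Degenerate inputs (all-zero signals, zero-variance targets,
constant series, < 2 beats) raise typed errors or produce defined zero-power
results as documented per function.

## Scope

The pipeline ingests already-separated maternal and fetal ECG (CSV). Fetal
ECG extraction from abdominal composites (blind source separation) is out of
scope, as are nonlinear HRV indices, time-domain RWAV statistics,
hyperparameter search, and gestational-age prediction. ECG interchange is
CSV-only.
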