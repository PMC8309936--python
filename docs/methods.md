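# Methods

`posturokit` implements an analysis chain for self-directed smartphone
balance tests: a 30 s quiet-stance recording from the phone's accelerometer
and gyroscope is turned into quantitative sway features, a percentile-based
balance impairment score against a normative reference cohort, and a fused
logistic falls-risk estimate combining sensor and questionnaire evidence.
This note records the models, the tunable parameters and the design choices
made where the procedure was genuinely open.

## Signal model and preprocessing

A raw recording is seven channels: timestamps (s, possibly irregular since
phones sample "as fast as the OS allows"), tri-axial specific force
(m/s², gravity included) and tri-axial angular velocity (°/s).

Processing order is fixed:

1. **Resampling.** Linear interpolation onto a uniform grid (default
   100 Hz). The grid starts at the first timestamp (no phase snapping)
   and never extrapolates.
2. **Gravity alignment.** The mean acceleration over the middle 50 % of
   the test estimates the gravity direction; a single axis–angle rotation
   maps it onto the device's nominal vertical (default Z) and is applied
   to both sensors. This replaces any device-specific calibration: it is
   a deliberate, minimal calibration model, toggleable off
   (`calibrate=false`). A mean acceleration below 2 m/s² is treated as a
   sensor fault ("implausible gravity").
3. **Band-pass filtering.** 2nd-order Butterworth, 0.1–5 Hz, applied
   forward–backward (`sosfiltfilt`) for zero phase — postural sway phase
   relationships are preserved and DC (gravity) is removed exactly. Only
   the band is externally prescribed; the order/family and the zero-phase
   realisation are this package's choices, standard in the sway
   literature.
4. **Trimming.** The first and last 5 s are dropped so settling and
   repositioning transients (and, conveniently, all filter edge
   transients) never enter the analysis. The retained support is
   `[trim, duration − trim)` counting one sample interval past the last
   sample, so a 30 s test at 100 Hz yields exactly 2000 samples. After
   trimming, each channel's residual mean is subtracted, making the sway
   channels exactly mean-free (RMS is defined on mean-free channels).

Re-filtering an already processed signal reproduces it to ≈5 % RMS, not
exactly: the gentle 2nd-order corners re-attenuate band-edge content on
every pass. This is a property of the chosen low filter order, accepted in
exchange for minimal ringing.

**Quality control** mirrors the checks a supervised assessment would make,
with invented but config-exposed thresholds (the checks themselves are
standard; no canonical numbers exist):

* orientation: mean gravity within a 30° cone of the nominal vertical;
* repositioning transients: any 1-s window inside the settling interval
  whose acceleration RMS exceeds 5× the median 1-s-window RMS (noted; the
  trim already removes it);
* movement: the same 5× ratio on any retained window, or gyroscope window
  RMS above 50 °/s.

A failed orientation or movement check marks the test rejected; feature
extraction refuses rejected tests.

## Sway features

Fourteen scalars per test:

* RMS amplitude of each axis and of the per-sample Euclidean resultant,
  for acceleration (m/s²) and angular velocity (°/s) — 8 features. The
  resultant satisfies `rms_res² = rms_x² + rms_y² + rms_z²` exactly.
* Median frequency (50 % spectral power), spectral edge frequency
  (SEF, 95 % spectral power) and normalized spectral entropy
  `H = −Σ pᵢ log pᵢ / log K ∈ [0, 1]`, per sensor family — 6 features.

Spectral features are computed on the mean-removed resultant-norm channel
of each family (the sources say only "the acceleration and angular
velocity signals"; the resultant is orientation-independent, which suits
hand-held phones). The PSD estimator is a Welch averaged periodogram
(Hann, 5 s segments, 50 % overlap on the 20 s analysed signal — 3 bins/Hz,
7 averages); no estimator is externally prescribed. Band-limited
quantities use the filter passband [0.1, 5] Hz by default but the analysis
band is independently configurable, because published normative medians
for lumbar sensors (e.g. 5.32 Hz median frequency) exceed a 5 Hz cut,
implying a wider original analysis band. Zero band power yields NaN
("undefined"), never an exception or a fake zero.

## Balance score

Each feature is oriented so that the direction with the higher mean among
reference-cohort fallers counts as worse (no external per-feature
direction of "worse" exists, so it is learned empirically). The
per-feature percentile is the percentage of cohort subjects at or below
the subject's oriented value — a rank statistic, invariant under monotone
transforms. The subject's mean per-feature percentile is then itself
rank-normalised against the cohort's own mean-percentile scores; this
second percentile step is the package's design choice. It guarantees the
probability-integral-transform property: subjects drawn from the
reference population score uniformly on [0, 100], so "score 80" really
means "worse than 80 % of the reference cohort" even when features are
correlated or many. Without it, averaging ~14 percentiles concentrates
scores near 50 and the percentile interpretation breaks.

Missing features are excluded from the mean with a logged note. Scoring
requires a cohort of at least 20 subjects.

## Falls-risk estimate

Two maximum-likelihood logistic classifiers are fitted against the
12-month falls-history label of the reference cohort: one on the sway
features (standardized by the training cohort's mean/SD, stored in the
model so prediction is self-contained), one on the ten binary
questionnaire risk factors (missing items imputed at the training
prevalence). Quasi-separation (any |coefficient| > 30 on the standardized
scale) triggers a ridge refit (L2, α = 10⁻²) with a logged warning.

Prediction fuses the posteriors: `p = λ·p_sensor + (1 − λ)·p_quest` with
λ = 0.5 by default (arithmetic mean; the fusion rule of the original
validated model is not public, and λ is exposed in config). The fused
posterior, reported in percent, is bounded by the component posteriors
for any λ ∈ [0, 1]. The estimate is **undefined below age 60** — an
explicit status, not zero and not an exception. If every questionnaire
item is missing, the sensor posterior is used alone and flagged.

The shipped training procedure is the contribution here; no claim is made
to reproduce the proprietary deployed coefficients. Models serialize to
JSON (coefficients, scaling, λ).

Risk categories partition [0, 100]: low < 50, medium [50, 70),
high ≥ 70. The published category wording leaves [69, 70) unassigned
("50–69 %" vs "> 70 %"); it is closed as medium = [50, 70).

## Cohort-level evaluation

* **Outlier rule:** per feature column, values strictly outside µ ± 2σ
  (mean and *sample* SD computed once from the full column, single pass,
  no re-estimation — the literal reading) are set to missing; missing
  values are excluded from µ, σ and all later analyses.
* **Per-phone averaging:** each phone is a participant surrogate;
  features are averaged per phone, and phones whose recorded gender or
  age changes between assessments are excluded.
* **Prevalence summaries:** count and percent (one decimal) of positive
  responses per risk factor, denominator = all responses.
* **Association tests:** standard one-way fixed-effects ANOVA
  (`scipy.stats.f_oneway`; normality/homoscedasticity deliberately not
  tested, matching common usage — a documented limitation) and a
  two-sided unequal-variance z-test
  `z = (x̄_a − x̄_b)/√(s_a²/n_a + s_b²/n_b)`; samples under 30 are flagged
  approximate.
* **Classification vs falls history:** 3-class (0 falls → low, 1 →
  medium, ≥ 2 → high) or 2-class (0 → non-faller, ≥ 1 → faller; low
  category predicts non-faller, medium and high merge to faller).
  Accuracy = 100·trace/total; sensitivity per true class; predictivity
  per predicted class. Empty classes give NaN, never zero, to avoid
  biasing summary tables. Merging 3 → 2 classes can only convert errors
  into correct cells, so 2-class accuracy ≥ 3-class accuracy.

## Synthetic data

The generators define the conditions every test runs under; they emulate
the study setting, not balance physiology.

* **Sway recordings:** gravity on the nominal vertical plus Gaussian
  noise shaped in the frequency domain (flat by default over 0.3–3 Hz —
  inside the analysis band, so the pipeline's filters barely attenuate
  it) scaled per axis to RMS targets, with optional timestamp jitter and
  injected pulse/drift/tilt artifacts. Default per-axis targets are
  scaled so the resultants hit the lumbar normative means (0.22 m/s²
  acceleration, 1.68 °/s angular velocity): the published per-axis means
  cannot be used directly because a population mean of resultants does
  not satisfy the resultant identity, and no gyroscope Z-axis normative
  value is published (1.21 °/s is invented to close the identity). The
  end-to-end closure test recovers these targets through the full
  pipeline within ~2 % (50-seed mean; tolerance 10 %).
* **Reference cohorts:** 277 subjects with exactly 100 fallers by
  default; features drawn per class from zero-truncated Gaussians at the
  normative means/SDs (entropy additionally truncated at 1), fallers
  shifted by invented standardized effect sizes (+0.4 on RMS features,
  −0.3 on entropies, 0 on spectral frequencies). Features are drawn
  independently (no published covariances); a correlation hook is the
  natural extension.
* **Assessment tables:** 594 assessments over 147 phones by default;
  per-phone counts are zero-truncated geometric (over-dispersed repeat
  use), falls-history classes at the deployment proportions
  (388/72/134 of 594), questionnaire items at the published prevalences
  (dizziness 20 % and foot problems 15 % are invented — no published
  values) coupled to faller status through odds ratios (2.0 for
  polypharmacy, mobility problems and dizziness; 1.0 otherwise; all
  invented so association tests have signal). Risk categories are drawn
  from an explicit confusion kernel given the true history class, so the
  expected accuracy of the evaluation module is known analytically
  (75.6 % 3-class, 84.3 % 2-class under the defaults).

Because features, categories and questionnaire items are generated from
explicit parametric models, passing tests demonstrate the correctness of
the algorithms and the internal consistency of the chain — not clinical
validity on real sway data, which would require the proprietary
deployment and reference datasets.

## Numerical choices and problem sizes

* Percentiles use non-strict comparison (`≤`), so a subject tied with
  cohort members ranks above them; scores are discrete at 100/n
  resolution.
* SEF/median frequency return the smallest grid frequency whose
  cumulative band power reaches the edge fraction (with a 10⁻¹² relative
  tolerance for exact ties); they are grid-valued, accurate to one
  frequency bin (0.2 Hz at the default Welch settings).
* Entropy uses natural log (any base cancels under normalization) with
  0·log 0 := 0.
* Standing simulation sizes: 50 seeds for closure and null simulations,
  n = 2000 for coefficient recovery, n = 500 for score-uniformity — sizes
  at which the checked tolerances are comfortably resolvable while the
  whole suite stays quick.
* Seeded `numpy.random.default_rng` everywhere; identical (params, seed)
  give bit-identical outputs.

## Known limitations

* The gravity alignment is static; slow orientation drift within a test
  is not tracked (out of scope).
* The sway generator is spectrally shaped noise, not an inverted-pendulum
  model; features involving true postural dynamics (e.g. realistic
  medf/SEF distributions per class) are only as faithful as the chosen
  target distributions.
* ANOVA/z-test assumptions are not verified, matching the evaluated
  usage.
* The deployed product's original classifier weights and fusion rule are
  unavailable; shipped models are synthetic-trained demonstrations.
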