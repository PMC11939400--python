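# Methods

## Scope and data model

The package analyses cohorts in which each participant contributes, per
season (winter / spring / summer / autumn), one 7-day wrist recording at
1-minute resolution — motor activity (PIM counts), white-light illuminance
(lux), blue-light irradiance (µW/cm²), wrist skin temperature (°C) — and
one 08:00 blood sample quantified by real-time PCR (target gene vs a
reference gene such as GAPDH).

Timestamps are naive local clock time throughout; no UTC or solar-time
conversion is applied. Every endpoint of interest — acrophase, M10/L5
onsets, clock-epoch correlations — is defined on the local clock, and the
blood draw is anchored to local 08:00.

Missing or corrupt minutes are **masked, never imputed**. Downstream
aggregates (hourly bins, 30-min clock epochs, whole-recording fits) require
at least 80% valid minutes in their support and are reported missing
otherwise. The 80% rule is this package's convention; recordings shorter
than the nominal 10080 minutes are accepted but flagged.

## Cosinor rhythmometry

The multi-component cosinor model

  y(t) = M + Σ_k A_k·cos(2π(t − φ_k)/τ_k) + e(t)

is linear in β_k = A_k cos(2πφ_k/τ_k), γ_k = A_k sin(2πφ_k/τ_k) and fitted
by OLS. Conventions and numerical choices:

* **Acrophase** is reported as the positive local clock time of the
  component maximum in [0, τ), not the classical negative-degrees phase
  (a converter `acrophase_to_degrees` is provided). This makes fitted peak
  times directly readable as clock times.
* **Zero-amplitude test**: F = [(TSS − RSS)/(2m)] / [RSS/(n − 2m − 1)] for
  m components jointly, referred to F(2m, n − 2m − 1). A numerically
  perfect fit (RSS ≈ 0) is flagged `degenerate`; it is treated as rhythmic
  for peak reporting but its F/p are not meaningful.
* **Confidence intervals** for M, A_k, φ_k use the delta method on the
  (β, γ) covariance, rather than exact Halberg elliptical regions. Coverage
  is verified by simulation (≈95% for all parameters at minute sampling
  over a week; see `experiments.cosinor_ci_coverage`).
* **Peak times** of the full fitted curve are local maxima on a 1-minute
  grid over [0, 24), cyclic, ties broken by earliest clock time — matching
  minute-precision peak reporting.
* Light channels are fitted on raw lux by default; a log10(x+1) transform
  is available (`log_light=True`) because illuminance is heavy-tailed. The
  "light phase" used by the GLMs is the 24 h acrophase of white light.

## Non-parametric circadian metrics

On consecutive bin means x_i (60-min bins by default; configurable, must
divide 1440), with N total bins, p bins per day, and x̄_h the p clock-time
means:

* IS = [N·Σ_h (x̄_h − x̄)²] / [p·Σ_i (x_i − x̄)²]
* IV = [N·Σ_{i≥2} (x_i − x_{i−1})²] / [(N−1)·Σ_i (x_i − x̄)²]
* M10/L5: extreme cyclic 10 h / 5 h moving-window means of the average day
  profile (profile first, windows second — not per-day extremes averaged);
  onsets are window start clock times, ties to the earliest.
* RA = (M10 − L5)/(M10 + L5); undefined (flagged) when M10 + L5 = 0.
* CFI = [IS + clip((2 − IV)/2, 0, 1) + RA] / 3 — the equal-weight composite
  convention. Note the source literature names CFI without a formula;
  cross-software numeric identity is not claimed.

Finite-sample behaviour worth knowing: on iid noise with d days of hourly
bins the sampling means are ≈(p−1)/(N−1) for IS (0.1377 for a week, vs the
asymptotic landmark 1/d = 1/7) and ≈2N/(N−1) for IV (2.012, landmark 2).
IV also loses one first-difference at the series boundary, which makes CFI
only approximately invariant under rotations of the day profile (~10⁻²).

## Relative expression (2^−ΔΔCq)

ΔCq_i = Cq_target,i − Cq_reference,i; ΔΔCq_i = ΔCq_i − ΔCq_cal;
RE_i = 2^−ΔΔCq_i. The default calibrator is the **mean ΔCq of the winter
group**, so seasonal profiles read as fold change versus winter; an
explicit calibrator sample is supported. Because RE_i/RE_j never depends on
the calibrator, every downstream statistic is calibrator-invariant; the
choice only sets the unit. No amplification-efficiency (Pfaffl) correction
and no replicate aggregation are applied.

## Clock-time correlation mapping

Per recording, the channel is averaged in 48 consecutive 30-minute clock
epochs pooling all days (≥80% coverage per epoch). Across participant-
season observations, expression is correlated with each epoch mean
(Pearson; Spearman available for sensitivity only), p from
t = r√((n−2)/(1−r²)). The 48 p-values form one Benjamini–Hochberg family at
q = 0.1; epochs with undefined r (zero variance, n < 3) are dropped from
the family with a logged count. All seasons are pooled into one family by
default (`per-season` subsets can be passed explicitly); pooling repeated
observations of a participant across seasons without a non-independence
correction replicates the emulated design and is a documented caveat, not a
recommendation.

The correlation-vs-clock-time profile is then approximated by a 24 h + 12 h
harmonic (cosinor) fit on the 48 (midpoint, r) points; fitted local maxima
are reported as major/minor by fitted height. When the 24 h amplitude CI
covers zero, a 12 h-only refit is attached — the structure seen when the
profile is symmetric/bimodal (as for activity). An outlier diagnostic
(|externally studentized residual| > 3 in the per-epoch regression) is
provided for inspection; nothing is ever auto-removed.

## Seasonal inference

* One-way ANOVA across seasons with Tukey HSD (studentized range) post hoc
  and per-group Shapiro–Wilk reported alongside; Kruskal–Wallis on request.
* Sigma-restricted GLM (ANCOVA): continuous predictors z-scored; binary
  factors effect-coded −1/+1 (second sorted level = +1) and left at those
  codes; the response z-scored so single-df βs are standardized
  coefficients (the `coef` column carries the per-SD effect on the raw
  response scale). Season enters by default as a single ordered numeric
  contrast winter < spring < summer (one printed β implies 1 df); a
  categorical k−1-column effect coding is available. Per-term F is the
  Type-III partial F (t² for single-df terms); partial
  η² = SS_term/(SS_term + SS_res) = F·df1/(F·df1 + df2); observed power is
  the noncentral-F tail at ncp = F_obs·df1, α = 0.05 — the sample-estimate
  convention of mainstream ANCOVA software. Restricting the fitted seasons
  (e.g. omitting autumn to avoid over-representing equinox light) is a
  flag, not a data edit.
* No mixed-effects/repeated-measures modelling: observations are treated as
  independent across seasons, matching the emulated analysis; this is a
  known limitation.

## Synthetic cohort generator

The generator defines the study conditions and the ground truth used by all
recovery experiments. Defaults: 29 participants, 27.6% natives (8 of 29),
seasonal participation 29/22/25/21 (winter/spring/summer/autumn, drawn as
exact-size random subsets so cohort counts are deterministic), 7-day
recordings.

* **Light**: a raised-cosine daylight envelope of width equal to the
  seasonal photoperiod (winter 1 h, equinoxes 12 h, summer 24 h) centred at
  12:00 plus a per-recording Gaussian centre jitter (sd 0.25 h, keeping
  acrophase spread within about an hour), multiplied by a per-person hourly
  "habit" profile (lognormal, sd 0.35 on the log scale, constant across the
  week — people differ in when they are outdoors) and per-minute mean-one
  lognormal noise (sd 0.5), gated to zero in the sleep window, plus a small
  ungated indoor/leakage baseline (0.5 lux). The habit profile and the
  baseline are deliberate realism features: without between-person
  profile-shape variation the 48 epoch means are collinear across the
  cohort and no predictive window is identifiable, and without nocturnal
  baseline variance the night epochs have undefined correlations and the
  harmonic model is unconstrained over a third of the clock. Peak daytime
  illuminance 1000 lux; blue channel = 2% of the white-light curve with its
  own noise.
* **Activity**: participant-level 24 h cosine (MESOR 150 ± 25 counts,
  amplitude 120 ± 20, acrophase 15:00 ± 0.75 h), clipped at zero, gated to
  near-zero during sleep (23:00–07:00 by default, configurable per season,
  disableable), plus exponential non-negative noise (mean 10 counts awake,
  reduced to 20% asleep). **Wrist temperature**: 24 h cosine in antiphase
  to activity (MESOR 34 °C, amplitude 1 °C) plus Gaussian noise (0.3 °C).
* **Ground truth** per participant-season is the 24 h cosinor of the
  *expected* (noise-free) minute curve — exactly the quantity the
  estimators converge to, so recovery tests are well-posed even under
  gating and habit modulation.
* **Expression**: log2 RE = b₀ + b_season(s) + b_native·1[native] +
  0.35·z(light MESOR) + 0.25·z(light acrophase) + 0.25·z(activity MESOR) +
  N(0, 0.6), with z-scores taken across the generated cohort and season
  offsets (−0.4, 0, +0.5, +0.2) giving the summer-max / winter-min ordering
  and native > non-native (b_native = 0.3). Magnitudes were chosen once to
  give Table-1-scale standardized effects; they are conventions, not fitted
  values. An alternative coupling mode ties expression to mean light in a
  configurable clock window (default 16:00–20:00, b = 0.8, residual 0.5)
  for end-to-end peak-localisation experiments. Quantification cycles are
  generated as Cq_ref ~ N(20, 0.5), Cq_target = Cq_ref + (3 − log2 RE), so
  the 2^−ΔΔCq stage inverts them exactly up to the calibrator convention.
* **Determinism**: one RNG substream per participant-season (and per
  channel) is derived from the master seed, so subsetting participants,
  seasons or channels never changes the remaining data; identical
  (config, seed) reproduce the cohort bit-identically.

What the generator does **not** emulate: weather/cloud cover, solar-time
offsets from longitude, free-running (non-24 h) periods, melatonin/DLMO
physiology, realistic sleep architecture (sleep is a hard gate), or
device-specific calibration. Passing recovery tests therefore demonstrates
correctness of the estimators under the stated statistical structure, not
fidelity to any particular device or population.

## Validation experiments and problem sizes

`circaseason.experiments` packages the Monte-Carlo studies used by the test
suite and the acceptance script: CI coverage (500 replicates of a noisy
two-component rhythm at minute sampling; script uses 300), zero-amplitude
type-I error (1000 white-noise series of 168 hourly points), iid-noise
IS/IV sampling means (1000 replicates; script 500), correlation-map peak
recovery on window-coupled cohorts of 60 participant-season observations
(500 replicates; script 200), and GLM coefficient recovery on default
cohorts of 97 observations (500 replicates; script 150). The reduced script
sizes keep a from-scratch reproduction quick while the full-size runs live
in the test suite; Monte-Carlo error bands scale accordingly.
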