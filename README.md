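# circaseason

Seasonal circadian rhythmometry for cohorts that combine week-long wrist
actigraphy (activity counts, white/blue light exposure, wrist temperature)
with a single morning qPCR measurement of clock-gene expression — the study
design used to ask how, at high Arctic latitudes, the extreme seasonal swing
in photoperiod (near-total winter darkness to continuous summer daylight)
shapes morning expression of a light-entrained gene, and which features of
the personal light and activity rhythm predict it.

The package provides, as composable estimators plus a thin CLI:

* **Cosinor rhythmometry** — single- and multi-component least-squares fits
  of `y(t) = M + Σ_k A_k cos(2π(t − φ_k)/τ_k)`, with MESOR `M`, amplitude
  `A_k`, acrophase `φ_k` reported as the local clock time of the component
  maximum, the zero-amplitude test `F = [(TSS − RSS)/2m]/[RSS/(n − 2m − 1)]`,
  delta-method 95% CIs, and fitted-curve peak detection on a 1-minute grid.
* **Non-parametric circadian metrics** — inter-daily stability (IS),
  intra-daily variability (IV), M10/L5 with onsets on the average day
  profile (cyclic windows), relative amplitude `RA = (M10 − L5)/(M10 + L5)`,
  and the circadian function index
  `CFI = [IS + clip((2 − IV)/2, 0, 1) + RA]/3`.
* **qPCR relative expression** — the `2^−ΔΔCq` method against a reference
  gene, with group-mean (default: winter) or explicit-sample calibration;
  all expression ratios are calibrator-invariant.
* **Clock-time correlation mapping** — Pearson correlation of expression
  with channel means in 48 consecutive 30-min clock epochs pooled across the
  recording week, Benjamini–Hochberg FDR at q = 0.1 across the epoch family,
  and a 24 h + 12 h harmonic model of the correlation profile whose fitted
  maxima locate the clock windows where exposure best predicts expression.
* **Inference** — one-way seasonal ANOVA with Tukey HSD post hoc and
  Shapiro–Wilk annotation, and sigma-restricted GLMs (ANCOVA) reporting per
  term the standardized β with 95% CI, Type-III F, partial
  `η² = F·df1/(F·df1 + df2)`, and observed power at the sample
  noncentrality `ncp = F·df1`.
* **A synthetic cohort generator** with full ground truth — photoperiod-
  driven raised-cosine daylight envelopes, sleep-gated activity/light,
  per-person light-habit profiles, and expression linearly coupled (log2
  scale) to light MESOR, light acrophase, activity MESOR, season and
  population — so every estimator can be validated by parameter recovery.

## Worked example

```python
from circaseason import GeneratorConfig, simulate_cohort, seasonal_anova, fit_glm
from circaseason.pipeline import build_cohort, derive_metric_table, run_correlation_analysis

cohort = simulate_cohort(GeneratorConfig(), seed=42)          # 29 participants, 97 recordings
metrics = derive_metric_table(cohort.recordings,
                              cosinor_channels=("light", "activity"),
                              npcra_channels=("activity",))
table = build_cohort(cohort.expression, cohort.meta, metrics=metrics)

res = seasonal_anova(table, response="relative_expression")
cmap, model = run_correlation_analysis(table, cohort.recordings)
glm = fit_glm(table, "log2_re",
              ["light_mesor", "light_acrophase", "population", "age", "bmi", "sex"],
              seasons=["winter", "spring", "summer"])
```

prints (via the obvious `print` calls):

```
ANOVA F(3,93) = 33.498, p = 9.04e-15
significant epochs: 33
peaks: [(18.77, 0.71), (10.93, 0.491)]
           term   beta      F     p  partial_eta_sq  observed_power
    light_mesor  0.651 62.817 0.000           0.477           1.000
light_acrophase  0.256  9.564 0.003           0.122           0.862
     population -0.081  1.034 0.313           0.015           0.171
            age  0.116  2.857 0.095           0.040           0.385
            bmi  0.063  0.845 0.361           0.012           0.148
            sex -0.093  1.792 0.185           0.025           0.262
```

Reading: expression differs strongly across seasons (summer highest, winter
lowest — the Tukey table pins the pairwise contrasts); light exposure in 33
of the 48 clock epochs survives FDR, and the harmonic model places the major
predictive peak at 18:46 with a secondary late-morning peak; in the ANCOVA
the light MESOR is the dominant predictor of log2 expression, followed by
the light acrophase (β is per SD of predictor on the standardized response;
binary factors are coded −1/+1, here `nonnative = +1`, so the negative sign
means higher expression in natives).

The same stages are scriptable:

```bash
circaseason simulate --seed 42 --out run/
circaseason qpcr --expr run/expression.csv --out run/re.csv
circaseason corrmap --acti run/actigraphy --expr run/expression.csv \
                    --meta run/metadata.csv --out run/cm
circaseason pipeline --seed 42 --out run/full
```

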