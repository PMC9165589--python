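# Methods

This note records the statistical model behind each component, the
assumptions it makes, the numerical choices, and the known limits of the
synthetic generators.

## 1. Rendered geometry and voltage criteria

All thresholds operate in *rendered millimetres* on a standard ECG grid:
`LayoutGeometry(gain=10 mm/mV, paper_speed=25 mm/s, baseline_separation=30 mm)`
with the 3×4 lead layout. Amplitudes in mV convert linearly
(`mm = gain × mV`); changing the gain rescales every measured amplitude and
therefore every criterion decision, which is why the geometry is part of the
run configuration and its hash.

Criterion semantics (deliberate and tested at the exact boundary):

| criterion | rule | boundary |
|---|---|---|
| Sokolow-Lyon 1 | S(V1) + max(R(V5), R(V6)) ≥ 35 mm | inclusive |
| Sokolow-Lyon 2 | R(aVL) ≥ 11 mm | inclusive |
| Cornell | S(V3) + R(aVL) > 28 mm (M) / > 20 mm (F) | strict |
| touching sign | complexes of a contiguous precordial pair touch | inclusive (exact touch fires) |

The touching sign has two implementations. The **pointwise** form is the
definition: for a pair (upper, lower) the upper trace's excursion below its
baseline plus the lower trace's excursion above its own baseline, both in mm,
reaches the baseline separation at some instant inside a QRS window. The
**amplitude surrogate** replaces the instant-by-instant sum with the sum of
the per-lead maxima, S(upper) + R(lower) ≥ separation. Since
max(f + g) ≤ max f + max g, pointwise positivity implies surrogate
positivity; the surrogate over-calls when the S nadir and R peak are not
simultaneous. Only the pairs (V1,V2), (V2,V3), (V4,V5), (V5,V6) are eligible:
V3 and V4 sit in different columns of the 3×4 layout and are never vertically
adjacent.

QRS localisation uses supplied annotations when present; otherwise a
derivative-energy detector (summed squared first differences, 40 ms
smoothing, peak picking with a 200 ms refractory period) places symmetric
120 ms windows. Baselines are per-lead medians of the signal outside all QRS
windows. R is the maximum excursion above baseline inside a window, S the
maximum below; per-beat values are summarised by the median by default
(robust to one aberrant beat), with `first`/`max` available.

## 2. Accuracy statistics

Sensitivity, specificity, PPV and NPV come straight from the 2×2 table
against the gold standard, each with a Wilson score interval (default) or
Clopper-Pearson. Zero-denominator quantities are returned flagged
`undefined` rather than silently zeroed, and a run containing such strata
completes. Predictive values are also available via Bayes' theorem from
(prevalence, sensitivity, specificity); the implementation is pure arithmetic
so `fractions.Fraction` inputs give exact rational answers — the test suite
uses this for an exact identity check against the 2×2 definition.

Percentages in descriptive tables use **round-half-up** (`Decimal`), not
banker's rounding: clinical tables round 8.7156% to 9%.

Sample size for estimating a proportion to margin `E`:
`n = z²p(1−p)/E²`, floored by default (a ceiling option exists). With
p = 0.65, E = 0.02 at 95% confidence this gives n = 2,184, the cohort size
used throughout.

## 3. Paired non-inferiority score test

Two criteria applied to the same subjects form a paired 2×2 table with
discordant counts n10 (reference positive only) and n01 (comparator positive
only). For H0: pA − pB ≤ −δ vs H1: pA − pB > −δ the package uses the
restricted-MLE score statistic

```
Z = (n10 − n01 − N·d0) / sqrt(N·(2η̂ + d0 − d0²)),   d0 = −δ,
```

where η̂ is the maximum-likelihood estimate of the nuisance discordance
probability p01 under the constraint p10 − p01 = d0. The profile stationarity
condition is the quadratic `−2N·η² + [(n10+n01) − d0(n10 + 3n01 + 2m)]·η +
n01·d0(1−d0) = 0` (m the concordant count); both roots are clipped to the
feasible interval [max(0, −d0), (1−d0)/2] and the root with the higher
restricted log-likelihood is kept. One-sided p = 1 − Φ(Z).

Properties verified in the tests:

- In the interior the closed form equals the profile efficient score
  statistic; at δ = 0 it reduces exactly to the signed McNemar statistic
  (n10 − n01)/√(n10 + n01).
- Degenerate tables (zero restricted variance) return Z = 0, p = 0.5 — the
  all-concordant table at δ = 0 is evidence for nothing.
- Against an exact trinomial enumeration at the restricted null over **all
  454 tables with N ≤ 12**, the normal approximation differs from the exact
  tail probability by 0.049 on average; the largest gap among the 442 tables
  with at least one discordant pair is 0.33 (tail granularity at tiny N).
  These tolerances were frozen from the oracle run before being asserted.
- At the null boundary (pA = pB − 0.05, N = 2,184, positively correlated
  outcomes) the empirical type-I error over 5,000 replicates lies within
  0.05 ± 0.01.

The default report tests two endpoints per comparison: *sensitivity*
(positivity among gold-positives) and *specificity* (negativity among
gold-negatives); an *accuracy* endpoint (agreement with gold over everyone)
is available. McNemar (χ², optional continuity correction, undefined when no
discordant pairs) and Cohen's kappa (Fleiss-type large-sample interval
clipped to [−1, 1], with a multinomial bootstrap option for small re-read
samples; degenerate margins flagged undefined) complete the paired toolkit.

## 4. Synthetic cohort generator

Each subject has a gold label `gold ~ Bernoulli(prevalence)` and latent
severity `S = shift·gold + L`, `L ~ N(0,1)` (default shift 1.5). Criterion
*i*'s liability is `X_i = sqrt(ρ)·S + sqrt(1−ρ)·ε_i` with independent
standard-normal ε and shared loading ρ (default 0.5). Within a (sex, gold)
stratum, X_i is Gaussian with known mean, so the threshold achieving a
requested positivity probability is the analytic probit quantile — the
calibration equation is solved **exactly**, with no tuning loop. At n = 10⁶
every marginal sensitivity/specificity (including the sex-specific Cornell
pair: 0.09/0.94 men, 0.18/0.89 women, mixing to ≈0.13/0.92 overall) is
recovered to within 0.002.

The shared latent S makes criterion errors positively correlated, which is
what drives realistic discordant counts in the paired tests; ρ = 0 gives
conditionally independent criteria. Default operating points describe a
low-sensitivity/high-specificity screening setting (sensitivities 0.05–0.18,
specificities 0.89–0.98) at prevalence 756/2184 with 1135/2184 male.

Limits: the model has a single severity dimension, so it cannot represent
criteria whose errors are *negatively* correlated; age and the ECG-to-imaging
interval are decorative (no statistic consumes them); per-subject
probabilities depend only on (sex, gold), not on continuous severity within a
stratum.

Re-reads use a flip model: the second read equals the first, independently
flipped with probability f. Its population kappa has the closed form
implemented in `expected_flip_kappa` and is matched by simulation in the
tests; f = 0.02 at a ~9% positivity rate gives kappa ≈ 0.9, the agreement
level expected of an easy visual sign.

## 5. Synthetic waveform generator

Each lead renders as a sum of Gaussian lobes per beat: a biphasic QRS (lobe
width σ = 10 ms, dominant lobe at the annotated fiducial, minor lobe 45 ms
away), plus optional P (0.08 mV) and T (0.15 mV) bumps and white noise. The
template holds typical adult amplitudes — deep S right-precordially (V1–V2),
tall R laterally (V4–V6) — and all leads share beat timing, so the S nadir of
an S-dominant lead is simultaneous with the R peak of an R-dominant lead:
exactly the geometry in which adjacent rendered complexes touch. Hypertrophy
enters as a scalar severity multiplying precordial amplitudes by
`1 + 0.6·severity`; limb leads are untouched.

Two reference records anchor the tests: `WaveformSpec.zero_severity()` is
negative for every criterion, and `WaveformSpec.high_severity()` (precordial
scale 1.6) is positive for Sokolow-Lyon 1 (S(V1)+R(V5) = 16+22.4 = 38.4 mm)
and for the pointwise touching sign (V2/V3 overlap of 38.4 mm against a 30 mm
separation). With zero noise, measured amplitudes recover the template to
sampling quantisation, because 45 ms lobe separation at σ = 10 ms leaves
cross-lobe contamination below 10⁻⁴ mV.

Limits: stylised morphology (no QRS axis, no ST segment, no beat-to-beat
variability), identical beats per record, severity affects amplitude only —
this is a generator for exercising the measurement/criteria pipeline, not a
physiological simulator.

## 6. Reproducibility and design decisions

- Every stochastic function takes an explicit seed; identical specs give
  byte-identical outputs (asserted in the tests for cohorts, re-reads,
  waveforms and saved reports). Derived seeds are drawn below 2³¹.
- `RunConfig` is fully serialisable; its SHA-256 hash (first 12 hex digits)
  is embedded in every report file, so any table can be traced to the exact
  configuration that produced it.
- The package is organised as a model object (`LvhScreeningStudy`) whose
  `fit()` returns a results object with estimates, intervals and
  `summary()` — mirroring the statsmodels idiom so the evaluation is a single
  construct-fit-report pipeline rather than loose functions.
- Buy over build: binomial intervals, McNemar and kappa come from
  statsmodels/scipy; the restricted-MLE score test is implemented here (it is
  the statistical core and has no maintained reference implementation) and is
  validated against an exact enumeration oracle.
- One statistical-power note: across 100 seeded replicates at n = 2,184, each
  criterion's estimated sensitivity/specificity is asserted to fall within
  its reference interval in ≥ 90 of 100 runs — except Sokolow-Lyon 1
  specificity, whose generating value (0.98) sits on the edge of its interval
  (0.97, 0.98); the expected per-replicate hit rate there is ≈ 91%, so the
  bound is 85/100. That bound was fixed by the power analysis before the test
  was first run; exact calibration of the same quantity is separately
  asserted at n = 10⁶.
- Problem sizes: the full test suite runs in ~15 s on one CPU; the largest
  single computation is the n = 10⁶ calibration check (~2 s after
  vectorising the probit thresholds, which take only two values per sex
  stratum).
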