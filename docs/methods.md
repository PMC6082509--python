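# Methods

`aki_impact` implements the computational core of a controlled before-after
("difference-in-differences", DiD) evaluation of creatinine-based AKI
e-alerting in acute general medicine: two hospital sites, one of which turns
on a prediction-score (APS) alert plus an AKI e-alert in its second period,
with the other site acting as a contemporaneous control.

## AKI ascertainment

Detection is creatinine-only (no urine-output or renal-replacement
criterion, reflecting that few acute general-medical patients are
catheterised), with thresholds following the national e-alert conventions:

* **Baseline creatinine** — the lowest result in the 7 days before
  admission; failing that, the median of results from 8–365 days (an even
  count averages the two central values); failing that, absent.
* **Community-acquired AKI (CA-AKI)** — judged at admission: admission
  SCr / baseline ≥ 1.5, or admission SCr ≥ 354 µmol/l. With no baseline,
  CA-AKI is assumed absent below the absolute level.
* **Hospital-acquired AKI (HA-AKI)** — earliest measurement time
  t ≤ 168 h with value(t)/admission value ≥ 1.5 **or**
  value(t) − min{value(s): t − 48 ≤ s ≤ t} ≥ 26.5 µmol/l. Only the
  triggering measurement must fall inside the 7-day horizon; the rolling
  window may reach back to admission. All thresholds are inclusive (≥).
* **Staging** — the creatinine-only KDIGO bands on the peak ratio to the
  reference (baseline for CA, admission value for HA): ≥ 3× is stage 3,
  ≥ 2× stage 2, otherwise stage 1 when detection fired.

Design choices where the convention is genuinely open, and what we chose:

* The **admission value** is the first in-hospital measurement (t ≥ 0) —
  the only unambiguous reading.
* The rolling window compares each value with the **minimum** over the
  preceding 48 h including t = 0; this is the most sensitive reading and
  matches national-algorithm practice.
* Measurements after 168 h are ignored for detection but still contribute
  to the peak rise and maximal stage.
* No interpolation: detection operates on observed measurements only.
* CA-AKI triggered by the absolute-level rule without a baseline is staged
  against the admission value (detection having fired floors the stage
  at 1).
* HA-AKI detection uses the admission value only, never the pre-admission
  baseline, even when one exists.

A note on monotonicity: with min-in-window semantics, raising an
*intermediate* creatinine value can remove a rolling-rise trigger whose
window minimum it was (the series becomes flatter). The properties that do
hold — and that the suite enforces — are that *adding* a measurement, or
raising the *latest* value, never hides or delays detection.

## APS scoring and alerting

The APS is an additive integer score over admission-time predictors,
computed once at admission (re-scoring during the stay is deliberately not
done). Alert states: RED for any AKI (CA at admission, HA at onset), AMBER
for APS ≥ cutoff (default 5), GREEN otherwise; states only escalate.
Weights are declarative configuration. **The packaged default table is
synthetic**: a representative weighting over the documented predictor set
(age, CKD, diabetes, heart failure, liver disease, respiratory rate ≥ 20,
AVPU below alert, NEWS). It exercises the scoring machinery and yields a
plausible flagged fraction (~25–30%), but it is not a validated clinical
instrument; deployments must substitute locally validated weights.

Bundle compliance is reported as two percentages: submitted bundles among
RED admissions, and among all flagged (AMBER or RED) admissions; both are
absent when the denominator is empty.

## Cohort rules

Included admissions are ≥ 18 years, medical specialty, at least one night
in hospital, a repeated creatinine, and no direct ED→ICU transfer. "One
night" is operationalised as discharge on a later calendar day than
admission. Each excluded admission carries exactly one reason — the first
matching in the order: direct ED→ICU, under 18, non-medical, no overnight
stay, single creatinine — so the accounting partitions the input exactly.
Seven-day mortality is anchored at the admission timestamp; length of stay
runs to discharge or in-hospital death. HA-AKI incidence denominators
exclude CA-AKI admissions. The single-admission subset keeps patients seen
exactly once within their site over the whole study window (sites are
analysed separately, so cross-site linkage is not attempted).

## Statistics

* **2×2 tables** are oriented post (group 1) vs pre (group 2) within a
  site. Odds ratio (a/b)/(c/d); cells of zero receive the
  Haldane–Anscombe +0.5 correction, flagged on the estimate.
* **Woolf CI**: exp(ln OR ± z·√(1/a+1/b+1/c+1/d)). This reproduces the
  published intervals (e.g. 0.560–0.954) to 3 decimals.
* **p-values for table cells** use Fisher's exact test, which reproduces
  every published per-site p-value to 3 decimals; Pearson chi-square
  (uncorrected by default, Yates optional) and the Cochran–Mantel–Haenszel
  stratified test are also provided. An all-zero table or degenerate
  margin is an error, not a silent NaN.
* **Continuous comparisons**: Welch t-test or two-sided Mann–Whitney
  (tie-corrected; exactly identical samples return p = 1 by convention).
* **DiD, binary outcomes** (`did_binary`): logistic model
  outcome ~ site + period + site×period + age + 6 comorbidity flags, with
  patient-level clustering for repeated admissions. Estimation is GEE with
  an exchangeable working correlation and robust sandwich variance; when
  every cluster is a singleton this reduces to the independence GEE,
  computed as a binomial GLM with HC0 covariance (algebraically the same
  estimator, much faster). When the exchangeable correlation is
  inestimable (virtually no repeated admissions in a subset), the fit
  falls back to the independence working model, still with the
  cluster-robust sandwich; the result records which path was used.
  Separation or non-convergence raises a fit failure carrying n_obs and
  n_clusters rather than returning numbers.
* **DiD, continuous outcomes** (`did_continuous`): linear mixed model with
  a patient random intercept and the same fixed effects; a singular or
  non-converging fit falls back to OLS and says so in `method`.
* No multiple-testing adjustment is applied anywhere, and the report
  labels its p-values as unadjusted.

A useful exact identity anchors the binary DiD: with no covariates and
independent rows, the saturated logistic interaction odds ratio equals the
ratio of the two within-site unadjusted odds ratios. The suite verifies
this to ~1e-9 relative precision on the reference-table fixture.

The *adjusted* interaction estimates printed in the source study are not
recomputable without the original patient-level records (and their printed
scale is not that of a conventional interaction OR); the package therefore
validates its DiD estimator by simulation — CI coverage of a planted
effect, type-I error under the null, and error shrinking with cell size —
rather than against those numbers.

## Synthetic cohort generator

The generator emulates the study conditions so every downstream stage is
testable without patient data. Defaults: ~6,000 patients per site×period
cell with a mean of 1.15 admissions per patient (1 + Poisson; repeat
attenders create the clustering the GEE exists for), CA-AKI prevalence
8.3%, HA-AKI base rates 8.3%/6.6% (intervention/control), HA-conditional
mortality 25%, background mortality 7%, age 74.5 ± 17 y, comorbidity
prevalences of an elderly acute intake (CKD 47%, hypertension 58.5%, heart
failure 24%, diabetes 23%, vascular disease 9%, liver disease 2.5%),
baseline-history missingness 20%, and within-site intervention odds
effects 0.93 (HA incidence) and 0.73 (mortality given HA) in the
intervention-post cell only. Length of stay is log-normal with mean ≈ 11 d.

Key generator mechanics:

* **Planting, not labelling.** CA cases get an admission creatinine of
  1.52–2.9× their *derived* baseline (or 360–480 µmol/l when no history
  exists); HA cases get a piecewise-linear rise that reaches exactly the
  1.5-fold threshold at the scheduled onset, climbs to the severity ratio
  over 48 h (stage mix 72/20/8% across stages 1/2/3), then plateaus.
  Non-AKI series use *bounded* ±4% noise around the admission value, which
  provably cannot cross either detection threshold — so ascertainment
  recovers the configured rates exactly in expectation, with no false
  positives. Real laboratory noise is unbounded and would produce a small
  false-positive rate; this is a deliberate idealisation.
* **Mortality model.** Death is Bernoulli on a logit scale: base rate by
  HA status, centred covariate effects (age, comorbidities), and the
  interaction effect in the intervention-post cell. Centring keeps the
  marginal rates at their configured values; including real covariate
  effects makes the adjusted DiD model meaningfully different from the
  unadjusted one.
* **Randomness.** Each patient draws from an independent substream keyed
  by (seed, cell, patient index) via `SeedSequence`, so enlarging a cell
  never perturbs earlier patients. A configured fraction (~3%) of
  admissions violate an inclusion rule, exercising the filters.
* **Fast path.** `simulate_admission_frame` produces only the analysis
  columns (no creatinine series), vectorised, for replicate studies; it is
  deterministic per (config, seed) but does not share streams with the
  full generator.

What the generator does **not** emulate: seasonal or secular trends,
between-site case-mix differences beyond the HA base rate, correlation
between comorbidities, creatinine assay noise (see above), patients
re-admitted across periods or sites, AKI recovery dynamics, and ICU/LOS
dependence on severity beyond a simple HA effect. Passing tests therefore
demonstrate the correctness of the algorithms and the calibration of the
estimators under these idealised conditions, not the realism of any
particular hospital's data.

## Calibration studies and problem sizes

`calibration.did_mortality_study` plants an interaction OR on
HA-conditional mortality with all else symmetric (equal HA base rates,
no incidence effect) and fits the adjusted DiD per replicate. The standard
configuration is 5,000 admissions per cell and 200 replicates — for a
planted OR of 0.7 the 95% CI covers the truth in ≥ 90% of replicates, and
under the null the rejection rate at α = 0.05 sits near 5%. The
consistency check reruns the study at 600 vs 5,000 admissions per cell
(30 replicates each) and verifies the mean absolute log-scale error
shrinks. Unit tests use smaller cohorts (≈ 100–600 patients per cell);
rate-recovery checks use ≈ 5,000 admissions per cell with 3-binomial-SE
bands.

## Numerical conventions

Thresholds compare with ≥ throughout. Planted trajectories add a 1e-9
relative headroom so threshold ratios survive floating-point division.
Table percentages are rounded to 2 dp (whole percents for the subgroup
table), odds ratios and CIs to 3 dp, matching the published formats.
Pipeline runs with the same config and seed produce byte-identical report
bundles; the manifest records the config hash (location-independent) and
package version.
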