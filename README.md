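# aki-impact

Tools for evaluating creatinine-based acute kidney injury (AKI) e-alerting
in hospitals: KDIGO-style AKI ascertainment from serum-creatinine series,
clinical-prediction-rule (APS) alerting, cohort construction, and the
controlled before-after **difference-in-differences** impact analysis used
when one of two sites switches an alerting intervention on. A synthetic
two-site EHR generator makes every stage testable without patient data.

Intended for biostatisticians and clinical informaticians reproducing or
planning this class of two-site, two-period natural experiment.

## The model

Admissions are classified from creatinine alone:

* **CA-AKI** (community-acquired, judged at admission):
  SCr/baseline ≥ 1.5 or SCr ≥ 354 µmol/l; the baseline is the lowest
  result within 7 days, else the median of 8–365 days.
* **HA-AKI** (hospital-acquired, within the first 7 days): the earliest
  measurement with value/admission value ≥ 1.5, or a rise ≥ 26.5 µmol/l
  above the minimum of a rolling 48 h window.
* Severity: creatinine-only KDIGO stages (≥2× stage 2, ≥3× stage 3).

For a binary outcome Y with site S (intervention vs control) and period P
(post vs pre), the impact model is the cluster-robust logistic DiD

    logit P(Y=1) = β₀ + β_S S + β_P P + β_SP (S·P) + γ'x

with covariates x (age and six comorbidity flags) and patient-level
clustering over repeated admissions (GEE, exchangeable working
correlation). `exp(β_SP)` — the interaction odds ratio — is the
intervention effect: the change at the intervention site relative to the
contemporaneous change at the control site. Per-site unadjusted tables get
odds ratios with Woolf intervals, `exp(ln OR ± 1.96·√(1/a+1/b+1/c+1/d))`,
and Fisher exact p-values; CMH stratified tests, chi-square and t /
Mann-Whitney comparisons round out the reporting surface.

## Worked example

`examples/03_reference_tables.py` recomputes a published two-site
evaluation's headline statistics from its integer cell counts:

```text
total admissions: 30295
overall CA-AKI: 8.3%   overall HA-AKI: 7.3%

HA-AKI incidence, intervention: 8.28% -> 7.73%  OR 0.928 (0.824-1.045), p=0.223
HA-AKI incidence, control     : 6.55% -> 6.67%  OR 1.019 (0.888-1.170), p=0.805

HA-AKI in-patient mortality   (intervention): 27.46% -> 21.67%  OR 0.731 (0.560-0.954), p=0.021
HA-AKI 7-day mortality        (intervention): 16.20% -> 10.51%  OR 0.608 (0.432-0.855), p=0.004
...
unadjusted DiD interaction on incidence: 0.910418 (= OR_intervention / OR_control = 0.910418)
```

Reading: HA-AKI incidence at the intervention site fell from 8.28% to
7.73% (within-site OR 0.928), while the control site was flat (OR 1.019);
among admissions that developed HA-AKI, in-hospital mortality fell from
27.46% to 21.67% (OR 0.731, 95% CI 0.560–0.954) with no improvement at the
control site. The last line demonstrates the exact identity between the
saturated unadjusted DiD interaction and the ratio of the two site ORs.

Other examples: `01_detect_aki.py` (classification of hand-built series),
`02_simulate_and_report.py` (synthetic cohort through the full pipeline),
`04_did_calibration.py` (planted-effect coverage study).

A thin CLI wraps the pipeline:

```bash
aki-impact simulate --config run.yaml --seed 1 --out cohort/
aki-impact ascertain --in cohort/ --out aki.csv
aki-impact analyse --in cohort/ --out report/
aki-impact report --config run.yaml --out report/
aki-impact all --seed 1 --out report/
```

## Library layout

| module | contents |
| --- | --- |
| `aki_impact.detect` | baseline derivation, CA/HA detection, KDIGO staging |
| `aki_impact.alerts` | APS scoring, RED/AMBER/GREEN states, bundle compliance |
| `aki_impact.cohort` | inclusion rules, outcome derivation, single-admission subset |
| `aki_impact.stats` | 2×2 tables, Woolf CIs, Fisher/χ²/CMH, DiD models |
| `aki_impact.synth` | synthetic cohort generator, trajectory planting, CSV I/O |
| `aki_impact.calibration` | replicate studies (coverage, type-I error, consistency) |
| `aki_impact.pipeline` / `cli` | end-to-end runs and report bundles |
| `aki_impact.reference_tables` | published cell counts used as a regression fixture |

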