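# Synthetic representative APS weight table.
#
# The predictor set mirrors the admission-time variables an AKI prediction
# score draws on (age, chronic kidney disease, diabetes, heart failure,
# liver disease, tachypnoea, reduced consciousness, early-warning score);
# the integer points here are a plausible stand-in, NOT a published
# weighting.  Replace with locally validated weights for real deployments.
cutoff: 5
entries:
  - {name: age_ge_65, field: age, op: ge, threshold: 65, points: 2}
  - {name: age_ge_80, field: age, op: ge, threshold: 80, points: 1}
  - {name: chronic_kidney_disease, field: ckd, op: is_true, points: 2}
  - {name: diabetes_mellitus, field: diabetes, op: is_true, points: 1}
  - {name: heart_failure, field: heart_failure, op: is_true, points: 2}
  - {name: liver_disease, field: liver_disease, op: is_true, points: 2}
  - {name: resp_rate_ge_20, field: resp_rate_ge20, op: is_true, points: 1}
  - {name: avpu_below_alert, field: avpu_below_alert, op: is_true, points: 2}
  - {name: news_ge_4, field: news, op: ge, threshold: 4, points: 1}
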