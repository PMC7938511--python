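n: 2000
baseline_rate: 0.08
censor_rate: 0.15
seed: null
variables:
- name: exposure
  kind: continuous
  role: exposure
  error_free: false
  thresholds: []
  log_hazard: 0.25
- name: age
  kind: continuous
  role: baseline_adjustment
  error_free: true
  thresholds: []
  log_hazard: 0.4
- name: sex
  kind: binary
  role: baseline_adjustment
  error_free: true
  thresholds:
  - 0.0
  log_hazard: 0.15
- name: race_ethnicity
  kind: ordinal
  role: adjustment
  error_free: true
  thresholds:
  - -0.12566134685507402
  - 0.5244005127080407
  - 1.2815515655446004
  log_hazard: 0.05
- name: smoking
  kind: binary
  role: adjustment
  error_free: false
  thresholds:
  - 0.6744897501960817
  log_hazard: 0.2
- name: bmi
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: 0.1
- name: systolic_bp
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: 0.15
- name: total_cholesterol
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: 0.08
- name: physical_activity
  kind: ordinal
  role: adjustment
  error_free: false
  thresholds:
  - -0.5244005127080409
  - 0.5244005127080407
  log_hazard: -0.1
- name: alcohol
  kind: binary
  role: adjustment
  error_free: false
  thresholds:
  - 0.2533471031357997
  log_hazard: -0.05
- name: education
  kind: ordinal
  role: adjustment
  error_free: false
  thresholds:
  - -0.6744897501960817
  - 0.12566134685507416
  - 0.8416212335729143
  log_hazard: -0.08
- name: income
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: -0.1
- name: crp
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: 0.12
- name: glucose
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: 0.1
- name: medication_use
  kind: binary
  role: adjustment
  error_free: false
  thresholds:
  - 0.38532046640756773
  log_hazard: 0.05
- name: diet_score
  kind: continuous
  role: adjustment
  error_free: false
  thresholds: []
  log_hazard: -0.06
corr:
- - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
  - 6.0e-06
  - 2.0e-06
  - 1.0e-06
  - 0.0
  - 0.0
  - 0.0
- - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
  - 6.0e-06
  - 2.0e-06
  - 1.0e-06
  - 0.0
  - 0.0
- - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
  - 6.0e-06
  - 2.0e-06
  - 1.0e-06
  - 0.0
- - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
  - 6.0e-06
  - 2.0e-06
  - 1.0e-06
- - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
  - 6.0e-06
  - 2.0e-06
- - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
  - 6.0e-06
- - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
  - 2.0e-05
- - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
  - 6.6e-05
- - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
  - 0.000219
- - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
  - 0.000729
- - 6.0e-06
  - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
  - 0.00243
- - 2.0e-06
  - 6.0e-06
  - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
  - 0.0081
- - 1.0e-06
  - 2.0e-06
  - 6.0e-06
  - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
  - 0.027
- - 0.0
  - 1.0e-06
  - 2.0e-06
  - 6.0e-06
  - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
  - 0.09
- - 0.0
  - 0.0
  - 1.0e-06
  - 2.0e-06
  - 6.0e-06
  - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
  - 0.3
- - 0.0
  - 0.0
  - 0.0
  - 1.0e-06
  - 2.0e-06
  - 6.0e-06
  - 2.0e-05
  - 6.6e-05
  - 0.000219
  - 0.000729
  - 0.00243
  - 0.0081
  - 0.027
  - 0.09
  - 0.3
  - 1.0
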