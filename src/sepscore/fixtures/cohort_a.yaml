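# Preset emulating a suspected-infection ED cohort: all patients infected,
# n = 506 with 46% sepsis, median age ~70 (sepsis) vs ~52 (no sepsis).
n: 506
sepsis_prevalence: 0.4605
true_thresholds:
  - {variable: age, cut: 60, direction: '>', weight: 2.2}
  - {variable: age, cut: 75, direction: '>', weight: 1.2}
  - {variable: age, cut: 80, direction: '>', weight: 0.6}
  - {variable: sbp, cut: 100, direction: '<', weight: 0.9}
  - {variable: dbp, cut: 56, direction: '<', weight: 0.4}
  - {variable: respiratory_rate, cut: 24, direction: '>', weight: 0.9}
  - {variable: heart_rate, cut: 110, direction: '>', weight: 0.5}
  - {variable: mental_status, cut: 3, direction: '>=', weight: 0.8}
marginals:
  age: [60.0, 20.0, 18.0, 100.0]
missing_rates:
  sbp: 0.03
  dbp: 0.03
  respiratory_rate: 0.05
  sao2: 0.04
  temperature: 0.05
  heart_rate: 0.02
  mental_status: 0.03
  lactate: 0.06
  hbp: 0.06
mar_dependence: {age: 0.3, outcome: 0.4}
infected_nonsepsis_rate: 1.0
dysfunction_free_sepsis_rate: 0.02
icu_rate_sepsis: 0.05
death_rate_sepsis: 0.017
event_rate_noninfected: 0.0
label: cohort_a
seed: 11
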