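# Preset emulating an undifferentiated acutely-ill ED cohort: n = 435 with
# 30% sepsis and 42% infected, median age ~77 (sepsis) vs ~72 (no sepsis);
# every sepsis case carries at least one organ dysfunction.
n: 435
sepsis_prevalence: 0.2966
true_thresholds:
  - {variable: age, cut: 60, direction: '>', weight: 0.9}
  - {variable: age, cut: 75, direction: '>', weight: 0.5}
  - {variable: age, cut: 80, direction: '>', weight: 0.3}
  - {variable: sbp, cut: 100, direction: '<', weight: 0.9}
  - {variable: dbp, cut: 56, direction: '<', weight: 0.4}
  - {variable: respiratory_rate, cut: 24, direction: '>', weight: 0.9}
  - {variable: heart_rate, cut: 110, direction: '>', weight: 0.5}
  - {variable: mental_status, cut: 3, direction: '>=', weight: 0.8}
marginals:
  age: [72.0, 14.0, 18.0, 100.0]
missing_rates:
  sbp: 0.04
  dbp: 0.04
  respiratory_rate: 0.06
  sao2: 0.05
  temperature: 0.06
  heart_rate: 0.03
  mental_status: 0.04
  lactate: 0.06
mar_dependence: {age: 0.3, outcome: 0.4}
infected_nonsepsis_rate: 0.1797
dysfunction_free_sepsis_rate: 0.0
icu_rate_sepsis: 0.09
death_rate_sepsis: 0.10
event_rate_noninfected: 0.065
label: cohort_b
seed: 13
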