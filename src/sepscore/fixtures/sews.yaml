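# Sepsis Early Warning Score (vital signs only), decision cut-off >= 7.
# Bands are strict inequalities; a variable contributes the points of the
# most severe band it satisfies. Mental status: 3 = confused, 4 = drowsy.
name: sews
cutoff: 7
combination_rule: max_band
bands:
  age:
    - {threshold: 45, direction: '>', points: 1}
    - {threshold: 60, direction: '>', points: 4}
    - {threshold: 80, direction: '>', points: 5}
  mental_status:
    - {threshold: [3, 4], direction: in, points: 3}
  respiratory_rate:
    - {threshold: 24, direction: '>', points: 5}
  sbp:
    - {threshold: 106, direction: '<', points: 3}
    - {threshold: 100, direction: '<', points: 4}
  dbp:
    - {threshold: 78, direction: '<', points: 1}
    - {threshold: 58, direction: '<', points: 2}
  heart_rate:
    - {threshold: 110, direction: '>', points: 2}
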