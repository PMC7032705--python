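# Sepsis Heparin-binding-protein-based Early Warning Score, cut-off >= 10.
# As sews.yaml but with HBP (ng/mL) bands and rebalanced vital-sign points.
name: shews
cutoff: 10
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
    - {threshold: 106, direction: '<', points: 2}
    - {threshold: 100, direction: '<', points: 6}
  dbp:
    - {threshold: 78, direction: '<', points: 1}
    - {threshold: 56, direction: '<', points: 3}
  heart_rate:
    - {threshold: 110, direction: '>', points: 2}
  hbp:
    - {threshold: 26, direction: '>', points: 3}
    - {threshold: 30, direction: '>', points: 6}
    - {threshold: 48, direction: '>', points: 7}
    - {threshold: 54, direction: '>', points: 8}
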