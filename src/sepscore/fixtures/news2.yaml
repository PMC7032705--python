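# National Early Warning Score 2 chart (SpO2 scale 1), cut-off >= 5.
# sao2 is a fraction (0.91 = 91%); temperature in Celsius; consciousness is
# scored from the 1-5 mental-status ordinal (anything other than 1 = not
# alert, i.e. new confusion or worse on the ACVPU scale).
name: news2
cutoff: 5
combination_rule: max_band
bands:
  respiratory_rate:
    - {threshold: 8, direction: '<=', points: 3}
    - {threshold: 11, direction: '<=', points: 1}
    - {threshold: 21, direction: '>=', points: 2}
    - {threshold: 25, direction: '>=', points: 3}
  sao2:
    - {threshold: 0.91, direction: '<=', points: 3}
    - {threshold: 0.93, direction: '<=', points: 2}
    - {threshold: 0.95, direction: '<=', points: 1}
  on_oxygen:
    - {threshold: [true], direction: in, points: 2}
  sbp:
    - {threshold: 90, direction: '<=', points: 3}
    - {threshold: 100, direction: '<=', points: 2}
    - {threshold: 110, direction: '<=', points: 1}
    - {threshold: 220, direction: '>=', points: 3}
  heart_rate:
    - {threshold: 40, direction: '<=', points: 3}
    - {threshold: 50, direction: '<=', points: 1}
    - {threshold: 91, direction: '>=', points: 1}
    - {threshold: 111, direction: '>=', points: 2}
    - {threshold: 131, direction: '>=', points: 3}
  mental_status:
    - {threshold: [2, 3, 4, 5], direction: in, points: 3}
  temperature:
    - {threshold: 35.0, direction: '<=', points: 3}
    - {threshold: 36.0, direction: '<=', points: 1}
    - {threshold: 38.1, direction: '>=', points: 1}
    - {threshold: 39.1, direction: '>=', points: 2}
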