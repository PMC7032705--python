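# RETTS adult vital-sign triage limits (editable). The assigned level is the
# worst level with at least one satisfied criterion; symptom algorithms can
# only escalate (handled as the red override in code). A criterion with an
# `oxygen` key applies only at that oxygen-therapy state.
# Units: respiratory_rate breaths/min, sao2 fraction, heart_rate beats/min,
# sbp mmHg, temperature Celsius, mental_status ordinal 1-5.
red:
  - {variable: respiratory_rate, direction: '>', threshold: 30}
  - {variable: respiratory_rate, direction: '<', threshold: 8}
  - {variable: sao2, direction: '<', threshold: 0.90, oxygen: true}
  - {variable: heart_rate, direction: '>', threshold: 130}
  - {variable: heart_rate, direction: '<', threshold: 40}
  - {variable: sbp, direction: '<', threshold: 90}
  - {variable: mental_status, direction: in, threshold: [5]}
orange:
  - {variable: respiratory_rate, direction: '>', threshold: 25}
  - {variable: sao2, direction: '<', threshold: 0.90, oxygen: false}
  - {variable: heart_rate, direction: '>', threshold: 120}
  - {variable: heart_rate, direction: '<', threshold: 50}
  - {variable: sbp, direction: '<', threshold: 100}
  - {variable: mental_status, direction: in, threshold: [3, 4]}
  - {variable: temperature, direction: '>', threshold: 41.0}
yellow:
  - {variable: sao2, direction: '<', threshold: 0.95}
  - {variable: heart_rate, direction: '>', threshold: 110}
  - {variable: heart_rate, direction: '<', threshold: 55}
  - {variable: temperature, direction: '>=', threshold: 38.5}
  - {variable: temperature, direction: '<', threshold: 35.0}
  - {variable: mental_status, direction: in, threshold: [2]}
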