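# Single-organ dysfunction cut-offs (sepsis-2 style), editable.
cardiovascular:
  sbp_hypotension: 90.0        # mmHg, systolic below
respiratory:
  pf_respiratory: 300.0        # mmHg, PaO2/FiO2 below (Severinghaus-estimated)
renal:
  creatinine_renal: 177.0      # umol/L, above
hematological:
  platelets_hematological: 100.0  # 1e9/L, below
hepatic:
  bilirubin_hepatic: 34.0      # umol/L, above
neurologic:
  mental_status_neurologic: 4  # ordinal, at or above (drowsy or unconscious)
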