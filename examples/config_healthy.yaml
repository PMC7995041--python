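lung:
  resistance_cmh2o_per_lps: 3.0
  compliance_ml_per_cmh2o: 30.0
  peep_base_cmh2o: 8.0
  label: healthy
diverter:
  source_flow_lpm: 30.0
  r_ec_open: 80.57
  r_ec_span: 76.72
  r_sc_open: 40.0
  r_sc_span: 60.0
  eta_insp: 0.69
  p_high_base: 20.0
  k_sc: 4.0
  k_fc: 4.0
  p_low_base: 8.0
  m_sc: 2.0
  m_fc: 2.0
screws:
  ec: 0.5
  fc: 0.5
  sc: 0.5
trigger:
  enabled: false
  amplitude_cmh2o: 3.0
  interval_s: 4.0
sim:
  dt_s: 0.001
  duration_s: 60.0
  transient_discard: 2
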