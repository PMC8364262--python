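# Small center: 1,500 treated cases, 4 Linacs, 1 4DCT simulator.
# Remaining fields completed per the assumption set in README.md.
center_id: small-reference
total_cases: 1500
equipment:
  linac: 4
  simulator: 1
  tps_system: 1
  rois_system: 1
  secondary_calc_system: 1
  qa_program: true
education:
  physics_residents: 1
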