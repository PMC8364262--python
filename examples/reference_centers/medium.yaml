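# Medium center: 2,300 treated cases, 7 Linacs, 2 4DCT simulators, HDR
# brachytherapy. Remaining fields completed per the assumption set in
# README.md (brachy fractions = 0.3 x cases = 690; TPS = EBRT + brachy).
center_id: medium-reference
total_cases: 2300
brachy_fractions: 690
equipment:
  linac: 7
  simulator: 2
  hdr_unit: 1
  tps_system: 2
  rois_system: 1
  secondary_calc_system: 1
  qa_program: true
education:
  physics_residents: 1
  grad_students: 1
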