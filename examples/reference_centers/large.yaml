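# Large academic center: ~5,000 distinct patients, 11 Linacs, HDR
# brachytherapy, multi-modality simulators (4DCT, MR, PET-CT), Gamma Knife,
# orthovoltage. Remaining fields completed per the assumption set in
# README.md (brachy fractions = 0.3 x cases = 1500; TPS = EBRT + brachy +
# radiosurgery; academic education load).
center_id: large-reference
total_cases: 5000
brachy_fractions: 1500
equipment:
  linac: 11
  gamma_knife: 1
  simulator: 3
  hdr_unit: 1
  orthovoltage: 1
  tps_system: 3
  rois_system: 1
  secondary_calc_system: 1
  qa_program: true
education:
  physics_residents: 3
  grad_students: 4
  therapy_students: 4
  onco_residents: 2
  courses: 2
options:
  caseload_basis: distinct_patients
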