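# Reference center inventories

Three representative Ontario-style centers — small, medium, large — used in
the worked examples and tests. Only the headline facts about each center are
public (annual caseload, Linac count, simulators, brachytherapy and specialty
platforms); the remaining inventory fields are completed here with one fixed,
documented assumption set:

- **Case mix**: the default 25% complex / 1% highly specialized split of the
  annual caseload; caseload given as treated cases (distinct patients for the
  large center, an interchangeable basis within ~1%).
- **TPS systems** are counted per unique vendor: one external-beam TPS per
  center, plus one brachytherapy planning system where an HDR program exists,
  plus one dedicated radiosurgery planning system where a Gamma Knife exists.
- **ROIS** and **secondary dose calculation**: one system each per center.
- **QA equipment**: the per-center QA program row applies everywhere.
- **Regulated items**: the default rule — MV treatment units plus one per
  brachytherapy program present.
- **HDR fraction load**: 0.3 brachytherapy fractions per annual treated case
  for centers with an HDR program (roughly 8% of patients receiving ~4
  fractions each), rounded to the nearest 10.
- **Education**: scaled with center size. Small: 1 physics resident.
  Medium: 1 physics resident, 1 graduate student. Large (academic): 3 physics
  residents, 4 graduate students, 4 therapy students, 2 radiation oncology
  residents, 2 half-credit courses.

These completions are assumptions, not survey data; totals computed from them
are expected to land near — not exactly on — published model outputs for
centers of these sizes.
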