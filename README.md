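# radstaff

Grid-based medical physics staffing estimates for radiation oncology
programs.

Radiotherapy departments need a defensible way to size their physics teams:
medical physicists, physics assistants, electronics and mechanical
engineering, and IT support. `radstaff` implements a workload-grid staffing
model of the kind used across Canadian cancer programs. A center's annual
inventory — treated cases and their complexity mix, brachytherapy fractions,
equipment and software systems, teaching loads — is multiplied through a
grid of per-role FTE weights and summed into five components:

1. **Clinical procedures** — e.g. 0.5 physicist FTE per 1,000 treated cases,
   plus 0.1 per 100 complex cases (default 25% of caseload), 0.25 per 100
   highly specialized cases (default 1%), and 0.2 per 100 brachytherapy
   fractions.
2. **Clinical equipment** — per-unit/per-system weights (0.2 physicist FTE
   per standard Linac, twice that for an MR-Linac, ...), a per-center QA
   allotment, plus procurement (2% of the equipment FTE), licensing (0.025
   FTE per regulated device or program), and operations training (0.02 FTE
   per Linac or TPS).
3. **Core services** — 20% of the procedures-plus-equipment physicist FTE
   for technique/protocol development, plus 0.04 FTE per 1,000 cases for
   incident investigation and QA-program oversight.
4. **Education and training** — per-trainee weights with a 0.1 physicist FTE
   baseline per active training program.
5. **Administration** — supervision pooled onto the physicist column
   (5%/2% of reporting FTEs) and 10% coverage per role for vacation,
   statutory holidays, and continuing education.

One FTE is a person-year at the nominal 37.5-hour week (1,950 h/year).
With the default grid and case mix this works out to about **1.5 physicist
hours per external-beam case**.

Beyond the forward model the package provides:

- **Calibration** (`radstaff.calibration`): bound-constrained, ridge-
  regularized linear least squares fitting the grid's free row weights to a
  panel of centers with observed staffing, with per-row identifiability
  diagnostics.
- **Synthetic panels** (`radstaff.synthetic`): seeded generation of
  realistic center inventories (≈1,000–5,000 cases, ~1 Linac per 450 cases,
  size-stratified specialty services) with observed staffing = model output
  plus per-role noise, so everything is testable without confidential
  survey data.
- **Reporting** (`radstaff.reporting`): caseload regressions, cases-per-FTE
  ratios, predicted-vs-actual comparison tables.
- A **CLI**: `radstaff estimate | batch | calibrate | synth`.

## Worked example

`examples/reference_centers/small.yaml` describes a small center: 1,500
treated cases, 4 Linacs, one 4DCT simulator, one TPS/ROIS/secondary-dose
system each, a QA program, and one physics resident.

```sh
radstaff estimate -i examples/reference_centers/small.yaml --out md
```

```
# Staffing estimate: small-reference

| component | physicist | assistant | elec | mech | it |
|---|---|---|---|---|---|
| procedures | 1.2 | 0.5 | 0.2 | 0.1 | 0.2 |
| equipment | 1.6 | 1.1 | 1.3 | 0.3 | 0.5 |
| core_services | 0.6 | 0.0 | 0.0 | 0.0 | 0.0 |
| education | 0.2 | 0.0 | 0.0 | 0.0 | 0.0 |
| administration | 0.6 | 0.2 | 0.2 | 0.0 | 0.1 |
| total | 4.2 | 1.8 | 1.7 | 0.4 | 0.8 |

Grand total: 9.0 FTE
```

Reading the output: the center needs about 4.2 medical physicists and 1.8
physics assistants (6.0 combined — jurisdictions without a separate
assistant category can merge the two with `--blend assistant:physicist`),
1.7 electronics engineers, under half a mechanical engineer, and 0.8 IT
FTE. Totals are reported to 0.1 FTE; full precision is retained internally
and in the JSON/CSV outputs, which also carry term-level provenance for
every additive contribution.

The same library calls in Python:

```python
from radstaff import default_weight_table, load_inventory, estimate_staffing

table = default_weight_table()
inv = load_inventory("examples/reference_centers/small.yaml")
est = estimate_staffing(inv, table)
print(est.totals.physicist)   # 4.193629...
```

## Calibrating the grid

```sh
radstaff synth --n 23 --seed 42 -o panel/          # synthetic survey panel
radstaff calibrate -p panel/ -o fitted.yaml --report report.json
```

`calibrate` fits the linear row weights (non-negative, ridge-pulled toward
the defaults) and reports per-role mean ± s.d. of predicted − actual
staffing. Structural percentage rows stay fixed; rows the panel cannot
identify are flagged, never silently zeroed. The fitted grid is one of many
panel-consistent solutions, not a unique optimum — see
`docs/methods.md`.

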