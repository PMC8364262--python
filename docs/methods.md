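# Methods

This note documents the staffing model as implemented, the choices made
where the design was genuinely open, what the synthetic data do and do not
emulate, and the numerical details that matter for reproducing results.

## The model

The model is a weighted workload grid. For one center and one year, each of
five staff roles r ∈ {physicist, assistant, electronics, mechanical, IT}
receives

    FTE_r = procedures_r + equipment_r + core_r + education_r + admin_r

with one FTE defined as 1,950 h (37.5 h/week nominal work year,
`WeightTable.work_year_hours`).

**Clinical procedures** is linear in the case-mix counts:

    procedures_r = w_cases,r·(N/1000) + w_cx,r·(N_cx/100)
                 + w_sp,r·(N_sp/100) + w_br,r·(N_br/100)

where N is annual treated cases (or distinct patients — the two bases
differ by ~1% and a metadata flag records which was supplied), N_cx and
N_sp default to 25% and 1% of N unless given as counts, and N_br is annual
brachytherapy fractions. Counts are real-valued internally; derived mixes
are never rounded.

**Clinical equipment** sums per-unit/per-system weights over the itemized
inventory (systems counted per unique vendor, not per workstation), adds a
per-center QA-equipment allotment when the QA-program flag is on, then
three overheads carried by the physicist column under default weights:

- *procurement* = 2% of each role's equipment base FTE (the base includes
  the QA row, which sits in the minor-equipment block, and excludes the
  overhead rows themselves — no self-reference);
- *licensing* = 0.025 FTE per regulated device or program; the default
  count is MV treatment units plus one per brachytherapy program present
  (HDR and/or LDR), overridable because licensing regimes vary;
- *operations training* = 0.02 FTE per Linac-class (MV) unit plus TPS
  system. MV units are Linacs, Gamma Knife units, MR-Linacs, and proton
  accelerators.

**Core services** gives each role its core-services percentage (physicist
default 20%, raisable per center for programs leading early evaluation of
novel techniques) of that role's procedures-plus-equipment FTE, plus an
incident-investigation/QA-oversight weight of 0.04 FTE per 1,000 cases.

**Education** applies per-trainee and per-course weights, plus a 0.1
physicist-FTE baseline per *active* training category among physics
residents, radiation oncology residents, and graduate students (program
infrastructure and administration; fires only when the category count is
positive). The baseline is stored as an ordinary grid row
(`education_program_baseline`, normalization `per_program`) so calibration
can treat it like any other linear row.

**Administration** is a single pass over the pre-administration totals:
supervision = 0.05·pre_physicist + 0.02·(other roles' pre totals), added to
the physicist column; coverage = 10% of each role's pre-administration FTE,
with the physicist coverage base including supervision (supervision is
physicist workload that itself needs vacation coverage; the
`supervision_in_coverage` flag switches this off). No fixed-point
iteration: the model mirrors a spreadsheet, and coverage-of-coverage terms
at 10% scale are deliberately out of scope.

Role blending (e.g. folding physics assistants into the physicist column
for jurisdictions without a separate assistant category) is a whole-role
merge applied to a finished estimate; the grand total is conserved.

### Degenerate inputs and conventions

- An all-zero inventory yields an all-zero estimate (no baselines fire).
- Equipment counts may be fractional (mid-year commissioning); no prorating
  rule beyond the fraction itself is asserted.
- Totals are *reported* to 0.1 FTE; all arithmetic keeps full precision.
- The inventory schema is closed: unknown keys are errors, so typos cannot
  silently drop workload. Defaults filled during loading are recorded in
  the inventory's provenance notes (documentation only, excluded from
  equality).

## Calibration

With the structural percentage rows (procurement, core services,
supervision, coverage) fixed, predictions are linear in the remaining row
weights, and fitting the grid to a panel of (inventory, observed staffing)
pairs is, per role,

    min_{w ≥ 0}  Σ_centers (predicted_r − actual_r)² + λ Σ_g (w_g − w_base,g)²

Freeing the percentage rows would make the problem bilinear and, at panel
sizes of a few dozen centers, non-identifiable; they stay fixed unless the
caller edits the table directly. The non-physicist roles are fitted first
and independently; the physicist column last, because its supervision term
depends on the other columns' totals. Design-matrix columns are obtained by
probing the (linear) engine rather than re-deriving closed forms, so the
fit can never drift out of sync with the forward model.

Choices:

- **Shared parameters.** Rows printed with identical weights (standard
  Linacs + Gamma Knife; simulators + HDR units; SRS cone sets + Cobalt-60;
  the six minor-equipment items) are fitted jointly as one parameter per
  group (`DEFAULT_GROUPS`); callers may split them.
- **Structurally collinear rows.** The operations-training row's exposure
  (MV units + TPS systems) and the incident/QA-oversight row's exposure
  (cases/1000) are *exact* linear combinations of other rows' exposures for
  every possible inventory. No panel can separate them from their
  companions, so they are fixed at base values by default
  (`COLLINEAR_FIXED_ROWS`); freeing them explicitly flags the whole
  collinear set as unidentifiable rather than silently splitting credit.
- **Ridge.** Default relative strength 1e-3; the absolute penalty is that
  times the mean squared base weight of the free cells. The fitted grid is
  one of many panel-consistent solutions; the ridge makes the reported one
  the solution nearest the defaults, and calibration reports say so.
- **Identifiability.** Diagnosed per role from the SVD of the
  unregularized design: zero-exposure columns and columns with significant
  weight in a null-space direction are flagged; with ridge 0, flagged
  parameters are pinned to base values and excluded from the solve.
- **Solver.** `scipy.optimize.lsq_linear` with the exact active-set method
  (`bvls`) whenever rows ≥ columns, falling back to `trf` otherwise; `bvls`
  reaches KKT residuals below 1e-8, which the reflective method did not.
- Fits are sorted by center id internally, so results are invariant to
  panel ordering.

## Synthetic data

The generator (`radstaff.synthetic`) emulates the population of Canadian
radiotherapy centers the model targets, so that calibration and reporting
can be exercised without confidential survey data:

- caseloads uniform on 1,000–5,000 treated cases/year; Linacs within one
  unit of caseload/450, never zero;
- per-center complexity mix drawn from 20–30% complex and 0.8–2%
  specialized (surveyed centers report a modest spread around the nominal
  25%/1%);
- specialty services stratified by size, as in practice: HDR-program
  probability ramps from ~25% in the smallest centers to ~98% in the
  largest (most regional programs offer at least gynaecological HDR), with
  ~0.3 fractions per annual case ±15%; MR-Linacs and Gamma Knives appear
  essentially only above ~3,500–4,000 cases; proton accelerators are absent
  by default (none operated in the emulated setting);
- education loads Poisson with size-scaled rates (~0.55 physics residents
  per 1,000 cases, matching a provincial residency program of a couple of
  dozen positions spread over 15 centers);
- observed staffing = engine output under a given grid plus independent
  zero-mean Gaussian noise per role (default s.d. 0.5 FTE), truncated at
  zero; untruncated values are kept in panel metadata so recovery
  diagnostics are not biased by truncation (at realistic staffing levels
  the truncation almost never binds).

Determinism: every field of every center draws from its own
`numpy.random.default_rng([seed, index, field_code])` stream, so output is
bit-reproducible and adding a field never perturbs existing draws.

What passing tests on synthetic panels show — and what they do not: the
panels are self-consistent by construction (observed = model + noise), so
they validate the machinery (linearity, recovery, reporting, round-trips),
not the empirical adequacy of the default weights for any real center.
Real staffing reflects local scope-of-practice, research load, vendor
service contracts, and minimum-coverage constraints that the generator does
not model; grid outputs should be read as minimum recommended staffing.

## Problem sizes used in tests

The suite exercises: 100 synthetic centers for the engine-vs-oracle
equivalence (tolerance 1e-9 per role); a noiseless 30-center panel for
exact parameter recovery (relative 1e-6 on identifiable rows; achieved
~1e-13); 100 seeds × 23-center noisy panels for the ±0.5-FTE mean-residual
check; and 23-center panels for the caseload-regression behaviour
(R² > 0.9). The complete suite runs in well under a minute.

## Known limitations

- Dosimetrist/treatment-planner staffing is out of scope (handled by
  therapist staffing models where this grid is used); physicist supervision
  of planning remains in the physicist weights.
- Vendor service contracts are not modelled; the equipment weights assume a
  shared service model excluding vendor-employed staff.
- Whether supervision should itself attract supervision is undefined in
  grid models of this kind; the single-pass choice here is documented and
  flag-switchable for the coverage interaction only.
- The default weights are calibrated to one jurisdiction's staffing
  equilibrium; applying them elsewhere is an extrapolation that the
  override and calibration machinery exists to correct.
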