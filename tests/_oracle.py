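"""Independent spreadsheet-style recomputation of the staffing model.

Deliberately written as a flat, cell-by-cell pass over the weight grid —
plain dict arithmetic, no shared code with the engine — so it can serve as
an independent cross-check of the engine's composition logic.
"""

from radstaff.roles import ROLES

MV_ITEMS = ["linac", "gamma_knife", "mr_linac", "proton"]
EQUIP_ITEMS = [
    "linac", "gamma_knife", "mr_linac", "proton", "tps_system", "rois_system",
    "simulator", "hdr_unit", "secondary_calc_system", "srs_cone_set",
    "cobalt_unit", "ldr_program", "orthovoltage", "ultrasound",
    "conventional_simulator", "c_arm", "motion_mgmt_system",
]
EDU_ITEMS = [
    "physics_residents", "therapy_students", "onco_residents",
    "grad_students", "courses",
]


def oracle_totals(inv, table):
    """Flat brute-force per-role totals for one center under a weight table."""
    w = {item: {r: row.weights.get(r) for r in ROLES}
         for item, row in table.rows.items()}
    mix, eq, ed, opts = inv.case_mix, inv.equipment, inv.education, inv.options

    totals = {}
    pre = {}
    for r in ROLES:
        proc = (
            w["treated_cases"][r] * mix.total_cases / 1000
            + w["complex_cases"][r] * mix.complex_cases / 100
            + w["specialized_cases"][r] * mix.specialized_cases / 100
            + w["brachy_fractions"][r] * mix.brachy_fractions / 100
        )
        equip_base = sum(w[item][r] * getattr(eq, item) for item in EQUIP_ITEMS)
        if eq.qa_program:
            equip_base += w["qa_equipment"][r]
        regulated = eq.regulated_items
        if regulated is None:
            regulated = sum(getattr(eq, i) for i in MV_ITEMS)
            regulated += 1 if eq.hdr_unit > 0 else 0
            regulated += 1 if eq.ldr_program > 0 else 0
        equip = (
            equip_base
            + w["procurement"][r] * equip_base
            + w["licensing"][r] * regulated
            + w["equipment_training"][r]
            * (sum(getattr(eq, i) for i in MV_ITEMS) + eq.tps_system)
        )
        core_frac = w["core_services"][r]
        if r == "physicist" and opts.core_services_fraction is not None:
            core_frac = opts.core_services_fraction
        core = core_frac * (proc + equip) + w["incident_qa_oversight"][r] * (
            mix.total_cases / 1000
        )
        edu = sum(w[item][r] * getattr(ed, item) for item in EDU_ITEMS)
        n_programs = sum(
            1
            for item in ("physics_residents", "onco_residents", "grad_students")
            if getattr(ed, item) > 0
        )
        edu += w["education_program_baseline"][r] * n_programs
        pre[r] = proc + equip + core + edu

    supervision = sum(w["supervision"][r] * pre[r] for r in ROLES)
    for r in ROLES:
        cov_base = pre[r] + (supervision if r == "physicist" else 0.0)
        admin = w["coverage"][r] * cov_base + (
            supervision if r == "physicist" else 0.0
        )
        totals[r] = pre[r] + admin
    if opts.blend_assistant_into_physicist:
        totals["physicist"] += totals["assistant"]
        totals["assistant"] = 0.0
    return totals
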