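"""The staffing computation: five components and the per-role totals.

The model estimates staffing for one center as the sum of five components,
evaluated in order:

1. **Clinical procedures** — linear in the annual caseload, its complex and
   highly specialized sub-categories, and brachytherapy fractions.
2. **Clinical equipment** — linear in the equipment/system counts, plus a
   per-center QA-equipment allotment, plus three physicist-side overheads:
   procurement (a percentage of the equipment FTE), licensing/radiation
   safety (per regulated device or program) and operations training of
   clinical staff (per MV unit and TPS system).
3. **Core services** — a percentage (default 20%) of the procedures-plus-
   equipment FTE, plus incident-investigation/QA-program oversight scaled by
   caseload.
4. **Education and training** — per-trainee and per-course weights, plus a
   per-program physicist baseline for each active training category.
5. **Administration** — supervision overhead pooled onto the physicist
   column, and a 10% coverage allotment (vacation, statutory holidays,
   continuing education) per role.  Both are a single pass over the
   pre-administration totals; coverage of the physicist includes the
   supervision workload.

All five are deterministic functions of the inventory and the weight table,
and every additive term is recorded with its provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional

import pandas as pd

from .inventory import CaseMix, CenterInventory, EducationProfile, EquipmentInventory
from .roles import ROLES, RoleVector
from .weights import (
    BASELINE_EDUCATION_ITEMS,
    EDUCATION_COUNT_ITEMS,
    EQUIPMENT_COUNT_ITEMS,
    WeightTable,
)

COMPONENT_ORDER = (
    "procedures",
    "equipment",
    "core_services",
    "education",
    "administration",
)


@dataclass(frozen=True)
class Term:
    """One additive contribution to the estimate, for provenance reporting."""

    component: str
    item_id: str
    role: str
    value: float


@dataclass
class StaffingEstimate:
    """Per-component role vectors, totals, and term-level provenance."""

    center_id: str
    procedures: RoleVector
    equipment: RoleVector
    core_services: RoleVector
    education: RoleVector
    administration: RoleVector
    terms: list[Term] = field(default_factory=list)
    options: dict = field(default_factory=dict)

    @property
    def totals(self) -> RoleVector:
        return (
            self.procedures
            + self.equipment
            + self.core_services
            + self.education
            + self.administration
        )

    def component(self, name: str) -> RoleVector:
        if name not in COMPONENT_ORDER:
            raise KeyError(f"unknown component {name!r}")
        return getattr(self, name)

    def to_frame(self) -> pd.DataFrame:
        """Component x role FTE matrix (with a totals row), full precision."""
        data = {name: self.component(name).to_dict() for name in COMPONENT_ORDER}
        data["total"] = self.totals.to_dict()
        return pd.DataFrame(data).T[list(ROLES)]

    def terms_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.component, t.item_id, t.role, t.value) for t in self.terms],
            columns=["component", "item_id", "role", "value"],
        )

    def to_dict(self) -> dict:
        return {
            "center_id": self.center_id,
            "components": {
                name: self.component(name).to_dict() for name in COMPONENT_ORDER
            },
            "totals": self.totals.to_dict(),
            "grand_total": self.totals.total(),
            "options": dict(self.options),
            "terms": [
                {"component": t.component, "item": t.item_id, "role": t.role,
                 "value": t.value}
                for t in self.terms
            ],
        }


# ---------------------------------------------------------------------------
# Linear-row exposures
# ---------------------------------------------------------------------------

def row_exposures(inv: CenterInventory) -> dict[str, float]:
    """Normalized multiplicities for every *linear* weight row of a center.

    The contribution of a linear row to a pre-administration component is
    ``weight * exposure``.  Percentage rows (procurement, core services,
    supervision, coverage) have no fixed exposure and are excluded.
    """
    mix, eq, ed = inv.case_mix, inv.equipment, inv.education
    exposures: dict[str, float] = {
        "treated_cases": mix.total_cases / 1000.0,
        "complex_cases": mix.complex_cases / 100.0,
        "specialized_cases": mix.specialized_cases / 100.0,
        "brachy_fractions": mix.brachy_fractions / 100.0,
    }
    for item in EQUIPMENT_COUNT_ITEMS:
        exposures[item] = eq.count(item)
    exposures["qa_equipment"] = 1.0 if eq.qa_program else 0.0
    exposures["licensing"] = eq.resolved_regulated_items
    exposures["equipment_training"] = eq.mv_unit_count + eq.tps_system
    exposures["incident_qa_oversight"] = mix.total_cases / 1000.0
    for item in EDUCATION_COUNT_ITEMS:
        exposures[item] = ed.count(item)
    exposures["education_program_baseline"] = float(
        sum(1 for item in BASELINE_EDUCATION_ITEMS if ed.count(item) > 0)
    )
    return exposures


# ---------------------------------------------------------------------------
# Component operations
# ---------------------------------------------------------------------------

_PROCEDURE_ROWS = (
    ("treated_cases", 1000.0, "total_cases"),
    ("complex_cases", 100.0, "complex_cases"),
    ("specialized_cases", 100.0, "specialized_cases"),
    ("brachy_fractions", 100.0, "brachy_fractions"),
)


def clinical_procedures_fte(
    mix: CaseMix, w: WeightTable, terms: Optional[list[Term]] = None
) -> RoleVector:
    """Per-patient clinical support FTE for one center.

    Each role r receives ``w_base,r * total/1000 + w_complex,r * complex/100
    + w_special,r * specialized/100 + w_brachy,r * brachy_fractions/100``.
    """
    out = RoleVector()
    for item_id, divisor, attr in _PROCEDURE_ROWS:
        exposure = getattr(mix, attr) / divisor
        contribution = w.lookup(item_id).weights * exposure
        out = out + contribution
        _record(terms, "procedures", item_id, contribution)
    return out


def clinical_equipment_fte(
    eq: EquipmentInventory, w: WeightTable, terms: Optional[list[Term]] = None
) -> RoleVector:
    """Equipment support FTE: unit/system rows plus equipment administration.

    The base is the sum of weight x count over MV, major and minor equipment
    rows plus the per-center QA-equipment row (if the QA program flag is on).
    On top of the base: procurement as a percentage of each role's base FTE
    (physicist-only under default weights), licensing per regulated device or
    program, and operations training per MV unit and TPS system.
    """
    base = RoleVector()
    for item in EQUIPMENT_COUNT_ITEMS:
        count = eq.count(item)
        if count:
            contribution = w.lookup(item).weights * count
            base = base + contribution
            _record(terms, "equipment", item, contribution)
    if eq.qa_program:
        contribution = w.lookup("qa_equipment").weights
        base = base + contribution
        _record(terms, "equipment", "qa_equipment", contribution)

    procurement_w = w.lookup("procurement").weights
    procurement = RoleVector.from_iterable(
        pw * b for pw, b in zip(procurement_w, base)
    )
    _record(terms, "equipment", "procurement", procurement)

    licensing = w.lookup("licensing").weights * eq.resolved_regulated_items
    _record(terms, "equipment", "licensing", licensing)

    training = w.lookup("equipment_training").weights * (
        eq.mv_unit_count + eq.tps_system
    )
    _record(terms, "equipment", "equipment_training", training)

    return base + procurement + licensing + training


def core_services_fte(
    proc: RoleVector,
    equip: RoleVector,
    mix: CaseMix,
    w: WeightTable,
    fraction: Optional[float] = None,
    terms: Optional[list[Term]] = None,
) -> RoleVector:
    """Program-level physics FTE: technique/protocol support and QA oversight.

    Each role receives its core-services percentage (physicist default 20%,
    overridable per center) of that role's procedures-plus-equipment FTE,
    plus the incident-investigation/QA-oversight weight per 1000 annual
    cases.
    """
    frac_weights = w.lookup("core_services").weights
    if fraction is not None:
        if not 0.0 <= fraction <= 1.0:
            raise ValueError(f"core services fraction must lie in [0, 1], got {fraction}")
        frac_weights = frac_weights.with_role("physicist", fraction)
    base = proc + equip
    protocol = RoleVector.from_iterable(f * b for f, b in zip(frac_weights, base))
    _record(terms, "core_services", "core_services", protocol)
    oversight = w.lookup("incident_qa_oversight").weights * (mix.total_cases / 1000.0)
    _record(terms, "core_services", "incident_qa_oversight", oversight)
    return protocol + oversight


def education_fte(
    ed: EducationProfile, w: WeightTable, terms: Optional[list[Term]] = None
) -> RoleVector:
    """Training workload FTE, including the per-program physicist baseline.

    Each active category among physics residents, radiation oncology
    residents, and graduate students adds one program baseline (default 0.1
    physicist FTE) for program infrastructure and administration.
    """
    out = RoleVector()
    for item in EDUCATION_COUNT_ITEMS:
        count = ed.count(item)
        if count:
            contribution = w.lookup(item).weights * count
            out = out + contribution
            _record(terms, "education", item, contribution)
    active = sum(1 for item in BASELINE_EDUCATION_ITEMS if ed.count(item) > 0)
    if active:
        baseline = w.lookup("education_program_baseline").weights * float(active)
        out = out + baseline
        _record(terms, "education", "education_program_baseline", baseline)
    return out


def administration_fte(
    pre_admin: RoleVector,
    w: WeightTable,
    terms: Optional[list[Term]] = None,
    supervision_in_coverage: bool = True,
) -> RoleVector:
    """Supervision plus coverage overhead on the pre-administration totals.

    Supervision is the supervision-row weights dotted with the per-role
    pre-administration FTEs, and the whole sum is applied to the physicist
    column (department head / supervisor workload).  Coverage adds the
    coverage-row percentage of each role's pre-administration FTE; the
    physicist coverage base includes the supervision workload (switchable
    via ``supervision_in_coverage``).  Single pass — coverage does not
    compound on itself.
    """
    for role in ROLES:
        if pre_admin.get(role) < 0:
            raise ValueError(f"pre-administration {role} FTE is negative")
    sup_w = w.lookup("supervision").weights
    supervision = float(
        sum(sw * p for sw, p in zip(sup_w, pre_admin))
    )
    _record(
        terms,
        "administration",
        "supervision",
        RoleVector(physicist=supervision),
    )
    cov_w = w.lookup("coverage").weights
    cov_base = pre_admin
    if supervision_in_coverage:
        cov_base = cov_base.with_role(
            "physicist", cov_base.physicist + supervision
        )
    coverage = RoleVector.from_iterable(cw * b for cw, b in zip(cov_w, cov_base))
    _record(terms, "administration", "coverage", coverage)
    return coverage.with_role("physicist", coverage.physicist + supervision)


def estimate_staffing(inv: CenterInventory, w: WeightTable) -> StaffingEstimate:
    """Evaluate the full model for one center.

    Composes the five components in order and populates term-level
    provenance.  If the center's options request blending the physics
    assistant into the physicist column, the merge is applied to the
    finished estimate (grand total unchanged).
    """
    terms: list[Term] = []
    proc = clinical_procedures_fte(inv.case_mix, w, terms)
    equip = clinical_equipment_fte(inv.equipment, w, terms)
    core = core_services_fte(
        proc, equip, inv.case_mix, w,
        fraction=inv.options.core_services_fraction, terms=terms,
    )
    edu = education_fte(inv.education, w, terms)
    pre_admin = proc + equip + core + edu
    admin = administration_fte(pre_admin, w, terms)
    estimate = StaffingEstimate(
        center_id=inv.center_id,
        procedures=proc,
        equipment=equip,
        core_services=core,
        education=edu,
        administration=admin,
        terms=terms,
        options=inv.options.model_dump(),
    )
    if inv.options.blend_assistant_into_physicist:
        estimate = blend_roles(estimate, {"assistant": "physicist"})
    return estimate


def blend_roles(
    est: StaffingEstimate, mapping: Mapping[str, str]
) -> StaffingEstimate:
    """Merge whole roles (e.g. assistant -> physicist) in a finished estimate.

    The destination role receives the source role's FTE in every component
    and every term; the source role drops to zero.  The grand total is
    conserved.
    """
    for src, dst in mapping.items():
        if src not in ROLES or dst not in ROLES:
            raise KeyError(f"role mapping {src!r} -> {dst!r} names an unknown role")
    if not mapping or all(src == dst for src, dst in mapping.items()):
        return est

    def merge(vec: RoleVector) -> RoleVector:
        out = vec
        for src, dst in mapping.items():
            if src == dst:
                continue
            moved = out.get(src)
            out = out.with_role(dst, out.get(dst) + moved).with_role(src, 0.0)
        return out

    role_map = {src: dst for src, dst in mapping.items() if src != dst}
    new_terms = [
        replace(t, role=role_map.get(t.role, t.role)) for t in est.terms
    ]
    return StaffingEstimate(
        center_id=est.center_id,
        procedures=merge(est.procedures),
        equipment=merge(est.equipment),
        core_services=merge(est.core_services),
        education=merge(est.education),
        administration=merge(est.administration),
        terms=new_terms,
        options={**est.options, "role_blend": dict(mapping)},
    )


def fte_to_hours(fte: float, w: WeightTable) -> float:
    """Convert FTE to annual hours at the table's nominal work year."""
    if fte < 0:
        raise ValueError(f"fte must be >= 0, got {fte}")
    return fte * w.work_year_hours


def _record(
    terms: Optional[list[Term]], component: str, item_id: str, value: RoleVector
) -> None:
    if terms is None:
        return
    for role in ROLES:
        v = value.get(role)
        if v != 0.0:
            terms.append(Term(component, item_id, role, v))
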