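"""The FTE weight grid: defaults, overrides, validation, and file I/O.

The staffing model is a weighted sum over a fixed grid of workload items
grouped into five components (clinical procedures, clinical equipment, core
services, education/training, administration).  Each row of the grid carries
one weight per staff role and a normalization unit saying what one weight's
worth of FTE is attached to (per 1000 treated cases, per treatment unit, per
vendor system, per cancer center, as a percentage of another FTE subtotal,
and so on).

The default grid encodes the Ontario-calibrated 2021 weights, e.g. 0.5
physicist FTE per 1000 treated cases and 0.2 physicist FTE per standard
linear accelerator.  Items that share a printed weight line (e.g. standard
Linacs and Gamma Knife units) are stored as separate rows sharing one weight
vector so that inventories can count the devices independently.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Any, Mapping, Union

import yaml

from .roles import ROLES, RoleVector

# ---------------------------------------------------------------------------
# Normalization units
# ---------------------------------------------------------------------------

#: Valid normalization tags for a weight row.
NORMALIZATIONS: tuple[str, ...] = (
    "per_1000_cases",      # annual treated cases / 1000
    "per_100_cases",       # annual cases in a category / 100
    "per_100_fractions",   # annual brachytherapy fractions / 100
    "per_unit",            # physical device count
    "per_system",          # software/system count (one per unique vendor)
    "per_center",          # applied once per cancer center
    "percent_of_base",     # fraction of another FTE subtotal (base_set names it)
    "per_person",          # trainee headcount
    "per_course",          # university half-credit courses taught
    "per_program",         # per active training-program category
    "per_staff_fte",       # per FTE of departmental staff (administration rows)
)

COMPONENTS: tuple[str, ...] = (
    "procedures",
    "equipment",
    "core_services",
    "education",
    "administration",
)

#: Item ids counted as megavoltage (MV) treatment units.
MV_UNIT_ITEMS: tuple[str, ...] = ("linac", "gamma_knife", "mr_linac", "proton")

#: Equipment items an inventory counts directly (order = canonical column order).
EQUIPMENT_COUNT_ITEMS: tuple[str, ...] = (
    "linac",
    "gamma_knife",
    "mr_linac",
    "proton",
    "tps_system",
    "rois_system",
    "simulator",
    "hdr_unit",
    "secondary_calc_system",
    "srs_cone_set",
    "cobalt_unit",
    "ldr_program",
    "orthovoltage",
    "ultrasound",
    "conventional_simulator",
    "c_arm",
    "motion_mgmt_system",
)

#: Education profile count fields, in grid order.
EDUCATION_COUNT_ITEMS: tuple[str, ...] = (
    "physics_residents",
    "therapy_students",
    "onco_residents",
    "grad_students",
    "courses",
)

#: Education categories whose presence (count > 0) triggers the per-program
#: physicist baseline for program infrastructure and administration.
BASELINE_EDUCATION_ITEMS: tuple[str, ...] = (
    "physics_residents",
    "onco_residents",
    "grad_students",
)


@dataclass(frozen=True)
class WeightRow:
    """One grid row: an item, its component, normalization, and role weights."""

    item_id: str
    component: str
    normalization: str
    weights: RoleVector
    base_set: str | None = None  # required for percent_of_base rows
    source: str = "default"      # provenance: "default", "override", "fitted", ...

    def __post_init__(self) -> None:
        if self.component not in COMPONENTS:
            raise ValueError(f"{self.item_id}: unknown component {self.component!r}")
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"{self.item_id}: unknown normalization {self.normalization!r}"
            )
        if self.normalization == "percent_of_base" and not self.base_set:
            raise ValueError(f"{self.item_id}: percent_of_base row needs a base_set")


# ---------------------------------------------------------------------------
# Canonical default grid
# ---------------------------------------------------------------------------
# (item_id, component, normalization, (physicist, assistant, elec, mech, it), base_set)
_DEFAULT_ROWS: tuple[tuple[str, str, str, tuple[float, ...], str | None], ...] = (
    # -- clinical procedures -------------------------------------------------
    ("treated_cases", "procedures", "per_1000_cases", (0.50, 0.20, 0.10, 0.05, 0.10), None),
    ("complex_cases", "procedures", "per_100_cases", (0.10, 0.05, 0.02, 0.01, 0.02), None),
    ("specialized_cases", "procedures", "per_100_cases", (0.25, 0.12, 0.05, 0.02, 0.05), None),
    ("brachy_fractions", "procedures", "per_100_fractions", (0.20, 0.05, 0.01, 0.01, 0.01), None),
    # -- clinical equipment: MV treatment units ------------------------------
    ("linac", "equipment", "per_unit", (0.20, 0.20, 0.25, 0.05, 0.03), None),
    ("gamma_knife", "equipment", "per_unit", (0.20, 0.20, 0.25, 0.05, 0.03), None),
    ("mr_linac", "equipment", "per_unit", (0.40, 0.40, 0.50, 0.10, 0.06), None),
    ("proton", "equipment", "per_unit", (2.00, 1.00, 0.50, 0.10, 0.06), None),
    # -- clinical equipment: major -------------------------------------------
    ("tps_system", "equipment", "per_system", (0.10, 0.05, 0.00, 0.00, 0.03), None),
    ("rois_system", "equipment", "per_system", (0.10, 0.05, 0.00, 0.00, 0.20), None),
    ("simulator", "equipment", "per_unit", (0.10, 0.05, 0.15, 0.03, 0.03), None),
    ("hdr_unit", "equipment", "per_unit", (0.10, 0.05, 0.15, 0.03, 0.03), None),
    # -- clinical equipment: minor -------------------------------------------
    ("secondary_calc_system", "equipment", "per_system", (0.05, 0.03, 0.00, 0.00, 0.03), None),
    ("srs_cone_set", "equipment", "per_unit", (0.05, 0.03, 0.10, 0.03, 0.00), None),
    ("cobalt_unit", "equipment", "per_unit", (0.05, 0.03, 0.10, 0.03, 0.00), None),
    ("ldr_program", "equipment", "per_system", (0.05, 0.03, 0.10, 0.03, 0.03), None),
    ("orthovoltage", "equipment", "per_unit", (0.05, 0.03, 0.10, 0.03, 0.03), None),
    ("ultrasound", "equipment", "per_unit", (0.05, 0.03, 0.10, 0.03, 0.03), None),
    ("conventional_simulator", "equipment", "per_unit", (0.05, 0.03, 0.10, 0.03, 0.03), None),
    ("c_arm", "equipment", "per_unit", (0.05, 0.03, 0.10, 0.03, 0.03), None),
    ("motion_mgmt_system", "equipment", "per_system", (0.05, 0.03, 0.10, 0.03, 0.03), None),
    ("qa_equipment", "equipment", "per_center", (0.20, 0.12, 0.20, 0.06, 0.12), None),
    # equipment administration: procurement is a percentage of the MV + major
    # + minor (incl. QA) equipment FTE; licensing counts regulated devices or
    # programs; operations training counts Linac-class units and TPS systems.
    ("procurement", "equipment", "percent_of_base", (0.02, 0.00, 0.00, 0.00, 0.00), "equipment_base"),
    ("licensing", "equipment", "per_unit", (0.025, 0.00, 0.00, 0.00, 0.00), None),
    ("equipment_training", "equipment", "per_unit", (0.02, 0.00, 0.00, 0.00, 0.00), None),
    # -- core services --------------------------------------------------------
    ("core_services", "core_services", "percent_of_base", (0.20, 0.00, 0.00, 0.00, 0.00), "procedures_plus_equipment"),
    ("incident_qa_oversight", "core_services", "per_1000_cases", (0.04, 0.00, 0.00, 0.00, 0.00), None),
    # -- education and training ----------------------------------------------
    ("physics_residents", "education", "per_person", (0.10, 0.025, 0.00, 0.00, 0.00), None),
    ("therapy_students", "education", "per_person", (0.02, 0.005, 0.00, 0.00, 0.00), None),
    ("onco_residents", "education", "per_person", (0.01, 0.000, 0.00, 0.00, 0.00), None),
    ("grad_students", "education", "per_person", (0.10, 0.025, 0.00, 0.00, 0.00), None),
    ("courses", "education", "per_course", (0.06, 0.000, 0.00, 0.00, 0.00), None),
    ("education_program_baseline", "education", "per_program", (0.10, 0.00, 0.00, 0.00, 0.00), None),
    # -- administration --------------------------------------------------------
    ("supervision", "administration", "per_staff_fte", (0.05, 0.02, 0.02, 0.02, 0.02), None),
    ("coverage", "administration", "per_staff_fte", (0.10, 0.10, 0.10, 0.10, 0.10), None),
)

#: Canonical row ids; a valid table contains exactly these rows (plus any
#: user-added equipment rows).
CANONICAL_ITEM_IDS: tuple[str, ...] = tuple(r[0] for r in _DEFAULT_ROWS)

#: Rows whose weights are percentages and must lie in [0, 1].
PERCENT_ITEM_IDS: tuple[str, ...] = tuple(
    r[0] for r in _DEFAULT_ROWS if r[2] in ("percent_of_base", "per_staff_fte")
)


@dataclass
class WeightTable:
    """The complete weight grid plus its scalar conventions.

    Attributes
    ----------
    rows
        Mapping item_id -> :class:`WeightRow`.
    work_year_hours
        Hours in one FTE-year (nominal 37.5 h week -> 1950 h).
    complex_fraction_default
        Default fraction of annual cases treated as complex (0.25).
    specialized_fraction_default
        Default fraction treated as highly specialized (0.01).
    """

    rows: dict[str, WeightRow] = field(default_factory=dict)
    work_year_hours: float = 1950.0
    complex_fraction_default: float = 0.25
    specialized_fraction_default: float = 0.01

    def lookup(self, item_id: str) -> WeightRow:
        try:
            return self.rows[item_id]
        except KeyError:
            raise KeyError(f"no weight row with item_id {item_id!r}") from None

    def __contains__(self, item_id: str) -> bool:
        return item_id in self.rows

    def items_in_component(self, component: str) -> list[WeightRow]:
        return [r for r in self.rows.values() if r.component == component]

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        rows: dict[str, Any] = {}
        for item_id, row in self.rows.items():
            entry: dict[str, Any] = {role: row.weights.get(role) for role in ROLES}
            entry["normalization"] = row.normalization
            entry["component"] = row.component
            if row.base_set is not None:
                entry["base_set"] = row.base_set
            rows[item_id] = entry
        return {
            "meta": {
                "work_year_hours": self.work_year_hours,
                "complex_fraction": self.complex_fraction_default,
                "specialized_fraction": self.specialized_fraction_default,
            },
            "rows": rows,
        }

    @classmethod
    def from_dict(cls, data: Mapping[str, Any], source: str = "file") -> "WeightTable":
        if not isinstance(data, Mapping) or "rows" not in data:
            raise ValueError("weight file must contain a 'rows' mapping")
        meta = data.get("meta", {})
        table = cls(
            work_year_hours=float(meta.get("work_year_hours", 1950.0)),
            complex_fraction_default=float(meta.get("complex_fraction", 0.25)),
            specialized_fraction_default=float(meta.get("specialized_fraction", 0.01)),
        )
        for item_id, entry in data["rows"].items():
            extra = set(entry) - set(ROLES) - {"normalization", "component", "base_set"}
            if extra:
                raise ValueError(f"row {item_id!r}: unknown keys {sorted(extra)}")
            weights = RoleVector.from_mapping(
                {role: float(entry.get(role, 0.0)) for role in ROLES}
            )
            table.rows[item_id] = WeightRow(
                item_id=item_id,
                component=entry["component"],
                normalization=entry["normalization"],
                weights=weights,
                base_set=entry.get("base_set"),
                source=source,
            )
        return table

    def save(self, path: Union[str, Path]) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def load(cls, source: Union[str, Path, IO[str]]) -> "WeightTable":
        if hasattr(source, "read"):
            text = source.read()
        else:
            text = Path(source).read_text()
        data = yaml.safe_load(text)  # YAML is a superset of JSON
        return cls.from_dict(data)


def default_weight_table() -> WeightTable:
    """Build the default (Ontario-calibrated) weight grid.

    Returns a fresh table each call; callers may mutate their copy freely.
    """
    table = WeightTable()
    for item_id, component, normalization, weights, base_set in _DEFAULT_ROWS:
        table.rows[item_id] = WeightRow(
            item_id=item_id,
            component=component,
            normalization=normalization,
            weights=RoleVector(*weights),
            base_set=base_set,
            source="default",
        )
    return table


# ---------------------------------------------------------------------------
# Overrides
# ---------------------------------------------------------------------------

def apply_overrides(base: WeightTable, overrides: Mapping[str, Any]) -> WeightTable:
    """Return a new table with selected cells (or whole new rows) replaced.

    ``overrides`` follows the weights-file layout: either the full
    ``{"meta": ..., "rows": {...}}`` shape or the bare ``rows`` mapping
    ``{item_id: {role: value, ...}}``.  Omitted cells inherit the base table.
    A new (unknown) item_id must come with a full specification: all five
    role weights, a ``normalization`` and optionally a ``component``
    (defaults to ``equipment``).

    Raises
    ------
    KeyError
        For an unknown role name, or a new item_id without full specification.
    ValueError
        For a negative weight.
    """
    if "rows" in overrides and all(
        k in ("rows", "meta") for k in overrides
    ):
        meta = overrides.get("meta", {})
        row_overrides = overrides["rows"]
    else:
        meta = {}
        row_overrides = overrides

    table = copy.deepcopy(base)
    if "work_year_hours" in meta:
        table.work_year_hours = float(meta["work_year_hours"])
    if "complex_fraction" in meta:
        table.complex_fraction_default = float(meta["complex_fraction"])
    if "specialized_fraction" in meta:
        table.specialized_fraction_default = float(meta["specialized_fraction"])

    for item_id, entry in row_overrides.items():
        if not isinstance(entry, Mapping):
            raise ValueError(f"override for {item_id!r} must be a mapping")
        unknown = set(entry) - set(ROLES) - {"normalization", "component", "base_set"}
        if unknown:
            raise KeyError(
                f"override for {item_id!r} names unknown role(s)/keys {sorted(unknown)}"
            )
        for role in ROLES:
            if role in entry and float(entry[role]) < 0:
                raise ValueError(
                    f"override for {item_id!r}, role {role!r}: negative weight "
                    f"{entry[role]}"
                )
        if item_id in table.rows:
            old = table.rows[item_id]
            weights = old.weights
            for role in ROLES:
                if role in entry:
                    weights = weights.with_role(role, float(entry[role]))
            table.rows[item_id] = WeightRow(
                item_id=item_id,
                component=entry.get("component", old.component),
                normalization=entry.get("normalization", old.normalization),
                weights=weights,
                base_set=entry.get("base_set", old.base_set),
                source="override" if weights != old.weights or set(entry) - set(ROLES)
                else old.source,
            )
        else:
            missing = [role for role in ROLES if role not in entry]
            if missing or "normalization" not in entry:
                raise KeyError(
                    f"unknown item_id {item_id!r}: a new row requires all five role "
                    f"weights and a normalization (missing: "
                    f"{missing + (['normalization'] if 'normalization' not in entry else [])})"
                )
            table.rows[item_id] = WeightRow(
                item_id=item_id,
                component=entry.get("component", "equipment"),
                normalization=entry["normalization"],
                weights=RoleVector.from_mapping({r: float(entry[r]) for r in ROLES}),
                base_set=entry.get("base_set"),
                source="override",
            )
    return table


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One validation failure, naming the offending row/role and the rule."""

    item_id: str
    role: str | None
    rule: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        where = self.item_id + (f".{self.role}" if self.role else "")
        return f"[{self.rule}] {where}: {self.message}"


def validate_weights(table: WeightTable) -> list[Violation]:
    """Check a table against the grid's invariants.

    Returns an empty list iff the table is valid.  Violations are data, not
    exceptions, so a UI can report all of them at once.
    """
    violations: list[Violation] = []
    if table.work_year_hours <= 0:
        violations.append(
            Violation("<meta>", None, "work_year_hours_positive",
                      f"work_year_hours must be > 0, got {table.work_year_hours}")
        )
    for name, value in (
        ("complex_fraction", table.complex_fraction_default),
        ("specialized_fraction", table.specialized_fraction_default),
    ):
        if not 0.0 <= value <= 1.0:
            violations.append(
                Violation("<meta>", None, "fraction_range",
                          f"{name} must lie in [0, 1], got {value}")
            )
    if table.complex_fraction_default + table.specialized_fraction_default > 1.0:
        violations.append(
            Violation("<meta>", None, "fraction_sum",
                      "complex + specialized default fractions exceed 1")
        )

    for item_id in CANONICAL_ITEM_IDS:
        if item_id not in table.rows:
            violations.append(
                Violation(item_id, None, "required_row_missing",
                          "canonical grid row absent from table")
            )

    for item_id, row in table.rows.items():
        if row.item_id != item_id:
            violations.append(
                Violation(item_id, None, "key_mismatch",
                          f"row stored under {item_id!r} names itself {row.item_id!r}")
            )
        for role in ROLES:
            w = row.weights.get(role)
            if w < 0:
                violations.append(
                    Violation(item_id, role, "non_negative",
                              f"weight {w} is negative")
                )
            if row.normalization in ("percent_of_base", "per_staff_fte") and not (
                0.0 <= w <= 1.0
            ):
                violations.append(
                    Violation(item_id, role, "percent_range",
                              f"percentage weight {w} outside [0, 1]")
                )
    return violations
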