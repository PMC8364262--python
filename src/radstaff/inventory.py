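"""Center inventories: data model, file I/O, and multi-center panels.

A center inventory is everything the staffing model needs to know about one
cancer center for one year: the annual caseload and its complexity mix,
brachytherapy fractions, an itemized equipment/system inventory, education
and training counts, and a handful of modelling options.

Inventories are read from and written to YAML or JSON files with a *closed*
schema — unknown keys are rejected rather than ignored, so a typo in an
equipment name fails loudly instead of silently dropping workload.  Panels
(many centers, optionally with observed staffing for comparison or
calibration) round-trip through a flat CSV with dotted column names, or a
directory of inventory files with an ``observed.csv`` sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Any, Iterable, Literal, Mapping, Optional, Union

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .roles import ROLES, RoleVector
from .weights import EDUCATION_COUNT_ITEMS, EQUIPMENT_COUNT_ITEMS, MV_UNIT_ITEMS

_CASE_TOLERANCE = 1e-9


class CaseMix(BaseModel):
    """Annual caseload: totals, complexity categories, brachytherapy fractions.

    Counts are real-valued internally: derived mixes (25% of 1500 cases) need
    not be integral, and FTE arithmetic is continuous.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    total_cases: float = Field(ge=0)
    complex_cases: float = Field(default=0.0, ge=0)
    specialized_cases: float = Field(default=0.0, ge=0)
    brachy_fractions: float = Field(default=0.0, ge=0)
    #: True when complex/specialized were supplied as counts rather than
    #: derived from the default fractions.
    fractions_explicit: bool = False

    @model_validator(mode="after")
    def _check_mix(self) -> "CaseMix":
        if self.complex_cases + self.specialized_cases > self.total_cases + _CASE_TOLERANCE:
            raise ValueError(
                f"complex ({self.complex_cases}) + specialized "
                f"({self.specialized_cases}) cases exceed total ({self.total_cases})"
            )
        return self


def derive_case_mix(
    total_cases: float,
    complex_fraction: float = 0.25,
    specialized_fraction: float = 0.01,
    brachy_fractions: float = 0.0,
) -> CaseMix:
    """Split an annual caseload into complexity categories by fraction.

    ``complex_cases = complex_fraction * total_cases`` and likewise for the
    highly specialized category; counts are kept as real numbers (no
    rounding) because they feed directly into FTE arithmetic.
    """
    for name, frac in (
        ("complex_fraction", complex_fraction),
        ("specialized_fraction", specialized_fraction),
    ):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    if complex_fraction + specialized_fraction > 1.0:
        raise ValueError("complex_fraction + specialized_fraction exceed 1")
    if total_cases < 0:
        raise ValueError(f"total_cases must be >= 0, got {total_cases}")
    return CaseMix(
        total_cases=float(total_cases),
        complex_cases=complex_fraction * total_cases,
        specialized_cases=specialized_fraction * total_cases,
        brachy_fractions=float(brachy_fractions),
        fractions_explicit=False,
    )


class EquipmentInventory(BaseModel):
    """Counts of treatment units and systems, plus licensing/QA metadata.

    Systems (TPS, ROIS, secondary dose calculation, motion management) are
    counted per unique vendor, irrespective of the number of workstations.
    Counts may be fractional (e.g. a unit commissioned mid-year).
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    linac: float = Field(default=0.0, ge=0)
    gamma_knife: float = Field(default=0.0, ge=0)
    mr_linac: float = Field(default=0.0, ge=0)
    proton: float = Field(default=0.0, ge=0)
    tps_system: float = Field(default=0.0, ge=0)
    rois_system: float = Field(default=0.0, ge=0)
    simulator: float = Field(default=0.0, ge=0)
    hdr_unit: float = Field(default=0.0, ge=0)
    secondary_calc_system: float = Field(default=0.0, ge=0)
    srs_cone_set: float = Field(default=0.0, ge=0)
    cobalt_unit: float = Field(default=0.0, ge=0)
    ldr_program: float = Field(default=0.0, ge=0)
    orthovoltage: float = Field(default=0.0, ge=0)
    ultrasound: float = Field(default=0.0, ge=0)
    conventional_simulator: float = Field(default=0.0, ge=0)
    c_arm: float = Field(default=0.0, ge=0)
    motion_mgmt_system: float = Field(default=0.0, ge=0)
    #: Whether the per-center QA equipment row applies (default on).
    qa_program: bool = True
    #: Count of devices/programs requiring national or provincial licensing.
    #: ``None`` means "use the default rule": MV units plus one per
    #: brachytherapy program present (HDR and/or LDR).
    regulated_items: Optional[float] = Field(default=None, ge=0)

    def count(self, item_id: str) -> float:
        if item_id not in EQUIPMENT_COUNT_ITEMS:
            raise KeyError(f"unknown equipment item {item_id!r}")
        return getattr(self, item_id)

    @property
    def mv_unit_count(self) -> float:
        return float(sum(getattr(self, item) for item in MV_UNIT_ITEMS))

    @property
    def default_regulated_items(self) -> float:
        programs = (1.0 if self.hdr_unit > 0 else 0.0) + (
            1.0 if self.ldr_program > 0 else 0.0
        )
        return self.mv_unit_count + programs

    @property
    def resolved_regulated_items(self) -> float:
        if self.regulated_items is None:
            return self.default_regulated_items
        return self.regulated_items


class EducationProfile(BaseModel):
    """Trainee headcounts and classroom teaching load."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    physics_residents: float = Field(default=0.0, ge=0)
    therapy_students: float = Field(default=0.0, ge=0)
    onco_residents: float = Field(default=0.0, ge=0)
    grad_students: float = Field(default=0.0, ge=0)
    courses: float = Field(default=0.0, ge=0)

    def count(self, item_id: str) -> float:
        if item_id not in EDUCATION_COUNT_ITEMS:
            raise KeyError(f"unknown education item {item_id!r}")
        return getattr(self, item_id)


class CenterOptions(BaseModel):
    """Per-center modelling options."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    complex_fraction: float = Field(default=0.25, ge=0, le=1)
    specialized_fraction: float = Field(default=0.01, ge=0, le=1)
    #: Physicist core-services percentage; ``None`` uses the weight table's
    #: default (20%).  Centers leading early evaluation of novel techniques
    #: may raise it.
    core_services_fraction: Optional[float] = Field(default=None, ge=0, le=1)
    #: Merge physics-assistant FTE into the physicist total (jurisdictions
    #: that do not employ assistants as a separate category).
    blend_assistant_into_physicist: bool = False
    #: Whether total_cases counts treated cases or distinct patients; the
    #: two differ by roughly 1% and the model treats them interchangeably,
    #: but the basis supplied is recorded.
    caseload_basis: Literal["treated_cases", "distinct_patients"] = "treated_cases"

    @model_validator(mode="after")
    def _check_sum(self) -> "CenterOptions":
        if self.complex_fraction + self.specialized_fraction > 1.0:
            raise ValueError("complex_fraction + specialized_fraction exceed 1")
        return self


class CenterInventory(BaseModel):
    """Everything the model needs to know about one center for one year."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    center_id: str = Field(min_length=1)
    case_mix: CaseMix
    equipment: EquipmentInventory = EquipmentInventory()
    education: EducationProfile = EducationProfile()
    options: CenterOptions = CenterOptions()
    #: Notes about defaults filled in during loading (documentation only;
    #: excluded from equality so a round-trip through a format that does not
    #: carry notes still compares equal).
    provenance: tuple[str, ...] = ()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CenterInventory):
            return NotImplemented
        return (
            self.center_id == other.center_id
            and self.case_mix == other.case_mix
            and self.equipment == other.equipment
            and self.education == other.education
            and self.options == other.options
        )

    def __hash__(self) -> int:
        return hash(self.center_id)


@dataclass(frozen=True)
class ObservedStaffing:
    """Actual (and optionally desired) staffing levels reported by a center."""

    center_id: str
    actual: RoleVector
    desired: Optional[RoleVector] = None

    def __post_init__(self) -> None:
        for role in ROLES:
            if self.actual.get(role) < 0:
                raise ValueError(
                    f"{self.center_id}: actual {role} staffing is negative"
                )


PanelEntry = tuple[CenterInventory, Optional[ObservedStaffing]]


# ---------------------------------------------------------------------------
# Inventory file I/O
# ---------------------------------------------------------------------------

_TOP_LEVEL_KEYS = {
    "center_id",
    "total_cases",
    "complex_cases",
    "specialized_cases",
    "brachy_fractions",
    "fractions_explicit",
    "equipment",
    "education",
    "options",
    "provenance",
}


def inventory_from_dict(data: Mapping[str, Any]) -> CenterInventory:
    """Build a validated inventory from the (closed) file schema.

    Missing optional fields take documented defaults: complex/specialized
    counts derive from the option fractions (25%/1%), the QA program is on,
    and regulated items default to the MV unit count plus one per
    brachytherapy program present.  Every default filled is recorded in the
    returned inventory's provenance notes.
    """
    if not isinstance(data, Mapping):
        raise ValueError("inventory document must be a mapping")
    unknown = set(data) - _TOP_LEVEL_KEYS
    if unknown:
        raise ValueError(f"unknown inventory key(s): {sorted(unknown)}")
    if "center_id" not in data:
        raise ValueError("inventory is missing required field 'center_id'")
    if "total_cases" not in data:
        raise ValueError("inventory is missing required field 'total_cases'")

    provenance: list[str] = list(data.get("provenance", []))
    options = CenterOptions(**(data.get("options") or {}))
    equipment = EquipmentInventory(**(data.get("equipment") or {}))
    education = EducationProfile(**(data.get("education") or {}))

    total = float(data["total_cases"])
    explicit = data.get("fractions_explicit")
    if "complex_cases" in data or "specialized_cases" in data:
        if explicit is None:
            explicit = True
        complex_cases = float(
            data.get("complex_cases", options.complex_fraction * total)
        )
        specialized = float(
            data.get("specialized_cases", options.specialized_fraction * total)
        )
        if "complex_cases" not in data:
            provenance.append(
                f"complex_cases defaulted to {options.complex_fraction:.0%} of total"
            )
        if "specialized_cases" not in data:
            provenance.append(
                f"specialized_cases defaulted to {options.specialized_fraction:.0%} of total"
            )
    else:
        if explicit is None:
            explicit = False
        complex_cases = options.complex_fraction * total
        specialized = options.specialized_fraction * total
        provenance.append(
            f"case mix derived from default fractions "
            f"{options.complex_fraction:g}/{options.specialized_fraction:g}"
        )
    case_mix = CaseMix(
        total_cases=total,
        complex_cases=complex_cases,
        specialized_cases=specialized,
        brachy_fractions=float(data.get("brachy_fractions", 0.0)),
        fractions_explicit=bool(explicit),
    )
    if equipment.regulated_items is None:
        provenance.append(
            f"regulated_items defaulted to MV units + brachy programs "
            f"= {equipment.default_regulated_items:g}"
        )
    return CenterInventory(
        center_id=str(data["center_id"]),
        case_mix=case_mix,
        equipment=equipment,
        education=education,
        options=options,
        provenance=tuple(provenance),
    )


def inventory_to_dict(inv: CenterInventory) -> dict[str, Any]:
    """Serialize an inventory to the file schema (fully explicit)."""
    return {
        "center_id": inv.center_id,
        "total_cases": inv.case_mix.total_cases,
        "complex_cases": inv.case_mix.complex_cases,
        "specialized_cases": inv.case_mix.specialized_cases,
        "brachy_fractions": inv.case_mix.brachy_fractions,
        "fractions_explicit": inv.case_mix.fractions_explicit,
        "equipment": inv.equipment.model_dump(),
        "education": inv.education.model_dump(),
        "options": inv.options.model_dump(),
        "provenance": list(inv.provenance),
    }


def load_inventory(
    source: Union[str, Path, IO[str]], fmt: Optional[str] = None
) -> CenterInventory:
    """Load and validate one center inventory from YAML or JSON.

    The format is inferred from the file suffix unless ``fmt`` is given
    (``"yaml"`` or ``"json"``; YAML parsing accepts JSON documents).
    """
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", "<stream>")
    else:
        path = Path(source)
        text = path.read_text()
        name = str(path)
        if fmt is None:
            fmt = "json" if path.suffix.lower() == ".json" else "yaml"
    try:
        if fmt == "json":
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ValueError(f"could not parse inventory {name}: {exc}") from exc
    try:
        return inventory_from_dict(data)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"invalid inventory {name}: {exc}") from exc


def save_inventory(inv: CenterInventory, path: Union[str, Path]) -> None:
    path = Path(path)
    data = inventory_to_dict(inv)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


# ---------------------------------------------------------------------------
# Panels
# ---------------------------------------------------------------------------

def _panel_columns() -> list[str]:
    cols = [
        "center_id",
        "total_cases",
        "complex_cases",
        "specialized_cases",
        "brachy_fractions",
        "fractions_explicit",
    ]
    cols += [f"equipment.{item}" for item in EQUIPMENT_COUNT_ITEMS]
    cols += ["equipment.qa_program", "equipment.regulated_items"]
    cols += [f"education.{item}" for item in EDUCATION_COUNT_ITEMS]
    cols += [
        "options.complex_fraction",
        "options.specialized_fraction",
        "options.core_services_fraction",
        "options.blend_assistant_into_physicist",
        "options.caseload_basis",
    ]
    return cols


ACTUAL_COLUMNS = [f"actual_{role}" for role in ROLES]
DESIRED_COLUMNS = [f"desired_{role}" for role in ROLES]


def _entry_to_row(entry: PanelEntry) -> dict[str, Any]:
    inv, obs = entry
    row: dict[str, Any] = {
        "center_id": inv.center_id,
        "total_cases": inv.case_mix.total_cases,
        "complex_cases": inv.case_mix.complex_cases,
        "specialized_cases": inv.case_mix.specialized_cases,
        "brachy_fractions": inv.case_mix.brachy_fractions,
        "fractions_explicit": inv.case_mix.fractions_explicit,
    }
    for item in EQUIPMENT_COUNT_ITEMS:
        row[f"equipment.{item}"] = inv.equipment.count(item)
    row["equipment.qa_program"] = inv.equipment.qa_program
    row["equipment.regulated_items"] = (
        "" if inv.equipment.regulated_items is None else inv.equipment.regulated_items
    )
    for item in EDUCATION_COUNT_ITEMS:
        row[f"education.{item}"] = inv.education.count(item)
    row["options.complex_fraction"] = inv.options.complex_fraction
    row["options.specialized_fraction"] = inv.options.specialized_fraction
    row["options.core_services_fraction"] = (
        "" if inv.options.core_services_fraction is None
        else inv.options.core_services_fraction
    )
    row["options.blend_assistant_into_physicist"] = (
        inv.options.blend_assistant_into_physicist
    )
    row["options.caseload_basis"] = inv.options.caseload_basis
    if obs is not None:
        for role in ROLES:
            row[f"actual_{role}"] = obs.actual.get(role)
        if obs.desired is not None:
            for role in ROLES:
                row[f"desired_{role}"] = obs.desired.get(role)
    return row


def save_panel_csv(entries: Iterable[PanelEntry], path: Union[str, Path]) -> None:
    """Write a panel to a flat CSV (one row per center, dotted column names)."""
    entries = list(entries)
    rows = [_entry_to_row(e) for e in entries]
    cols = _panel_columns()
    if any(obs is not None for _, obs in entries):
        cols += ACTUAL_COLUMNS
    if any(obs is not None and obs.desired is not None for _, obs in entries):
        cols += DESIRED_COLUMNS
    df = pd.DataFrame(rows, columns=cols)
    # %.17g round-trips IEEE doubles exactly
    df.to_csv(path, index=False, float_format="%.17g")


def _row_to_entry(row: Mapping[str, Any]) -> PanelEntry:
    def present(key: str) -> bool:
        return key in row and row[key] == row[key] and row[key] != ""  # NaN-safe

    data: dict[str, Any] = {
        "center_id": str(row["center_id"]),
        "total_cases": float(row["total_cases"]),
    }
    for key in ("complex_cases", "specialized_cases", "brachy_fractions"):
        if present(key):
            data[key] = float(row[key])
    if present("fractions_explicit"):
        data["fractions_explicit"] = _parse_bool(row["fractions_explicit"])

    equipment: dict[str, Any] = {}
    for item in EQUIPMENT_COUNT_ITEMS:
        key = f"equipment.{item}"
        if present(key):
            equipment[item] = float(row[key])
    if present("equipment.qa_program"):
        equipment["qa_program"] = _parse_bool(row["equipment.qa_program"])
    if present("equipment.regulated_items"):
        equipment["regulated_items"] = float(row["equipment.regulated_items"])
    if equipment:
        data["equipment"] = equipment

    education = {}
    for item in EDUCATION_COUNT_ITEMS:
        key = f"education.{item}"
        if present(key):
            education[item] = float(row[key])
    if education:
        data["education"] = education

    options: dict[str, Any] = {}
    for opt in ("complex_fraction", "specialized_fraction", "core_services_fraction"):
        key = f"options.{opt}"
        if present(key):
            options[opt] = float(row[key])
    if present("options.blend_assistant_into_physicist"):
        options["blend_assistant_into_physicist"] = _parse_bool(
            row["options.blend_assistant_into_physicist"]
        )
    if present("options.caseload_basis"):
        options["caseload_basis"] = str(row["options.caseload_basis"])
    if options:
        data["options"] = options

    inv = inventory_from_dict(data)
    obs: Optional[ObservedStaffing] = None
    if all(present(c) for c in ACTUAL_COLUMNS):
        actual = RoleVector.from_mapping(
            {role: float(row[f"actual_{role}"]) for role in ROLES}
        )
        desired = None
        if all(present(c) for c in DESIRED_COLUMNS):
            desired = RoleVector.from_mapping(
                {role: float(row[f"desired_{role}"]) for role in ROLES}
            )
        obs = ObservedStaffing(center_id=inv.center_id, actual=actual, desired=desired)
    return inv, obs


def _parse_bool(value: Any) -> bool:
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise ValueError(f"cannot interpret {value!r} as a boolean")


def _load_observed_csv(path: Path) -> dict[str, ObservedStaffing]:
    df = pd.read_csv(path, float_precision="round_trip")
    observed: dict[str, ObservedStaffing] = {}
    for _, row in df.iterrows():
        cid = str(row["center_id"])
        if cid in observed:
            raise ValueError(f"duplicate center_id {cid!r} in {path}")
        desired = None
        if all(c in df.columns for c in DESIRED_COLUMNS) and not any(
            pd.isna(row[c]) for c in DESIRED_COLUMNS
        ):
            desired = RoleVector.from_mapping(
                {role: float(row[f"desired_{role}"]) for role in ROLES}
            )
        observed[cid] = ObservedStaffing(
            center_id=cid,
            actual=RoleVector.from_mapping(
                {role: float(row[f"actual_{role}"]) for role in ROLES}
            ),
            desired=desired,
        )
    return observed


def load_panel(source: Union[str, Path]) -> list[PanelEntry]:
    """Load a multi-center panel from a CSV file or a directory.

    A directory panel contains one inventory file per center (``*.yaml`` /
    ``*.yml`` / ``*.json``, sorted by name) plus an optional ``observed.csv``
    sidecar with columns ``center_id, actual_physicist, ..., actual_it``
    (and optionally ``desired_*``).

    Raises
    ------
    ValueError
        On duplicate center ids, or observed staffing without a matching
        inventory.
    """
    path = Path(source)
    entries: list[PanelEntry] = []
    seen: set[str] = set()
    if path.is_dir():
        inv_files = sorted(
            p
            for p in path.iterdir()
            if p.suffix.lower() in (".yaml", ".yml", ".json")
            and p.name not in ("manifest.json", "manifest.yaml")
        )
        observed = {}
        obs_path = path / "observed.csv"
        if obs_path.exists():
            observed = _load_observed_csv(obs_path)
        for p in inv_files:
            inv = load_inventory(p)
            if inv.center_id in seen:
                raise ValueError(f"duplicate center_id {inv.center_id!r} in panel {path}")
            seen.add(inv.center_id)
            entries.append((inv, observed.pop(inv.center_id, None)))
        if observed:
            raise ValueError(
                f"observed staffing for unknown center(s): {sorted(observed)}"
            )
    else:
        df = pd.read_csv(path, float_precision="round_trip")
        if "center_id" not in df.columns:
            raise ValueError(f"panel CSV {path} lacks a center_id column")
        for _, row in df.iterrows():
            inv, obs = _row_to_entry(row)
            if inv.center_id in seen:
                raise ValueError(f"duplicate center_id {inv.center_id!r} in panel {path}")
            seen.add(inv.center_id)
            entries.append((inv, obs))
    return entries


def save_panel_dir(entries: Iterable[PanelEntry], directory: Union[str, Path]) -> None:
    """Write a panel as a directory of inventory YAMLs plus observed.csv."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    entries = list(entries)
    obs_rows = []
    for i, (inv, obs) in enumerate(entries):
        save_inventory(inv, directory / f"{i:03d}_{inv.center_id}.yaml")
        if obs is not None:
            row = {"center_id": obs.center_id}
            row.update({f"actual_{role}": obs.actual.get(role) for role in ROLES})
            if obs.desired is not None:
                row.update(
                    {f"desired_{role}": obs.desired.get(role) for role in ROLES}
                )
            obs_rows.append(row)
    if obs_rows:
        pd.DataFrame(obs_rows).to_csv(
            directory / "observed.csv", index=False, float_format="%.17g"
        )
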