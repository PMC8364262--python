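"""Seeded synthetic center inventories and calibration panels.

Real multi-center staffing surveys are confidential, so every stochastic
test and worked example in this package runs on synthetic panels.  The
generator emulates the range of Canadian radiotherapy centers the model was
built for: annual caseloads from roughly 1,000 to 5,000 treated cases,
about one Linac per 450 cases, a roughly even split of centers with an HDR
brachytherapy program, and occasional specialty platforms (MR-Linac, Gamma
Knife, protons, orthovoltage, Cobalt-60).  Education loads scale loosely
with center size, mimicking the concentration of residency and graduate
programs in larger academic centers.

Observed staffing in a generated panel is the model's own prediction under
a given weight table plus independent zero-mean Gaussian noise per role
(default s.d. 0.5 FTE), truncated at zero because real staffing cannot be
negative.  Panels are therefore self-consistent by construction: they test
the machinery (calibration, reporting, serialization), not the realism of
any particular center.

Determinism: each field of each center draws from its own generator keyed
by ``(seed, center index, field code)``, so adding a field or reordering
the sampling code does not perturb unrelated draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .engine import estimate_staffing
from .inventory import (
    CaseMix,
    CenterInventory,
    CenterOptions,
    EducationProfile,
    EquipmentInventory,
    ObservedStaffing,
    PanelEntry,
)
from .roles import ROLES, RoleVector
from .weights import WeightTable, default_weight_table

#: Stable per-field stream codes; append only, never renumber.
_FIELD_CODES = {
    "caseload": 0,
    "linacs": 1,
    "mr_linac": 2,
    "gamma_knife": 3,
    "proton": 4,
    "hdr": 5,
    "ldr": 6,
    "brachy_fractions": 7,
    "simulators": 8,
    "tps": 9,
    "rois": 10,
    "secondary_calc": 11,
    "srs_cones": 12,
    "cobalt": 13,
    "orthovoltage": 14,
    "ultrasound": 15,
    "conventional_simulator": 16,
    "c_arm": 17,
    "motion_mgmt": 18,
    "physics_residents": 19,
    "therapy_students": 20,
    "onco_residents": 21,
    "grad_students": 22,
    "courses": 23,
    "noise": 24,
    "complex_fraction": 25,
    "specialized_fraction": 26,
}


@dataclass(frozen=True)
class PanelSpec:
    """Sampling specification for a synthetic panel.

    Defaults span small (~1,500 cases, 4 Linacs) to large (~5,000 cases,
    11+ Linacs) centers.  ``noise_sd`` applies per role to the observed
    staffing (FTE); probabilities are per-center presence probabilities.
    """

    n_centers: int = 23
    seed: int = 0
    caseload_range: tuple[float, float] = (1000.0, 5000.0)
    cases_per_linac: float = 450.0
    #: HDR-program presence scale (1.0 = the default ramp: ~25% of the
    #: smallest centers up to ~98% of the largest, since most regional
    #: programs offer at least gynaecological HDR).
    brachy_prob: float = 1.0
    ldr_prob: float = 0.2
    #: Presence probabilities *in large academic centers*; small centers get
    #: a tenth of these (specialty platforms concentrate with size).
    mr_linac_prob: float = 0.25
    gamma_knife_prob: float = 0.30
    proton_prob: float = 0.0
    orthovoltage_prob: float = 0.30
    cobalt_prob: float = 0.05
    srs_cone_prob: float = 0.40
    #: HDR fractions per annual case for centers with an HDR program
    #: (~8% of patients x ~4 fractions), jittered +/-50%.
    brachy_fractions_per_case: float = 0.30
    #: Per-center reported complexity mix, drawn uniformly from these ranges
    #: (centers report a modest spread around the nominal 25%/1%).
    complex_fraction_range: tuple[float, float] = (0.20, 0.30)
    specialized_fraction_range: tuple[float, float] = (0.008, 0.02)
    resident_rate_per_1000_cases: float = 0.55  # ~24 residency FTE over 15 centers
    noise_sd: dict[str, float] = field(
        default_factory=lambda: {role: 0.5 for role in ROLES}
    )
    metadata_label: str = "synthetic"

    def __post_init__(self) -> None:
        lo, hi = self.caseload_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid caseload_range {self.caseload_range}")
        if self.n_centers < 1:
            raise ValueError("n_centers must be >= 1")
        for name in (
            "ldr_prob", "mr_linac_prob", "gamma_knife_prob",
            "proton_prob", "orthovoltage_prob", "cobalt_prob", "srs_cone_prob",
        ):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.brachy_prob < 0:
            raise ValueError("brachy_prob must be >= 0")
        for role, sd in self.noise_sd.items():
            if role not in ROLES:
                raise ValueError(f"noise_sd names unknown role {role!r}")
            if sd < 0:
                raise ValueError(f"noise_sd[{role!r}] must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_centers": self.n_centers,
            "seed": self.seed,
            "caseload_range": list(self.caseload_range),
            "cases_per_linac": self.cases_per_linac,
            "brachy_prob": self.brachy_prob,
            "ldr_prob": self.ldr_prob,
            "mr_linac_prob": self.mr_linac_prob,
            "gamma_knife_prob": self.gamma_knife_prob,
            "proton_prob": self.proton_prob,
            "orthovoltage_prob": self.orthovoltage_prob,
            "cobalt_prob": self.cobalt_prob,
            "srs_cone_prob": self.srs_cone_prob,
            "brachy_fractions_per_case": self.brachy_fractions_per_case,
            "complex_fraction_range": list(self.complex_fraction_range),
            "specialized_fraction_range": list(self.specialized_fraction_range),
            "resident_rate_per_1000_cases": self.resident_rate_per_1000_cases,
            "noise_sd": dict(self.noise_sd),
            "metadata_label": self.metadata_label,
        }


def _rng(spec: PanelSpec, index: int, fieldname: str) -> np.random.Generator:
    return np.random.default_rng([spec.seed, index, _FIELD_CODES[fieldname]])


def generate_center(spec: PanelSpec, index: int) -> CenterInventory:
    """Draw one synthetic center, deterministic in ``(spec.seed, index)``.

    Equipment is kept coherent with caseload: at least one Linac whenever
    external-beam cases are treated, and the Linac count stays within one
    unit of ``caseload / cases_per_linac``.
    """
    lo, hi = spec.caseload_range
    cases = float(np.floor(_rng(spec, index, "caseload").uniform(lo, hi + 1.0)))
    cases = min(cases, hi)

    target = cases / spec.cases_per_linac
    linacs = max(
        1, int(round(target + _rng(spec, index, "linacs").uniform(-0.5, 0.5)))
    )

    # Specialty services concentrate in larger (academic) centers: MR-Linacs
    # and Gamma Knives appear essentially only above ~3500-4000 cases, and
    # the HDR-program probability ramps from ~25% in the smallest centers to
    # near-certainty in the largest.
    large = cases > 3500.0
    mr_linac = int(
        _rng(spec, index, "mr_linac").random()
        < (spec.mr_linac_prob if large else spec.mr_linac_prob / 10.0)
    )
    gamma_knife = int(
        _rng(spec, index, "gamma_knife").random()
        < (spec.gamma_knife_prob if cases > 4000.0 else spec.gamma_knife_prob / 10.0)
    )
    proton = int(
        _rng(spec, index, "proton").random()
        < (spec.proton_prob if large else spec.proton_prob / 10.0)
    )
    p_hdr = min(1.0, spec.brachy_prob * float(np.clip((cases - 800.0) / 1200.0, 0.25, 0.98)))
    hdr = int(_rng(spec, index, "hdr").random() < p_hdr)
    ldr = int(_rng(spec, index, "ldr").random() < spec.ldr_prob)

    brachy_fractions = 0.0
    if hdr or ldr:
        jitter = _rng(spec, index, "brachy_fractions").uniform(0.85, 1.15)
        brachy_fractions = float(
            np.round(spec.brachy_fractions_per_case * cases * jitter)
        )

    # CT/MR/PET-CT simulators scale with the number of treatment units.
    simulators = max(1, int(round(linacs / 4 + _rng(spec, index, "simulators").uniform(-0.4, 0.6))))
    tps = 1 + hdr + int(_rng(spec, index, "tps").random() < 0.3) + gamma_knife
    rois = 1 + int(_rng(spec, index, "rois").random() < 0.2)
    secondary_calc = 1 + int(_rng(spec, index, "secondary_calc").random() < 0.3)
    srs_cones = int(_rng(spec, index, "srs_cones").random() < spec.srs_cone_prob)
    cobalt = int(_rng(spec, index, "cobalt").random() < spec.cobalt_prob)
    ortho = int(_rng(spec, index, "orthovoltage").random() < spec.orthovoltage_prob)
    ultrasound = int(_rng(spec, index, "ultrasound").random() < 0.4)
    conv_sim = int(_rng(spec, index, "conventional_simulator").random() < 0.1)
    c_arm = int(_rng(spec, index, "c_arm").random() < 0.3)
    motion_rng = _rng(spec, index, "motion_mgmt")
    motion = int(motion_rng.random() < 0.6) + int(motion_rng.random() < 0.2)

    equipment = EquipmentInventory(
        linac=linacs,
        gamma_knife=gamma_knife,
        mr_linac=mr_linac,
        proton=proton,
        tps_system=tps,
        rois_system=rois,
        simulator=simulators,
        hdr_unit=hdr,
        secondary_calc_system=secondary_calc,
        srs_cone_set=srs_cones,
        cobalt_unit=cobalt,
        ldr_program=ldr,
        orthovoltage=ortho,
        ultrasound=ultrasound,
        conventional_simulator=conv_sim,
        c_arm=c_arm,
        motion_mgmt_system=motion,
        qa_program=True,
        regulated_items=None,  # default rule: MV units + brachy programs
    )

    size = cases / 1000.0
    education = EducationProfile(
        physics_residents=int(
            _rng(spec, index, "physics_residents").poisson(
                spec.resident_rate_per_1000_cases * size
            )
        ),
        therapy_students=int(_rng(spec, index, "therapy_students").poisson(1.2 * size)),
        onco_residents=int(_rng(spec, index, "onco_residents").poisson(0.8 * size)),
        grad_students=int(_rng(spec, index, "grad_students").poisson(0.6 * size)),
        courses=int(_rng(spec, index, "courses").poisson(0.4 * size)),
    )

    complex_fraction = float(
        _rng(spec, index, "complex_fraction").uniform(*spec.complex_fraction_range)
    )
    specialized_fraction = float(
        _rng(spec, index, "specialized_fraction").uniform(
            *spec.specialized_fraction_range
        )
    )
    options = CenterOptions(
        complex_fraction=round(complex_fraction, 4),
        specialized_fraction=round(specialized_fraction, 4),
    )
    mix = CaseMix(
        total_cases=cases,
        complex_cases=options.complex_fraction * cases,
        specialized_cases=options.specialized_fraction * cases,
        brachy_fractions=brachy_fractions,
        fractions_explicit=True,
    )
    return CenterInventory(
        center_id=f"SYN-{spec.seed}-{index:03d}",
        case_mix=mix,
        equipment=equipment,
        education=education,
        options=options,
    )


def generate_panel(
    spec: PanelSpec, w: Optional[WeightTable] = None
) -> "CalibrationPanel":
    """Generate a full panel with observed staffing = prediction + noise.

    Noise is independent zero-mean Gaussian per role with the spec's s.d.,
    truncated at zero.  The untruncated values are kept in the panel
    metadata (``raw_observed``) so parameter-recovery checks are not biased
    by the truncation.
    """
    from .calibration import CalibrationPanel  # local import: avoid cycle

    if w is None:
        w = default_weight_table()
    entries: list[PanelEntry] = []
    raw_observed: dict[str, dict[str, float]] = {}
    for i in range(spec.n_centers):
        inv = generate_center(spec, i)
        predicted = estimate_staffing(inv, w).totals
        noise_rng = _rng(spec, i, "noise")
        raw = {
            role: predicted.get(role)
            + noise_rng.normal(0.0, spec.noise_sd.get(role, 0.0))
            for role in ROLES
        }
        raw_observed[inv.center_id] = raw
        actual = RoleVector.from_mapping(
            {role: max(0.0, v) for role, v in raw.items()}
        )
        entries.append(
            (inv, ObservedStaffing(center_id=inv.center_id, actual=actual))
        )
    return CalibrationPanel(
        entries=entries,
        metadata={
            "label": spec.metadata_label,
            "seed": spec.seed,
            "spec": spec.to_dict(),
            "raw_observed": raw_observed,
        },
    )
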