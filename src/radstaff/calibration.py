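"""Fitting the weight grid to observed staffing across a panel of centers.

With the structural percentage rows (procurement, core services,
supervision, coverage) held fixed, every predicted FTE total is *linear* in
the remaining row weights.  Fitting the grid to a panel of
``(inventory, actual staffing)`` pairs therefore reduces to one
bound-constrained regularized linear least-squares problem per staff role:

    minimize  sum_centers (predicted_r - actual_r)^2
              + lambda * sum_groups (w_g - w_base,g)^2
    subject to  w >= 0.

Freeing the percentage rows as well would make the problem bilinear and —
at realistic panel sizes of a few dozen centers — non-identifiable, so they
stay fixed unless a caller explicitly frees nothing-else-works cases by
overriding the table directly.

The four non-physicist roles are fitted first and independently; the
physicist column is fitted last because its administration term
(supervision) depends on the other columns' pre-administration totals.

Rows that share a printed weight line (standard Linacs with Gamma Knife
units; simulators with HDR units; SRS cone sets with Cobalt-60 units; the
minor-equipment line) are fitted jointly as one shared parameter unless the
caller splits them.

Identifiability is diagnosed from the singular value decomposition of each
role's design matrix: groups with zero exposure across the panel, or with
significant weight in a null-space direction, are flagged rather than
silently zeroed.  The ridge term (default 1e-3, scaled by the mean squared
base weight of the free cells) biases such rows toward the default grid,
reflecting that the fit is not a unique solution to the underlying
multivariate problem.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear

from .engine import estimate_staffing, row_exposures
from .inventory import (
    CenterInventory,
    CenterOptions,
    CaseMix,
    EducationProfile,
    EquipmentInventory,
    ObservedStaffing,
    PanelEntry,
)
from .roles import ROLES
from .weights import WeightTable

#: Default weight-sharing groups: group name -> member row ids.  Singleton
#: linear rows form their own group.
DEFAULT_GROUPS: dict[str, tuple[str, ...]] = {
    "treated_cases": ("treated_cases",),
    "complex_cases": ("complex_cases",),
    "specialized_cases": ("specialized_cases",),
    "brachy_fractions": ("brachy_fractions",),
    "linac_class": ("linac", "gamma_knife"),
    "mr_linac": ("mr_linac",),
    "proton": ("proton",),
    "tps_system": ("tps_system",),
    "rois_system": ("rois_system",),
    "simulator_class": ("simulator", "hdr_unit"),
    "secondary_calc_system": ("secondary_calc_system",),
    "srs_cobalt": ("srs_cone_set", "cobalt_unit"),
    "minor_shared": (
        "ldr_program",
        "orthovoltage",
        "ultrasound",
        "conventional_simulator",
        "c_arm",
        "motion_mgmt_system",
    ),
    "qa_equipment": ("qa_equipment",),
    "licensing": ("licensing",),
    "physics_residents": ("physics_residents",),
    "therapy_students": ("therapy_students",),
    "onco_residents": ("onco_residents",),
    "grad_students": ("grad_students",),
    "courses": ("courses",),
    "education_program_baseline": ("education_program_baseline",),
}

#: Structural percentage rows held fixed during fitting.
STRUCTURAL_ROWS: tuple[str, ...] = (
    "procurement",
    "core_services",
    "supervision",
    "coverage",
)

#: Linear rows whose exposure is an *exact* linear combination of other
#: rows' exposures for every possible inventory: operations training counts
#: MV units + TPS systems (the sum of four equipment columns plus the TPS
#: column) and incident/QA oversight shares the treated-cases exposure.
#: Panel totals therefore can never separate them from their companions, so
#: they stay at their base values by default.  Freeing them explicitly is
#: allowed; the whole collinear set is then flagged as unidentifiable.
COLLINEAR_FIXED_ROWS: tuple[str, ...] = ("equipment_training", "incident_qa_oversight")

_FIT_ROLE_ORDER: tuple[str, ...] = ("assistant", "elec", "mech", "it", "physicist")


@dataclass
class CalibrationPanel:
    """(inventory, observed staffing) pairs plus sampling metadata."""

    entries: list[PanelEntry]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("a calibration panel needs at least one entry")

    def __len__(self) -> int:
        return len(self.entries)

    def with_observed(self) -> list[tuple[CenterInventory, ObservedStaffing]]:
        out = [(inv, obs) for inv, obs in self.entries if obs is not None]
        if not out:
            raise ValueError("panel has no entries with observed staffing")
        return out


@dataclass
class CalibrationResult:
    """Fitted grid plus residual diagnostics.

    ``residuals`` is centers x roles of (predicted - actual) under the
    fitted table; ``summary`` holds the per-role mean and sample s.d. of the
    residuals; ``identifiability`` maps role -> list of group names whose
    weights the panel cannot pin down.
    """

    fitted: WeightTable
    residuals: pd.DataFrame
    summary: pd.DataFrame
    ridge: float
    ridge_lambda: float
    free_groups: dict[str, tuple[str, ...]]
    identifiability: dict[str, list[str]]
    kkt_residual: float

    def unidentifiable(self) -> set[str]:
        return {g for groups in self.identifiability.values() for g in groups}


def _group_exposures(
    inventories: Sequence[CenterInventory], groups: Mapping[str, tuple[str, ...]]
) -> pd.DataFrame:
    rows = []
    for inv in inventories:
        exp = row_exposures(inv)
        rows.append({g: sum(exp[item] for item in items) for g, items in groups.items()})
    return pd.DataFrame(rows, index=[inv.center_id for inv in inventories])


def _probe_inventory() -> CenterInventory:
    """A center with strictly positive exposure for every linear row."""
    return CenterInventory(
        center_id="probe",
        case_mix=CaseMix(
            total_cases=1000.0,
            complex_cases=100.0,
            specialized_cases=10.0,
            brachy_fractions=100.0,
            fractions_explicit=True,
        ),
        equipment=EquipmentInventory(
            **{item: 1.0 for item in (
                "linac", "gamma_knife", "mr_linac", "proton", "tps_system",
                "rois_system", "simulator", "hdr_unit", "secondary_calc_system",
                "srs_cone_set", "cobalt_unit", "ldr_program", "orthovoltage",
                "ultrasound", "conventional_simulator", "c_arm",
                "motion_mgmt_system",
            )},
            qa_program=True,
            regulated_items=1.0,
        ),
        education=EducationProfile(
            physics_residents=1, therapy_students=1, onco_residents=1,
            grad_students=1, courses=1,
        ),
        options=CenterOptions(),
    )


def _set_group_weight(
    table: WeightTable, group_items: Iterable[str], role: str, value: float
) -> None:
    from dataclasses import replace

    for item in group_items:
        row = table.rows[item]
        table.rows[item] = replace(
            row, weights=row.weights.with_role(role, value), source="fitted"
        )


def _solve_nnls(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Non-negative least squares; BVLS (exact active-set) when possible."""
    method = "bvls" if A.shape[0] >= A.shape[1] else "trf"
    res = lsq_linear(A, b, bounds=(0.0, np.inf), method=method, tol=1e-14)
    return res.x


def _role_multipliers(
    table: WeightTable,
    role: str,
    groups: Mapping[str, tuple[str, ...]],
) -> dict[str, float]:
    """Center-independent multiplier of each free group for one role.

    Because predictions are linear in the free weights, the multiplier (the
    factor by which a unit of ``weight x exposure`` propagates into the
    role's final total through procurement, core services, supervision and
    coverage) can be measured with two model evaluations on a probe center
    with known exposures.
    """
    probe = _probe_inventory()
    exposures = row_exposures(probe)
    zero_table = copy.deepcopy(table)
    for g, items in groups.items():
        _set_group_weight(zero_table, items, role, 0.0)
    base_total = estimate_staffing(probe, zero_table).totals.get(role)
    multipliers: dict[str, float] = {}
    for g, items in groups.items():
        probe_table = copy.deepcopy(zero_table)
        _set_group_weight(probe_table, items, role, 1.0)
        total = estimate_staffing(probe, probe_table).totals.get(role)
        x = sum(exposures[item] for item in items)
        multipliers[g] = (total - base_total) / x
    return multipliers


def fit_weights(
    panel: CalibrationPanel,
    base: Optional[WeightTable] = None,
    free_groups: Optional[Mapping[str, tuple[str, ...]]] = None,
    ridge: float = 1e-3,
    svd_tol: float = 1e-8,
) -> CalibrationResult:
    """Fit the free row weights to a panel's observed staffing.

    Parameters
    ----------
    panel
        Centers with observed staffing for at least the roles being fitted.
    base
        Starting grid; also the target of the ridge penalty.  Defaults to
        the default table.
    free_groups
        Mapping of group name -> member row ids to fit (weights shared
        within a group).  Defaults to :data:`DEFAULT_GROUPS`.  Structural
        percentage rows may not be freed.
    ridge
        Relative ridge strength; the absolute penalty is ``ridge`` times the
        mean squared base weight over the free cells.  ``0`` disables
        regularization (rank deficiency is then flagged per group, not
        silently resolved).
    svd_tol
        Relative singular-value threshold for the identifiability diagnosis.
    """
    from .weights import default_weight_table

    if base is None:
        base = default_weight_table()
    if ridge < 0:
        raise ValueError(f"ridge must be >= 0, got {ridge}")
    groups = dict(free_groups) if free_groups is not None else dict(DEFAULT_GROUPS)
    for g, items in groups.items():
        for item in items:
            if item in STRUCTURAL_ROWS:
                raise ValueError(
                    f"group {g!r} frees structural percentage row {item!r}; "
                    "structural rows stay fixed during fitting"
                )
            if item not in base.rows:
                raise KeyError(f"group {g!r} names unknown row {item!r}")

    observed = panel.with_observed()
    # deterministic, order-invariant: sort by center id
    observed = sorted(observed, key=lambda pair: pair[0].center_id)
    inventories = [inv for inv, _ in observed]
    actual = {
        role: np.array([obs.actual.get(role) for _, obs in observed])
        for role in ROLES
    }
    X = _group_exposures(inventories, groups)
    group_names = list(groups)

    # absolute ridge scaled by the magnitude of the base grid's free cells
    base_cells = np.array(
        [base.rows[items[0]].weights.get(role)
         for role in ROLES for g, items in groups.items()]
    )
    scale = float(np.mean(base_cells**2))
    lam = ridge * (scale if scale > 0 else 1.0)

    fitted = copy.deepcopy(base)
    identifiability: dict[str, list[str]] = {}
    kkt_worst = 0.0

    for role in _FIT_ROLE_ORDER:
        m = _role_multipliers(fitted, role, groups)
        A = X.to_numpy() * np.array([m[g] for g in group_names])[None, :]

        # offsets: predictions with all free weights of this role zeroed,
        # other roles at their current (already fitted) values
        zero_table = copy.deepcopy(fitted)
        for g in group_names:
            _set_group_weight(zero_table, groups[g], role, 0.0)
        offsets = np.array(
            [estimate_staffing(inv, zero_table).totals.get(role)
             for inv in inventories]
        )
        b = actual[role] - offsets
        w_base = np.array(
            [base.rows[groups[g][0]].weights.get(role) for g in group_names]
        )

        # identifiability from the unregularized design
        col_norms = np.linalg.norm(A, axis=0)
        flagged = [g for g, cn in zip(group_names, col_norms) if cn <= svd_tol]
        active = [j for j, cn in enumerate(col_norms) if cn > svd_tol]
        if active:
            u, s, vt = np.linalg.svd(A[:, active], full_matrices=False)
            null_mask = s <= svd_tol * s[0] if s[0] > 0 else np.ones_like(s, bool)
            for v in vt[null_mask]:
                for j, comp in zip(active, np.abs(v)):
                    if comp > 1e-6 and group_names[j] not in flagged:
                        flagged.append(group_names[j])
        identifiability[role] = flagged

        if lam > 0:
            A_aug = np.vstack([A, np.sqrt(lam) * np.eye(len(group_names))])
            b_aug = np.concatenate([b, np.sqrt(lam) * w_base])
            w_fit = _solve_nnls(A_aug, b_aug)
        else:
            # without regularization, pin flagged (rank-deficient) columns to
            # the base value and solve only for the identifiable ones
            w_fit = w_base.astype(float).copy()
            keep = [j for j, g in enumerate(group_names) if g not in flagged]
            drop = [j for j in range(len(group_names)) if j not in keep]
            if keep:
                b_eff = b - A[:, drop] @ w_base[drop]
                w_fit[keep] = _solve_nnls(A[:, keep], b_eff)

        # KKT check: for w > 0 the gradient must vanish; at w = 0 it must be >= 0
        grad = A.T @ (A @ w_fit - b) + lam * (w_fit - w_base)
        free_idx = [j for j, g in enumerate(group_names) if g not in flagged]
        kkt = 0.0
        for j in free_idx:
            if w_fit[j] > 1e-12:
                kkt = max(kkt, abs(grad[j]))
            else:
                kkt = max(kkt, max(0.0, -grad[j]))
        kkt_worst = max(kkt_worst, kkt)

        for j, g in enumerate(group_names):
            _set_group_weight(fitted, groups[g], role, float(max(0.0, w_fit[j])))

    predictions = {
        inv.center_id: estimate_staffing(inv, fitted).totals for inv in inventories
    }
    residuals = pd.DataFrame(
        {
            role: [
                predictions[inv.center_id].get(role) - obs.actual.get(role)
                for inv, obs in observed
            ]
            for role in ROLES
        },
        index=[inv.center_id for inv, _ in observed],
    )
    summary = pd.DataFrame(
        {
            "mean_diff": residuals.mean(),
            "sd": residuals.std(ddof=1) if len(residuals) > 1 else np.nan,
            "n": len(residuals),
        }
    )
    return CalibrationResult(
        fitted=fitted,
        residuals=residuals,
        summary=summary,
        ridge=ridge,
        ridge_lambda=lam,
        free_groups=groups,
        identifiability=identifiability,
        kkt_residual=kkt_worst,
    )


def evaluate_fit(
    panel: CalibrationPanel,
    w: WeightTable,
    grouping: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Per-role mean and sample s.d. of (predicted - actual) staffing.

    A positive mean difference means the grid over-predicts the actual
    staffing level.  ``grouping`` maps center_id -> group label (e.g. a
    region); the returned tidy frame then contains one block per group plus
    an ``overall`` block.

    Returns a DataFrame with columns ``group, role, mean_diff, sd, n``.
    """
    observed = panel.with_observed()
    diffs = pd.DataFrame(
        {
            role: [
                estimate_staffing(inv, w).totals.get(role) - obs.actual.get(role)
                for inv, obs in observed
            ]
            for role in ROLES
        },
        index=[inv.center_id for inv, _ in observed],
    )
    blocks = [("overall", diffs)]
    if grouping is not None:
        labels = pd.Series(
            [grouping[cid] for cid in diffs.index], index=diffs.index
        )
        for label in sorted(labels.unique()):
            blocks.append((label, diffs[labels == label]))
    records = []
    for label, block in blocks:
        for role in ROLES:
            records.append(
                {
                    "group": label,
                    "role": role,
                    "mean_diff": float(block[role].mean()),
                    "sd": float(block[role].std(ddof=1)) if len(block) > 1 else float("nan"),
                    "n": len(block),
                }
            )
    return pd.DataFrame(records)
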