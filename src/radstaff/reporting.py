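"""Panel analytics: caseload regressions, case ratios, comparison summaries.

These are pure functions of their inputs: identical panels give identical
tables.  Figures are deliberately not produced here — numeric tables are
the contract, and plotting styles change; callers can plot the returned
frames however they like.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .engine import COMPONENT_ORDER, StaffingEstimate
from .inventory import ObservedStaffing
from .roles import ROLES


@dataclass(frozen=True)
class RegressionSummary:
    """Ordinary least-squares line of FTE against annual caseload."""

    slope: float       # FTE per case
    intercept: float   # FTE
    r_squared: float
    n: int


def caseload_regression(
    points: Iterable[tuple[float, float]]
) -> RegressionSummary:
    """OLS fit of FTE (y) on annual cases (x) with coefficient of determination.

    Requires at least two points with distinct caseloads.
    """
    pts = list(points)
    if len(pts) < 2:
        raise ValueError("caseload regression needs at least 2 points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("caseload regression needs distinct caseload values")
    fit = stats.linregress(x, y)
    return RegressionSummary(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pts),
    )


@dataclass(frozen=True)
class CaseRatioSummary:
    """Annual cases per predicted physicist FTE, per center and pooled."""

    ratios: tuple[float, ...]
    mean: float
    sd: float  # sample s.d. (NaN for a single center)


def cases_per_fte(
    pairs: Iterable[tuple[float, float]]
) -> CaseRatioSummary:
    """Per-center ratio of annual cases to physicist FTE, with mean +/- s.d.

    ``pairs`` are (annual cases, physicist FTE); FTE must be positive.
    """
    ratios = []
    for cases, fte in pairs:
        if fte <= 0:
            raise ValueError(f"physicist FTE must be > 0 to form a ratio, got {fte}")
        ratios.append(cases / fte)
    if not ratios:
        raise ValueError("no centers supplied")
    arr = np.array(ratios)
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else float("nan")
    return CaseRatioSummary(
        ratios=tuple(float(r) for r in arr), mean=float(arr.mean()), sd=sd
    )


def summarize_estimates(
    estimates: Mapping[str, StaffingEstimate],
    observed: Mapping[str, ObservedStaffing],
    grouping: Optional[Mapping[str, str]] = None,
) -> dict[str, pd.DataFrame]:
    """Compare predicted with actual staffing across a panel.

    Returns a dict with:

    ``differences``
        Tidy frame (group, role, mean_diff, sd, n) of predicted - actual,
        positive when the grid over-predicts; sample (n-1) s.d.; an
        ``overall`` block plus one per grouping label when given.
    ``per_center``
        Centers x roles frame of (predicted - actual).
    ``breakdown``
        Stacked per-center component breakdown (center, component, role,
        fte) of the predictions.

    Raises on center ids present in ``observed`` but absent from
    ``estimates``.
    """
    missing = set(observed) - set(estimates)
    if missing:
        raise KeyError(f"observed staffing for unmatched center(s): {sorted(missing)}")
    ids = [cid for cid in estimates if cid in observed]
    if not ids:
        raise ValueError("no centers with both an estimate and observed staffing")
    per_center = pd.DataFrame(
        {
            role: [
                estimates[cid].totals.get(role) - observed[cid].actual.get(role)
                for cid in ids
            ]
            for role in ROLES
        },
        index=ids,
    )
    blocks: list[tuple[str, pd.DataFrame]] = [("overall", per_center)]
    if grouping is not None:
        labels = pd.Series([grouping[cid] for cid in ids], index=ids)
        for label in sorted(labels.unique()):
            blocks.append((label, per_center[labels == label]))
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
    breakdown_records = []
    for cid in estimates:
        est = estimates[cid]
        for component in COMPONENT_ORDER:
            vec = est.component(component)
            for role in ROLES:
                breakdown_records.append(
                    {
                        "center_id": cid,
                        "component": component,
                        "role": role,
                        "fte": vec.get(role),
                    }
                )
    return {
        "differences": pd.DataFrame(records),
        "per_center": per_center,
        "breakdown": pd.DataFrame(breakdown_records),
    }


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def estimate_markdown(est: StaffingEstimate, precision: int = 1) -> str:
    """Markdown summary table of one estimate, totals reported to 0.1 FTE."""
    frame = est.to_frame().round(precision)
    header = "| component | " + " | ".join(ROLES) + " |"
    sep = "|" + "---|" * (len(ROLES) + 1)
    lines = [f"# Staffing estimate: {est.center_id}", "", header, sep]
    for name, row in frame.iterrows():
        cells = " | ".join(f"{row[role]:.{precision}f}" for role in ROLES)
        lines.append(f"| {name} | {cells} |")
    lines.append("")
    lines.append(f"Grand total: {est.totals.total():.{precision}f} FTE")
    return "\n".join(lines) + "\n"


def estimate_csv(est: StaffingEstimate) -> str:
    """CSV breakdown: the component x role matrix then term provenance."""
    frame = est.to_frame()
    frame.index.name = "component"
    return frame.to_csv()
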