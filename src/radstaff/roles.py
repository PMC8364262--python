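"""Staff roles and the per-role FTE vector.

The model tracks five staff categories found in Canadian radiation oncology
physics departments: medical physicists, physics assistants, electronics
engineering, mechanical engineering, and IT support.  Every quantity in the
model — a weight, a component subtotal, a staffing total — is a vector over
these five roles, expressed in full-time equivalents (FTE), i.e. person-years
at the nominal work year.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from typing import Iterable, Iterator, Mapping

import numpy as np

#: Canonical role order used everywhere (arrays, CSV columns, reports).
ROLES: tuple[str, ...] = ("physicist", "assistant", "elec", "mech", "it")

ROLE_LABELS: dict[str, str] = {
    "physicist": "Medical physicist",
    "assistant": "Physics assistant",
    "elec": "Engineering (electronics)",
    "mech": "Engineering (mechanical)",
    "it": "IT support",
}


@dataclass(frozen=True)
class RoleVector:
    """An FTE quintuple, one entry per staff role.

    Supports addition, subtraction and scalar multiplication so component
    contributions can be accumulated with ordinary arithmetic.  The container
    itself places no sign restriction (residuals are differences of vectors);
    non-negativity of weights and staffing levels is enforced where those
    objects are validated.
    """

    physicist: float = 0.0
    assistant: float = 0.0
    elec: float = 0.0
    mech: float = 0.0
    it: float = 0.0

    def __add__(self, other: "RoleVector") -> "RoleVector":
        return RoleVector(*(a + b for a, b in zip(self.as_tuple(), other.as_tuple())))

    def __sub__(self, other: "RoleVector") -> "RoleVector":
        return RoleVector(*(a - b for a, b in zip(self.as_tuple(), other.as_tuple())))

    def __mul__(self, scalar: float) -> "RoleVector":
        return RoleVector(*(a * scalar for a in self.as_tuple()))

    __rmul__ = __mul__

    def __iter__(self) -> Iterator[float]:
        return iter(self.as_tuple())

    def as_tuple(self) -> tuple[float, ...]:
        return (self.physicist, self.assistant, self.elec, self.mech, self.it)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.as_tuple(), dtype=float)

    def to_dict(self) -> dict[str, float]:
        return {role: getattr(self, role) for role in ROLES}

    def get(self, role: str) -> float:
        if role not in ROLES:
            raise KeyError(f"unknown role {role!r}; expected one of {ROLES}")
        return getattr(self, role)

    def with_role(self, role: str, value: float) -> "RoleVector":
        if role not in ROLES:
            raise KeyError(f"unknown role {role!r}; expected one of {ROLES}")
        return replace(self, **{role: value})

    def total(self) -> float:
        """Grand total FTE summed over roles."""
        return float(sum(self.as_tuple()))

    def isclose(self, other: "RoleVector", atol: float = 1e-12) -> bool:
        return bool(np.allclose(self.as_array(), other.as_array(), atol=atol, rtol=0.0))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, float]) -> "RoleVector":
        unknown = set(mapping) - set(ROLES)
        if unknown:
            raise KeyError(f"unknown role(s) {sorted(unknown)}; expected {ROLES}")
        return cls(**{k: float(v) for k, v in mapping.items()})

    @classmethod
    def from_iterable(cls, values: Iterable[float]) -> "RoleVector":
        vals = tuple(float(v) for v in values)
        if len(vals) != len(ROLES):
            raise ValueError(f"expected {len(ROLES)} values, got {len(vals)}")
        return cls(*vals)


def zero_vector() -> RoleVector:
    return RoleVector()


# dataclass field order must agree with ROLES; cheap import-time check
assert tuple(f.name for f in fields(RoleVector)) == ROLES
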