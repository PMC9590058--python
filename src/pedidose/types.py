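"""Domain types for pediatric dose prediction.

Doses and clearances always carry an explicit basis — per kilogram of body
weight or absolute — because silently mixing the two is the classic failure
mode of pediatric dose arithmetic. All types validate on construction and
raise :class:`InvalidInputError` (or a subclass) on bad values rather than
clamping or coercing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

__all__ = [
    "Basis",
    "DrugClass",
    "AgeClass",
    "ReferenceType",
    "WeightStratum",
    "DoseSpec",
    "ClearanceSpec",
    "Subject",
    "AdultReference",
    "ObservationRow",
    "PedidoseError",
    "InvalidInputError",
    "BasisMismatchError",
    "MissingFieldError",
    "UnitParseError",
    "SchemaError",
    "NEONATAL_AGE_CLASSES",
]


class PedidoseError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(PedidoseError, ValueError):
    """A numeric input is non-positive, non-finite, or otherwise unusable."""


class BasisMismatchError(PedidoseError, ValueError):
    """Two quantities that must share a per-kg/absolute basis (or unit) do not.

    Raised eagerly because a silent per-kg vs absolute confusion produces
    doses wrong by a factor of the body weight.
    """


class MissingFieldError(PedidoseError, ValueError):
    """A row lacks a field required by the requested computation."""


class UnitParseError(PedidoseError, ValueError):
    """A unit string could not be mapped to a known basis."""


class SchemaError(PedidoseError, ValueError):
    """An input table is missing mandatory columns."""


class Basis(str, Enum):
    """Whether an amount is expressed per kilogram of body weight or in total."""

    PER_KG = "per_kg"
    ABSOLUTE = "absolute"


class DrugClass(str, Enum):
    MONOCLONAL = "monoclonal"
    POLYCLONAL = "polyclonal"
    NON_ANTIBODY = "non_antibody"


class AgeClass(str, Enum):
    PRETERM_NEONATE = "preterm_neonate"
    TERM_NEONATE = "term_neonate"
    CHILD = "child"
    ADOLESCENT = "adolescent"


NEONATAL_AGE_CLASSES = frozenset({AgeClass.PRETERM_NEONATE, AgeClass.TERM_NEONATE})


class ReferenceType(str, Enum):
    """Provenance of the observed pediatric dose used as comparator.

    ``per_kg_label``: the label dose, extrapolated from adults on a mg/kg
    basis. ``cl_based``: computed from the adult dose scaled by the
    child/adult clearance ratio. ``investigator_selected``: chosen in the
    source study (typical for neonatal polyclonal antibodies).
    """

    PER_KG_LABEL = "per_kg_label"
    CL_BASED = "cl_based"
    INVESTIGATOR_SELECTED = "investigator_selected"


class WeightStratum(str, Enum):
    LT30 = "lt30"
    GE30 = "ge30"
    NEONATE = "neonate"


def _check_positive_finite(value: float, name: str) -> None:
    if not isinstance(value, (int, float)) or isinstance(value, bool):
        raise InvalidInputError(f"{name} must be a real number, got {value!r}")
    if not math.isfinite(value):
        raise InvalidInputError(f"{name} must be finite, got {value!r}")
    if value <= 0:
        raise InvalidInputError(f"{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class DoseSpec:
    """A dose amount with an explicit basis.

    Parameters
    ----------
    amount
        Strictly positive dose amount (mass units, e.g. mg, per kg of body
        weight when ``basis`` is per-kg).
    basis
        ``Basis.PER_KG`` or ``Basis.ABSOLUTE``.
    unit
        Mass-unit label; "mg" by default. Purely a label — no unit
        conversion is performed, but mismatched labels are rejected when two
        doses are compared.
    """

    amount: float
    basis: Basis
    unit: str = "mg"

    def __post_init__(self) -> None:
        _check_positive_finite(self.amount, "dose amount")
        object.__setattr__(self, "basis", Basis(self.basis))


@dataclass(frozen=True)
class ClearanceSpec:
    """A clearance value (volume per time, optionally per kg) with explicit basis."""

    value: float
    basis: Basis
    unit: str = "mL/h"

    def __post_init__(self) -> None:
        _check_positive_finite(self.value, "clearance value")
        object.__setattr__(self, "basis", Basis(self.basis))


@dataclass(frozen=True)
class Subject:
    """A pediatric subject: body weight plus a coarse age class.

    Neonates (preterm or term) must weigh no more than 5 kg; the neonatal
    cohorts modelled here span 1–3 kg.
    """

    weight_kg: float
    age_class: AgeClass = AgeClass.CHILD

    def __post_init__(self) -> None:
        _check_positive_finite(self.weight_kg, "subject weight_kg")
        object.__setattr__(self, "age_class", AgeClass(self.age_class))
        if self.age_class in NEONATAL_AGE_CLASSES and self.weight_kg > 5:
            raise InvalidInputError(
                f"neonate weight_kg must be <= 5 kg, got {self.weight_kg!r}"
            )

    @property
    def is_neonate(self) -> bool:
        return self.age_class in NEONATAL_AGE_CLASSES


@dataclass(frozen=True)
class AdultReference:
    """The adult regimen a pediatric dose is derived from.

    The reference body weight defaults to 70 kg: the weight at which the
    percent-of-adult-dose rule reaches 100%, so that an adult receives
    exactly the adult dose.
    """

    dose: DoseSpec
    weight_kg: float = 70.0
    clearance: Optional[ClearanceSpec] = None

    def __post_init__(self) -> None:
        _check_positive_finite(self.weight_kg, "adult weight_kg")


@dataclass(frozen=True)
class ObservationRow:
    """One pediatric observation: drug, subject, observed dose, provenance."""

    drug_id: str
    drug_class: DrugClass
    subject: Subject
    observed_dose: DoseSpec
    reference_type: ReferenceType
    child_clearance: Optional[ClearanceSpec] = field(default=None)

    def __post_init__(self) -> None:
        object.__setattr__(self, "drug_class", DrugClass(self.drug_class))
        object.__setattr__(self, "reference_type", ReferenceType(self.reference_type))
        if (
            self.reference_type is ReferenceType.CL_BASED
            and self.child_clearance is None
        ):
            raise MissingFieldError(
                f"row for drug {self.drug_id!r}: clearance-based reference "
                "requires a child clearance"
            )

    @property
    def weight_stratum(self) -> WeightStratum:
        if self.subject.is_neonate:
            return WeightStratum.NEONATE
        if self.subject.weight_kg < 30:
            return WeightStratum.LT30
        return WeightStratum.GE30
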