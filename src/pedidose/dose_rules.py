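"""Pediatric dose prediction rules.

The core is the Salisbury weight rule, a piecewise-linear percent-of-adult-dose
rule for children under 70 kg:

* below 30 kg: ``2 × weight (kg)`` percent of the adult dose,
* from 30 kg to below 70 kg: ``weight (kg) + 30`` percent of the adult dose.

Both branches give 60% at 30 kg, so the rule is continuous; at 70 kg it
reaches 100% and is capped there (dosing a child above the full adult dose
would be unsafe extrapolation, and the rule is defined only below 70 kg).

Two reference dosing methods are provided alongside it: plain per-kg
extrapolation of the adult dose, and clearance-ratio dosing
(child dose = adult dose × CL_child / CL_adult), the comparator that
clearance-minded pharmacologists regard as the more physiological standard.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

from .types import (
    AdultReference,
    Basis,
    BasisMismatchError,
    ClearanceSpec,
    DoseSpec,
    InvalidInputError,
)

__all__ = [
    "PredictionDose",
    "salisbury_percent",
    "to_absolute",
    "to_per_kg",
    "salisbury_dose",
    "cl_based_dose",
    "perkg_extrapolated_dose",
]


@dataclass(frozen=True)
class PredictionDose:
    """A predicted pediatric dose expressed on both bases."""

    absolute: float
    per_kg: float
    unit: str = "mg"

    def as_spec(self, basis: Basis) -> DoseSpec:
        basis = Basis(basis)
        amount = self.per_kg if basis is Basis.PER_KG else self.absolute
        return DoseSpec(amount, basis, self.unit)


def _check_weight(weight_kg: float, name: str = "weight_kg") -> None:
    if (
        not isinstance(weight_kg, (int, float))
        or isinstance(weight_kg, bool)
        or not math.isfinite(weight_kg)
        or weight_kg <= 0
    ):
        raise InvalidInputError(f"{name} must be a positive finite number, got {weight_kg!r}")


def salisbury_percent(weight_kg: float) -> float:
    """Percent of the adult dose prescribed by the Salisbury rule.

    Parameters
    ----------
    weight_kg
        Child body weight in kg; must be positive and finite.

    Returns
    -------
    float
        ``2 × weight_kg`` for weights below 30 kg, ``weight_kg + 30`` for
        weights from 30 up to (but not including) 70 kg, and 100 for
        weights of 70 kg or more (capped, with a warning: the rule is
        defined only below 70 kg).
    """
    _check_weight(weight_kg)
    if weight_kg >= 70:
        if weight_kg > 70:
            warnings.warn(
                f"weight {weight_kg} kg is at or above the 70 kg adult reference; "
                "capping at 100% of the adult dose",
                UserWarning,
                stacklevel=2,
            )
        return 100.0
    if weight_kg < 30:
        return 2.0 * weight_kg
    return weight_kg + 30.0


def to_absolute(dose: DoseSpec, weight_kg: float) -> float:
    """Absolute dose amount for a subject of the given weight.

    Per-kg doses are multiplied by the weight; absolute doses pass through.
    """
    _check_weight(weight_kg)
    if dose.basis is Basis.PER_KG:
        return dose.amount * weight_kg
    return dose.amount


def to_per_kg(dose: DoseSpec, weight_kg: float) -> float:
    """Per-kg dose amount for a subject of the given weight."""
    _check_weight(weight_kg)
    if dose.basis is Basis.PER_KG:
        return dose.amount
    return dose.amount / weight_kg


def salisbury_dose(adult: AdultReference, child_weight_kg: float) -> PredictionDose:
    """Pediatric dose predicted by the Salisbury rule.

    The rule's percentage is applied to the *absolute* adult dose (the adult
    per-kg dose times the adult reference weight, 70 kg by default), and the
    result is reported both as an absolute amount and renormalized to the
    child's weight.

    A consequence worth knowing: with a 70 kg reference, the per-kg
    prediction below 30 kg is weight-free — always 1.4 × the adult per-kg
    dose — because the child weight cancels: (2W/100) × 70d / W = 1.4 d.
    """
    _check_weight(child_weight_kg, "child_weight_kg")
    adult_absolute = to_absolute(adult.dose, adult.weight_kg)
    percent = salisbury_percent(child_weight_kg)
    absolute = percent / 100.0 * adult_absolute
    return PredictionDose(
        absolute=absolute,
        per_kg=absolute / child_weight_kg,
        unit=adult.dose.unit,
    )


def cl_based_dose(
    adult_dose: DoseSpec, cl_child: ClearanceSpec, cl_adult: ClearanceSpec
) -> DoseSpec:
    """Clearance-ratio pediatric dose: adult dose × (CL_child / CL_adult).

    Both clearances must share the same basis and unit; mixing a per-kg
    child clearance with an absolute adult clearance silently rescales the
    dose by the body weight, so it is a hard error. The returned dose keeps
    the basis of ``adult_dose``: absolute adult dose with absolute
    clearances yields an absolute child dose, per-kg with per-kg yields
    per-kg.
    """
    if cl_child.basis is not cl_adult.basis:
        raise BasisMismatchError(
            f"clearance bases differ: child {cl_child.basis.value}, "
            f"adult {cl_adult.basis.value}"
        )
    if cl_child.unit != cl_adult.unit:
        raise BasisMismatchError(
            f"clearance units differ: child {cl_child.unit!r}, adult {cl_adult.unit!r}"
        )
    return DoseSpec(
        amount=adult_dose.amount * (cl_child.value / cl_adult.value),
        basis=adult_dose.basis,
        unit=adult_dose.unit,
    )


def perkg_extrapolated_dose(
    adult_dose: DoseSpec, adult_weight_kg: float, child_weight_kg: float
) -> PredictionDose:
    """Linear per-kg extrapolation of the adult dose to a child.

    The child receives the adult per-kg dose unchanged — the conventional
    label practice for most therapeutic proteins, and the practice the
    Salisbury rule deliberately departs from below 30 kg.
    """
    _check_weight(adult_weight_kg, "adult_weight_kg")
    _check_weight(child_weight_kg, "child_weight_kg")
    per_kg = to_per_kg(adult_dose, adult_weight_kg)
    return PredictionDose(
        absolute=per_kg * child_weight_kg,
        per_kg=per_kg,
        unit=adult_dose.unit,
    )
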