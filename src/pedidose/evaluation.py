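"""Prediction-error evaluation and stratified accuracy summaries.

Predicted and observed doses are compared by

* percent error = (predicted − observed) / observed × 100 (positive means
  over-prediction), and
* fold error = predicted / observed, so fold = 1 + percent/100.

Fold errors are binned into the accuracy categories conventional in
pharmacokinetic dose-prediction work:

* *wide*: within 0.5–1.5-fold (the lenient band),
* *narrow*: within 0.7–1.3-fold, i.e. at most ±30% error (the band taken
  as an acceptable first-in-pediatric prediction),
* *over*: above 1.3-fold; *under*: below 0.7-fold.

Narrow/over/under partition the fold axis (narrow is the closed interval
[0.7, 1.3]); wide overlaps them and is reported as its own category, which
is how such results tables are conventionally printed.

Comparisons are made on the per-kg basis. The fold ratio is basis-invariant
— predicted and observed scale by the same child weight — so this is a
convention, not a modelling choice; the invariance is asserted in the tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .dose_rules import PredictionDose, cl_based_dose, salisbury_dose, to_per_kg
from .types import (
    AdultReference,
    Basis,
    BasisMismatchError,
    DoseSpec,
    DrugClass,
    InvalidInputError,
    MissingFieldError,
    ObservationRow,
    ReferenceType,
    WeightStratum,
)

__all__ = [
    "CategoryFlags",
    "PredictionResult",
    "SummaryTable",
    "WIDE_BOUNDS",
    "NARROW_BOUNDS",
    "percent_error",
    "fold_error",
    "classify",
    "evaluate_observation",
    "evaluate_cohort",
    "summarize",
    "round_half_away",
]

#: Closed fold-error interval of the lenient accuracy band.
WIDE_BOUNDS = (0.5, 1.5)
#: Closed fold-error interval of the ±30% accuracy band.
NARROW_BOUNDS = (0.7, 1.3)

_CATEGORIES = ("wide", "narrow", "over", "under")

#: Row labels used when rendering a summary the way such tables are printed.
CATEGORY_LABELS = {
    "wide": "0.5–1.5-fold",
    "narrow": "≤30% (≥0.7–≤1.3)",
    "over": "≥130% (>1.3-fold)",
    "under": "≤70% (≤0.7-fold)",
}


def round_half_away(value: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention of printed dose tables).

    Python's built-in ``round`` is banker's rounding; printed percent
    columns such as "87.1" use ordinary half-away-from-zero.
    """
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


DoseLike = Union[float, int, DoseSpec]


def _amount(dose: DoseLike, other: DoseLike, name: str) -> float:
    if isinstance(dose, DoseSpec):
        if isinstance(other, DoseSpec):
            if dose.basis is not other.basis:
                raise BasisMismatchError(
                    f"cannot compare doses on different bases: "
                    f"{dose.basis.value} vs {other.basis.value}"
                )
            if dose.unit != other.unit:
                raise BasisMismatchError(
                    f"cannot compare doses in different units: "
                    f"{dose.unit!r} vs {other.unit!r}"
                )
        return dose.amount
    if not math.isfinite(dose):
        raise InvalidInputError(f"{name} dose must be finite, got {dose!r}")
    return float(dose)


def percent_error(predicted: DoseLike, observed: DoseLike) -> float:
    """Percent prediction error, (predicted − observed)/observed × 100.

    Positive values are over-predictions. Both arguments may be bare
    amounts or :class:`DoseSpec` objects; two specs must share basis and
    unit.
    """
    pred = _amount(predicted, observed, "predicted")
    obs = _amount(observed, predicted, "observed")
    if obs <= 0:
        raise InvalidInputError(f"observed dose must be positive, got {obs!r}")
    return (pred - obs) / obs * 100.0


def fold_error(predicted: DoseLike, observed: DoseLike) -> float:
    """Fold (ratio) prediction error, predicted/observed."""
    pred = _amount(predicted, observed, "predicted")
    obs = _amount(observed, predicted, "observed")
    if obs <= 0:
        raise InvalidInputError(f"observed dose must be positive, got {obs!r}")
    return pred / obs


@dataclass(frozen=True)
class CategoryFlags:
    """Accuracy-category membership of one fold error."""

    within_wide: bool
    within_narrow: bool
    over: bool
    under: bool


def classify(fold: float) -> CategoryFlags:
    """Bin a fold error into the accuracy categories.

    Narrow is the closed interval [0.7, 1.3]; over/under are the strict
    complements, so exactly one of narrow/over/under holds. Wide is the
    closed interval [0.5, 1.5] and overlaps the others.
    """
    if not math.isfinite(fold) or fold <= 0:
        raise InvalidInputError(f"fold error must be positive and finite, got {fold!r}")
    return CategoryFlags(
        within_wide=WIDE_BOUNDS[0] <= fold <= WIDE_BOUNDS[1],
        within_narrow=NARROW_BOUNDS[0] <= fold <= NARROW_BOUNDS[1],
        over=fold > NARROW_BOUNDS[1],
        under=fold < NARROW_BOUNDS[0],
    )


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of evaluating one observation against the Salisbury prediction."""

    drug_id: str
    drug_class: DrugClass
    weight_kg: float
    weight_stratum: WeightStratum
    reference_type: ReferenceType
    predicted: PredictionDose
    observed_per_kg: float
    percent_error: float
    fold_error: float
    flags: CategoryFlags


def _observed_per_kg(row: ObservationRow, adult: AdultReference) -> float:
    """Observed comparator dose on the per-kg basis, per the row's provenance.

    For clearance-based rows the comparator is recomputed from the adult
    dose and the clearance ratio: with absolute clearances the ratio is
    applied to the absolute adult dose, with per-kg clearances to the adult
    per-kg dose. Otherwise the recorded observed dose is used as-is.
    """
    weight = row.subject.weight_kg
    if row.reference_type is ReferenceType.CL_BASED:
        if row.child_clearance is None:
            raise MissingFieldError(
                f"row for drug {row.drug_id!r}: clearance-based reference "
                "requires a child clearance"
            )
        if adult.clearance is None:
            raise MissingFieldError(
                f"row for drug {row.drug_id!r}: clearance-based reference "
                "requires an adult clearance on the adult reference"
            )
        if row.child_clearance.basis is Basis.ABSOLUTE:
            from .dose_rules import to_absolute

            adult_dose = DoseSpec(
                to_absolute(adult.dose, adult.weight_kg), Basis.ABSOLUTE, adult.dose.unit
            )
        else:
            adult_dose = DoseSpec(
                to_per_kg(adult.dose, adult.weight_kg), Basis.PER_KG, adult.dose.unit
            )
        observed = cl_based_dose(adult_dose, row.child_clearance, adult.clearance)
        return to_per_kg(observed, weight)
    return to_per_kg(row.observed_dose, weight)


def evaluate_observation(row: ObservationRow, adult: AdultReference) -> PredictionResult:
    """Evaluate one pediatric observation against the Salisbury prediction.

    The predicted dose is the Salisbury-rule dose from the adult reference;
    the observed comparator depends on the row's reference type (recorded
    dose, or clearance-ratio dose). Errors are computed on per-kg doses.
    """
    predicted = salisbury_dose(adult, row.subject.weight_kg)
    observed_pk = _observed_per_kg(row, adult)
    pct = percent_error(predicted.per_kg, observed_pk)
    fold = fold_error(predicted.per_kg, observed_pk)
    return PredictionResult(
        drug_id=row.drug_id,
        drug_class=row.drug_class,
        weight_kg=row.subject.weight_kg,
        weight_stratum=row.weight_stratum,
        reference_type=row.reference_type,
        predicted=predicted,
        observed_per_kg=observed_pk,
        percent_error=pct,
        fold_error=fold,
        flags=classify(fold),
    )


def evaluate_cohort(
    pairs: Iterable[tuple[AdultReference, ObservationRow]]
) -> list[PredictionResult]:
    """Evaluate every (adult reference, observation) pair of a cohort."""
    return [evaluate_observation(row, adult) for adult, row in pairs]


@dataclass
class SummaryTable:
    """Accuracy-category counts and percents per (class, stratum, reference) row.

    ``data`` has one row per stratum with columns ``n`` plus
    ``{wide,narrow,over,under}_{count,pct}``; percents are rounded to one
    decimal, half away from zero. Strata known to the table but without
    observations keep ``n = 0`` and NA percents, mirroring how such tables
    print "NA" for unavailable strata. ``is_empty`` marks the zero-row
    table produced from an empty result collection.
    """

    data: pd.DataFrame
    is_empty: bool = False

    def to_csv(self, path_or_buf=None, **kwargs):
        return self.data.to_csv(path_or_buf, index=False, **kwargs)

    def to_markdown(self) -> str:
        """Render with the conventional printed row labels."""
        lines = [
            "| Drug class | Stratum | Reference | n | "
            + " | ".join(CATEGORY_LABELS[c] for c in _CATEGORIES)
            + " |",
            "|" + "---|" * (4 + len(_CATEGORIES)),
        ]
        for _, row in self.data.iterrows():
            cells = [str(row["drug_class"]), str(row["stratum"]), str(row["reference_type"]), str(int(row["n"]))]
            for cat in _CATEGORIES:
                if row["n"] == 0:
                    cells.append("NA")
                else:
                    cells.append(f"{int(row[f'{cat}_count'])} ({row[f'{cat}_pct']:.1f}%)")
            lines.append("| " + " | ".join(cells) + " |")
        return "\n".join(lines)


_SUMMARY_COLUMNS = [
    "drug_class",
    "stratum",
    "reference_type",
    "n",
    *(f"{cat}_{kind}" for cat in _CATEGORIES for kind in ("count", "pct")),
]


def summarize(results: Sequence[PredictionResult]) -> SummaryTable:
    """Stratify results by (drug class, weight stratum, reference type).

    Weight strata: neonates (by age class) are their own stratum; other
    children split at 30 kg. For each stratum row, counts and one-decimal
    percents of the four accuracy categories are reported. Narrow, over and
    under always sum to n; wide overlaps them.

    An empty input yields a zero-row table flagged ``is_empty`` rather than
    an exception.
    """
    if not results:
        return SummaryTable(pd.DataFrame(columns=_SUMMARY_COLUMNS), is_empty=True)

    rows = []
    keys = sorted(
        {(r.drug_class, r.weight_stratum, r.reference_type) for r in results},
        key=lambda k: (k[0].value, k[1].value, k[2].value),
    )
    # For every drug class present, also emit its empty strata so the table
    # shows NA rather than silently dropping them.
    classes = {k[0] for k in keys}
    reference_types = {k[2] for k in keys}
    full_grid = [
        (cls, stratum, ref)
        for cls in sorted(classes, key=lambda c: c.value)
        for stratum in (WeightStratum.NEONATE, WeightStratum.LT30, WeightStratum.GE30)
        for ref in sorted(reference_types, key=lambda r: r.value)
    ]
    for cls, stratum, ref in full_grid:
        members = [
            r
            for r in results
            if r.drug_class is cls
            and r.weight_stratum is stratum
            and r.reference_type is ref
        ]
        n = len(members)
        row: dict = {
            "drug_class": cls.value,
            "stratum": stratum.value,
            "reference_type": ref.value,
            "n": n,
        }
        counts = {
            "wide": sum(r.flags.within_wide for r in members),
            "narrow": sum(r.flags.within_narrow for r in members),
            "over": sum(r.flags.over for r in members),
            "under": sum(r.flags.under for r in members),
        }
        for cat in _CATEGORIES:
            row[f"{cat}_count"] = counts[cat]
            row[f"{cat}_pct"] = (
                round_half_away(100.0 * counts[cat] / n, 1) if n else float("nan")
            )
        rows.append(row)
    return SummaryTable(pd.DataFrame(rows, columns=_SUMMARY_COLUMNS))
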