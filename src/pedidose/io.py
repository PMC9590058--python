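"""Reading and writing cohort and result tables.

Cohorts are exchanged as UTF-8 comma-separated text with a mandatory header.
Dose and clearance values embed their unit in the value string — "400 mg/kg",
"28000 mg", "2.5 mL/h/kg" — and the per-kg/absolute basis is parsed from the
unit (a trailing "/kg"), never guessed from magnitude. The schema mirrors the
per-observation appendix tables of pediatric dosing studies, so transcribed
published data can be fed straight in:

``drug, drug_class, age_class, weight_kg, adult_dose, adult_weight_kg,
adult_clearance, observed_dose, child_clearance, reference_type``

``adult_clearance`` and ``child_clearance`` may be empty except for
clearance-based rows. Malformed rows are collected with their line numbers
rather than aborting the read.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence, Union

import pandas as pd

from .dose_rules import PredictionDose
from .evaluation import PredictionResult, classify
from .types import (
    AdultReference,
    AgeClass,
    Basis,
    ClearanceSpec,
    DoseSpec,
    DrugClass,
    ObservationRow,
    ReferenceType,
    SchemaError,
    Subject,
    UnitParseError,
    WeightStratum,
)

__all__ = [
    "COHORT_COLUMNS",
    "MalformedRow",
    "CohortReadResult",
    "parse_dose",
    "parse_clearance",
    "format_dose",
    "format_clearance",
    "read_cohort",
    "write_cohort",
    "results_to_frame",
    "write_results",
    "read_results",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "drug",
    "drug_class",
    "age_class",
    "weight_kg",
    "adult_dose",
    "adult_weight_kg",
    "adult_clearance",
    "observed_dose",
    "child_clearance",
    "reference_type",
]
_MANDATORY = [c for c in COHORT_COLUMNS if c not in ("adult_clearance", "child_clearance")]

_DOSE_UNIT_RE = re.compile(r"^(?P<unit>mcg|ug|µg|mg|g|IU|U)(?P<perkg>/kg)?$")
_CL_UNIT_RE = re.compile(r"^(?P<unit>(?:mL|L)/(?:h|hr|min|day))(?P<perkg>/kg)?$")
_VALUE_RE = re.compile(r"^\s*(?P<value>[-+0-9.eE]+)\s+(?P<unit>\S+)\s*$")


def _split(text: str, kind: str) -> tuple[float, str]:
    match = _VALUE_RE.match(text)
    if not match:
        raise UnitParseError(f"cannot parse {kind} value {text!r}: expected '<number> <unit>'")
    try:
        value = float(match.group("value"))
    except ValueError as exc:
        raise UnitParseError(f"cannot parse {kind} number in {text!r}") from exc
    return value, match.group("unit")


def parse_dose(text: str) -> DoseSpec:
    """Parse a dose string like "400 mg/kg" or "28000 mg"."""
    value, unit = _split(text, "dose")
    match = _DOSE_UNIT_RE.match(unit)
    if not match:
        raise UnitParseError(f"unknown dose unit {unit!r} in {text!r}")
    basis = Basis.PER_KG if match.group("perkg") else Basis.ABSOLUTE
    return DoseSpec(value, basis, match.group("unit"))


def parse_clearance(text: str) -> ClearanceSpec:
    """Parse a clearance string like "2.5 mL/h/kg" or "140 mL/h"."""
    value, unit = _split(text, "clearance")
    match = _CL_UNIT_RE.match(unit)
    if not match:
        raise UnitParseError(f"unknown clearance unit {unit!r} in {text!r}")
    basis = Basis.PER_KG if match.group("perkg") else Basis.ABSOLUTE
    return ClearanceSpec(value, basis, match.group("unit"))


def format_dose(dose: DoseSpec) -> str:
    suffix = "/kg" if dose.basis is Basis.PER_KG else ""
    return f"{dose.amount!r} {dose.unit}{suffix}"


def format_clearance(cl: ClearanceSpec) -> str:
    suffix = "/kg" if cl.basis is Basis.PER_KG else ""
    return f"{cl.value!r} {cl.unit}{suffix}"


@dataclass(frozen=True)
class MalformedRow:
    """A rejected input row: its line number, raw content and the reason."""

    line_number: int
    message: str
    raw: dict


@dataclass
class CohortReadResult:
    """Typed rows plus the malformed rows that were set aside."""

    pairs: list[tuple[AdultReference, ObservationRow]] = field(default_factory=list)
    malformed: list[MalformedRow] = field(default_factory=list)

    def __iter__(self) -> Iterator[tuple[AdultReference, ObservationRow]]:
        return iter(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


def _parse_row(raw: dict) -> tuple[AdultReference, ObservationRow]:
    adult_cl = (
        parse_clearance(raw["adult_clearance"])
        if raw.get("adult_clearance", "").strip()
        else None
    )
    child_cl = (
        parse_clearance(raw["child_clearance"])
        if raw.get("child_clearance", "").strip()
        else None
    )
    adult = AdultReference(
        dose=parse_dose(raw["adult_dose"]),
        weight_kg=float(raw["adult_weight_kg"]),
        clearance=adult_cl,
    )
    row = ObservationRow(
        drug_id=raw["drug"].strip(),
        drug_class=DrugClass(raw["drug_class"].strip()),
        subject=Subject(float(raw["weight_kg"]), AgeClass(raw["age_class"].strip())),
        observed_dose=parse_dose(raw["observed_dose"]),
        reference_type=ReferenceType(raw["reference_type"].strip()),
        child_clearance=child_cl,
    )
    return adult, row


def read_cohort(path: Union[str, Path]) -> CohortReadResult:
    """Read a cohort CSV into typed (adult reference, observation) pairs.

    Raises :class:`SchemaError` if mandatory columns are missing. Rows that
    fail parsing or validation are collected in ``malformed`` with their
    file line numbers; they never abort the read.
    """
    path = Path(path)
    result = CohortReadResult()
    with path.open(newline="", encoding="utf-8") as handle:
        reader = csv.DictReader(handle)
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, expected a header row")
        missing = [c for c in _MANDATORY if c not in reader.fieldnames]
        if missing:
            raise SchemaError(f"{path}: missing mandatory columns {missing}")
        for raw in reader:
            try:
                result.pairs.append(_parse_row(raw))
            except (KeyError, ValueError) as exc:
                result.malformed.append(
                    MalformedRow(reader.line_num, str(exc), dict(raw))
                )
    if not result.pairs and not result.malformed:
        logger.warning("%s: header only, no observations", path)
    if result.malformed:
        for bad in result.malformed:
            logger.warning("%s line %d: %s", path, bad.line_number, bad.message)
    return result


def write_cohort(
    pairs: Sequence[tuple[AdultReference, ObservationRow]], path: Union[str, Path]
) -> None:
    """Write (adult reference, observation) pairs to a cohort CSV.

    Floats are written with full ``repr`` precision, so a write/read
    round-trip reproduces an equal in-memory collection.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as handle:
        writer = csv.DictWriter(handle, fieldnames=COHORT_COLUMNS)
        writer.writeheader()
        for adult, row in pairs:
            writer.writerow(
                {
                    "drug": row.drug_id,
                    "drug_class": row.drug_class.value,
                    "age_class": row.subject.age_class.value,
                    "weight_kg": repr(row.subject.weight_kg),
                    "adult_dose": format_dose(adult.dose),
                    "adult_weight_kg": repr(adult.weight_kg),
                    "adult_clearance": (
                        format_clearance(adult.clearance) if adult.clearance else ""
                    ),
                    "observed_dose": format_dose(row.observed_dose),
                    "child_clearance": (
                        format_clearance(row.child_clearance)
                        if row.child_clearance
                        else ""
                    ),
                    "reference_type": row.reference_type.value,
                }
            )


def results_to_frame(results: Sequence[PredictionResult]) -> pd.DataFrame:
    """Per-observation results as a DataFrame (one row per observation)."""
    return pd.DataFrame(
        {
            "drug": [r.drug_id for r in results],
            "drug_class": [r.drug_class.value for r in results],
            "weight_kg": [r.weight_kg for r in results],
            "stratum": [r.weight_stratum.value for r in results],
            "reference_type": [r.reference_type.value for r in results],
            "predicted_absolute": [r.predicted.absolute for r in results],
            "predicted_per_kg": [r.predicted.per_kg for r in results],
            "observed_per_kg": [r.observed_per_kg for r in results],
            "percent_error": [r.percent_error for r in results],
            "fold_error": [r.fold_error for r in results],
            "within_wide": [r.flags.within_wide for r in results],
            "within_narrow": [r.flags.within_narrow for r in results],
            "over": [r.flags.over for r in results],
            "under": [r.flags.under for r in results],
        }
    )


def write_results(
    results: Sequence[PredictionResult], path: Union[str, Path]
) -> None:
    results_to_frame(results).to_csv(path, index=False)


def read_results(path: Union[str, Path]) -> list[PredictionResult]:
    """Read a per-observation results CSV back into result objects.

    Category flags are recomputed from the fold error, so a hand-edited
    table cannot carry inconsistent flags.
    """
    frame = pd.read_csv(path)
    required = {"drug", "drug_class", "weight_kg", "stratum", "reference_type",
                "predicted_absolute", "predicted_per_kg", "observed_per_kg",
                "percent_error", "fold_error"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing result columns {sorted(missing)}")
    results = []
    for rec in frame.to_dict("records"):
        fold = float(rec["fold_error"])
        results.append(
            PredictionResult(
                drug_id=str(rec["drug"]),
                drug_class=DrugClass(rec["drug_class"]),
                weight_kg=float(rec["weight_kg"]),
                weight_stratum=WeightStratum(rec["stratum"]),
                reference_type=ReferenceType(rec["reference_type"]),
                predicted=PredictionDose(
                    absolute=float(rec["predicted_absolute"]),
                    per_kg=float(rec["predicted_per_kg"]),
                ),
                observed_per_kg=float(rec["observed_per_kg"]),
                percent_error=float(rec["percent_error"]),
                fold_error=fold,
                flags=classify(fold),
            )
        )
    return results
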