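"""Synthetic drug cohorts with the structure of published pediatric dosing data.

Per-observation pediatric dosing data for therapeutic proteins live in
appendices and package inserts, not in reusable tables, so the pipeline is
exercised on generated cohorts that emulate their structure: a handful of
drugs per class (monoclonal antibody, polyclonal antibody, non-antibody
protein), each with an adult mg/kg regimen and adult clearance, observed in
children whose weights fall in a neonatal stratum (1–3 kg), a below-30-kg
stratum (4.5–30 kg) or an at-or-above-30-kg stratum (30–60 kg).

Pediatric clearance scales allometrically, CL_child = CL_adult × (W/70)^b
with b = 0.75 by default and log-normal noise, which makes per-kg clearance
— and hence per-kg dose requirement — higher in smaller children, the
physiological premise behind weight-nonlinear dosing rules. Observed doses
follow one of three policies: the adult per-kg dose extrapolated unchanged
(label practice), the clearance-ratio dose, or an investigator-selected
per-kg grid (the neonatal polyclonal situation, doses 250–1000 mg/kg).
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .dose_rules import cl_based_dose, to_absolute
from .types import (
    AdultReference,
    AgeClass,
    Basis,
    ClearanceSpec,
    DoseSpec,
    DrugClass,
    ObservationRow,
    ReferenceType,
    Subject,
    WeightStratum,
)

__all__ = ["SyntheticConfig", "generate_cohort", "table1_scenario"]

Cohort = list[tuple[AdultReference, ObservationRow]]


class SyntheticConfig(BaseModel):
    """Configuration of the synthetic cohort generator.

    Defaults mirror the published cohort structure: 21 monoclonal, 5
    polyclonal and 11 non-antibody drugs; neonates 1–3 kg; children 4.5–60
    kg split at 30 kg; allometric clearance exponent 0.75 with 15% CV
    log-normal noise; adult reference weight 70 kg.
    """

    model_config = ConfigDict(frozen=True)

    n_monoclonal: int = Field(default=21, ge=0)
    n_polyclonal: int = Field(default=5, ge=0)
    n_non_antibody: int = Field(default=11, ge=0)
    obs_per_drug: int = Field(default=3, ge=1)

    neonate_weight_range: tuple[float, float] = (1.0, 3.0)
    lt30_weight_range: tuple[float, float] = (4.5, 30.0)
    ge30_weight_range: tuple[float, float] = (30.0, 60.0)
    adult_weight_kg: float = Field(default=70.0, gt=0)

    #: Adult per-kg doses are drawn log-uniformly from this range (mg/kg),
    #: spanning low-dose monoclonals to high-dose immunoglobulins.
    adult_perkg_dose_range: tuple[float, float] = (1.0, 500.0)
    #: Adult per-kg clearances drawn log-uniformly from this range (mL/h/kg).
    adult_perkg_cl_range: tuple[float, float] = (0.1, 10.0)

    allometric_exponent: float = Field(default=0.75, gt=0, le=1.25)
    clearance_cv: float = Field(default=0.15, ge=0)

    #: Sampling weights of the dosing policies for non-neonatal rows;
    #: neonates always get investigator-selected doses.
    policy_mix: dict[ReferenceType, float] = {
        ReferenceType.PER_KG_LABEL: 0.5,
        ReferenceType.CL_BASED: 0.3,
        ReferenceType.INVESTIGATOR_SELECTED: 0.2,
    }
    #: Per-kg dose grid (mg/kg) for investigator-selected neonatal polyclonals.
    investigator_dose_grid: tuple[float, ...] = (250.0, 500.0, 750.0, 1000.0)
    #: Fraction of polyclonal observations placed in the neonatal stratum.
    neonate_fraction_polyclonal: float = Field(default=0.4, ge=0, le=1)
    #: Fraction of non-neonatal observations in the below-30-kg stratum.
    lt30_fraction: float = Field(default=0.5, ge=0, le=1)

    seed: int = 0

    @model_validator(mode="after")
    def _check_ranges(self) -> "SyntheticConfig":
        problems = []
        for name in ("neonate_weight_range", "lt30_weight_range", "ge30_weight_range",
                     "adult_perkg_dose_range", "adult_perkg_cl_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                problems.append(f"{name} must satisfy 0 < low < high, got ({lo}, {hi})")
        if self.neonate_weight_range[1] > self.lt30_weight_range[0]:
            problems.append("neonate and lt30 weight ranges overlap")
        if self.lt30_weight_range[1] > self.ge30_weight_range[0]:
            problems.append("lt30 and ge30 weight ranges overlap")
        if self.lt30_weight_range[1] > 30 or self.ge30_weight_range[0] < 30:
            problems.append("lt30/ge30 ranges must split at 30 kg")
        if not self.policy_mix or any(v < 0 for v in self.policy_mix.values()):
            problems.append("policy_mix weights must be non-negative and non-empty")
        elif math.isclose(sum(self.policy_mix.values()), 0):
            problems.append("policy_mix weights must not all be zero")
        if not self.investigator_dose_grid or any(
            d <= 0 for d in self.investigator_dose_grid
        ):
            problems.append("investigator_dose_grid must contain positive doses")
        if problems:
            raise ValueError("; ".join(problems))
        return self


def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal: sigma^2 = ln(1 + CV^2)
    return math.sqrt(math.log1p(cv * cv))


def _child_clearance_abs(
    adult_cl_abs: float,
    weight_kg: float,
    adult_weight_kg: float,
    exponent: float,
    cv: float,
    rng: np.random.Generator,
) -> float:
    noise = 1.0 if cv == 0 else float(rng.lognormal(0.0, _lognormal_sigma(cv)))
    return adult_cl_abs * (weight_kg / adult_weight_kg) ** exponent * noise


def _draw_subject(
    stratum: WeightStratum, config: SyntheticConfig, rng: np.random.Generator
) -> Subject:
    if stratum is WeightStratum.NEONATE:
        lo, hi = config.neonate_weight_range
        age = AgeClass.PRETERM_NEONATE if rng.random() < 0.5 else AgeClass.TERM_NEONATE
        return Subject(float(rng.uniform(lo, hi)), age)
    lo, hi = (
        config.lt30_weight_range
        if stratum is WeightStratum.LT30
        else config.ge30_weight_range
    )
    return Subject(float(rng.uniform(lo, hi)), AgeClass.CHILD)


def _make_row(
    drug_id: str,
    drug_class: DrugClass,
    adult: AdultReference,
    subject: Subject,
    policy: ReferenceType,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> ObservationRow:
    cl_child = ClearanceSpec(
        _child_clearance_abs(
            adult.clearance.value,
            subject.weight_kg,
            config.adult_weight_kg,
            config.allometric_exponent,
            config.clearance_cv,
            rng,
        ),
        Basis.ABSOLUTE,
        adult.clearance.unit,
    )
    if policy is ReferenceType.PER_KG_LABEL:
        observed = DoseSpec(adult.dose.amount, Basis.PER_KG, adult.dose.unit)
    elif policy is ReferenceType.CL_BASED:
        adult_abs = DoseSpec(
            to_absolute(adult.dose, config.adult_weight_kg),
            Basis.ABSOLUTE,
            adult.dose.unit,
        )
        observed = cl_based_dose(adult_abs, cl_child, adult.clearance)
    else:  # investigator-selected per-kg grid
        observed = DoseSpec(
            float(rng.choice(config.investigator_dose_grid)),
            Basis.PER_KG,
            adult.dose.unit,
        )
    return ObservationRow(
        drug_id=drug_id,
        drug_class=drug_class,
        subject=subject,
        observed_dose=observed,
        reference_type=policy,
        child_clearance=cl_child,
    )


def generate_cohort(config: SyntheticConfig) -> Cohort:
    """Generate a deterministic cohort of (adult reference, observation) pairs.

    One adult reference (per-kg dose, 70 kg weight, absolute clearance) is
    drawn per drug and shared across that drug's observations. Pediatric
    absolute clearance is the adult clearance scaled by (W/70)^b with
    log-normal noise; observed doses follow the configured policy mix, with
    neonatal rows always investigator-selected.
    """
    rng = np.random.default_rng(config.seed)
    policies = list(config.policy_mix)
    weights = np.array([config.policy_mix[p] for p in policies], dtype=float)
    weights /= weights.sum()

    cohort: Cohort = []
    class_counts = (
        (DrugClass.MONOCLONAL, config.n_monoclonal),
        (DrugClass.POLYCLONAL, config.n_polyclonal),
        (DrugClass.NON_ANTIBODY, config.n_non_antibody),
    )
    for drug_class, n_drugs in class_counts:
        for i in range(n_drugs):
            drug_id = f"{drug_class.value}-{i + 1}"
            lo, hi = config.adult_perkg_dose_range
            dose_pk = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            lo, hi = config.adult_perkg_cl_range
            cl_pk = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            adult = AdultReference(
                dose=DoseSpec(dose_pk, Basis.PER_KG, "mg"),
                weight_kg=config.adult_weight_kg,
                clearance=ClearanceSpec(
                    cl_pk * config.adult_weight_kg, Basis.ABSOLUTE, "mL/h"
                ),
            )
            for _ in range(config.obs_per_drug):
                if (
                    drug_class is DrugClass.POLYCLONAL
                    and rng.random() < config.neonate_fraction_polyclonal
                ):
                    stratum = WeightStratum.NEONATE
                    policy = ReferenceType.INVESTIGATOR_SELECTED
                else:
                    stratum = (
                        WeightStratum.LT30
                        if rng.random() < config.lt30_fraction
                        else WeightStratum.GE30
                    )
                    policy = policies[int(rng.choice(len(policies), p=weights))]
                subject = _draw_subject(stratum, config, rng)
                cohort.append(
                    (adult, _make_row(drug_id, drug_class, adult, subject, policy, config, rng))
                )
    return cohort


#: (class, stratum) -> (weight range, policy, adult per-kg dose in mg/kg).
#: Weight ranges follow the published cohort descriptions; adult doses are
#: typical for the class (hundreds of mg/kg for pooled immunoglobulins,
#: ~10 mg/kg for monoclonals, ~1 mg/kg for non-antibody proteins).
_SCENARIOS: dict[
    tuple[DrugClass, WeightStratum],
    tuple[tuple[float, float], ReferenceType, float],
] = {
    (DrugClass.POLYCLONAL, WeightStratum.LT30): (
        (15.0, 30.0),
        ReferenceType.PER_KG_LABEL,
        400.0,
    ),
    (DrugClass.POLYCLONAL, WeightStratum.GE30): (
        (30.0, 50.0),
        ReferenceType.PER_KG_LABEL,
        400.0,
    ),
    (DrugClass.POLYCLONAL, WeightStratum.NEONATE): (
        (1.0, 3.0),
        ReferenceType.INVESTIGATOR_SELECTED,
        400.0,
    ),
    (DrugClass.MONOCLONAL, WeightStratum.LT30): (
        (4.5, 30.0),
        ReferenceType.PER_KG_LABEL,
        10.0,
    ),
    (DrugClass.MONOCLONAL, WeightStratum.GE30): (
        (30.0, 60.0),
        ReferenceType.PER_KG_LABEL,
        10.0,
    ),
    (DrugClass.NON_ANTIBODY, WeightStratum.LT30): (
        (4.0, 30.0),
        ReferenceType.PER_KG_LABEL,
        1.0,
    ),
    (DrugClass.NON_ANTIBODY, WeightStratum.GE30): (
        (30.0, 60.0),
        ReferenceType.PER_KG_LABEL,
        1.0,
    ),
}


def table1_scenario(
    drug_class: DrugClass,
    stratum: WeightStratum,
    n: int,
    *,
    seed: int = 0,
    config: Optional[SyntheticConfig] = None,
) -> Cohort:
    """A preset cohort reproducing one published stratum scenario.

    For example, the polyclonal below-30-kg stratum is nine observations at
    weights uniform in [15, 30) kg whose observed dose is the adult per-kg
    dose extrapolated unchanged. Neonatal strata exist only for polyclonal
    antibodies (investigator-selected doses from the 250–1000 mg/kg grid);
    other neonatal combinations raise ``NotImplementedError``.
    """
    drug_class = DrugClass(drug_class)
    stratum = WeightStratum(stratum)
    key = (drug_class, stratum)
    if key not in _SCENARIOS:
        raise NotImplementedError(
            f"no scenario for ({drug_class.value}, {stratum.value})"
        )
    if n < 1:
        raise ValueError(f"n must be at least 1, got {n}")
    config = config or SyntheticConfig(seed=seed)
    (lo, hi), policy, adult_perkg = _SCENARIOS[key]
    rng = np.random.default_rng(seed)
    adult = AdultReference(
        dose=DoseSpec(adult_perkg, Basis.PER_KG, "mg"),
        weight_kg=config.adult_weight_kg,
        clearance=ClearanceSpec(
            2.0 * config.adult_weight_kg, Basis.ABSOLUTE, "mL/h"
        ),
    )
    cohort: Cohort = []
    for i in range(n):
        if stratum is WeightStratum.NEONATE:
            age = AgeClass.PRETERM_NEONATE if rng.random() < 2 / 3 else AgeClass.TERM_NEONATE
            subject = Subject(float(rng.uniform(lo, hi)), age)
        else:
            subject = Subject(float(rng.uniform(lo, hi)), AgeClass.CHILD)
        cohort.append(
            (
                adult,
                _make_row(
                    f"{drug_class.value}-scenario-{i + 1}",
                    drug_class,
                    adult,
                    subject,
                    policy,
                    config,
                    rng,
                ),
            )
        )
    return cohort
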