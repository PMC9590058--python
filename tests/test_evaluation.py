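"""Percent/fold error arithmetic, accuracy-category binning, and the
stratified summary table, checked against brute-force recount oracles."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from pedidose import (
    AdultReference,
    AgeClass,
    Basis,
    BasisMismatchError,
    ClearanceSpec,
    DoseSpec,
    DrugClass,
    InvalidInputError,
    MissingFieldError,
    ObservationRow,
    ReferenceType,
    Subject,
    WeightStratum,
    classify,
    evaluate_cohort,
    evaluate_observation,
    fold_error,
    percent_error,
    summarize,
)
from pedidose.dose_rules import PredictionDose
from pedidose.evaluation import PredictionResult, round_half_away
from pedidose.synthetic import SyntheticConfig, generate_cohort


def make_result(fold, drug_class=DrugClass.MONOCLONAL, stratum=WeightStratum.LT30,
                reference=ReferenceType.PER_KG_LABEL):
    """Minimal result with a given fold error, for summarizer tests."""
    weight = 10.0 if stratum is WeightStratum.LT30 else 40.0
    observed = 100.0
    return PredictionResult(
        drug_id="x",
        drug_class=drug_class,
        weight_kg=weight,
        weight_stratum=stratum,
        reference_type=reference,
        predicted=PredictionDose(absolute=fold * observed * weight, per_kg=fold * observed),
        observed_per_kg=observed,
        percent_error=(fold - 1) * 100,
        fold_error=fold,
        flags=classify(fold),
    )


class TestErrorMetrics:
    @pytest.mark.parametrize(
        "predicted, observed, pct, fold",
        [
            (560, 250, 124.0, 2.24),
            (100, 100, 0.0, 1.0),
            (70, 100, -30.0, 0.7),
            (130, 100, 30.0, 1.3),
        ],
    )
    def test_examples(self, predicted, observed, pct, fold):
        assert percent_error(predicted, observed) == pytest.approx(pct)
        assert fold_error(predicted, observed) == pytest.approx(fold)

    @given(predicted=st.floats(0.1, 1e4), observed=st.floats(0.1, 1e4))
    def test_fold_is_one_plus_percent_over_hundred(self, predicted, observed):
        assert fold_error(predicted, observed) == pytest.approx(
            1 + percent_error(predicted, observed) / 100, rel=1e-9
        )

    def test_dose_spec_basis_mismatch_rejected(self):
        with pytest.raises(BasisMismatchError):
            percent_error(DoseSpec(5, Basis.PER_KG), DoseSpec(5, Basis.ABSOLUTE))
        with pytest.raises(BasisMismatchError):
            fold_error(DoseSpec(5, Basis.PER_KG, "mg"), DoseSpec(5, Basis.PER_KG, "g"))

    def test_nonpositive_observed_rejected(self):
        with pytest.raises(InvalidInputError):
            percent_error(10, 0)


class TestClassify:
    @pytest.mark.parametrize(
        "fold, wide, narrow, over, under",
        [
            (1.4, True, False, True, False),
            (1.0, True, True, False, False),
            (0.7, True, True, False, False),  # boundary inclusive to narrow
            (1.3, True, True, False, False),
            (0.5, True, False, False, True),
            (1.5, True, False, True, False),
            (0.4, False, False, False, True),
            (2.0, False, False, True, False),
        ],
    )
    def test_boundaries(self, fold, wide, narrow, over, under):
        flags = classify(fold)
        assert (flags.within_wide, flags.within_narrow, flags.over, flags.under) == (
            wide, narrow, over, under
        )

    def test_partition_and_nesting_against_brute_force(self):
        # 10,000 random folds: narrow/over/under partition, wide ⊇ narrow
        rng = np.random.default_rng(20220)
        folds = rng.lognormal(0.0, 0.5, size=10_000)
        flags = [classify(f) for f in folds]
        for fl in flags:
            assert fl.within_narrow + fl.over + fl.under == 1
            if fl.within_narrow:
                assert fl.within_wide
        # brute-force recount oracle
        assert sum(fl.within_narrow for fl in flags) == int(
            np.sum((folds >= 0.7) & (folds <= 1.3))
        )
        assert sum(fl.within_wide for fl in flags) == int(
            np.sum((folds >= 0.5) & (folds <= 1.5))
        )
        assert sum(fl.over for fl in flags) == int(np.sum(folds > 1.3))
        assert sum(fl.under for fl in flags) == int(np.sum(folds < 0.7))
        assert sum(fl.within_wide for fl in flags) >= sum(
            fl.within_narrow for fl in flags
        )

    def test_rejects_nonpositive_fold(self):
        with pytest.raises(InvalidInputError):
            classify(0.0)


class TestEvaluateObservation:
    def _perkg_row(self, weight, dose=400.0, **kwargs):
        return ObservationRow(
            drug_id="ivig",
            drug_class=DrugClass.POLYCLONAL,
            subject=Subject(weight, kwargs.pop("age_class", AgeClass.CHILD)),
            observed_dose=DoseSpec(dose, Basis.PER_KG),
            reference_type=ReferenceType.PER_KG_LABEL,
            **kwargs,
        )

    def test_perkg_extrapolated_under_30_gives_40_percent(self, adult_ivig):
        result = evaluate_observation(self._perkg_row(20.0), adult_ivig)
        assert result.percent_error == pytest.approx(40.0)
        assert result.flags.over and result.flags.within_wide

    def test_narrow_boundary_at_35_kg(self, adult_ivig):
        # (65/100)*(70/35) = 1.3 exactly
        result = evaluate_observation(self._perkg_row(35.0), adult_ivig)
        assert result.percent_error == pytest.approx(30.0)
        assert result.fold_error == pytest.approx(1.3)
        assert result.flags.within_narrow

    def test_zero_error_at_reference_weight(self, adult_ivig):
        result = evaluate_observation(self._perkg_row(70.0), adult_ivig)
        assert result.percent_error == pytest.approx(0.0)

    def test_fold_error_is_basis_invariant(self, adult_ivig):
        # the same observation recorded absolute instead of per-kg gives
        # the identical fold error
        weight = 12.5
        per_kg = evaluate_observation(self._perkg_row(weight), adult_ivig)
        absolute_row = ObservationRow(
            drug_id="ivig",
            drug_class=DrugClass.POLYCLONAL,
            subject=Subject(weight),
            observed_dose=DoseSpec(400.0 * weight, Basis.ABSOLUTE),
            reference_type=ReferenceType.PER_KG_LABEL,
        )
        absolute = evaluate_observation(absolute_row, adult_ivig)
        assert absolute.fold_error == pytest.approx(per_kg.fold_error, rel=1e-12)

    def test_cl_based_reference_uses_clearance_ratio(self):
        adult = AdultReference(
            dose=DoseSpec(400.0, Basis.PER_KG),
            weight_kg=70.0,
            clearance=ClearanceSpec(140.0, Basis.ABSOLUTE),
        )
        weight = 14.0
        # noise-free allometric child clearance, b = 0.75
        clc = 140.0 * (weight / 70.0) ** 0.75
        row = ObservationRow(
            drug_id="mab",
            drug_class=DrugClass.MONOCLONAL,
            subject=Subject(weight),
            observed_dose=DoseSpec(1.0, Basis.PER_KG),  # ignored for cl_based
            reference_type=ReferenceType.CL_BASED,
            child_clearance=ClearanceSpec(clc, Basis.ABSOLUTE),
        )
        result = evaluate_observation(row, adult)
        expected_fold = (2 * weight / 100) / (weight / 70.0) ** 0.75
        assert result.fold_error == pytest.approx(expected_fold, rel=1e-12)

    def test_cl_based_without_adult_clearance_is_missing_field(self, adult_ivig):
        row = ObservationRow(
            drug_id="mab",
            drug_class=DrugClass.MONOCLONAL,
            subject=Subject(10.0),
            observed_dose=DoseSpec(1.0, Basis.PER_KG),
            reference_type=ReferenceType.CL_BASED,
            child_clearance=ClearanceSpec(10.0, Basis.ABSOLUTE),
        )
        with pytest.raises(MissingFieldError, match="mab"):
            evaluate_observation(row, adult_ivig)

    def test_cl_based_row_requires_child_clearance_at_construction(self):
        with pytest.raises(MissingFieldError):
            ObservationRow(
                drug_id="mab",
                drug_class=DrugClass.MONOCLONAL,
                subject=Subject(10.0),
                observed_dose=DoseSpec(1.0, Basis.PER_KG),
                reference_type=ReferenceType.CL_BASED,
            )


class TestSummarize:
    def test_nine_overpredicted_polyclonals(self):
        results = [make_result(1.4, DrugClass.POLYCLONAL) for _ in range(9)]
        table = summarize(results).data
        row = table[(table.n > 0)].iloc[0]
        assert row["n"] == 9
        assert (row["wide_count"], row["wide_pct"]) == (9, 100.0)
        assert (row["narrow_count"], row["narrow_pct"]) == (0, 0.0)
        assert (row["over_count"], row["over_pct"]) == (9, 100.0)
        assert (row["under_count"], row["under_pct"]) == (0, 0.0)

    def test_single_result_percents_are_zero_or_hundred(self):
        table = summarize([make_result(1.0)]).data
        row = table[table.n > 0].iloc[0]
        assert row["n"] == 1
        for cat in ("wide", "narrow", "over", "under"):
            assert row[f"{cat}_pct"] in (0.0, 100.0)

    def test_mixed_stratum_percents_to_one_decimal(self):
        # 31 observations: 27 wide, 11 narrow, 17 over, 3 under
        folds = (
            [1.0] * 11          # narrow (and wide)
            + [1.4] * 14        # over, inside wide
            + [1.8] * 3         # over, outside wide
            + [0.6] * 2         # under, inside wide
            + [0.4] * 1         # under, outside wide
        )
        table = summarize([make_result(f) for f in folds]).data
        row = table[table.n > 0].iloc[0]
        assert row["n"] == 31
        assert (row["wide_count"], row["wide_pct"]) == (27, 87.1)
        assert (row["narrow_count"], row["narrow_pct"]) == (11, 35.5)
        assert (row["over_count"], row["over_pct"]) == (17, 54.8)
        assert (row["under_count"], row["under_pct"]) == (3, 9.7)

    def test_partition_in_every_stratum_of_a_synthetic_cohort(self):
        cohort = generate_cohort(SyntheticConfig(seed=7, obs_per_drug=2))
        results = evaluate_cohort(cohort)
        table = summarize(results).data
        # oracle: recount raw fold errors per stratum
        for _, row in table.iterrows():
            members = [
                r
                for r in results
                if r.drug_class.value == row["drug_class"]
                and r.weight_stratum.value == row["stratum"]
                and r.reference_type.value == row["reference_type"]
            ]
            folds = np.array([r.fold_error for r in members])
            assert row["n"] == len(folds)
            assert row["narrow_count"] == np.sum((folds >= 0.7) & (folds <= 1.3))
            assert row["over_count"] == np.sum(folds > 1.3)
            assert row["under_count"] == np.sum(folds < 0.7)
            assert row["narrow_count"] + row["over_count"] + row["under_count"] == row["n"]
            assert row["wide_count"] >= row["narrow_count"]
        assert table["n"].sum() == len(results)

    def test_neonates_are_their_own_stratum(self):
        neonate = make_result(1.1, DrugClass.POLYCLONAL, WeightStratum.NEONATE,
                              ReferenceType.INVESTIGATOR_SELECTED)
        table = summarize([neonate]).data
        row = table[table.n > 0].iloc[0]
        assert row["stratum"] == "neonate"

    def test_empty_input_yields_flagged_empty_table(self):
        table = summarize([])
        assert table.is_empty
        assert len(table.data) == 0

    def test_markdown_prints_na_for_empty_strata(self):
        text = summarize([make_result(1.4, DrugClass.POLYCLONAL)]).to_markdown()
        assert "0.5–1.5-fold" in text and "≥130% (>1.3-fold)" in text
        assert "NA" in text  # ge30/neonate strata carry no observations


@pytest.mark.parametrize(
    "value, ndigits, expected",
    [(2.5, 0, 3.0), (-2.5, 0, -3.0), (35.48, 1, 35.5), (0.5, 0, 1.0)],
)
def test_round_half_away_from_zero(value, ndigits, expected):
    assert round_half_away(value, ndigits) == expected
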