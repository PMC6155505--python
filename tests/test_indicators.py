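"""Recoding rules: raw survey fields -> binary indicators and outcomes."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from mvindex import (
    INDICATORS,
    OUTCOMES,
    build_matrix,
    derive_indicators,
    derive_outcomes,
)
from mvindex.indicators import read_survey_csv, write_survey_csv

from conftest import records_from


def test_all_nonvulnerable_record_gives_zero_row(base_record):
    ind = derive_indicators(records_from(base_record))
    assert list(ind.columns) == list(INDICATORS)
    assert (ind.iloc[0] == 0).all()


#: For each indicator, a raw-field change in the vulnerable direction.
VULNERABLE_FLIPS = {
    "young_age": {"age": 24},
    "street_solicitation": {"solicitation_place": "street"},
    "high_dependency": {"n_dependents": 3},
    "high_mobility": {"mobility_frequency": "monthly_or_more"},
    "no_alternative_income": {"has_alternative_income": False},
    "no_savings_account": {"has_savings_account": False},
    "no_savings_or_investment": {"has_savings_or_investment": False},
    "informal_loan": {"informal_loan_12m": True},
    "no_insurance": {"has_insurance": False},
    "no_id_card": {"has_id_card": False},
    "food_insecurity": {"food_insecure_6m": True},
    "no_ration_card": {"has_ration_card": False},
    "no_legal_training": {"legal_training": False},
    "no_co_membership": {"co_member": False},
    "no_hiv_services": {"hiv_services_12m": False},
    "no_crisis_support": {"community_crisis_support_6m": False},
}


@pytest.mark.parametrize("indicator", INDICATORS)
def test_vulnerable_flip_sets_exactly_one_indicator(base_record, indicator):
    """Flipping one raw field in the vulnerable direction raises only
    the matching indicator (and never lowers any other)."""
    flipped = {**base_record, **VULNERABLE_FLIPS[indicator]}
    ind = derive_indicators(records_from(flipped)).iloc[0]
    assert ind[indicator] == 1
    others = ind.drop(indicator)
    assert (others == 0).all()


@pytest.mark.parametrize(
    "updates, indicator, expected",
    [
        ({"age": 24}, "young_age", 1),
        ({"age": 25}, "young_age", 0),  # "< 25" is strict
        ({"n_dependents": 2}, "high_dependency", 0),
        ({"n_dependents": 3}, "high_dependency", 1),  # "more than two"
        ({"mobility_frequency": "monthly_or_more", "is_native": True}, "high_mobility", 1),
        ({"mobility_frequency": "less_than_monthly", "is_native": False}, "high_mobility", 1),
        ({"mobility_frequency": "less_than_monthly", "is_native": True}, "high_mobility", 0),
    ],
)
def test_indicator_boundaries(base_record, updates, indicator, expected):
    ind = derive_indicators(records_from({**base_record, **updates}))
    assert ind.iloc[0][indicator] == expected


@pytest.mark.parametrize(
    "regular, occasional, expected",
    [
        ("always", "always", 0),
        ("always", "most_of_the_time", 1),
        ("sometimes", "always", 1),
        ("never", "never", 1),
    ],
)
def test_consistent_condom_requires_always_with_both(base_record, regular, occasional, expected):
    record = {
        **base_record,
        "condom_regular_clients": regular,
        "condom_occasional_clients": occasional,
    }
    out = derive_outcomes(records_from(record))
    assert out.iloc[0]["inconsistent_condom_use"] == expected


@pytest.mark.parametrize(
    "updates, outcome, expected",
    [
        ({}, "sti_symptoms", 0),  # all three symptoms absent
        ({"sti_symptom_groin_swelling": True}, "sti_symptoms", 1),
        ({"hiv_tests_2y": 3}, "few_hiv_tests", 0),  # boundary of "< 3"
        ({"hiv_tests_2y": 2}, "few_hiv_tests", 1),
        ({"sti_checkup_12m": False}, "no_sti_checkup", 1),
        ({"fp_method_current": False}, "no_family_planning", 1),
    ],
)
def test_outcome_rules(base_record, updates, outcome, expected):
    out = derive_outcomes(records_from({**base_record, **updates}))
    assert out.iloc[0][outcome] == expected


def test_completeness_16_indicators_8_outcomes(matrix_small):
    assert matrix_small.indicators.shape[1] == 16
    assert list(matrix_small.outcomes.columns) == list(OUTCOMES)


def test_unknown_categorical_level_rejected_with_field_and_row(base_record):
    bad = {**base_record, "solicitation_place": "brothel"}
    with pytest.raises(ValueError, match="solicitation_place.*brothel.*row"):
        derive_indicators(records_from(base_record, bad))


def test_missing_field_propagates_and_policies_differ(base_record):
    incomplete = {**base_record, "age": None}
    records = records_from(base_record, incomplete)
    ind = derive_indicators(records)
    assert pd.isna(ind.iloc[1]["young_age"])

    cc = build_matrix(records, missing_policy="complete_case")
    clean, _, dropped = cc.complete_case_indicators()
    assert dropped == 1 and len(clean) == 1

    nz = build_matrix(records, missing_policy="nonvulnerable")
    assert nz.indicators.iloc[1]["young_age"] == 0


def test_missing_operand_of_a_true_or_is_still_true(base_record):
    """Kleene OR: a determined composite is not discarded because the
    other operand is missing."""
    record = {**base_record, "mobility_frequency": "monthly_or_more", "is_native": None}
    ind = derive_indicators(records_from(record))
    assert ind.iloc[0]["high_mobility"] == 1


def test_derivation_is_deterministic(matrix_small, survey_small):
    again = derive_indicators(survey_small.records)
    pd.testing.assert_frame_equal(again, matrix_small.indicators)


def test_csv_round_trip_preserves_derived_matrices(tmp_path, survey_small):
    path = tmp_path / "survey.csv"
    write_survey_csv(survey_small.records, path)
    back = read_survey_csv(path)
    pd.testing.assert_frame_equal(
        derive_indicators(back).astype("Float64"),
        derive_indicators(survey_small.records).astype("Float64"),
    )
    pd.testing.assert_frame_equal(
        derive_outcomes(back).astype("Float64"),
        derive_outcomes(survey_small.records).astype("Float64"),
    )
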