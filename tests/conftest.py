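from __future__ import annotations

import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mvindex import IndexDefinition, SyntheticConfig, build_matrix, generate_survey

settings.register_profile(
    "default",
    max_examples=40,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def definition() -> IndexDefinition:
    return IndexDefinition()


@pytest.fixture(scope="session")
def survey_small():
    """A fixed synthetic survey, small enough for fast unit tests."""
    return generate_survey(SyntheticConfig(n=600, seed=11))


@pytest.fixture(scope="session")
def matrix_small(survey_small, definition):
    return build_matrix(survey_small.records, definition)


@pytest.fixture
def base_record() -> dict:
    """One raw record with every field in its non-vulnerable state."""
    return {
        "respondent_id": "R00000",
        "age": 30,
        "solicitation_place": "other",
        "n_dependents": 0,
        "mobility_frequency": "less_than_monthly",
        "is_native": True,
        "has_alternative_income": True,
        "has_savings_account": True,
        "has_savings_or_investment": True,
        "informal_loan_12m": False,
        "has_insurance": True,
        "has_id_card": True,
        "food_insecure_6m": False,
        "has_ration_card": True,
        "legal_training": True,
        "co_member": True,
        "hiv_services_12m": True,
        "community_crisis_support_6m": True,
        "condom_regular_clients": "always",
        "condom_occasional_clients": "always",
        "wanted_condom_could_not_6m": False,
        "anal_sex_12m": False,
        "alcohol_current": False,
        "sti_symptom_ulcer": False,
        "sti_symptom_groin_swelling": False,
        "sti_symptom_painful_urination": False,
        "sti_checkup_12m": True,
        "hiv_tests_2y": 4,
        "fp_method_current": True,
        "duration_sex_work": 7.0,
        "education": "formal",
        "marital_status": "currently_married",
        "state": "Karnataka",
    }


def records_from(*dicts) -> pd.DataFrame:
    return pd.DataFrame(list(dicts))
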