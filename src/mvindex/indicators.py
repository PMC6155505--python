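"""Derivation of binary vulnerability indicators and risk-behavior outcomes.

Raw survey records (one row per respondent) are recoded into

* sixteen binary vulnerability indicators (1 = vulnerable condition),
* eight binary HIV-related risk-behavior outcomes (1 = risky/adverse),
* the regression covariates (duration in sex work, education, marital
  status, state).

Missing raw values propagate to missing derived values (pandas NA) under
Kleene logic, so an OR that is already True from a non-missing operand
stays True.  What to do with missing derived values is decided
downstream: the aggregation stage drops incomplete rows (complete-case,
the default) or treats missing as non-vulnerable, and each regression is
complete-case for its own outcome.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .definitions import INDICATORS, IndexDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "OUTCOMES",
    "CONDOM_LEVELS",
    "BOOLEAN_FIELDS",
    "NUMERIC_FIELDS",
    "CATEGORICAL_LEVELS",
    "DeprivationMatrix",
    "derive_indicators",
    "derive_outcomes",
    "derive_covariates",
    "build_matrix",
    "read_survey_csv",
    "write_survey_csv",
]

#: Outcome columns in reporting order.
OUTCOMES: tuple[str, ...] = (
    "inconsistent_condom_use",
    "poor_negotiation",
    "anal_sex",
    "sti_symptoms",
    "alcohol_use",
    "no_sti_checkup",
    "few_hiv_tests",
    "no_family_planning",
)

OUTCOME_LABELS: dict[str, str] = {
    "inconsistent_condom_use": "Inconsistent condom-use with clients in last one month",
    "poor_negotiation": "Wanted to use condom but could not use in past 6 months",
    "anal_sex": "Had anal sex with clients in last 12 months",
    "sti_symptoms": "Experienced self-reported STI symptoms in past 6 months",
    "alcohol_use": "Currently consuming alcohol",
    "no_sti_checkup": "Did not go for STI check-up and counselling in last 12 months",
    "few_hiv_tests": "Tested for HIV < 3 times in last two years",
    "no_family_planning": "Currently not using any family planning method",
}

CONDOM_LEVELS = ("always", "most_of_the_time", "sometimes", "never")

BOOLEAN_FIELDS: tuple[str, ...] = (
    "is_native",
    "has_alternative_income",
    "has_savings_account",
    "has_savings_or_investment",
    "informal_loan_12m",
    "has_insurance",
    "has_id_card",
    "food_insecure_6m",
    "has_ration_card",
    "legal_training",
    "co_member",
    "hiv_services_12m",
    "community_crisis_support_6m",
    "wanted_condom_could_not_6m",
    "anal_sex_12m",
    "alcohol_current",
    "sti_symptom_ulcer",
    "sti_symptom_groin_swelling",
    "sti_symptom_painful_urination",
    "sti_checkup_12m",
    "fp_method_current",
)

NUMERIC_FIELDS: tuple[str, ...] = (
    "age",
    "n_dependents",
    "hiv_tests_2y",
    "duration_sex_work",
)

#: Declared categorical levels; None means free-form (validated non-empty only).
CATEGORICAL_LEVELS: dict[str, tuple[str, ...] | None] = {
    "solicitation_place": ("street", "other"),
    "mobility_frequency": ("monthly_or_more", "less_than_monthly"),
    "condom_regular_clients": CONDOM_LEVELS,
    "condom_occasional_clients": CONDOM_LEVELS,
    "education": ("no_formal", "formal"),
    "marital_status": ("currently_married", "never_married", "formerly_married"),
    "state": None,
}

COVARIATE_FIELDS = ("duration_sex_work", "education", "marital_status", "state")


def _validate_levels(records: pd.DataFrame, fields: Iterable[str]) -> None:
    for field_name in fields:
        levels = CATEGORICAL_LEVELS.get(field_name)
        if levels is None or field_name not in records:
            continue
        col = records[field_name]
        bad = col.notna() & ~col.isin(levels)
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"field {field_name!r}: unknown level {col.loc[row]!r} at row {row!r}"
            )


def _bool(records: pd.DataFrame, field_name: str) -> pd.Series:
    return records[field_name].astype("boolean")


def _num(records: pd.DataFrame, field_name: str) -> pd.Series:
    return records[field_name].astype("Float64")


def _eq(records: pd.DataFrame, field_name: str, level: str) -> pd.Series:
    # string dtype equality keeps NA as NA
    return records[field_name].astype("string") == level


def derive_indicators(
    records: pd.DataFrame,
    definition: IndexDefinition | None = None,
    *,
    high_mobility_levels: Sequence[str] = ("monthly_or_more",),
) -> pd.DataFrame:
    """Recode raw records into the 16 binary vulnerability indicators.

    Rules (1 = vulnerable): age < 25; solicits on the street; more than
    two dependents on the respondent's income; highly mobile (changes
    place for sex work at the declared high-frequency levels) OR not a
    native of the district of work; no alternative income source; no
    savings account; neither savings nor investment in land/gold/house;
    informal loan in the last 12 months; no insurance; no citizen
    identity card; food insecurity in the last 6 months; no ration card;
    no legal-rights training; not a member of a community organization;
    no HIV prevention services in the last 12 months; no community
    crisis support in the last 6 months.

    Returns a DataFrame with nullable 0/1 entries (``Float64``), columns
    in canonical order, index preserved.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    _validate_levels(
        records, ("solicitation_place", "mobility_frequency")
    )
    if definition is not None and tuple(definition.indicators) != INDICATORS:
        # custom trees are allowed but must be a subset of the rules we know
        unknown = set(definition.indicators) - set(INDICATORS)
        if unknown:
            raise ValueError(f"no derivation rule for indicators: {sorted(unknown)}")

    mobile = (
        records["mobility_frequency"]
        .isin(tuple(high_mobility_levels))
        .astype("boolean")
        .mask(records["mobility_frequency"].isna())
    )
    rules: dict[str, pd.Series] = {
        "young_age": _num(records, "age") < 25,
        "street_solicitation": _eq(records, "solicitation_place", "street"),
        "high_dependency": _num(records, "n_dependents") > 2,
        "high_mobility": mobile | ~_bool(records, "is_native"),
        "no_alternative_income": ~_bool(records, "has_alternative_income"),
        "no_savings_account": ~_bool(records, "has_savings_account"),
        "no_savings_or_investment": ~_bool(records, "has_savings_or_investment"),
        "informal_loan": _bool(records, "informal_loan_12m"),
        "no_insurance": ~_bool(records, "has_insurance"),
        "no_id_card": ~_bool(records, "has_id_card"),
        "food_insecurity": _bool(records, "food_insecure_6m"),
        "no_ration_card": ~_bool(records, "has_ration_card"),
        "no_legal_training": ~_bool(records, "legal_training"),
        "no_co_membership": ~_bool(records, "co_member"),
        "no_hiv_services": ~_bool(records, "hiv_services_12m"),
        "no_crisis_support": ~_bool(records, "community_crisis_support_6m"),
    }
    order = definition.indicators if definition is not None else INDICATORS
    out = pd.DataFrame(
        {name: rules[name].astype("Float64") for name in order},
        index=records.index,
    )
    return out


def derive_outcomes(records: pd.DataFrame) -> pd.DataFrame:
    """Recode raw responses into the 8 binary risk-behavior outcomes.

    A respondent is a consistent condom user only if she reports
    "always" with both regular and occasional clients; any other
    combination is inconsistent use.  STI symptoms are positive if any
    of the three symptom items (genital ulcers/sores, groin swelling,
    frequent painful urination) is positive.  "Few HIV tests" means
    fewer than three tests in the last two years.
    """
    if len(records) == 0:
        raise ValueError("records must be non-empty")
    _validate_levels(records, ("condom_regular_clients", "condom_occasional_clients"))

    consistent = _eq(records, "condom_regular_clients", "always") & _eq(
        records, "condom_occasional_clients", "always"
    )
    sti = (
        _bool(records, "sti_symptom_ulcer")
        | _bool(records, "sti_symptom_groin_swelling")
        | _bool(records, "sti_symptom_painful_urination")
    )
    rules: dict[str, pd.Series] = {
        "inconsistent_condom_use": ~consistent,
        "poor_negotiation": _bool(records, "wanted_condom_could_not_6m"),
        "anal_sex": _bool(records, "anal_sex_12m"),
        "sti_symptoms": sti,
        "alcohol_use": _bool(records, "alcohol_current"),
        "no_sti_checkup": ~_bool(records, "sti_checkup_12m"),
        "few_hiv_tests": _num(records, "hiv_tests_2y") < 3,
        "no_family_planning": ~_bool(records, "fp_method_current"),
    }
    return pd.DataFrame(
        {name: rules[name].astype("Float64") for name in OUTCOMES},
        index=records.index,
    )


def derive_covariates(records: pd.DataFrame) -> pd.DataFrame:
    """Validated covariate frame: duration (years), education, marital, state."""
    _validate_levels(records, ("education", "marital_status"))
    cov = pd.DataFrame(index=records.index)
    cov["duration_sex_work"] = records["duration_sex_work"].astype("Float64")
    for field_name in ("education", "marital_status", "state"):
        cov[field_name] = records[field_name].astype("string")
    return cov


@dataclass
class DeprivationMatrix:
    """Derived per-respondent matrices plus subgroup labels.

    Attributes
    ----------
    indicators : DataFrame (n × 16, nullable 0/1)
    outcomes : DataFrame (n × 8, nullable 0/1)
    covariates : DataFrame (duration_sex_work, education, marital_status, state)
    subgroup : Series of state labels
    """

    indicators: pd.DataFrame
    outcomes: pd.DataFrame
    covariates: pd.DataFrame
    subgroup: pd.Series

    def __post_init__(self) -> None:
        n = len(self.indicators)
        for name, frame in (
            ("outcomes", self.outcomes),
            ("covariates", self.covariates),
            ("subgroup", self.subgroup),
        ):
            if len(frame) != n:
                raise ValueError(f"{name} length {len(frame)} != indicators length {n}")
        if self.indicators.columns.duplicated().any():
            raise ValueError("indicator column names are not unique")
        for frame in (self.indicators, self.outcomes):
            values = frame.to_numpy(dtype=float, na_value=np.nan)
            finite = values[~np.isnan(values)]
            if not np.isin(finite, (0.0, 1.0)).all():
                raise ValueError("derived entries must be 0, 1 or missing")

    @property
    def n(self) -> int:
        return len(self.indicators)

    def complete_case_indicators(self) -> tuple[pd.DataFrame, pd.Series, int]:
        """Rows with all 16 indicators observed, as int8, plus drop count."""
        mask = self.indicators.notna().all(axis=1)
        dropped = int((~mask).sum())
        if dropped:
            logger.info("complete-case: dropped %d rows with missing indicators", dropped)
        clean = self.indicators.loc[mask].astype(np.int8)
        return clean, self.subgroup.loc[mask], dropped


def build_matrix(
    records: pd.DataFrame,
    definition: IndexDefinition | None = None,
    *,
    missing_policy: str = "complete_case",
    high_mobility_levels: Sequence[str] = ("monthly_or_more",),
) -> DeprivationMatrix:
    """Full derivation: indicators + outcomes + covariates + subgroup.

    ``missing_policy`` is ``"complete_case"`` (missing indicator entries
    stay missing; the aggregation stage drops those rows) or
    ``"nonvulnerable"`` (missing indicator entries recoded to 0).
    """
    if missing_policy not in ("complete_case", "nonvulnerable"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    ind = derive_indicators(
        records, definition, high_mobility_levels=high_mobility_levels
    )
    if missing_policy == "nonvulnerable":
        ind = ind.fillna(0.0)
    return DeprivationMatrix(
        indicators=ind,
        outcomes=derive_outcomes(records),
        covariates=derive_covariates(records),
        subgroup=records["state"].astype("string"),
    )


# ---------------------------------------------------------------------------
# CSV I/O


def write_survey_csv(records: pd.DataFrame, path) -> None:
    """Write raw records as UTF-8 CSV; missing values as empty cells."""
    records.to_csv(path, index=False, encoding="utf-8")


def read_survey_csv(path, *, column_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a raw survey CSV, normalising dtypes.

    ``column_map`` renames input columns to canonical field names
    (``{"input name": "canonical_name"}``).  Booleans accept
    True/False/1/0/yes/no in any case; empty cells are missing.
    """
    df = pd.read_csv(path, dtype="string", encoding="utf-8")
    if column_map:
        df = df.rename(columns=dict(column_map))
    truthy = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}

    def parse_bool(s: pd.Series) -> pd.Series:
        lowered = s.str.strip().str.lower()
        bad = lowered.notna() & ~lowered.isin(truthy)
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"field {s.name!r}: unknown boolean value {s.loc[row]!r} at row {row!r}"
            )
        return lowered.map(truthy).astype("boolean")

    for col in df.columns:
        if col in BOOLEAN_FIELDS:
            df[col] = parse_bool(df[col])
        elif col in NUMERIC_FIELDS:
            df[col] = pd.to_numeric(df[col], errors="raise").astype("Float64")
    return df
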