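"""Synthetic survey generator.

Emulates the statistical structure the analysis assumes, with no real
microdata: ~4,098 respondents across four state strata, sixteen
correlated binary deprivation indicators at specified marginal
prevalences, socio-demographic covariates, and binary risk-behavior
outcomes drawn from a logistic model in which multidimensional
vulnerability status carries a configurable log odds ratio.

Indicators come from a latent Gaussian threshold (Gaussian copula)
model: draw z ~ N(0, R) and set x_j = 1 iff z_j > Φ⁻¹(1 − p_j).  This
gives independent control of the marginals p_j and the dependence R;
the default R is exchangeable, 0.3 within a dimension and 0.1 between
dimensions.  The joint law of the real survey is unknown, so R is a
modelling choice, not an estimate.

Raw survey fields are *back-constructed* from each drawn indicator or
outcome (e.g. age uniform on 18–24 when the young-age indicator is 1,
on 25–50 otherwise), which guarantees that re-deriving indicators from
the generated records reproduces the drawn matrix exactly — the
round-trip contract that makes the derivation stage testable
end-to-end.

One master seed drives everything; per-stage substreams are spawned
deterministically, so the same seed yields byte-identical records.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import norm

from . import af
from .definitions import DIMENSIONS, INDICATORS, IndexDefinition
from .indicators import OUTCOMES

__all__ = [
    "DEFAULT_MARGINALS",
    "DEFAULT_STATE_SHARES",
    "DEFAULT_OUTCOME_MODEL",
    "SyntheticConfig",
    "latent_correlation",
    "generate_population",
    "generate_outcomes",
    "generate_survey",
    "SyntheticSurvey",
]

#: National marginal deprivation prevalences for the 16 indicators.
DEFAULT_MARGINALS: dict[str, float] = {
    "young_age": 0.099,
    "street_solicitation": 0.239,
    "high_dependency": 0.640,
    "high_mobility": 0.444,
    "no_alternative_income": 0.478,
    "no_savings_account": 0.316,
    "no_savings_or_investment": 0.613,
    "informal_loan": 0.200,
    "no_insurance": 0.869,
    "no_id_card": 0.053,
    "food_insecurity": 0.162,
    "no_ration_card": 0.203,
    "no_legal_training": 0.633,
    "no_co_membership": 0.229,
    "no_hiv_services": 0.269,
    "no_crisis_support": 0.518,
}

#: Four sampling strata (Andhra Pradesh and Telangana form one domain).
DEFAULT_STATE_SHARES: dict[str, float] = {
    "Andhra Pradesh & Telangana": 0.25,
    "Karnataka": 0.25,
    "Tamil Nadu": 0.25,
    "Maharashtra": 0.25,
}

#: Per-outcome (baseline prevalence among the non-vulnerable, odds ratio
#: for vulnerability).  Baselines and ORs mirror the published national
#: association table for these eight behaviors.
DEFAULT_OUTCOME_MODEL: dict[str, tuple[float, float]] = {
    "inconsistent_condom_use": (0.056, 1.75),
    "poor_negotiation": (0.060, 1.58),
    "anal_sex": (0.077, 1.42),
    "sti_symptoms": (0.132, 1.17),
    "alcohol_use": (0.207, 1.51),
    "no_sti_checkup": (0.344, 2.69),
    "few_hiv_tests": (0.161, 1.39),
    "no_family_planning": (0.320, 1.35),
}

#: Covariate effects (log-odds) shared across outcomes: modest,
#: plausible confounding rather than an estimate of anything.
DEFAULT_COVARIATE_EFFECTS: dict[str, float] = {
    "duration_sex_work": 0.02,
    "education[formal]": -0.15,
    "marital_status[never_married]": 0.10,
    "marital_status[formerly_married]": 0.15,
}


@dataclass
class SyntheticConfig:
    """Generator settings; defaults are the study conditions emulated.

    ``marginals`` apply to every stratum unless overridden per stratum
    in ``stratum_marginals``.  ``duration_shape``/``duration_scale``
    parameterise a gamma for years in sex work (mean 7).  Education and
    marital distributions match the published sample description (42%
    no formal education, 62% currently married).
    """

    n: int = 4098
    state_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STATE_SHARES)
    )
    marginals: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS)
    )
    stratum_marginals: Mapping[str, Mapping[str, float]] | None = None
    within_dimension_rho: float = 0.3
    between_dimension_rho: float = 0.1
    duration_shape: float = 2.0
    duration_scale: float = 3.5
    education_p_formal: float = 0.58
    marital_probs: Mapping[str, float] = field(
        default_factory=lambda: {
            "currently_married": 0.62,
            "never_married": 0.15,
            "formerly_married": 0.23,
        }
    )
    outcome_model: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_OUTCOME_MODEL)
    )
    covariate_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n < 1:
            raise ValueError("n must be positive")
        if abs(sum(self.state_shares.values()) - 1.0) > 1e-9:
            raise ValueError("state shares must sum to 1")
        for name, p in self.marginals.items():
            if not (0 < p < 1):
                raise ValueError(f"marginal for {name!r} must lie in (0, 1): {p}")
        if set(self.marginals) != set(INDICATORS):
            raise ValueError("marginals must cover exactly the 16 indicators")
        probs = self.marital_probs
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError("marital status probabilities must sum to 1")
        for name, (p0, or_) in self.outcome_model.items():
            if not (0 < p0 < 1) or or_ <= 0:
                raise ValueError(f"invalid outcome model for {name!r}")


def latent_correlation(
    definition: IndexDefinition | None = None,
    within: float = 0.3,
    between: float = 0.1,
) -> np.ndarray:
    """Exchangeable block correlation for the latent Gaussian layer.

    ``within`` on pairs inside a dimension, ``between`` across
    dimensions, 1 on the diagonal.  Raises if the result is not
    positive semi-definite (the caller should move the off-diagonal
    values toward each other, i.e. use the nearest-PSD correction).
    """
    dims = definition.dimensions if definition is not None else DIMENSIONS
    names = [j for members in dims.values() for j in members]
    J = len(names)
    dim_idx = np.array(
        [d for d, members in enumerate(dims.values()) for _ in members]
    )
    R = np.where(dim_idx[:, None] == dim_idx[None, :], within, between)
    np.fill_diagonal(R, 1.0)
    eigmin = float(np.linalg.eigvalsh(R).min())
    if eigmin < -1e-10:
        raise ValueError(
            f"latent correlation is not PSD (min eigenvalue {eigmin:.3g}); "
            "bring the within/between values closer or project to the nearest PSD matrix"
        )
    assert R.shape == (J, J)
    return R


# ---------------------------------------------------------------------------
# population (indicators + covariates)


def _state_counts(config: SyntheticConfig) -> dict[str, int]:
    # largest-remainder apportionment of n over the strata
    shares = config.state_shares
    raw = {s: config.n * p for s, p in shares.items()}
    counts = {s: int(math.floor(v)) for s, v in raw.items()}
    short = config.n - sum(counts.values())
    for s in sorted(raw, key=lambda s: raw[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1
    return counts


def _back_construct(
    x: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Raw fields whose derivation reproduces the drawn indicators."""
    n = len(x)
    rec = pd.DataFrame(index=x.index)
    rec["age"] = np.where(
        x["young_age"] == 1, rng.integers(18, 25, n), rng.integers(25, 51, n)
    )
    rec["solicitation_place"] = np.where(
        x["street_solicitation"] == 1, "street", "other"
    )
    rec["n_dependents"] = np.where(
        x["high_dependency"] == 1, rng.integers(3, 7, n), rng.integers(0, 3, n)
    )
    # mobility composite: indicator = highly mobile OR not native
    combo = rng.integers(0, 3, n)  # which true combination when deprived
    deprived = x["high_mobility"] == 1
    rec["mobility_frequency"] = np.where(
        deprived & (combo != 2), "monthly_or_more", "less_than_monthly"
    )
    rec["is_native"] = np.where(deprived & (combo != 0), False, True)
    rec["has_alternative_income"] = x["no_alternative_income"] == 0
    rec["has_savings_account"] = x["no_savings_account"] == 0
    rec["has_savings_or_investment"] = x["no_savings_or_investment"] == 0
    rec["informal_loan_12m"] = x["informal_loan"] == 1
    rec["has_insurance"] = x["no_insurance"] == 0
    rec["has_id_card"] = x["no_id_card"] == 0
    rec["food_insecure_6m"] = x["food_insecurity"] == 1
    rec["has_ration_card"] = x["no_ration_card"] == 0
    rec["legal_training"] = x["no_legal_training"] == 0
    rec["co_member"] = x["no_co_membership"] == 0
    rec["hiv_services_12m"] = x["no_hiv_services"] == 0
    rec["community_crisis_support_6m"] = x["no_crisis_support"] == 0
    return rec


def generate_population(
    config: SyntheticConfig,
    definition: IndexDefinition | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw indicators and back-construct raw records (no outcomes yet).

    Returns ``(records, indicators)``; ``indicators`` is the drawn
    binary matrix (int8, canonical columns) that
    :func:`mvindex.indicators.derive_indicators` recovers exactly from
    ``records``.
    """
    config.validate()
    definition = definition or IndexDefinition()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])
    R = latent_correlation(
        definition, config.within_dimension_rho, config.between_dimension_rho
    )
    L = np.linalg.cholesky(R)
    counts = _state_counts(config)
    states = np.repeat(list(counts), list(counts.values()))
    n = config.n
    z = rng.standard_normal((n, len(INDICATORS))) @ L.T

    thresholds = np.empty((n, len(INDICATORS)))
    for s, cnt in counts.items():
        marg = dict(config.marginals)
        if config.stratum_marginals and s in config.stratum_marginals:
            marg.update(config.stratum_marginals[s])
        row = norm.ppf(1.0 - np.array([marg[j] for j in INDICATORS]))
        thresholds[states == s] = row
    x = pd.DataFrame((z > thresholds).astype(np.int8), columns=list(INDICATORS))

    records = _back_construct(x, rng)
    records["duration_sex_work"] = np.round(
        rng.gamma(config.duration_shape, config.duration_scale, n), 1
    )
    records["education"] = np.where(
        rng.random(n) < config.education_p_formal, "formal", "no_formal"
    )
    marital_levels = list(config.marital_probs)
    records["marital_status"] = rng.choice(
        marital_levels, size=n, p=[config.marital_probs[m] for m in marital_levels]
    )
    records["state"] = states
    records.insert(0, "respondent_id", [f"R{i:05d}" for i in range(n)])
    return records, x


# ---------------------------------------------------------------------------
# outcomes


def _covariate_term(records: pd.DataFrame, effects: Mapping[str, float]) -> np.ndarray:
    eta = np.zeros(len(records))
    for term, beta in effects.items():
        if "[" in term:
            field_name, level = term[:-1].split("[")
            eta += beta * (records[field_name] == level).to_numpy(dtype=float)
        else:
            eta += beta * records[term].to_numpy(dtype=float)
    return eta


def _expected_covariate_term(config: SyntheticConfig) -> float:
    """Mean of the covariate linear predictor under the generator law."""
    expected = 0.0
    for term, beta in config.covariate_effects.items():
        if term == "duration_sex_work":
            expected += beta * config.duration_shape * config.duration_scale
        elif term == "education[formal]":
            expected += beta * config.education_p_formal
        elif term.startswith("marital_status["):
            level = term[len("marital_status[") : -1]
            expected += beta * config.marital_probs.get(level, 0.0)
    return expected


def _back_construct_outcomes(
    y: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    n = len(y)
    rec = pd.DataFrame(index=y.index)
    # condom ordinals: consistent users report "always" with both client
    # types; inconsistent users get a uniform draw over the other 15 combos
    levels = np.array(["always", "most_of_the_time", "sometimes", "never"])
    combo = rng.integers(1, 16, n)  # 1..15, combo 0 = (always, always)
    inconsistent = y["inconsistent_condom_use"] == 1
    rec["condom_regular_clients"] = np.where(
        inconsistent, levels[combo // 4], "always"
    )
    rec["condom_occasional_clients"] = np.where(
        inconsistent, levels[combo % 4], "always"
    )
    rec["wanted_condom_could_not_6m"] = y["poor_negotiation"] == 1
    rec["anal_sex_12m"] = y["anal_sex"] == 1
    # at least one of the three symptoms when positive (bits of 1..7)
    bits = rng.integers(1, 8, n)
    positive = (y["sti_symptoms"] == 1).to_numpy()
    rec["sti_symptom_ulcer"] = positive & (bits & 1 > 0)
    rec["sti_symptom_groin_swelling"] = positive & (bits & 2 > 0)
    rec["sti_symptom_painful_urination"] = positive & (bits & 4 > 0)
    rec["alcohol_current"] = y["alcohol_use"] == 1
    rec["sti_checkup_12m"] = y["no_sti_checkup"] == 0
    rec["hiv_tests_2y"] = np.where(
        y["few_hiv_tests"] == 1, rng.integers(0, 3, n), rng.integers(3, 7, n)
    )
    rec["fp_method_current"] = y["no_family_planning"] == 0
    return rec


def generate_outcomes(
    records: pd.DataFrame,
    vulnerable: np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the 8 outcomes given vulnerability status; back-construct fields.

    Each outcome is Bernoulli(expit(α + β·status + γ·covariates)) with
    β = log(OR) from the config and α chosen so that the expected
    prevalence among the non-vulnerable matches the configured baseline
    (the mean covariate contribution is absorbed into α).
    Returns ``(outcome_fields, drawn_outcomes)``.
    """
    n = len(records)
    status = np.asarray(vulnerable, dtype=float)
    cov_eta = _covariate_term(records, config.covariate_effects)
    alpha_shift = _expected_covariate_term(config)
    y = pd.DataFrame(index=records.index)
    for name in OUTCOMES:
        p0, or_ = config.outcome_model[name]
        eta = logit(p0) - alpha_shift + math.log(or_) * status + cov_eta
        y[name] = (rng.random(n) < expit(eta)).astype(np.int8)
    fields = _back_construct_outcomes(y, rng)
    return fields, y


# ---------------------------------------------------------------------------
# full survey


@dataclass
class SyntheticSurvey:
    """A generated survey: raw records plus the internally drawn truth."""

    records: pd.DataFrame
    indicators: pd.DataFrame  # drawn binary matrix (ground truth)
    outcomes: pd.DataFrame    # drawn binary outcomes (ground truth)
    vulnerable: np.ndarray    # status at the definition's k
    config: SyntheticConfig


def generate_survey(
    config: SyntheticConfig | None = None,
    definition: IndexDefinition | None = None,
) -> SyntheticSurvey:
    """Generate a complete survey (population, status, outcomes).

    Vulnerability status is computed from the drawn indicator matrix at
    the definition's cut-off k before outcomes are drawn, exactly as
    the analysis will recompute it from the records.
    """
    config = config or SyntheticConfig()
    definition = definition or IndexDefinition()
    pop_ss, out_ss = np.random.SeedSequence(config.seed).spawn(2)
    records, x = generate_population(
        config, definition, np.random.default_rng(pop_ss)
    )
    scores = af.deprivation_scores(x[list(definition.indicators)], definition)
    fields, y = generate_outcomes(
        records, scores.vulnerable, config, np.random.default_rng(out_ss)
    )
    records = pd.concat([records, fields], axis=1)
    return SyntheticSurvey(
        records=records,
        indicators=x,
        outcomes=y,
        vulnerable=scores.vulnerable,
        config=config,
    )
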