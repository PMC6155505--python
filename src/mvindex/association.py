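"""Associations between vulnerability status and risk-behavior outcomes.

For each binary outcome a multiple logistic regression is fitted with
multidimensional vulnerability status as the key exposure and duration
in sex work (continuous), education, marital status and state as
covariates.  The adjusted odds ratio is exp(beta_exposure) with a Wald
95% confidence interval exp(beta ± 1.96·SE).  Unadjusted outcome
prevalences by exposure group accompany each fit.

Fits are complete-case per outcome.  Rank-deficient designs, perfect
separation and non-convergence raise :class:`FitFailure` with a
diagnostic — a failed fit is never reported as a silent number.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError

logger = logging.getLogger(__name__)

__all__ = [
    "FitFailure",
    "AssociationResult",
    "fit_logistic",
    "associate_all",
    "DEFAULT_REFERENCES",
]

Z_95 = 1.959963984540054  # two-sided 95% normal quantile

DEFAULT_REFERENCES: dict[str, str] = {
    "education": "no_formal",
    "marital_status": "currently_married",
    # state reference defaults to the first level alphabetically
}


class FitFailure(RuntimeError):
    """A logistic fit that cannot be trusted, with a diagnostic message."""


@dataclass
class AssociationResult:
    outcome: str
    n_used: int
    pct_nonvulnerable: float
    pct_vulnerable: float
    aor: float
    ci_low: float
    ci_high: float
    coefficients: pd.DataFrame  # index: term; columns: coef, se


def _design(
    exposure: pd.Series,
    covariates: pd.DataFrame | None,
    references: dict[str, str],
) -> pd.DataFrame:
    X = pd.DataFrame(index=exposure.index)
    X["const"] = 1.0
    X["vulnerable"] = exposure.astype(float)
    if covariates is not None:
        if "duration_sex_work" in covariates:
            X["duration_sex_work"] = covariates["duration_sex_work"].astype(float)
        for cat in ("education", "marital_status", "state"):
            if cat not in covariates:
                continue
            col = covariates[cat].astype("string")
            levels = sorted(col.dropna().unique())
            ref = references.get(cat, levels[0] if levels else None)
            if ref is not None and ref not in levels:
                raise FitFailure(
                    f"reference level {ref!r} for {cat!r} not present in data"
                )
            for level in levels:
                if level == ref:
                    continue
                X[f"{cat}[{level}]"] = (col == level).astype(float)
    return X


def fit_logistic(
    outcome: pd.Series,
    exposure: pd.Series,
    covariates: pd.DataFrame | None = None,
    *,
    references: dict[str, str] | None = None,
    outcome_name: str = "outcome",
) -> AssociationResult:
    """Maximum-likelihood logistic fit of one outcome on the exposure.

    Rows missing the outcome, the exposure or any covariate are
    excluded (complete-case for this outcome only).  Newton/IRLS with
    convergence at max coefficient change < 1e-8 or 100 iterations.
    """
    refs = dict(DEFAULT_REFERENCES)
    if references:
        refs.update(references)
    y = pd.Series(outcome).astype("Float64")
    exp_series = pd.Series(exposure)

    mask = y.notna() & exp_series.notna()
    if covariates is not None:
        mask &= covariates.notna().all(axis=1)
    y_used = y[mask].astype(float)
    exp_used = exp_series[mask].astype(float)
    cov_used = covariates.loc[mask] if covariates is not None else None
    n_used = int(mask.sum())

    if y_used.nunique() < 2:
        raise FitFailure(f"{outcome_name}: outcome has a single class in the data used")
    if exp_used.nunique() < 2:
        raise FitFailure(f"{outcome_name}: exposure has a single level in the data used")

    # unadjusted percentages by exposure group
    pct_no = float(y_used[exp_used == 0].mean() * 100)
    pct_yes = float(y_used[exp_used == 1].mean() * 100)

    X = _design(exp_used, cov_used, refs)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise FitFailure(
            f"{outcome_name}: design matrix rank {rank} < {X.shape[1]} columns "
            "(collinear or constant column)"
        )
    try:
        fit = sm.Logit(y_used.to_numpy(), X).fit(
            method="newton", maxiter=100, tol=1e-8, disp=0, warn_convergence=False
        )
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise FitFailure(f"{outcome_name}: {exc}") from exc
    if not fit.mle_retvals.get("converged", False):
        raise FitFailure(f"{outcome_name}: Newton iterations did not converge")
    if not np.isfinite(fit.bse).all():
        raise FitFailure(f"{outcome_name}: non-finite standard errors (separation?)")

    beta = float(fit.params["vulnerable"])
    se = float(fit.bse["vulnerable"])
    return AssociationResult(
        outcome=outcome_name,
        n_used=n_used,
        pct_nonvulnerable=pct_no,
        pct_vulnerable=pct_yes,
        aor=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z_95 * se)),
        ci_high=float(np.exp(beta + Z_95 * se)),
        coefficients=pd.DataFrame({"coef": fit.params, "se": fit.bse}),
    )


def associate_all(
    outcomes: pd.DataFrame,
    exposure: pd.Series,
    covariates: pd.DataFrame,
    *,
    references: dict[str, str] | None = None,
) -> tuple[dict[str, AssociationResult], dict[str, str]]:
    """Fit every outcome column; returns (results, failures) by name."""
    results: dict[str, AssociationResult] = {}
    failures: dict[str, str] = {}
    for name in outcomes.columns:
        try:
            results[name] = fit_logistic(
                outcomes[name],
                exposure,
                covariates,
                references=references,
                outcome_name=name,
            )
        except FitFailure as exc:
            logger.warning("fit failed for %s: %s", name, exc)
            failures[name] = str(exc)
    return results, failures
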