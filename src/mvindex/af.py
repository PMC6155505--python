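"""Alkire-Foster dual cut-off aggregation.

Given an n × J binary deprivation matrix X, rational weights w_j summing
to 1 and an identification cut-off k, the engine computes

* the weighted deprivation score c_i = Σ_j w_j x_ij for each respondent,
* identification: respondent i is multidimensionally vulnerable when
  c_i ≥ k (the comparison operator is configurable),
* the headcount ratio H = q/n (q = number identified),
* the intensity A = mean c_i among the identified (censored mean),
* the adjusted headcount MVI = H · A,
* the severe headcount (share with c_i ≥ severe_k, ≥ always),
* censored headcounts CH_j = share of the *whole* population that is
  both identified and deprived in indicator j,
* contributions φ_j = w_j · CH_j / MVI, which sum to 1, and their
  dimension totals.

Two exact identities are the backbone of the method and of this
module's tests: MVI = H · A and MVI = Σ_j w_j · CH_j.

Scores are accumulated as integers over the common denominator of the
weights and cut-offs, so identification at a tied score (possible with
rational weights, e.g. c = 80/240 at k = 1/3) is exact rather than a
floating-point accident.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .definitions import IndexDefinition

logger = logging.getLogger(__name__)

__all__ = [
    "ScoreVector",
    "AFSummary",
    "AFResult",
    "deprivation_scores",
    "aggregate",
    "mvi_from_components",
    "mvi_from_censored_headcounts",
    "indicator_contributions",
    "dimension_contributions",
]


@dataclass
class ScoreVector:
    """Per-respondent weighted deprivation scores and identification.

    ``raw`` holds the integer score numerators on denominator ``den``
    (``score = raw / den`` exactly)."""

    score: np.ndarray
    vulnerable: np.ndarray
    censored_score: np.ndarray
    severe: np.ndarray
    raw: np.ndarray
    den: int


def _check_columns(indicators: pd.DataFrame, definition: IndexDefinition) -> pd.DataFrame:
    expected = list(definition.indicators)
    got = list(indicators.columns)
    if set(got) != set(expected):
        unmatched = sorted(set(got) ^ set(expected))
        raise ValueError(f"indicator columns do not match definition: {unmatched}")
    return indicators[expected]


def deprivation_scores(
    indicators: pd.DataFrame, definition: IndexDefinition
) -> ScoreVector:
    """Weighted scores c_i and dual cut-off identification.

    ``indicators`` must be a complete (no missing entries) 0/1 matrix
    whose columns match the definition's indicators (any order; they are
    aligned by name).
    """
    aligned = _check_columns(indicators, definition)
    X = aligned.to_numpy(dtype=np.int64)
    if X.size and not np.isin(X, (0, 1)).all():
        raise ValueError("indicator matrix must be binary with no missing entries")
    den = definition.common_denominator
    w_int = definition.integer_weights()
    raw = X @ w_int
    k_int = int(definition.k * den)
    severe_int = int(definition.severe_k * den)
    if definition.tie_op == "ge":
        vulnerable = raw >= k_int
    else:
        vulnerable = raw > k_int
    score = raw / den
    return ScoreVector(
        score=score,
        vulnerable=vulnerable,
        censored_score=np.where(vulnerable, score, 0.0),
        severe=raw >= severe_int,
        raw=raw,
        den=den,
    )


@dataclass
class AFSummary:
    """AF measures for one population (or one subgroup).

    ``censored_headcount`` is CH_j over the whole (sub)population;
    ``ch_among_vulnerable`` is CH_j / H, the share deprived in j among
    the identified — both are reported because published tables use
    either normalisation.  ``contribution`` entries are proportions of
    the index (they sum to 1); the reporting layer turns them into
    percentages.
    """

    n: int
    q: int
    headcount: float
    intensity: float
    mvi: float
    severe_headcount: float
    censored_headcount: pd.Series
    ch_among_vulnerable: pd.Series
    contribution: pd.Series
    dimension_contribution: pd.Series


@dataclass
class AFResult:
    overall: AFSummary
    by_subgroup: dict[str, AFSummary] = field(default_factory=dict)
    n_dropped: int = 0


# -- identity helpers (also the acceptance-script entry points) -------------


def mvi_from_components(headcount: float, intensity: float) -> float:
    """Adjusted headcount from its two components: MVI = H × A."""
    if not (0 <= headcount <= 1 and 0 <= intensity <= 1):
        raise ValueError("H and A must be proportions in [0, 1]")
    return headcount * intensity


def mvi_from_censored_headcounts(
    censored_headcounts: Mapping[str, float] | pd.Series,
    definition: IndexDefinition,
) -> float:
    """Decomposition identity: MVI = Σ_j w_j · CH_j."""
    ch = pd.Series(dict(censored_headcounts))
    missing = set(definition.indicators) ^ set(ch.index)
    if missing:
        raise ValueError(f"censored headcounts do not match indicators: {sorted(missing)}")
    return float(
        sum(float(definition.weights[j]) * float(ch[j]) for j in definition.indicators)
    )


def indicator_contributions(
    censored_headcounts: Mapping[str, float] | pd.Series,
    definition: IndexDefinition,
    mvi: float,
) -> pd.Series:
    """φ_j = w_j · CH_j / MVI, as proportions of the index.

    Undefined when MVI = 0: returns an empty Series and logs a note.
    """
    if mvi <= 0:
        logger.info("MVI is 0; indicator contributions are undefined")
        return pd.Series(dtype=float)
    ch = pd.Series(dict(censored_headcounts))
    return pd.Series(
        {
            j: float(definition.weights[j]) * float(ch[j]) / mvi
            for j in definition.indicators
        }
    )


def dimension_contributions(
    contribution: pd.Series, definition: IndexDefinition
) -> pd.Series:
    """Sum member-indicator contributions within each dimension."""
    if contribution.empty:
        return pd.Series(dtype=float)
    return pd.Series(
        {
            dim: float(contribution[list(members)].sum())
            for dim, members in definition.dimensions.items()
        }
    )


def _summarize(
    X: np.ndarray, scores: ScoreVector, definition: IndexDefinition
) -> AFSummary:
    n = X.shape[0]
    q = int(scores.vulnerable.sum())
    headcount = q / n
    intensity = float(scores.censored_score.sum() / q) if q > 0 else 0.0
    mvi = headcount * intensity
    severe = float(scores.severe.mean())
    ch = pd.Series(
        (X * scores.vulnerable[:, None]).mean(axis=0),
        index=list(definition.indicators),
    )
    contribution = indicator_contributions(ch, definition, mvi)
    return AFSummary(
        n=n,
        q=q,
        headcount=headcount,
        intensity=intensity,
        mvi=mvi,
        severe_headcount=severe,
        censored_headcount=ch,
        ch_among_vulnerable=ch / headcount if headcount > 0 else ch * np.nan,
        contribution=contribution,
        dimension_contribution=dimension_contributions(contribution, definition),
    )


def aggregate(
    indicators: pd.DataFrame,
    definition: IndexDefinition,
    subgroup: pd.Series | None = None,
    *,
    n_dropped: int = 0,
) -> AFResult:
    """Full AF aggregation, overall and (optionally) per subgroup.

    ``indicators`` must already be complete-case (no missing entries);
    use :meth:`DeprivationMatrix.complete_case_indicators` first.
    Subgroup summaries rerun the whole computation on each subset, so
    every invariant holds within subgroups too.
    """
    if len(indicators) < 1:
        raise ValueError("need at least one respondent")
    aligned = _check_columns(indicators, definition)
    scores = deprivation_scores(aligned, definition)
    X = aligned.to_numpy(dtype=np.int64)
    overall = _summarize(X, scores, definition)
    by_subgroup: dict[str, AFSummary] = {}
    if subgroup is not None:
        labels = pd.Series(subgroup)
        for label in sorted(labels.dropna().unique()):
            mask = (labels == label).to_numpy(dtype=bool)
            sub = aligned.loc[mask]
            if len(sub) == 0:
                logger.warning("subgroup %r is empty; skipped", label)
                continue
            by_subgroup[str(label)] = _summarize(
                sub.to_numpy(dtype=np.int64),
                deprivation_scores(sub, definition),
                definition,
            )
    return AFResult(overall=overall, by_subgroup=by_subgroup, n_dropped=n_dropped)
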