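"""Report tables and rounding rules.

All internal arithmetic stays at full precision; rounding happens only
here.  Indices are printed to 3 decimals and percentages to 1 decimal,
half away from zero (published tables use commercial rounding, not
banker's rounding).
"""
from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .af import AFResult, AFSummary
from .association import AssociationResult
from .definitions import DIMENSION_LABELS, INDICATOR_LABELS, IndexDefinition
from .indicators import OUTCOME_LABELS
from .robustness import RobustnessResult

__all__ = [
    "round_half_up",
    "round_index",
    "round_pct",
    "measures_table",
    "contributions_table",
    "robustness_table",
    "association_table",
]


def round_half_up(value: float, ndigits: int = 0) -> float:
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def round_index(value: float) -> float:
    return round_half_up(value, 3)


def round_pct(value: float) -> float:
    return round_half_up(value, 1)


def measures_table(result: AFResult, subgroup_order: list[str] | None = None) -> pd.DataFrame:
    """Headcount / intensity / MVI / severe headcount by subgroup + overall."""
    order = subgroup_order or sorted(result.by_subgroup)
    columns = {label: result.by_subgroup[label] for label in order}
    columns["Overall"] = result.overall

    def col(summary: AFSummary) -> list[float]:
        return [
            round_pct(summary.headcount * 100),
            round_pct(summary.intensity * 100),
            round_index(summary.mvi),
            round_pct(summary.severe_headcount * 100),
        ]

    return pd.DataFrame(
        {label: col(s) for label, s in columns.items()},
        index=[
            "Percentage multidimensionally vulnerable",
            "Average intensity of vulnerability",
            "Multidimensional vulnerability index (MVI)",
            "Percentage severely vulnerable",
        ],
    )


def contributions_table(summary: AFSummary, definition: IndexDefinition) -> pd.DataFrame:
    """Per-indicator contribution and censored headcounts, both normalisations."""
    rows = []
    for dim, members in definition.dimensions.items():
        for j in members:
            rows.append(
                {
                    "dimension": DIMENSION_LABELS.get(dim, dim),
                    "indicator": INDICATOR_LABELS.get(j, j),
                    "contribution_pct": (
                        round_pct(summary.contribution[j] * 100)
                        if not summary.contribution.empty
                        else float("nan")
                    ),
                    "censored_headcount_pct": round_pct(
                        summary.censored_headcount[j] * 100
                    ),
                    "pct_deprived_among_vulnerable": round_pct(
                        summary.ch_among_vulnerable[j] * 100
                    ),
                }
            )
    return pd.DataFrame(rows)


def robustness_table(result: RobustnessResult) -> pd.DataFrame:
    """Subgroup × k table of MVI values, rounded for printing."""
    table = result.mvi_table.copy()
    table.columns = [f"k = {k:g}" for k in result.k_grid]
    return table.map(round_index)


def association_table(results: dict[str, AssociationResult]) -> pd.DataFrame:
    rows = []
    for name, res in results.items():
        rows.append(
            {
                "outcome": OUTCOME_LABELS.get(name, name),
                "pct_nonvulnerable": round_pct(res.pct_nonvulnerable),
                "pct_vulnerable": round_pct(res.pct_vulnerable),
                "aor": round_half_up(res.aor, 2),
                "ci_low": round_half_up(res.ci_low, 2),
                "ci_high": round_half_up(res.ci_high, 2),
                "n": res.n_used,
            }
        )
    return pd.DataFrame(rows)
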