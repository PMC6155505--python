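"""Threshold robustness: MVI across a k-grid and ranking stability.

The choice of the identification cut-off k is normative; the analysis
is considered robust when the ordering of subgroups by MVI (and by
headcount) is stable as k moves over a grid.  Stability is quantified
with the Kendall tau-b rank correlation between the subgroup value
vectors at each pair of grid points; tau-b corrects for ties, which
matter with only a handful of subgroups.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import af
from .definitions import IndexDefinition, as_fraction

logger = logging.getLogger(__name__)

__all__ = ["RobustnessResult", "kendall_tau_b", "mvi_by_threshold"]

DEFAULT_K_GRID: tuple[float, ...] = (0.25, 0.33, 0.40, 0.50)


def kendall_tau_b(values_x: Sequence[float], values_y: Sequence[float]) -> float | None:
    """Kendall tau-b between two paired value lists.

    tau_b = (C − D) / sqrt((C + D + T_x)(C + D + T_y)) with C/D the
    concordant/discordant pair counts and T_x/T_y the pairs tied only in
    x / only in y.  Returns None (missing) when either list is constant,
    where the coefficient is undefined.
    """
    x = np.asarray(values_x, dtype=float)
    y = np.asarray(values_y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("inputs must be paired 1-d lists of equal length >= 2")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        return None
    tau = stats.kendalltau(x, y, variant="b").statistic
    return float(tau)


@dataclass
class RobustnessResult:
    """MVI/H by subgroup and threshold, rankings, and tau-b matrix."""

    k_grid: tuple[float, ...]
    mvi_table: pd.DataFrame        # subgroup rows × k columns
    headcount_table: pd.DataFrame
    rankings: dict[float, list[str]]  # per k, subgroups ordered by MVI desc
    tau_matrix: pd.DataFrame       # k × k pairwise tau-b of subgroup MVIs
    consistent: bool | None        # all pairwise tau-b >= threshold (None if any undefined)


def mvi_by_threshold(
    indicators: pd.DataFrame,
    definition: IndexDefinition,
    subgroup: pd.Series,
    k_grid: Sequence[float] = DEFAULT_K_GRID,
    *,
    consistency_threshold: float = 0.9,
) -> RobustnessResult:
    """Rerun the full AF aggregation at every threshold in ``k_grid``.

    ``k_grid`` values must lie in (0, 1] and be strictly increasing.
    Each cell of the output tables comes from a complete AF aggregation
    of that subgroup at that k, so monotonicity in k is inherited from
    the identification rule, not imposed.
    """
    ks = [float(k) for k in k_grid]
    if not ks or any(not (0 < k <= 1) for k in ks):
        raise ValueError("k-grid values must lie in (0, 1]")
    if any(b <= a for a, b in zip(ks, ks[1:])):
        raise ValueError("k-grid must be strictly increasing")

    labels = sorted(pd.Series(subgroup).dropna().unique())
    mvi = pd.DataFrame(index=[str(s) for s in labels], columns=ks, dtype=float)
    hc = mvi.copy()
    rankings: dict[float, list[str]] = {}
    for k in ks:
        result = af.aggregate(indicators, definition.with_k(as_fraction(k)), subgroup)
        for label in mvi.index:
            if label in result.by_subgroup:
                mvi.loc[label, k] = result.by_subgroup[label].mvi
                hc.loc[label, k] = result.by_subgroup[label].headcount
            else:
                logger.warning("subgroup %r empty at k=%s; cell missing", label, k)
        col = mvi[k]
        # order by MVI descending; ties broken alphabetically for determinism
        rankings[k] = sorted(col.index, key=lambda s: (-col[s], s))

    tau = pd.DataFrame(index=ks, columns=ks, dtype=float)
    for ka in ks:
        for kb in ks:
            if ka == kb:
                tau.loc[ka, kb] = 1.0
            elif len(labels) < 2:
                tau.loc[ka, kb] = np.nan  # ranking of one subgroup is vacuous
            else:
                t = kendall_tau_b(mvi[ka].to_numpy(), mvi[kb].to_numpy())
                tau.loc[ka, kb] = np.nan if t is None else t
    off_diag = tau.to_numpy()[~np.eye(len(ks), dtype=bool)]
    if np.isnan(off_diag).any():
        consistent: bool | None = None
    else:
        consistent = bool((off_diag >= consistency_threshold).all())
    return RobustnessResult(
        k_grid=tuple(ks),
        mvi_table=mvi,
        headcount_table=hc,
        rankings=rankings,
        tau_matrix=tau,
        consistent=consistent,
    )
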