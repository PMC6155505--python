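"""Independent brute-force oracles used only by the tests.

These loop over respondents/indicators/pairs with exact Fraction
arithmetic and share no code with the vectorised implementation.
"""
from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from typing import Sequence


def af_brute_force(
    rows: Sequence[Sequence[int]],
    weights: Sequence[Fraction],
    k: Fraction,
    severe_k: Fraction,
    tie_op: str = "ge",
) -> dict:
    """Exact AF measures by looping over respondents and indicators."""
    n = len(rows)
    scores = []
    for row in rows:
        c = Fraction(0)
        for w, x in zip(weights, row):
            if x:
                c += w
        scores.append(c)
    if tie_op == "ge":
        vulnerable = [c >= k for c in scores]
    else:
        vulnerable = [c > k for c in scores]
    q = sum(vulnerable)
    headcount = Fraction(q, n)
    if q:
        intensity = sum(c for c, v in zip(scores, vulnerable) if v) / q
    else:
        intensity = Fraction(0)
    censored_headcount = []
    for j in range(len(weights)):
        count = sum(1 for row, v in zip(rows, vulnerable) if v and row[j])
        censored_headcount.append(Fraction(count, n))
    return {
        "q": q,
        "headcount": headcount,
        "intensity": intensity,
        "mvi": headcount * intensity,
        "severe_headcount": Fraction(sum(1 for c in scores if c >= severe_k), n),
        "censored_headcount": censored_headcount,
    }


def tau_b_brute_force(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Kendall tau-b by enumerating every pair."""
    concordant = discordant = ties_x_only = ties_y_only = 0
    for (xi, yi), (xj, yj) in combinations(zip(x, y), 2):
        dx, dy = xi - xj, yi - yj
        if dx == 0 and dy == 0:
            continue
        if dx == 0:
            ties_x_only += 1
        elif dy == 0:
            ties_y_only += 1
        elif (dx > 0) == (dy > 0):
            concordant += 1
        else:
            discordant += 1
    denom_x = concordant + discordant + ties_x_only
    denom_y = concordant + discordant + ties_y_only
    if denom_x == 0 or denom_y == 0:
        return None
    return (concordant - discordant) / (denom_x * denom_y) ** 0.5
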