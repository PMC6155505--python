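"""Dual cut-off aggregation: weights, scores, measures, decomposition."""
from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mvindex import (
    IndexDefinition,
    aggregate,
    build_weights,
    deprivation_scores,
    indicator_contributions,
    mvi_from_censored_headcounts,
    mvi_from_components,
)
from mvindex.definitions import DIMENSIONS, INDICATORS

from _oracles import af_brute_force


def frame(rows, columns=INDICATORS) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=list(columns), dtype=np.int8)


# ---------------------------------------------------------------------------
# weights


def test_equal_nested_weights_for_the_4_5_4_3_structure():
    weights = build_weights(DIMENSIONS)
    per_dim = {
        "personal_attributes": Fraction(1, 16),
        "financial_security": Fraction(1, 20),
        "social_protection": Fraction(1, 16),
        "social_network": Fraction(1, 12),
    }
    for dim, members in DIMENSIONS.items():
        for j in members:
            assert weights[j] == per_dim[dim]
    assert sum(weights.values()) == 1


@pytest.mark.parametrize(
    "dimensions, expected",
    [
        ({"only": ("a",)}, {"a": Fraction(1)}),
        (
            {"d1": ("a", "b"), "d2": ("c", "d")},
            {j: Fraction(1, 4) for j in "abcd"},
        ),
    ],
)
def test_weight_edge_structures(dimensions, expected):
    assert build_weights(dimensions) == expected


def test_empty_dimension_rejected():
    with pytest.raises(ValueError, match="no indicators"):
        build_weights({"d1": ("a",), "d2": ()})


# ---------------------------------------------------------------------------
# scores


def test_score_normalization(definition):
    rows = frame([[1] * 16, [0] * 16])
    sv = deprivation_scores(rows, definition)
    assert sv.score[0] == 1.0
    assert sv.score[1] == 0.0 and not sv.vulnerable[1]


def test_three_network_deprivations_score_quarter_not_vulnerable(definition):
    row = {j: 0 for j in INDICATORS}
    for j in DIMENSIONS["social_network"]:
        row[j] = 1
    sv = deprivation_scores(frame([list(row.values())]), definition)
    assert sv.score[0] == pytest.approx(0.25)
    assert not sv.vulnerable[0]  # 0.25 < 1/3


def test_tie_with_k_follows_tie_operator():
    # personal block (4/16) + two financial indicators (2/20) = 0.35 > 1/3;
    # build the exact tie 80/240 = 1/3: 4 personal? 4/16=0.25, +1 network 1/12
    # = 1/3 exactly.
    row = {j: 0 for j in INDICATORS}
    for j in DIMENSIONS["personal_attributes"]:
        row[j] = 1
    row["no_co_membership"] = 1
    data = frame([list(row.values())])
    ge = deprivation_scores(data, IndexDefinition(tie_op="ge"))
    gt = deprivation_scores(data, IndexDefinition(tie_op="gt"))
    assert ge.score[0] == pytest.approx(1 / 3)
    assert ge.vulnerable[0] and not gt.vulnerable[0]


def test_column_mismatch_rejected(definition):
    bad = frame([[0] * 16]).rename(columns={"young_age": "typo"})
    with pytest.raises(ValueError, match="typo"):
        deprivation_scores(bad, definition)


# ---------------------------------------------------------------------------
# aggregation examples


def test_toy_population_with_scores_1_05_025_0(definition):
    personal = [1 if j in DIMENSIONS["personal_attributes"] else 0 for j in INDICATORS]
    financial = [1 if j in DIMENSIONS["financial_security"] else 0 for j in INDICATORS]
    rows = frame(
        [
            [1] * 16,                                    # c = 1.0
            [p or f for p, f in zip(personal, financial)],  # c = 0.5
            personal,                                    # c = 0.25
            [0] * 16,                                    # c = 0.0
        ]
    )
    result = aggregate(rows, definition).overall
    assert result.headcount == pytest.approx(0.5)
    assert result.intensity == pytest.approx(0.75)
    assert result.mvi == pytest.approx(0.375)


def test_nobody_deprived_gives_all_zero_and_empty_contributions(definition):
    result = aggregate(frame([[0] * 16] * 5), definition).overall
    assert result.headcount == result.intensity == result.mvi == 0
    assert result.severe_headcount == 0
    assert result.contribution.empty


def test_single_indicator_index_contributes_everything():
    d = IndexDefinition(dimensions={"only": ("no_insurance",)})
    contributions = indicator_contributions({"no_insurance": 0.4}, d, mvi=0.4)
    assert contributions["no_insurance"] == pytest.approx(1.0)


def test_mvi_from_components_validates_range():
    with pytest.raises(ValueError):
        mvi_from_components(1.2, 0.5)


# ---------------------------------------------------------------------------
# properties


matrices = st.integers(1, 30).flatmap(
    lambda n: st.lists(
        st.lists(st.integers(0, 1), min_size=16, max_size=16),
        min_size=n,
        max_size=n,
    )
)


@given(matrices)
def test_af_identities_hold_on_random_populations(rows):
    """MVI = H·A and MVI = Σ_j w_j·CH_j, contributions sum to 1, and the
    censored headcount is bounded by both H and the raw headcount."""
    definition = IndexDefinition()
    result = aggregate(frame(rows), definition).overall
    assert result.mvi == pytest.approx(result.headcount * result.intensity, abs=1e-12)
    assert result.mvi == pytest.approx(
        mvi_from_censored_headcounts(result.censored_headcount, definition), abs=1e-12
    )
    if result.mvi > 0:
        assert result.contribution.sum() == pytest.approx(1.0, abs=1e-9)
    assert result.severe_headcount <= result.headcount + 1e-12  # severe_k >= k
    raw = frame(rows).mean(axis=0)
    for j in INDICATORS:
        assert result.censored_headcount[j] <= min(result.headcount, raw[j]) + 1e-12


@given(matrices)
def test_headcount_and_mvi_decrease_in_k(rows):
    definition = IndexDefinition()
    grid = [0.1, 0.25, 1 / 3, 0.5, 0.75, 1.0]
    values = [
        aggregate(frame(rows), definition.with_k(Fraction(k).limit_denominator(100))).overall
        for k in grid
    ]
    for lo, hi in zip(values, values[1:]):
        assert lo.headcount >= hi.headcount - 1e-12
        assert lo.mvi >= hi.mvi - 1e-12


@given(matrices)
def test_union_and_intersection_limits(rows):
    definition = IndexDefinition()
    X = frame(rows)
    min_w = min(definition.weights.values())
    union = aggregate(X, definition.with_k(min_w)).overall
    assert union.headcount == pytest.approx((X.sum(axis=1) >= 1).mean())
    inter = aggregate(X, definition.with_k(1)).overall
    assert inter.headcount == pytest.approx((X.sum(axis=1) == 16).mean())


@given(matrices, st.data())
def test_dimensional_monotonicity(rows, data):
    """Adding a deprivation to an identified respondent never lowers MVI."""
    definition = IndexDefinition()
    X = frame(rows)
    before = aggregate(X, definition)
    sv = deprivation_scores(X, definition)
    candidates = [
        (i, j)
        for i in range(len(X))
        if sv.vulnerable[i]
        for j, name in enumerate(INDICATORS)
        if X.iloc[i, j] == 0
    ]
    if not candidates:
        return
    i, j = data.draw(st.sampled_from(candidates))
    X2 = X.copy()
    X2.iloc[i, j] = 1
    after = aggregate(X2, definition)
    assert after.overall.mvi >= before.overall.mvi - 1e-12


@given(matrices, st.data())
def test_population_decomposability_over_subgroups(rows, data):
    """Overall MVI equals the population-share-weighted mean of subgroup MVIs."""
    definition = IndexDefinition()
    X = frame(rows)
    labels = data.draw(
        st.lists(st.sampled_from(["a", "b", "c"]), min_size=len(X), max_size=len(X))
    )
    result = aggregate(X, definition, pd.Series(labels))
    weighted = sum(
        s.n / result.overall.n * s.mvi for s in result.by_subgroup.values()
    )
    assert result.overall.mvi == pytest.approx(weighted, abs=1e-12)


small_problems = st.tuples(
    st.integers(1, 8),   # respondents
    st.integers(1, 4),   # indicators
).flatmap(
    lambda shape: st.tuples(
        st.just(shape),
        st.lists(
            st.lists(st.integers(0, 1), min_size=shape[1], max_size=shape[1]),
            min_size=shape[0],
            max_size=shape[0],
        ),
        st.integers(1, shape[1]),  # size of the first dimension
    )
)


@given(small_problems, st.fractions(Fraction(1, 10), Fraction(1, 1)))
def test_matches_brute_force_oracle_on_small_problems(problem, k):
    (n, J), rows, split = problem
    names = [f"x{j}" for j in range(J)]
    dims = (
        {"d1": tuple(names[:split]), "d2": tuple(names[split:])}
        if split < J
        else {"d1": tuple(names)}
    )
    definition = IndexDefinition(dimensions=dims, k=k, severe_k=Fraction(1, 2))
    weights = [definition.weights[j] for j in definition.indicators]
    order = list(definition.indicators)
    rows_ordered = [
        [row[names.index(j)] for j in order] for row in rows
    ]
    expected = af_brute_force(rows_ordered, weights, k, Fraction(1, 2))
    result = aggregate(frame(rows_ordered, order), definition).overall
    assert result.q == expected["q"]
    assert result.headcount == pytest.approx(float(expected["headcount"]), abs=1e-12)
    assert result.intensity == pytest.approx(float(expected["intensity"]), abs=1e-12)
    assert result.mvi == pytest.approx(float(expected["mvi"]), abs=1e-12)
    assert result.severe_headcount == pytest.approx(
        float(expected["severe_headcount"]), abs=1e-12
    )
    for j, ch in zip(order, expected["censored_headcount"]):
        assert result.censored_headcount[j] == pytest.approx(float(ch), abs=1e-12)
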