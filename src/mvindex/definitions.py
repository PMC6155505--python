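"""Structure of the multidimensional vulnerability index (MVI).

The index is a two-level tree: *dimensions* at the top and binary
deprivation *indicators* underneath.  The default structure has four
dimensions — personal attributes, financial security, social protection,
and social support & network — holding 4, 5, 4 and 3 indicators
respectively, sixteen in total.

Equal nested weighting gives every dimension the same total weight 1/D
and splits it evenly among the dimension's m_d indicators, so an
indicator in a five-indicator dimension carries w = (1/4)(1/5) = 1/20.
Weights and cut-offs are kept as exact :class:`fractions.Fraction`
values: with rational weights the weighted deprivation score can tie
exactly with the identification cut-off k (e.g. c = 80/240 at k = 1/3),
and exact arithmetic makes the ≥ / > choice well-defined instead of a
floating-point accident.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping, Sequence

import yaml

__all__ = [
    "DIMENSIONS",
    "INDICATORS",
    "INDICATOR_LABELS",
    "DIMENSION_LABELS",
    "build_weights",
    "IndexDefinition",
    "as_fraction",
]

#: Canonical dimension -> indicator tree, in reporting order.
DIMENSIONS: dict[str, tuple[str, ...]] = {
    "personal_attributes": (
        "young_age",
        "street_solicitation",
        "high_dependency",
        "high_mobility",
    ),
    "financial_security": (
        "no_alternative_income",
        "no_savings_account",
        "no_savings_or_investment",
        "informal_loan",
        "no_insurance",
    ),
    "social_protection": (
        "no_id_card",
        "food_insecurity",
        "no_ration_card",
        "no_legal_training",
    ),
    "social_network": (
        "no_co_membership",
        "no_hiv_services",
        "no_crisis_support",
    ),
}

#: Canonical indicator order (concatenation of the dimension blocks).
INDICATORS: tuple[str, ...] = tuple(
    name for members in DIMENSIONS.values() for name in members
)

#: Human-readable component labels used in report tables.
INDICATOR_LABELS: dict[str, str] = {
    "young_age": "Age",
    "street_solicitation": "Place of solicitation",
    "high_dependency": "Degree of dependency",
    "high_mobility": "Mobility",
    "no_alternative_income": "Livelihood",
    "no_savings_account": "Savings account",
    "no_savings_or_investment": "Savings or investment",
    "informal_loan": "Indebtedness",
    "no_insurance": "Insurance",
    "no_id_card": "Citizen identity card",
    "food_insecurity": "Food security",
    "no_ration_card": "Ration card",
    "no_legal_training": "Legal rights",
    "no_co_membership": "Membership in CO",
    "no_hiv_services": "Access to HIV prevention services",
    "no_crisis_support": "Community coherence",
}

DIMENSION_LABELS: dict[str, str] = {
    "personal_attributes": "Personal attributes",
    "financial_security": "Financial security",
    "social_protection": "Social protection",
    "social_network": "Social support and network",
}


def as_fraction(value) -> Fraction:
    """Coerce ``value`` to an exact Fraction.

    Floats are parsed through their decimal repr so that a grid value
    written as 0.33 becomes the literal 33/100 rather than the binary
    float nearest to it.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, float):
        return Fraction(repr(value))
    return Fraction(value)


def build_weights(
    dimensions: Mapping[str, Sequence[str]],
) -> dict[str, Fraction]:
    """Equal nested weights for a dimension->indicator tree.

    Indicator j in dimension d receives w_j = (1/D)(1/m_d) where D is
    the number of dimensions and m_d the number of indicators in d; the
    weights sum exactly to 1.

    Raises
    ------
    ValueError
        If there are no dimensions, a dimension is empty, or an
        indicator name appears twice.
    """
    if not dimensions:
        raise ValueError("at least one dimension is required")
    n_dim = len(dimensions)
    weights: dict[str, Fraction] = {}
    for dim, members in dimensions.items():
        if not members:
            raise ValueError(f"dimension {dim!r} has no indicators")
        w = Fraction(1, n_dim) * Fraction(1, len(members))
        for name in members:
            if name in weights:
                raise ValueError(f"duplicate indicator name {name!r}")
            weights[name] = w
    assert sum(weights.values()) == 1
    return weights


@dataclass(frozen=True)
class IndexDefinition:
    """Dimension/indicator tree, weights and the dual cut-offs.

    Parameters
    ----------
    dimensions
        Ordered mapping dimension name -> ordered indicator names.
    weights
        Indicator -> weight, exact rationals summing to 1.  Defaults to
        equal nested weights over ``dimensions``.
    k
        Identification cut-off on the weighted deprivation score
        (default 1/3, stored exactly).
    severe_k
        Cut-off for severe vulnerability (default 1/2).
    tie_op
        Comparison used at the identification cut-off: ``"ge"``
        (score ≥ k, default, consistent with the "50% or more" severe
        rule) or ``"gt"``.  Severe identification always uses ≥.
    """

    dimensions: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DIMENSIONS)
    )
    weights: Mapping[str, Fraction] = None  # type: ignore[assignment]
    k: Fraction = Fraction(1, 3)
    severe_k: Fraction = Fraction(1, 2)
    tie_op: str = "ge"

    def __post_init__(self) -> None:
        dims = {d: tuple(m) for d, m in self.dimensions.items()}
        object.__setattr__(self, "dimensions", dims)
        if self.weights is None:
            object.__setattr__(self, "weights", build_weights(dims))
        else:
            object.__setattr__(
                self,
                "weights",
                {j: as_fraction(w) for j, w in self.weights.items()},
            )
        names = [n for members in dims.values() for n in members]
        if len(set(names)) != len(names):
            raise ValueError("indicator names are not unique")
        if set(self.weights) != set(names):
            missing = set(names) ^ set(self.weights)
            raise ValueError(f"weights do not match indicators: {sorted(missing)}")
        total = sum(self.weights.values())
        if total != 1:
            raise ValueError(f"weights must sum to 1 exactly, got {total}")
        for j, w in self.weights.items():
            if not (0 < w <= 1):
                raise ValueError(f"weight for {j!r} out of (0, 1]: {w}")
        object.__setattr__(self, "k", as_fraction(self.k))
        object.__setattr__(self, "severe_k", as_fraction(self.severe_k))
        for name, value in (("k", self.k), ("severe_k", self.severe_k)):
            if not (0 < value <= 1):
                raise ValueError(f"{name} must lie in (0, 1], got {value}")
        if self.tie_op not in ("ge", "gt"):
            raise ValueError(f"tie_op must be 'ge' or 'gt', got {self.tie_op!r}")

    # -- structure helpers -------------------------------------------------

    @property
    def indicators(self) -> tuple[str, ...]:
        """Indicator names in canonical (dimension-block) order."""
        return tuple(n for members in self.dimensions.values() for n in members)

    @property
    def dimension_of(self) -> dict[str, str]:
        return {
            name: dim
            for dim, members in self.dimensions.items()
            for name in members
        }

    def weight_array(self):
        import numpy as np

        return np.array([float(self.weights[j]) for j in self.indicators])

    # -- exact arithmetic --------------------------------------------------

    @property
    def common_denominator(self) -> int:
        """LCM of all weight and cut-off denominators.

        Scores expressed in units of 1/common_denominator are integers,
        so identification is an exact integer comparison.
        """
        den = math.lcm(*(w.denominator for w in self.weights.values()))
        return math.lcm(den, self.k.denominator, self.severe_k.denominator)

    def integer_weights(self):
        import numpy as np

        den = self.common_denominator
        return np.array(
            [int(self.weights[j] * den) for j in self.indicators], dtype=np.int64
        )

    def with_k(self, k) -> "IndexDefinition":
        return replace(self, k=as_fraction(k))

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "dimensions": {d: list(m) for d, m in self.dimensions.items()},
            "weights": {j: str(w) for j, w in self.weights.items()},
            "k": str(self.k),
            "severe_k": str(self.severe_k),
            "tie_op": self.tie_op,
        }

    @classmethod
    def from_dict(cls, data: Mapping) -> "IndexDefinition":
        return cls(
            dimensions={d: tuple(m) for d, m in data["dimensions"].items()},
            weights=(
                {j: Fraction(w) for j, w in data["weights"].items()}
                if data.get("weights")
                else None
            ),
            k=Fraction(data.get("k", "1/3")),
            severe_k=Fraction(data.get("severe_k", "1/2")),
            tie_op=data.get("tie_op", "ge"),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "IndexDefinition":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))
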