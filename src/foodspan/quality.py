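"""NutriGrade evidence-quality bookkeeping.

NutriGrade grades the meta-analytic evidence behind each food group on a
0-10 scale. Scores are inputs (read from the curve-metadata table); this
module maps them to the four published categories and combines them into
an overall score for a diet-change scenario by weighting each group's
score with the absolute LE contribution of changing that group alone.
"""

from __future__ import annotations

import enum
from typing import Mapping

from .food_model import FoodGroup


class QualityCategory(str, enum.Enum):
    VERY_LOW = "very_low"
    LOW = "low"
    MODERATE = "moderate"
    HIGH = "high"


# category -> [lower bound, upper bound]; boundaries belong to the upper class
_BOUNDS = (
    (4.0, QualityCategory.VERY_LOW),
    (6.0, QualityCategory.LOW),
    (8.0, QualityCategory.MODERATE),
    (10.0 + 1e-12, QualityCategory.HIGH),
)


def categorize(score: float) -> QualityCategory:
    """Map a NutriGrade score to its category.

    very_low [0, 4), low [4, 6), moderate [6, 8), high [8, 10].
    """
    if not (0.0 <= score <= 10.0):
        raise ValueError(f"NutriGrade score must lie in [0, 10], got {score}")
    for upper, cat in _BOUNDS:
        if score < upper:
            return cat
    raise AssertionError("unreachable")  # pragma: no cover


def weighted_overall(
    scores: Mapping[FoodGroup, float], contributions: Mapping[FoodGroup, float]
) -> float:
    """Mean NutriGrade score weighted by absolute per-group LE contribution.

    ``contributions`` are per-group LE gains in years (sign ignored); groups
    with zero contribution — including mortality-neutral ones — carry no
    weight. The result is invariant to rescaling all contributions.
    """
    num = 0.0
    den = 0.0
    for g, dle in contributions.items():
        w = abs(dle)
        if w == 0.0:
            continue
        if g not in scores:
            raise KeyError(f"no NutriGrade score for contributing group {g.value}")
        s = scores[g]
        if not (0.0 <= s <= 10.0):
            raise ValueError(f"NutriGrade score for {g.value} must lie in [0, 10], got {s}")
        num += s * w
        den += w
    if den == 0.0:
        raise ValueError("all contributions are zero; weighted score undefined")
    return num / den


#: NutriGrade scores of the meta-analyses behind each food group.
DEFAULT_NUTRIGRADE_SCORES: dict[FoodGroup, float] = {
    FoodGroup.WHOLE_GRAINS: 8.0,
    FoodGroup.FISH: 7.75,
    FoodGroup.PROCESSED_MEAT: 7.5,
    FoodGroup.NUTS: 7.0,
    FoodGroup.RED_MEAT: 6.5,
    FoodGroup.LEGUMES: 6.0,
    FoodGroup.MILK_DAIRY: 6.0,
    FoodGroup.VEGETABLES: 5.8,
    FoodGroup.FRUITS: 5.8,
    FoodGroup.SSB: 5.5,
    FoodGroup.REFINED_GRAINS: 5.0,
    FoodGroup.EGGS: 3.8,
    FoodGroup.WHITE_MEAT: 2.0,
    FoodGroup.ADDED_OILS: 5.0,
}
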