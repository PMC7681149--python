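"""School-meal food basket (SMFB) price-shock adjustment.

A basket is one week of school meals (six daily meals). When prices rise,
each meal is shrunk proportionally so that its cost at post-shock prices
equals its original pre-shock cost, preserving the community-designed
ingredient proportions exactly:

    r = pre-shock meal cost / post-shock meal cost
    adjusted grams_i = original grams_i x r

Because nutrients are linear in grams, every nutrient of the adjusted meal
is exactly r times the original — scaling ingredients and re-deriving
nutrients, or scaling the original nutrient vector by r, are the same
operation. The weekly comparison sums the six meals, whose ratios generally
differ, so per-nutrient weekly changes differ by nutrient according to
which meals carry it.
"""

from __future__ import annotations

import json
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, replace
from pathlib import Path

from .errors import ZeroCostChange, ZeroPostCost
from .nutrition import (
    FoodCompositionTable,
    NutrientVector,
    RequirementProfile,
    percent_of_reference,
    nutrients_of_quantity,
    sum_nutrients,
)
from .prices import PriceTable, cost_of_items


@dataclass(frozen=True)
class Ingredient:
    food_id: str
    grams: float  # per serving

    def __post_init__(self):
        if self.grams < 0:
            raise ValueError(f"{self.food_id}: grams must be >= 0")


@dataclass(frozen=True)
class Meal:
    """One daily meal: a named list of ingredients with fixed proportions."""

    name: str
    day_index: int
    ingredients: tuple[Ingredient, ...]

    def __post_init__(self):
        if not self.ingredients:
            raise ValueError(f"meal {self.name!r} has no ingredients")

    def quantities(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for ing in self.ingredients:
            out[ing.food_id] = out.get(ing.food_id, 0.0) + ing.grams
        return out

    def scaled(self, factor: float) -> "Meal":
        return replace(self, ingredients=tuple(
            replace(ing, grams=ing.grams * factor) for ing in self.ingredients
        ))


@dataclass(frozen=True)
class SchoolMealBasket:
    """One district's weekly basket: six meals with distinct day indices."""

    district: str
    meals: tuple[Meal, ...]

    def __post_init__(self):
        days = [m.day_index for m in self.meals]
        if len(set(days)) != len(days):
            raise ValueError(f"duplicate day_index in basket for {self.district!r}")

    @classmethod
    def from_json(cls, path: str | Path) -> "SchoolMealBasket":
        raw = json.loads(Path(path).read_text())
        meals = tuple(
            Meal(name=m["meal_name"], day_index=int(m["day_index"]),
                 ingredients=tuple(Ingredient(i["food_id"], float(i["grams"]))
                                   for i in m["ingredients"]))
            for m in raw["meals"]
        )
        return cls(district=raw["district"], meals=meals)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "district": self.district,
            "meals": [
                {"meal_name": m.name, "day_index": m.day_index,
                 "ingredients": [{"food_id": i.food_id, "grams": i.grams}
                                 for i in m.ingredients]}
                for m in self.meals
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def meal_cost(meal: Meal, prices: PriceTable, district: str, period: str,
              **cost_kwargs) -> float:
    """Per-serving cost of one meal in NPR."""
    return cost_of_items(meal.quantities(), prices, district, period, **cost_kwargs)


def meal_nutrients(meal: Meal, fct: FoodCompositionTable) -> NutrientVector:
    return sum_nutrients(
        nutrients_of_quantity(fct.resolve(ing.food_id), ing.grams)
        for ing in meal.ingredients
    )


@dataclass(frozen=True)
class MealAdjustment:
    """One meal's proportional adjustment: r = pre_cost / post_cost."""

    original: Meal
    adjusted: Meal
    pre_cost: float
    post_cost: float
    ratio: float
    deflation: bool  # ratio > 1: prices fell, quantities scale up


def adjust_meal(meal: Meal, prices: PriceTable, district: str,
                **cost_kwargs) -> MealAdjustment:
    """Scale a meal by its cost ratio so its post-price cost equals its pre cost.

    Every ingredient is multiplied by r = pre_cost/post_cost, so proportions
    are preserved exactly and the adjusted meal costs, at post prices,
    precisely what the original cost at pre prices. Deflation (r > 1) scales
    quantities up and is flagged, not clamped.
    """
    pre = meal_cost(meal, prices, district, "pre")
    post = meal_cost(meal, prices, district, "post", **cost_kwargs)
    if post <= 0:
        raise ZeroPostCost(f"meal {meal.name!r}: post-period cost is {post}")
    ratio = pre / post
    return MealAdjustment(original=meal, adjusted=meal.scaled(ratio),
                          pre_cost=pre, post_cost=post, ratio=ratio,
                          deflation=ratio > 1.0)


def weekly_nutrient_supply(basket: SchoolMealBasket | Iterable[Meal],
                           fct: FoodCompositionTable) -> NutrientVector:
    """Total nutrients over the basket's week (sum over meals)."""
    meals: Sequence[Meal] = basket.meals if isinstance(basket, SchoolMealBasket) else tuple(basket)
    return sum_nutrients(meal_nutrients(m, fct) for m in meals)


@dataclass(frozen=True)
class SmfbResult:
    """Weekly pre/post comparison of a school-meal basket under a price shock.

    ``pct_decrease`` is 100 x (pre - post)/pre per nutrient (positive =
    supply fell); ``rda_pre``/``rda_post`` are %RDA over ``days`` days.
    The unit cost is the mean of the per-meal costs.
    """

    district: str
    meals: tuple[MealAdjustment, ...]
    weekly_pre: NutrientVector
    weekly_post: NutrientVector
    pct_decrease: dict[str, float]
    rda_pre: dict[str, float]
    rda_post: dict[str, float]
    unit_cost_pre: float
    unit_cost_post: float
    unit_cost_pct_increase: float
    days: int = 6

    def to_dict(self) -> dict:
        return {
            "district": self.district,
            "unit_cost": {"pre": self.unit_cost_pre, "post": self.unit_cost_post,
                          "pct_increase": self.unit_cost_pct_increase},
            "weekly_pre": self.weekly_pre.to_dict(),
            "weekly_post": self.weekly_post.to_dict(),
            "pct_decrease": dict(self.pct_decrease),
            "rda_pre": dict(self.rda_pre),
            "rda_post": dict(self.rda_post),
            "meal_ratios": {m.original.name: m.ratio for m in self.meals},
            "days": self.days,
        }


def compare_smfb(basket: SchoolMealBasket, prices: PriceTable,
                 fct: FoodCompositionTable, requirement: RequirementProfile,
                 district: str | None = None, days: int = 6,
                 **cost_kwargs) -> SmfbResult:
    """Adjust every meal in the basket and compare weekly nutrient supply.

    Each meal gets its own cost ratio; the weekly post-shock supply is the
    ratio-weighted mix of meal contributions. %RDA uses the cumulative
    reference over ``days`` days, so the relative change in %RDA equals the
    relative change in intake for every nutrient (same denominator).
    """
    district = district or basket.district
    adjustments = tuple(adjust_meal(m, prices, district, **cost_kwargs)
                        for m in basket.meals)
    weekly_pre = weekly_nutrient_supply((a.original for a in adjustments), fct)
    weekly_post = weekly_nutrient_supply((a.adjusted for a in adjustments), fct)
    pct_decrease = {
        n: 100.0 * (weekly_pre[n] - weekly_post[n]) / weekly_pre[n] if weekly_pre[n] > 0 else 0.0
        for n in weekly_pre
    }
    unit_pre = sum(a.pre_cost for a in adjustments) / len(adjustments)
    unit_post = sum(a.post_cost for a in adjustments) / len(adjustments)
    return SmfbResult(
        district=district, meals=adjustments,
        weekly_pre=weekly_pre, weekly_post=weekly_post,
        pct_decrease=pct_decrease,
        rda_pre=percent_of_reference(weekly_pre, requirement, days=days),
        rda_post=percent_of_reference(weekly_post, requirement, days=days),
        unit_cost_pre=unit_pre, unit_cost_post=unit_post,
        unit_cost_pct_increase=100.0 * (unit_post - unit_pre) / unit_pre,
        days=days,
    )


def unit_cost_sensitivity(result: SmfbResult, delta: float = 1.0) -> dict[str, float]:
    """Percent nutrient decrease attributable to a ``delta``-NPR unit-cost rise.

    Linear attribution: observed percent decrease divided by the observed
    unit-cost increase, rescaled to ``delta`` NPR (default 1 NPR).
    """
    rise = result.unit_cost_post - result.unit_cost_pre
    if rise <= 0:
        raise ZeroCostChange(f"unit cost did not increase (change {rise:.4f} NPR)")
    return {n: pct / rise * delta for n, pct in result.pct_decrease.items()}
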