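"""Typical household food basket (THFB) coping-strategy adjustment.

Models how a poor household claws back a food-price shock while keeping its
daily food budget fixed. The post-shock basket costs D NPR/day more than it
did pre-shock; that excess is removed by cutting expenditure on foods
according to coping weights W per food class (fruits & dairy 2.5,
vegetables 2.0, roots/tubers/pulses 1.0, cereals 0.5; oil and sugar are
protected, W = 0, on the assumption that cheap calories are kept).

The allocation interprets W as relative sacrifice propensity: item i's
expenditure cut is

    reduction_i = D * W_c(i) * e_i / sum_j W_c(j) * e_j

where e_i is the item's post-shock daily expenditure. The cuts sum to D
exactly, so the adjusted basket costs, at post-shock prices, precisely the
pre-shock amount; equal weights reduce to plain proportional cuts.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import AllWeightsZero, InfeasibleReduction, ZeroCostChange
from .nutrition import (
    FoodCompositionTable,
    Household,
    NutrientVector,
    RequirementProfile,
    nutrients_of_quantity,
    percent_of_reference,
    sum_nutrients,
    weight_class,
)
from .prices import PriceTable, cost_of_items

#: Coping weights per expenditure-reduction class (0 = protected).
DEFAULT_WEIGHTS: dict[str, float] = {
    "fruits_dairy": 2.5,
    "vegetables": 2.0,
    "roots_pulses": 1.0,
    "cereals": 0.5,
    "protected": 0.0,
}

_FEASIBILITY_TOL = 1e-9


def validate_weights(weights: Mapping[str, float]) -> dict[str, float]:
    w = {k: float(v) for k, v in weights.items()}
    if any(v < 0 for v in w.values()):
        raise ValueError("reduction weights must be >= 0")
    if not any(v > 0 for v in w.values()):
        raise ValueError("at least one weight class must be > 0")
    return w


@dataclass(frozen=True)
class HouseholdBasket:
    """Daily grams of each food a household consumes, with fine-group labels."""

    district: str
    items: Mapping[str, float]          # food_id -> grams per day
    groups: Mapping[str, str]           # food_id -> fine group label
    household: Household | None = None

    def __post_init__(self):
        for fid, grams in self.items.items():
            if grams < 0:
                raise ValueError(f"{fid}: grams must be >= 0")
            if fid not in self.groups:
                raise ValueError(f"{fid}: no fine-group label")

    def weight_class_of(self, food_id: str) -> str:
        return weight_class(self.groups[food_id])

    @classmethod
    def from_csv(cls, path: str | Path, fct: FoodCompositionTable,
                 district: str | None = None,
                 household: Household | None = None) -> "HouseholdBasket":
        df = pd.read_csv(path, dtype={"district": str, "food_id": str})
        if district is not None:
            df = df[df["district"] == district]
        elif df["district"].nunique() == 1:
            district = df["district"].iloc[0]
        else:
            raise ValueError("basket CSV spans several districts; pass district=")
        items = dict(zip(df["food_id"], df["grams_per_day"].astype(float)))
        groups = {fid: fct.group_of(fid) for fid in items}
        return cls(district=district, items=items, groups=groups, household=household)

    def nutrients(self, fct: FoodCompositionTable) -> NutrientVector:
        return sum_nutrients(
            nutrients_of_quantity(fct.resolve(fid), grams)
            for fid, grams in self.items.items()
        )


def basket_cost(basket: HouseholdBasket, prices: PriceTable, period: str,
                **cost_kwargs) -> float:
    return cost_of_items(basket.items, prices, basket.district, period, **cost_kwargs)


def cost_difference(basket: HouseholdBasket, prices: PriceTable,
                    **cost_kwargs) -> float:
    """D = post-shock daily cost minus pre-shock daily cost, in NPR."""
    return (basket_cost(basket, prices, "post", **cost_kwargs)
            - basket_cost(basket, prices, "pre"))


def weighted_reductions(basket: HouseholdBasket, prices: PriceTable,
                        weights: Mapping[str, float], d: float, *,
                        redistribute: bool = False) -> dict[str, float]:
    """Per-item expenditure cuts (NPR/day) summing exactly to ``d``.

    Allocation is proportional to W x post-shock expenditure. A cut larger
    than the item's own expenditure raises :class:`InfeasibleReduction`
    unless ``redistribute=True``, which caps exhausted items at their full
    expenditure and re-allocates the remainder over the rest (an extension
    beyond the plain weighted scheme).
    """
    weights = validate_weights(weights)
    if d < 0:
        raise ValueError("cost difference must be >= 0 for reduction allocation")
    expenditure = {
        fid: grams / 1000.0 * prices.price(basket.district, "post", fid)
        for fid, grams in basket.items.items() if grams > 0
    }
    reductions = {fid: 0.0 for fid in basket.items}
    if d == 0:
        return reductions

    active = {fid: weights[basket.weight_class_of(fid)] * e
              for fid, e in expenditure.items()
              if weights[basket.weight_class_of(fid)] > 0}
    if not active:
        raise AllWeightsZero("no item carries a positive reduction weight")
    remaining = d
    while True:
        pool = sum(active.values())
        if pool <= 0:
            # every weighted item already cut to zero expenditure
            raise InfeasibleReduction({"<weighted pool>": (remaining, 0.0)})
        share = {fid: remaining * we / pool for fid, we in active.items()}
        over = {fid: (reductions[fid] + share[fid], expenditure[fid])
                for fid in share
                if reductions[fid] + share[fid] > expenditure[fid] + _FEASIBILITY_TOL}
        if not over:
            for fid, cut in share.items():
                reductions[fid] += cut
            return reductions
        if not redistribute:
            raise InfeasibleReduction(over)
        # cap exhausted items at full expenditure, re-allocate the rest
        for fid in over:
            remaining -= expenditure[fid] - reductions[fid]
            reductions[fid] = expenditure[fid]
            del active[fid]
        if remaining <= _FEASIBILITY_TOL:
            return reductions


def apply_reductions(basket: HouseholdBasket, reductions: Mapping[str, float],
                     prices: PriceTable) -> HouseholdBasket:
    """Convert expenditure cuts back into adjusted daily grams.

    new grams_i = 1000 x (e_i - reduction_i) / post price_i; protected items
    (reduction 0) keep their grams bit-identical.
    """
    new_items: dict[str, float] = {}
    for fid, grams in basket.items.items():
        cut = reductions.get(fid, 0.0)
        if cut == 0.0:
            new_items[fid] = grams
            continue
        price = prices.price(basket.district, "post", fid)
        e_i = grams / 1000.0 * price
        new_e = e_i - cut
        if new_e < -_FEASIBILITY_TOL:
            raise InfeasibleReduction({fid: (cut, e_i)})
        new_items[fid] = max(new_e, 0.0) * 1000.0 / price
    return HouseholdBasket(district=basket.district, items=new_items,
                           groups=dict(basket.groups), household=basket.household)


@dataclass(frozen=True)
class ThfbResult:
    """Daily pre/post comparison of a household basket under a price shock."""

    district: str
    basket_pre: HouseholdBasket
    basket_post: HouseholdBasket
    cost_pre: float
    cost_post: float
    cost_pct_increase: float
    cost_difference: float
    reductions: dict[str, float]
    nutrients_pre: NutrientVector
    nutrients_post: NutrientVector
    pct_decrease: dict[str, float]
    rda_pre: dict[str, float]
    rda_post: dict[str, float]
    days: int = 1

    def to_dict(self) -> dict:
        return {
            "district": self.district,
            "cost": {"pre": self.cost_pre, "post": self.cost_post,
                     "pct_increase": self.cost_pct_increase,
                     "difference": self.cost_difference},
            "reductions_npr": dict(self.reductions),
            "grams_pre": dict(self.basket_pre.items),
            "grams_post": dict(self.basket_post.items),
            "nutrients_pre": self.nutrients_pre.to_dict(),
            "nutrients_post": self.nutrients_post.to_dict(),
            "pct_decrease": dict(self.pct_decrease),
            "rda_pre": dict(self.rda_pre),
            "rda_post": dict(self.rda_post),
            "days": self.days,
        }


def compare_thfb(basket: HouseholdBasket, prices: PriceTable,
                 fct: FoodCompositionTable, requirement: RequirementProfile,
                 weights: Mapping[str, float] = DEFAULT_WEIGHTS, *,
                 days: int = 1, redistribute: bool = False,
                 adjust_deflation: bool = False, **cost_kwargs) -> ThfbResult:
    """Full household coping chain: D -> weighted cuts -> adjusted grams -> nutrients.

    %RDA compares the daily basket to the household's summed daily
    requirement (``days=1``). If the basket got cheaper (D <= 0) the basket
    is left unchanged by default — coping is one-directional — unless
    ``adjust_deflation=True`` scales consumption up proportionally.
    """
    cost_pre = basket_cost(basket, prices, "pre")
    cost_post = basket_cost(basket, prices, "post", **cost_kwargs)
    d = cost_post - cost_pre
    if d > 0:
        reductions = weighted_reductions(basket, prices, weights, d,
                                         redistribute=redistribute)
        adjusted = apply_reductions(basket, reductions, prices)
    elif adjust_deflation and d < 0:
        scale = cost_pre / cost_post
        adjusted = HouseholdBasket(
            district=basket.district,
            items={fid: g * scale for fid, g in basket.items.items()},
            groups=dict(basket.groups), household=basket.household)
        reductions = {fid: 0.0 for fid in basket.items}
    else:
        adjusted = basket
        reductions = {fid: 0.0 for fid in basket.items}

    pre_vec = basket.nutrients(fct)
    post_vec = adjusted.nutrients(fct)
    pct_decrease = {
        n: 100.0 * (pre_vec[n] - post_vec[n]) / pre_vec[n] if pre_vec[n] > 0 else 0.0
        for n in pre_vec
    }
    return ThfbResult(
        district=basket.district, basket_pre=basket, basket_post=adjusted,
        cost_pre=cost_pre, cost_post=cost_post,
        cost_pct_increase=100.0 * d / cost_pre, cost_difference=d,
        reductions=reductions,
        nutrients_pre=pre_vec, nutrients_post=post_vec,
        pct_decrease=pct_decrease,
        rda_pre=percent_of_reference(pre_vec, requirement, days=days),
        rda_post=percent_of_reference(post_vec, requirement, days=days),
        days=days,
    )


def unit_sensitivity_10npr(result: ThfbResult, delta: float = 10.0) -> dict[str, float]:
    """Percent nutrient decrease per ``delta``-NPR rise in daily basket cost.

    The 10 NPR default reflects the household budget scale (vs 1 NPR for a
    single school meal); ``delta=1`` reproduces the per-meal convention.
    """
    if result.cost_difference <= 0:
        raise ZeroCostChange(
            f"basket cost did not increase (D = {result.cost_difference:.4f} NPR)")
    return {n: pct / result.cost_difference * delta
            for n, pct in result.pct_decrease.items()}
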