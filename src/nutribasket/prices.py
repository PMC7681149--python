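"""Two-period commodity price tables and price-change analysis.

Prices are NPR per kg, keyed by (district, period, food_id) with the two
named periods ``pre`` (before the shock) and ``post`` (after). Group-level
change follows the mean-of-prices convention: the group's pre and post
prices are averaged (unweighted) and the change is the relative change of
those means. Item-level changes are exposed separately for intra-group
heterogeneity analysis.
"""

from __future__ import annotations

import json
import logging
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .errors import EmptyGroup, EmptySeries, MissingPeriod, MissingPrice

logger = logging.getLogger(__name__)

PERIODS = ("pre", "post")


@dataclass(frozen=True)
class PriceRecord:
    food_id: str
    district: str
    period: str
    price: float  # NPR per kg

    def __post_init__(self):
        if self.period not in PERIODS:
            raise ValueError(f"period must be one of {PERIODS}, got {self.period!r}")
        if self.price <= 0:
            raise ValueError(f"price must be > 0, got {self.price}")


class PriceTable:
    """Collection of price records indexed by (district, period, food_id)."""

    def __init__(self, records: Iterable[PriceRecord] = ()):
        self._prices: dict[tuple[str, str, str], float] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: PriceRecord) -> None:
        key = (rec.district, rec.period, rec.food_id)
        if key in self._prices:
            raise ValueError(f"duplicate price record for {key}")
        self._prices[key] = rec.price

    @classmethod
    def from_csv(cls, path: str | Path) -> "PriceTable":
        df = pd.read_csv(path, dtype={"district": str, "period": str, "food_id": str})
        required = {"district", "period", "food_id", "price_npr_per_kg"}
        if not required.issubset(df.columns):
            raise ValueError(f"price CSV {path}: needs columns {sorted(required)}")
        return cls(
            PriceRecord(food_id=r.food_id, district=r.district, period=r.period,
                        price=float(r.price_npr_per_kg))
            for r in df.itertuples()
        )

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"district": d, "period": p, "food_id": f, "price_npr_per_kg": price}
            for (d, p, f), price in sorted(self._prices.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)

    def get(self, district: str, period: str, food_id: str) -> float | None:
        return self._prices.get((district, period, food_id))

    def price(self, district: str, period: str, food_id: str) -> float:
        val = self.get(district, period, food_id)
        if val is None:
            raise MissingPrice(district, period, [food_id])
        return val

    def districts(self) -> list[str]:
        return sorted({d for d, _, _ in self._prices})

    def foods(self, district: str, period: str | None = None) -> list[str]:
        if period is None:
            return sorted({f for d, _, f in self._prices if d == district})
        return sorted({f for d, p, f in self._prices if d == district and p == period})

    def __len__(self) -> int:
        return len(self._prices)


@dataclass(frozen=True)
class InflationSeries:
    """Ordered monthly inflation rates (fractions) between two months."""

    monthly_rates: tuple[float, ...]
    start_month: str = ""
    end_month: str = ""

    @classmethod
    def from_json(cls, path: str | Path) -> "InflationSeries":
        raw = json.loads(Path(path).read_text())
        return cls(monthly_rates=tuple(float(r) for r in raw["monthly_rates"]),
                   start_month=str(raw.get("start_month", "")),
                   end_month=str(raw.get("end_month", "")))


def inflation_adjust(price: float, monthly_rates: Sequence[float] | InflationSeries) -> float:
    """Compound a base price forward through a series of monthly inflation rates."""
    if isinstance(monthly_rates, InflationSeries):
        monthly_rates = monthly_rates.monthly_rates
    rates = list(monthly_rates)
    if not rates:
        raise EmptySeries("no monthly rates supplied")
    adjusted = price
    for rate in rates:
        if rate <= -1:
            raise ValueError(f"monthly rate must be > -1, got {rate}")
        adjusted *= 1.0 + rate
    return adjusted


def item_price_change(table: PriceTable, district: str, food_id: str) -> float:
    """Percent change of a single food's price between the two periods."""
    pre = table.get(district, "pre", food_id)
    post = table.get(district, "post", food_id)
    if pre is None or post is None:
        missing = [p for p, v in (("pre", pre), ("post", post)) if v is None]
        raise MissingPeriod(f"{food_id} in {district}: no {' or '.join(missing)} price")
    return 100.0 * (post - pre) / pre


@dataclass(frozen=True)
class GroupPriceChange:
    """Result of a group-level price-change computation.

    ``percent`` is the relative change of the unweighted group mean price;
    ``skipped`` lists foods excluded for lacking one of the two periods.
    """

    district: str
    group: str
    percent: float
    mean_pre: float
    mean_post: float
    foods: tuple[str, ...]
    skipped: tuple[str, ...]


def group_price_change(table: PriceTable, district: str, group: str,
                       price_groups: Mapping[str, str]) -> GroupPriceChange:
    """Percent change of the unweighted mean price of a food group.

    ``price_groups`` maps food_id -> price-analysis group (normally from
    :meth:`FoodCompositionTable.price_groups`). Foods missing either period
    are excluded and reported in ``skipped``.
    """
    members = sorted(f for f in table.foods(district) if price_groups.get(f) == group)
    included, skipped = [], []
    for fid in members:
        pre = table.get(district, "pre", fid)
        post = table.get(district, "post", fid)
        if pre is None or post is None:
            skipped.append(fid)
        else:
            included.append((fid, pre, post))
    if not included:
        raise EmptyGroup(f"group {group!r} has no two-period foods in {district!r}")
    if skipped:
        logger.warning("group %s in %s: excluded %s (missing a period)",
                       group, district, skipped)
    mean_pre = sum(pre for _, pre, _ in included) / len(included)
    mean_post = sum(post for _, _, post in included) / len(included)
    return GroupPriceChange(
        district=district, group=group,
        percent=100.0 * (mean_post - mean_pre) / mean_pre,
        mean_pre=mean_pre, mean_post=mean_post,
        foods=tuple(fid for fid, _, _ in included), skipped=tuple(skipped),
    )


def cost_of_items(quantities: Mapping[str, float], table: PriceTable,
                  district: str, period: str, *,
                  missing_policy: str = "error",
                  carried: list[str] | None = None) -> float:
    """Cost in NPR of a set of daily/meal quantities (grams) at period prices.

    ``missing_policy="carry_pre"`` substitutes the pre price for a food with
    no post price (logged, and appended to ``carried`` if given); the default
    is a hard :class:`MissingPrice` error — silent imputation would bias the
    measured inflation downward.
    """
    if missing_policy not in ("error", "carry_pre"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    total = 0.0
    unpriced: list[str] = []
    for food_id, grams in quantities.items():
        if grams < 0:
            raise ValueError(f"{food_id}: grams must be >= 0")
        if grams == 0:
            continue
        price = table.get(district, period, food_id)
        if price is None and missing_policy == "carry_pre" and period == "post":
            price = table.get(district, "pre", food_id)
            if price is not None:
                logger.warning("carry_pre: using pre price for %s in %s", food_id, district)
                if carried is not None:
                    carried.append(food_id)
        if price is None:
            unpriced.append(food_id)
            continue
        total += grams / 1000.0 * price
    if unpriced:
        raise MissingPrice(district, period, unpriced)
    return total
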