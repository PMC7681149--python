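"""Exception hierarchy for the nutribasket pipeline.

Every error raised by the library derives from :class:`NutribasketError`,
so callers can catch one base class at the CLI boundary.
"""


class NutribasketError(Exception):
    """Base class for all nutribasket errors."""


class ConfigError(NutribasketError):
    """A run configuration is invalid (missing file, unknown district, ...)."""


# --- food composition -------------------------------------------------------

class UnknownFood(NutribasketError):
    """A food id is absent from the composition table and its whole fallback chain."""


class IncompleteNutrients(NutribasketError):
    """A nutrient component is missing from every table in the fallback chain."""

    def __init__(self, food_id: str, missing: list[str]):
        self.food_id = food_id
        self.missing = list(missing)
        super().__init__(f"food {food_id!r}: no value anywhere for {', '.join(self.missing)}")


class NegativeQuantity(NutribasketError):
    """A gram quantity was negative."""


# --- requirements -----------------------------------------------------------

class MissingReference(NutribasketError):
    """No reference-intake stratum covers the person's age/sex."""


class ZeroReference(NutribasketError):
    """A reference intake of zero makes a percentage undefined."""


# --- prices -----------------------------------------------------------------

class EmptySeries(NutribasketError):
    """Inflation adjustment called with no monthly rates."""


class EmptyGroup(NutribasketError):
    """No food in the group has prices for both periods in the district."""


class MissingPeriod(NutribasketError):
    """A food lacks a price record for one of the two periods."""


class MissingPrice(NutribasketError):
    """One or more basket foods have no price in the requested (district, period)."""

    def __init__(self, district: str, period: str, foods: list[str]):
        self.district = district
        self.period = period
        self.foods = list(foods)
        super().__init__(
            f"no {period!r} price in district {district!r} for: {', '.join(self.foods)}"
        )


# --- basket adjustment ------------------------------------------------------

class ZeroPostCost(NutribasketError):
    """A meal costs nothing at post-shock prices, so the cost ratio is undefined."""


class AllWeightsZero(NutribasketError):
    """Every item in the basket is protected; the cost difference cannot be absorbed."""


class InfeasibleReduction(NutribasketError):
    """A computed expenditure reduction exceeds the item's own expenditure."""

    def __init__(self, offenders: dict[str, tuple[float, float]]):
        self.offenders = dict(offenders)
        detail = "; ".join(
            f"{fid}: reduction {red:.2f} > expenditure {exp:.2f}"
            for fid, (red, exp) in self.offenders.items()
        )
        super().__init__(f"cost difference too large for the weighted pool ({detail})")


class ZeroCostChange(NutribasketError):
    """Sensitivity per unit cost is undefined when the cost did not increase."""
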