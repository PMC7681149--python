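"""Seeded synthetic scenarios: composition tables, two-period prices with
known group inflation, school-meal and household baskets, and reference
configs, with ground truth recorded for recovery tests.

The generator emulates the structure of a district food-price survey:
roughly 26 commodities spanning five price-analysis groups (plus oil and
sugar for basket costing), group-level inflation with multiplicative
item-level heterogeneity, a six-meal weekly school basket and a six-member
poorest-quintile household basket. Default group inflations are the
study-condition averages: pulses +18 %, vegetables & fruits +14 %, roots &
tubers and cereals +10 %, animal proteins +2 %. Nutrient ranges are
documented synthetic constants with realistic group signatures (cereals
zinc-rich, dairy and leafy vegetables vitamin-A-rich, pulses protein- and
iron-rich); they make no claim of matching any national composition table.

Everything is a pure function of the :class:`ScenarioSpec` seed.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np

from .nutrition import (
    DEFAULT_NUTRIENTS,
    FoodCompositionTable,
    Household,
    PersonProfile,
    price_group,
)
from .prices import PriceRecord, PriceTable
from .smfb import Ingredient, Meal, SchoolMealBasket
from .thfb import DEFAULT_WEIGHTS, HouseholdBasket

#: Default group-level inflation fractions (post = pre x (1 + g) x noise).
DEFAULT_GROUP_INFLATION: dict[str, float] = {
    "cereals": 0.10,
    "pulses": 0.18,
    "veg_fruits": 0.14,
    "roots_tubers": 0.10,
    "animal_proteins": 0.02,
    "oils_sugar": 0.08,
}

#: Synthetic per-100 g nutrient ranges (low, high) per fine group.
#: Deliberately coarse; only the group *signatures* matter for tests.
NUTRIENT_RANGES: dict[str, dict[str, tuple[float, float]]] = {
    "cereals_grains":      {"energy_kcal": (330, 365), "protein_g": (7, 12),  "fat_g": (1, 3),
                            "vitamin_a_mcg": (0, 10),   "vitamin_c_mg": (0, 1), "iron_mg": (2, 5),
                            "zinc_mg": (2.0, 4.0),      "calcium_mg": (10, 50)},
    "pulses_legumes_nuts": {"energy_kcal": (320, 360), "protein_g": (20, 26), "fat_g": (1, 6),
                            "vitamin_a_mcg": (0, 30),   "vitamin_c_mg": (0, 5), "iron_mg": (5, 9),
                            "zinc_mg": (2.5, 4.0),      "calcium_mg": (50, 150)},
    "vegetables":          {"energy_kcal": (20, 60),   "protein_g": (1, 4),   "fat_g": (0, 1),
                            "vitamin_a_mcg": (50, 800), "vitamin_c_mg": (10, 100), "iron_mg": (0.5, 3),
                            "zinc_mg": (0.2, 0.8),      "calcium_mg": (20, 150)},
    "fruits":              {"energy_kcal": (40, 90),   "protein_g": (0.5, 1.5), "fat_g": (0, 0.5),
                            "vitamin_a_mcg": (10, 300), "vitamin_c_mg": (20, 60), "iron_mg": (0.3, 1),
                            "zinc_mg": (0.1, 0.4),      "calcium_mg": (5, 30)},
    "roots_tubers":        {"energy_kcal": (70, 120),  "protein_g": (1, 2.5), "fat_g": (0, 0.3),
                            "vitamin_a_mcg": (0, 50),   "vitamin_c_mg": (5, 30), "iron_mg": (0.5, 1.5),
                            "zinc_mg": (0.3, 0.6),      "calcium_mg": (10, 40)},
    "animal_protein":      {"energy_kcal": (120, 250), "protein_g": (15, 25), "fat_g": (5, 20),
                            "vitamin_a_mcg": (10, 100), "vitamin_c_mg": (0, 1), "iron_mg": (1, 3),
                            "zinc_mg": (1.0, 3.0),      "calcium_mg": (10, 30)},
    "dairy":               {"energy_kcal": (60, 90),   "protein_g": (3, 4),   "fat_g": (3, 5),
                            "vitamin_a_mcg": (30, 60),  "vitamin_c_mg": (1, 2), "iron_mg": (0.1, 0.2),
                            "zinc_mg": (0.3, 0.5),      "calcium_mg": (100, 130)},
    "oil":                 {"energy_kcal": (880, 900), "protein_g": (0, 0),   "fat_g": (99, 100),
                            "vitamin_a_mcg": (0, 0),    "vitamin_c_mg": (0, 0), "iron_mg": (0, 0),
                            "zinc_mg": (0, 0),          "calcium_mg": (0, 0)},
    "sugar":               {"energy_kcal": (390, 400), "protein_g": (0, 0),   "fat_g": (0, 0),
                            "vitamin_a_mcg": (0, 0),    "vitamin_c_mg": (0, 0), "iron_mg": (0, 0.1),
                            "zinc_mg": (0, 0.1),        "calcium_mg": (0, 5)},
}

#: Pre-shock price ranges in NPR/kg per fine group.
PRICE_RANGES: dict[str, tuple[float, float]] = {
    "cereals_grains": (40, 90),
    "pulses_legumes_nuts": (90, 180),
    "vegetables": (30, 90),
    "fruits": (60, 150),
    "roots_tubers": (30, 80),
    "animal_protein": (250, 700),
    "dairy": (60, 110),
    "oil": (140, 250),
    "sugar": (80, 120),
}

#: Which fine groups each price-analysis group draws foods from.
_FINE_OF_PRICE_GROUP: dict[str, tuple[str, ...]] = {
    "cereals": ("cereals_grains",),
    "pulses": ("pulses_legumes_nuts",),
    "veg_fruits": ("vegetables", "fruits"),
    "roots_tubers": ("roots_tubers",),
    "animal_proteins": ("animal_protein", "dairy"),
}


@dataclass(frozen=True)
class ScenarioSpec:
    """All knobs of a synthetic scenario; the seed fixes every draw."""

    seed: int = 0
    n_foods_per_group: int = 5          # per price-analysis group (+ oil + sugar ≈ 27 foods)
    group_inflation: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_INFLATION))
    item_noise_sd: float = 0.05         # lognormal sd of item inflation around group mean
    n_meals: int = 6
    household_size: int = 6
    districts: tuple[str, ...] = ("district_1",)
    drop_zinc_fraction: float = 0.0     # fraction of foods with zinc blanked in the primary table

    def __post_init__(self):
        if any(g <= -1 for g in self.group_inflation.values()):
            raise ValueError("group inflation must be > -1")
        if self.item_noise_sd < 0:
            raise ValueError("item noise sd must be >= 0")
        if self.n_foods_per_group < 1 or self.n_meals < 1 or self.household_size < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class ScenarioBundle:
    """A complete, internally consistent scenario plus its ground truth."""

    spec: ScenarioSpec
    fct: FoodCompositionTable
    prices: PriceTable
    smfbs: dict[str, SchoolMealBasket]
    thfbs: dict[str, HouseholdBasket]
    household: Household
    weights: dict[str, float]
    refs: dict
    school_child: PersonProfile
    ground_truth: dict


def _rng(spec: ScenarioSpec, stream: str) -> np.random.Generator:
    # crc32 is a stable stream label (str.__hash__ is salted per process)
    label = zlib.crc32(stream.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([spec.seed, label]))


def generate_fct(spec: ScenarioSpec) -> FoodCompositionTable:
    """Synthetic composition table (with a fallback table when zinc is dropped).

    Foods are named ``<fine_group>_<i>``. With ``drop_zinc_fraction`` > 0 a
    matching fraction of foods has zinc blanked in the primary table; a
    generated regional fallback table supplies every blanked value, so the
    fallback chain always resolves completely.
    """
    rng = _rng(spec, "fct")
    records, fallback_records = [], []
    for pg in _FINE_OF_PRICE_GROUP:
        for i in range(spec.n_foods_per_group):
            fine = _FINE_OF_PRICE_GROUP[pg][i % len(_FINE_OF_PRICE_GROUP[pg])]
            records.append(_draw_food(rng, f"{fine}_{i:02d}", fine))
    for fine in ("oil", "sugar"):
        records.append(_draw_food(rng, f"{fine}_00", fine))

    if spec.drop_zinc_fraction > 0:
        drop = rng.random(len(records)) < spec.drop_zinc_fraction
        for i, hit in enumerate(drop):
            if hit:
                fallback_records.append({**records[i], "name": records[i]["name"] + " (regional)"})
                records[i] = {**records[i], "zinc_mg": None}
    primary = FoodCompositionTable.from_records(records)
    if fallback_records:
        fallback = FoodCompositionTable.from_records(fallback_records)
        return primary.with_fallbacks(fallback)
    return primary


def _draw_food(rng: np.random.Generator, food_id: str, fine: str) -> dict:
    ranges = NUTRIENT_RANGES[fine]
    rec = {"food_id": food_id, "name": food_id.replace("_", " "), "fine_group": fine}
    for nutrient in DEFAULT_NUTRIENTS:
        lo, hi = ranges[nutrient]
        rec[nutrient] = float(rng.uniform(lo, hi)) if hi > lo else float(lo)
    return rec


def generate_prices(spec: ScenarioSpec, fct: FoodCompositionTable
                    ) -> tuple[PriceTable, dict]:
    """Two-period prices for every food in every district, plus ground truth.

    post = pre x (1 + group inflation) x lognormal noise with unit mean
    (sigma = item_noise_sd), so prices stay positive and the expected group
    inflation equals the configured value. Ground truth records the true
    group inflations and every item's realised inflation.
    """
    rng = _rng(spec, "prices")
    table = PriceTable()
    truth_items: dict[str, dict[str, float]] = {}
    for district in spec.districts:
        truth_items[district] = {}
        for fid in fct.food_ids:
            fine = fct.group_of(fid)
            pg = price_group(fine)
            lo, hi = PRICE_RANGES[fine]
            pre = float(rng.uniform(lo, hi))
            g = spec.group_inflation.get(pg, 0.0)
            if spec.item_noise_sd > 0:
                sigma = spec.item_noise_sd
                noise = float(rng.lognormal(mean=-0.5 * sigma ** 2, sigma=sigma))
            else:
                noise = 1.0
            post = pre * (1.0 + g) * noise
            table.add(PriceRecord(fid, district, "pre", pre))
            table.add(PriceRecord(fid, district, "post", post))
            truth_items[district][fid] = post / pre - 1.0
    truth = {"group_inflation": dict(spec.group_inflation),
             "item_inflation": truth_items}
    return table, truth


#: Illustrative six-member poorest-quintile household: two working-age
#: adults (moderate activity), one older female (sedentary) and three
#: children. Not a survey household; a documented modelling default.
DEFAULT_HOUSEHOLD_MEMBERS: tuple[PersonProfile, ...] = (
    PersonProfile(age=35, sex="male", weight=58, pal=1.8),
    PersonProfile(age=32, sex="female", weight=50, pal=1.8),
    PersonProfile(age=62, sex="female", weight=45, pal=1.6),
    PersonProfile(age=14, sex="female", weight=40, pal=1.7),
    PersonProfile(age=9, sex="male", weight=26, pal=1.7),
    PersonProfile(age=4, sex="female", weight=15, pal=1.6),
)

#: Reference child for school-meal %RDA accounting.
DEFAULT_SCHOOL_CHILD = PersonProfile(age=9, sex="male", weight=26, pal=1.7)


def default_reference_config() -> dict:
    """Illustrative table-driven reference-intake config.

    Magnitudes follow FAO/WHO-style guideline tables (e.g. adult-female iron
    RDA of 58.8 mg/day at 5 % bioavailability); values are rounded,
    synthetic defaults for closed-box runs, not a transcription of any
    guideline document. Iron and zinc carry per-bioavailability columns;
    the default selectors (iron 5 %, zinc 15 %) model a plant-heavy diet.
    """
    def band(a0, a1, bmr, prot, vita, vitc, ca, fe, zn):
        return {"age_min": a0, "age_max": a1, "bmr_kcal_per_kg": bmr,
                "protein_safe_g_per_kg": prot,
                "rda": {"vitamin_a_mcg": vita, "vitamin_c_mg": vitc, "calcium_mg": ca},
                "rda_by_bioavailability": {
                    "iron_mg": {"0.05": fe, "0.10": fe / 2, "0.15": fe / 3},
                    "zinc_mg": {"0.15": zn, "0.30": zn / 2, "0.50": zn / 3.3},
                }}

    return {
        "bioavailability": {"iron_mg": 0.05, "zinc_mg": 0.15},
        "fat_energy_fraction_max": 0.30,
        "strata": {
            "female": [
                band(0, 3, 55, 1.1, 400, 30, 500, 11.6, 8.3),
                band(4, 8, 45, 1.0, 450, 30, 600, 12.6, 9.6),
                band(9, 13, 35, 0.95, 500, 35, 1000, 18.7, 12.8),
                band(14, 18, 28, 0.88, 530, 40, 1000, 42.6, 14.4),
                band(19, 59, 23, 0.83, 500, 45, 1000, 58.8, 9.8),
                band(60, 120, 21, 0.83, 500, 45, 1100, 22.6, 9.8),
            ],
            "male": [
                band(0, 3, 55, 1.1, 400, 30, 500, 11.6, 8.3),
                band(4, 8, 46, 1.0, 450, 30, 600, 12.6, 9.6),
                band(9, 13, 36, 0.95, 600, 35, 1000, 29.2, 17.1),
                band(14, 18, 30, 0.88, 600, 40, 1000, 37.6, 17.1),
                band(19, 59, 24, 0.83, 600, 45, 1000, 27.4, 14.0),
                band(60, 120, 22, 0.83, 600, 45, 1100, 27.4, 14.0),
            ],
        },
    }


def generate_baskets(spec: ScenarioSpec, fct: FoodCompositionTable, district: str
                     ) -> tuple[SchoolMealBasket, HouseholdBasket]:
    """A weekly school basket and a daily household basket for one district.

    Each meal has a cereal staple, a pulse, a vegetable, oil and sometimes a
    fruit, animal-source food or dairy (3–6 ingredients, ≥3 food groups).
    The household basket covers every weight class including the protected
    oil and sugar, at quantities plausible for a six-member household.
    """
    rng = _rng(spec, f"baskets:{district}")
    by_fine: dict[str, list[str]] = {}
    for fid in fct.food_ids:
        by_fine.setdefault(fct.group_of(fid), []).append(fid)

    def pick(fine: str) -> str:
        pool = by_fine[fine]
        return pool[int(rng.integers(len(pool)))]

    meals = []
    extras = ("fruits", "animal_protein", "dairy", "pulses_legumes_nuts")
    for day in range(1, spec.n_meals + 1):
        ingredients = [
            Ingredient(pick("cereals_grains"), float(rng.uniform(80, 150))),
            Ingredient(pick("pulses_legumes_nuts"), float(rng.uniform(20, 40))),
            Ingredient(pick("vegetables"), float(rng.uniform(30, 80))),
            Ingredient(pick("oil"), float(rng.uniform(5, 10))),
        ]
        for fine in rng.permutation(extras)[: int(rng.integers(0, 3))]:
            ingredients.append(Ingredient(pick(str(fine)), float(rng.uniform(15, 60))))
        # collapse duplicate foods so Ingredient lists stay unambiguous
        merged: dict[str, float] = {}
        for ing in ingredients:
            merged[ing.food_id] = merged.get(ing.food_id, 0.0) + ing.grams
        meals.append(Meal(name=f"meal_day{day}", day_index=day,
                          ingredients=tuple(Ingredient(f, g) for f, g in merged.items())))
    smfb = SchoolMealBasket(district=district, meals=tuple(meals))

    # household daily grams per fine group, split over 1-2 foods per group
    daily_targets = {
        "cereals_grains": 1800.0, "pulses_legumes_nuts": 180.0,
        "vegetables": 500.0, "fruits": 120.0, "roots_tubers": 400.0,
        "animal_protein": 80.0, "dairy": 250.0, "oil": 90.0, "sugar": 80.0,
    }
    items: dict[str, float] = {}
    groups: dict[str, str] = {}
    for fine, total in daily_targets.items():
        pool = by_fine.get(fine, [])
        if not pool:
            continue
        chosen = [pick(fine)] if len(pool) == 1 else list(
            rng.choice(pool, size=min(2, len(pool)), replace=False))
        shares = rng.dirichlet(np.ones(len(chosen)))
        for fid, share in zip(chosen, shares):
            grams = float(total * share * rng.uniform(0.85, 1.15))
            items[fid] = items.get(fid, 0.0) + grams
            groups[fid] = fine
    thfb = HouseholdBasket(district=district, items=items, groups=groups)
    return smfb, thfb


def generate_household(spec: ScenarioSpec, district: str = "") -> Household:
    members = DEFAULT_HOUSEHOLD_MEMBERS[: spec.household_size]
    if len(members) < spec.household_size:
        members = members + tuple(
            DEFAULT_HOUSEHOLD_MEMBERS[i % len(DEFAULT_HOUSEHOLD_MEMBERS)]
            for i in range(spec.household_size - len(members)))
    return Household(members=members, district=district)


def rda_shift_example(rda_pre_pct: float = 4.73, rda_post_pct: float = 4.48,
                      nutrient: str = "vitamin_a_mcg"):
    """Minimal basket whose weekly %RDA for one nutrient moves between two
    stated coverage levels under a uniform price shock.

    Illustrates how a sub-percentage-point %RDA shift corresponds to a much
    larger relative intake change: coverage falling 4.73 % -> 4.48 % of the
    weekly reference is a 100 x (4.73 - 4.48)/4.73 ≈ 5 % intake decrease.
    Returns ``(basket, prices, fct, requirement)`` ready for
    :func:`nutribasket.smfb.compare_smfb` with ``days=6``.
    """
    from .nutrition import person_requirement

    refs = default_reference_config()
    requirement = person_requirement(DEFAULT_SCHOOL_CHILD, refs)
    per_100g = 500.0  # µg of the nutrient per 100 g of the single food
    weekly_ref = requirement.daily[nutrient] * 6
    grams_per_meal = (rda_pre_pct / 100.0) * weekly_ref / 6 / (per_100g / 100.0)
    fct = FoodCompositionTable.from_records([{
        "food_id": "greens", "name": "leafy greens", "fine_group": "vegetables",
        **{n: 0.0 for n in DEFAULT_NUTRIENTS}, nutrient: per_100g,
    }])
    # a uniform shock: every meal's cost ratio is rda_post/rda_pre
    prices = PriceTable([
        PriceRecord("greens", "example", "pre", rda_post_pct),
        PriceRecord("greens", "example", "post", rda_pre_pct),
    ])
    basket = SchoolMealBasket(district="example", meals=tuple(
        Meal(name=f"meal_day{d}", day_index=d,
             ingredients=(Ingredient("greens", grams_per_meal),))
        for d in range(1, 7)))
    return basket, prices, fct, requirement


def generate_scenario(spec: ScenarioSpec) -> ScenarioBundle:
    """Generate a complete scenario: a pure function of the spec (and seed)."""
    fct = generate_fct(spec)
    prices, truth = generate_prices(spec, fct)
    smfbs, thfbs = {}, {}
    household = generate_household(spec, spec.districts[0])
    for district in spec.districts:
        smfb, thfb = generate_baskets(spec, fct, district)
        smfbs[district] = smfb
        thfbs[district] = HouseholdBasket(
            district=district, items=thfb.items, groups=thfb.groups,
            household=household)
    return ScenarioBundle(
        spec=spec, fct=fct, prices=prices, smfbs=smfbs, thfbs=thfbs,
        household=household, weights=dict(DEFAULT_WEIGHTS),
        refs=default_reference_config(), school_child=DEFAULT_SCHOOL_CHILD,
        ground_truth=truth,
    )
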