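"""Shared fixtures: a small hand-written composition table, matching price
tables and the default reference config."""

import pytest

from nutribasket import (
    FoodCompositionTable,
    PersonProfile,
    PriceRecord,
    PriceTable,
)
from nutribasket.simulate import default_reference_config

# hand-written per-100 g composition with round numbers for easy arithmetic
TOY_FOODS = [
    {"food_id": "rice", "name": "rice", "fine_group": "cereals_grains",
     "energy_kcal": 350, "protein_g": 7, "fat_g": 1, "vitamin_a_mcg": 0,
     "vitamin_c_mg": 0, "iron_mg": 4, "zinc_mg": 2, "calcium_mg": 10},
    {"food_id": "lentils", "name": "lentils", "fine_group": "pulses_legumes_nuts",
     "energy_kcal": 340, "protein_g": 24, "fat_g": 2, "vitamin_a_mcg": 10,
     "vitamin_c_mg": 2, "iron_mg": 7, "zinc_mg": 3, "calcium_mg": 60},
    {"food_id": "spinach", "name": "spinach", "fine_group": "vegetables",
     "energy_kcal": 25, "protein_g": 3, "fat_g": 0.4, "vitamin_a_mcg": 470,
     "vitamin_c_mg": 30, "iron_mg": 2.7, "zinc_mg": 0.5, "calcium_mg": 100},
    {"food_id": "milk", "name": "milk", "fine_group": "dairy",
     "energy_kcal": 65, "protein_g": 3.3, "fat_g": 3.6, "vitamin_a_mcg": 50,
     "vitamin_c_mg": 1, "iron_mg": 0.1, "zinc_mg": 0.4, "calcium_mg": 120},
    {"food_id": "potato", "name": "potato", "fine_group": "roots_tubers",
     "energy_kcal": 90, "protein_g": 2, "fat_g": 0.1, "vitamin_a_mcg": 2,
     "vitamin_c_mg": 20, "iron_mg": 0.8, "zinc_mg": 0.3, "calcium_mg": 12},
    {"food_id": "oil", "name": "cooking oil", "fine_group": "oil",
     "energy_kcal": 890, "protein_g": 0, "fat_g": 100, "vitamin_a_mcg": 0,
     "vitamin_c_mg": 0, "iron_mg": 0, "zinc_mg": 0, "calcium_mg": 0},
    {"food_id": "sugar", "name": "sugar", "fine_group": "sugar",
     "energy_kcal": 395, "protein_g": 0, "fat_g": 0, "vitamin_a_mcg": 0,
     "vitamin_c_mg": 0, "iron_mg": 0.1, "zinc_mg": 0, "calcium_mg": 1},
]


@pytest.fixture
def toy_fct() -> FoodCompositionTable:
    return FoodCompositionTable.from_records(TOY_FOODS)


def make_prices(district: str, pre: dict[str, float],
                post: dict[str, float] | None = None) -> PriceTable:
    """Two-period table; post defaults to a copy of pre (no shock)."""
    table = PriceTable()
    for fid, price in pre.items():
        table.add(PriceRecord(fid, district, "pre", price))
    for fid, price in (post if post is not None else pre).items():
        table.add(PriceRecord(fid, district, "post", price))
    return table


TOY_PRE_PRICES = {"rice": 50, "lentils": 120, "spinach": 40, "milk": 80,
                  "potato": 35, "oil": 180, "sugar": 90}


@pytest.fixture
def refs() -> dict:
    return default_reference_config()


@pytest.fixture
def adult() -> PersonProfile:
    return PersonProfile(age=30, sex="female", weight=50, pal=1.8)
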