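"""Composition resolution, nutrient arithmetic and reference intakes."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutribasket import (
    FoodCompositionTable,
    Household,
    NutrientVector,
    PersonProfile,
    household_requirement,
    nutrients_of_quantity,
    percent_of_reference,
    person_requirement,
    price_group,
    sum_nutrients,
    weight_class,
)
from nutribasket.errors import (
    IncompleteNutrients,
    MissingReference,
    NegativeQuantity,
    UnknownFood,
)
from nutribasket.nutrition import DEFAULT_NUTRIENTS, FINE_GROUPS

from conftest import TOY_FOODS


def _nv(**kwargs):
    return NutrientVector(kwargs)


# --- NutrientVector ---------------------------------------------------------

def test_vector_addition_and_scaling_are_componentwise():
    a = _nv(iron_mg=1, energy_kcal=100)
    b = _nv(iron_mg=2, protein_g=5)
    total = a + b
    assert total["iron_mg"] == 3
    assert total["energy_kcal"] == 100
    assert total["protein_g"] == 5
    doubled = 2 * a
    assert doubled["iron_mg"] == 2 and doubled["energy_kcal"] == 200


def test_vector_rejects_negative_and_non_finite():
    with pytest.raises(ValueError):
        NutrientVector({"iron_mg": -1})
    with pytest.raises(ValueError):
        NutrientVector({"iron_mg": float("nan")})


def test_sum_nutrients_matches_loop_oracle_and_empty_is_zero():
    rng = __import__("numpy").random.default_rng(7)
    vectors = [NutrientVector({n: rng.uniform(0, 10) for n in DEFAULT_NUTRIENTS})
               for _ in range(100)]
    total = sum_nutrients(vectors)
    for n in DEFAULT_NUTRIENTS:  # brute-force elementwise accumulation
        acc = 0.0
        for v in vectors:
            acc += v[n]
        assert total[n] == pytest.approx(acc, rel=1e-12)
    assert sum_nutrients([]) == NutrientVector.zero()
    assert sum_nutrients(reversed(vectors))["iron_mg"] == pytest.approx(
        total["iron_mg"], rel=1e-12)


# --- food groups ------------------------------------------------------------

def test_every_fine_group_maps_to_one_price_group_and_weight_class():
    for fine in FINE_GROUPS:
        assert isinstance(price_group(fine), str)
        assert isinstance(weight_class(fine), str)
    assert weight_class("oil") == "protected"
    assert weight_class("sugar") == "protected"
    with pytest.raises(ValueError):
        price_group("snacks")


# --- fallback resolution ----------------------------------------------------

def _table(rows, **kw):
    return FoodCompositionTable.from_records(rows, **kw)


def test_fallback_fills_missing_zinc_per_nutrient():
    primary = _table([{"food_id": "maize", "name": "maize", "fine_group": "cereals_grains",
                       "energy_kcal": 350, "protein_g": 9, "fat_g": 2,
                       "vitamin_a_mcg": 5, "vitamin_c_mg": 0, "iron_mg": 3,
                       "zinc_mg": None, "calcium_mg": 20}])
    regional = _table([{"food_id": "maize", "name": "maize (regional)",
                        "fine_group": "cereals_grains",
                        "energy_kcal": 999, "protein_g": 1, "fat_g": 1,
                        "vitamin_a_mcg": 1, "vitamin_c_mg": 1, "iron_mg": 1,
                        "zinc_mg": 2.1, "calcium_mg": 1}])
    item = primary.with_fallbacks(regional).resolve("maize")
    assert item.per_100g["zinc_mg"] == 2.1
    # only the missing component came from the fallback
    assert item.per_100g["energy_kcal"] == 350
    assert item.source == "fallback_1"
    assert item.component_sources["zinc_mg"] == "fallback_1"
    assert item.component_sources["energy_kcal"] == "primary"


def test_fully_specified_item_resolves_unchanged(toy_fct):
    item = toy_fct.resolve("rice")
    assert item.source == "primary"
    assert item.per_100g["energy_kcal"] == 350
    assert item.group == "cereals_grains"


def test_resolution_is_deterministic(toy_fct):
    assert toy_fct.resolve("milk").per_100g == toy_fct.resolve("milk").per_100g


def test_unknown_and_incomplete_foods_error():
    primary = _table([{"food_id": "x", "name": "x", "fine_group": "oil",
                       "energy_kcal": 880, "protein_g": 0, "fat_g": 100,
                       "vitamin_a_mcg": 0, "vitamin_c_mg": 0, "iron_mg": 0,
                       "zinc_mg": None, "calcium_mg": 0}])
    with pytest.raises(UnknownFood):
        primary.resolve("nope")
    with pytest.raises(IncompleteNutrients) as exc:
        primary.resolve("x")
    assert "zinc_mg" in exc.value.missing


def test_whole_food_fallback_when_absent_from_primary(toy_fct):
    extra = _table([TOY_FOODS[0] | {"food_id": "millet", "name": "millet"}])
    chained = toy_fct.with_fallbacks(extra)
    item = chained.resolve("millet")
    assert item.source == "fallback_1"
    assert item.per_100g["energy_kcal"] == 350


def test_explicit_zero_is_not_overridden_by_fallback():
    primary = _table([{"food_id": "y", "name": "y", "fine_group": "sugar",
                       "energy_kcal": 390, "protein_g": 0, "fat_g": 0,
                       "vitamin_a_mcg": 0, "vitamin_c_mg": 0, "iron_mg": 0,
                       "zinc_mg": 0, "calcium_mg": 0}])
    regional = _table([{"food_id": "y", "name": "y", "fine_group": "sugar",
                        "energy_kcal": 390, "protein_g": 0, "fat_g": 0,
                        "vitamin_a_mcg": 0, "vitamin_c_mg": 0, "iron_mg": 5,
                        "zinc_mg": 5, "calcium_mg": 5}])
    item = primary.with_fallbacks(regional).resolve("y")
    assert item.per_100g["zinc_mg"] == 0
    assert item.source == "primary"


def test_fct_csv_roundtrip_preserves_missing_cells(tmp_path, toy_fct):
    rows = [dict(TOY_FOODS[0]), dict(TOY_FOODS[1])]
    rows[0]["zinc_mg"] = None
    table = _table(rows)
    path = tmp_path / "fct.csv"
    table.to_csv(path)
    text = path.read_text()
    assert ",," in text or text.rstrip().endswith(",")  # empty cell, not 0
    back = FoodCompositionTable.from_csv(path)
    with pytest.raises(IncompleteNutrients):
        back.resolve(rows[0]["food_id"])
    assert back.resolve("lentils").per_100g["zinc_mg"] == 3


# --- quantity scaling -------------------------------------------------------

@pytest.mark.parametrize("food_id,grams,nutrient,expected", [
    ("rice", 200, "energy_kcal", 700.0),   # 350 kcal/100 g x 2
    ("rice", 0, "energy_kcal", 0.0),
    ("rice", 50, "iron_mg", 2.0),          # 4 mg/100 g x 0.5
])
def test_nutrients_of_quantity_scales_per_100g(toy_fct, food_id, grams, nutrient, expected):
    vec = nutrients_of_quantity(toy_fct.resolve(food_id), grams)
    assert vec[nutrient] == pytest.approx(expected, rel=1e-12)


def test_negative_grams_rejected(toy_fct):
    with pytest.raises(NegativeQuantity):
        nutrients_of_quantity(toy_fct.resolve("rice"), -1)


@settings(deadline=None, max_examples=50)
@given(a=st.floats(0, 500), b=st.floats(0, 500))
def test_quantity_scaling_is_linear(a, b):
    fct = FoodCompositionTable.from_records(TOY_FOODS)
    item = fct.resolve("spinach")
    left = nutrients_of_quantity(item, a + b)
    right = nutrients_of_quantity(item, a) + nutrients_of_quantity(item, b)
    for n in left:
        assert left[n] == pytest.approx(right[n], rel=1e-12, abs=1e-12)


# --- reference intakes ------------------------------------------------------

def test_energy_requirement_increases_with_pal(refs):
    lo = person_requirement(PersonProfile(30, "female", 50, 1.7), refs)
    hi = person_requirement(PersonProfile(30, "female", 50, 1.9), refs)
    assert hi.daily["energy_kcal"] > lo.daily["energy_kcal"]


def test_low_bioavailability_columns_selected(refs, adult):
    req = person_requirement(adult, refs)
    band = refs["strata"]["female"][4]  # 19-59
    assert req.daily["iron_mg"] == band["rda_by_bioavailability"]["iron_mg"]["0.05"]
    assert req.daily["zinc_mg"] == band["rda_by_bioavailability"]["zinc_mg"]["0.15"]
    assert req.bioavailability == {"iron_mg": 0.05, "zinc_mg": 0.15}


def test_fat_reference_is_amdr_ceiling(refs, adult):
    req = person_requirement(adult, refs)
    assert req.daily["fat_g"] == pytest.approx(
        0.30 * req.daily["energy_kcal"] / 9.0, rel=1e-12)


def test_person_outside_strata_raises(refs):
    with pytest.raises(MissingReference):
        person_requirement(PersonProfile(150, "male", 60, 1.7), refs)


def test_household_requirement_is_additive_and_permutation_invariant(refs):
    members = (PersonProfile(35, "male", 58, 1.8),
               PersonProfile(32, "female", 50, 1.8),
               PersonProfile(9, "male", 26, 1.7))
    hh = Household(members=members)
    req = household_requirement(hh, refs)
    summed = sum(person_requirement(m, refs).daily["energy_kcal"] for m in members)
    assert req.daily["energy_kcal"] == pytest.approx(summed, rel=1e-12)
    shuffled = household_requirement(Household(members=members[::-1]), refs)
    for n in req.daily:
        assert shuffled.daily[n] == pytest.approx(req.daily[n], rel=1e-12)
    solo = Household(members=members[:1])
    assert household_requirement(solo, refs).daily == person_requirement(members[0], refs).daily


# --- %RDA -------------------------------------------------------------------

def test_percent_of_reference_weekly_example(refs, adult):
    req = person_requirement(adult, refs)
    # iron: supply 12 mg over 6 days against a 10 mg daily reference -> 20 %
    import dataclasses
    req10 = dataclasses.replace(req, daily=NutrientVector(
        {**req.daily.to_dict(), "iron_mg": 10.0}))
    pct = percent_of_reference(_nv(iron_mg=12), req10, days=6)
    assert pct["iron_mg"] == pytest.approx(20.0, rel=1e-12)


def test_supply_equal_to_cumulative_reference_is_100pct(refs, adult):
    req = person_requirement(adult, refs)
    supply = req.daily * 6
    pct = percent_of_reference(supply, req, days=6)
    assert all(math.isclose(v, 100.0, rel_tol=1e-12) for v in pct.values())
    daily = percent_of_reference(req.daily, req, days=1)
    assert all(math.isclose(v, 100.0, rel_tol=1e-12) for v in daily.values())


@settings(deadline=None, max_examples=30)
@given(scale=st.floats(0.1, 10))
def test_percent_of_reference_is_homogeneous(scale):
    refs = __import__("nutribasket.simulate", fromlist=["default_reference_config"]
                      ).default_reference_config()
    req = person_requirement(PersonProfile(30, "female", 50, 1.8), refs)
    base = NutrientVector({n: 5.0 for n in DEFAULT_NUTRIENTS})
    one = percent_of_reference(base, req, days=1)
    scaled = percent_of_reference(base * scale, req, days=1)
    for n in one:
        assert scaled[n] == pytest.approx(one[n] * scale, rel=1e-12)
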