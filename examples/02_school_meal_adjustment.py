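"""Proportional school-meal adjustment under a price shock.

One daily meal (rice, lentils, spinach, oil) gets more expensive; the meal
is shrunk by its cost ratio r = pre cost / post cost so it fits the old
budget, and every nutrient falls by exactly 100 x (1 - r) percent.
"""

from nutribasket import (
    FoodCompositionTable, Ingredient, Meal, PriceRecord, PriceTable,
    adjust_meal, weekly_nutrient_supply,
)

fct = FoodCompositionTable.from_records([
    {"food_id": "rice", "name": "rice", "fine_group": "cereals_grains",
     "energy_kcal": 350, "protein_g": 7, "fat_g": 1, "vitamin_a_mcg": 0,
     "vitamin_c_mg": 0, "iron_mg": 4, "zinc_mg": 2, "calcium_mg": 10},
    {"food_id": "lentils", "name": "lentils", "fine_group": "pulses_legumes_nuts",
     "energy_kcal": 340, "protein_g": 24, "fat_g": 2, "vitamin_a_mcg": 10,
     "vitamin_c_mg": 2, "iron_mg": 7, "zinc_mg": 3, "calcium_mg": 60},
    {"food_id": "spinach", "name": "spinach", "fine_group": "vegetables",
     "energy_kcal": 25, "protein_g": 3, "fat_g": 0.4, "vitamin_a_mcg": 470,
     "vitamin_c_mg": 30, "iron_mg": 2.7, "zinc_mg": 0.5, "calcium_mg": 100},
    {"food_id": "oil", "name": "oil", "fine_group": "oil",
     "energy_kcal": 890, "protein_g": 0, "fat_g": 100, "vitamin_a_mcg": 0,
     "vitamin_c_mg": 0, "iron_mg": 0, "zinc_mg": 0, "calcium_mg": 0},
])

pre = {"rice": 50, "lentils": 120, "spinach": 40, "oil": 180}
post = {"rice": 58, "lentils": 145, "spinach": 48, "oil": 190}
table = PriceTable([PriceRecord(f, "hills", p, v)
                    for prices, p in ((pre, "pre"), (post, "post"))
                    for f, v in prices.items()])

meal = Meal(name="khichdi day", day_index=1, ingredients=(
    Ingredient("rice", 120), Ingredient("lentils", 35),
    Ingredient("spinach", 50), Ingredient("oil", 8)))

adj = adjust_meal(meal, table, "hills")
print(f"meal cost: {adj.pre_cost:.2f} -> {adj.post_cost:.2f} NPR "
      f"(ratio r = {adj.ratio:.4f})")
for before, after in zip(meal.ingredients, adj.adjusted.ingredients):
    print(f"  {before.food_id:8s} {before.grams:6.1f} g -> {after.grams:6.1f} g")
before = weekly_nutrient_supply([meal], fct)
after = weekly_nutrient_supply([adj.adjusted], fct)
for n in ("energy_kcal", "protein_g", "iron_mg", "vitamin_a_mcg"):
    print(f"  {n:14s} {before[n]:8.1f} -> {after[n]:8.1f}  "
          f"({100 * (before[n] - after[n]) / before[n]:.2f} % less)")
print("Proportions are preserved; every nutrient falls by the same 100(1-r) %.")
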