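"""Weighted household expenditure reduction after a price shock.

A basket's daily cost rises by D NPR. The household claws D back by cutting
expenditure in proportion to coping weight x post-shock expenditure — dairy
and fruits are cut hardest (W 2.5), cereals lightly (W 0.5), oil and sugar
never (protected) — so the daily food budget is exactly restored.
"""

from nutribasket import (
    DEFAULT_WEIGHTS, HouseholdBasket, PriceRecord, PriceTable,
    apply_reductions, weighted_reductions,
)
from nutribasket.thfb import basket_cost

pre = {"rice": 50, "lentils": 120, "spinach": 40, "milk": 80, "oil": 180, "sugar": 90}
post = {"rice": 55, "lentils": 140, "spinach": 50, "milk": 95, "oil": 200, "sugar": 95}
table = PriceTable([PriceRecord(f, "d", p, v)
                    for prices, p in ((pre, "pre"), (post, "post"))
                    for f, v in prices.items()])

basket = HouseholdBasket(
    district="d",
    items={"rice": 1800, "lentils": 200, "spinach": 500, "milk": 300,
           "oil": 90, "sugar": 80},
    groups={"rice": "cereals_grains", "lentils": "pulses_legumes_nuts",
            "spinach": "vegetables", "milk": "dairy", "oil": "oil", "sugar": "sugar"})

cost_pre = basket_cost(basket, table, "pre")
cost_post = basket_cost(basket, table, "post")
d = cost_post - cost_pre
print(f"daily basket cost {cost_pre:.2f} -> {cost_post:.2f} NPR  (D = {d:.2f})")

cuts = weighted_reductions(basket, table, DEFAULT_WEIGHTS, d)
adjusted = apply_reductions(basket, cuts, table)
for fid in basket.items:
    print(f"  {fid:8s} cut {cuts[fid]:5.2f} NPR  {basket.items[fid]:7.1f} g -> "
          f"{adjusted.items[fid]:7.1f} g")
print(f"adjusted basket at post prices: {basket_cost(adjusted, table, 'post'):.2f} NPR "
      f"(= pre-shock budget); oil and sugar untouched.")
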