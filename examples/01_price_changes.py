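"""Two-period commodity price analysis: group means vs item heterogeneity.

Builds a tiny cereal price table in which most staples barely move but dry
maize jumps 52 -> 80 NPR/kg, then prints the group-level change (change of
unweighted mean prices) next to the item-level changes it masks.
"""

from nutribasket import PriceRecord, PriceTable, group_price_change, item_price_change

table = PriceTable([
    PriceRecord("rice", "terai", "pre", 55), PriceRecord("rice", "terai", "post", 57),
    PriceRecord("wheat_flour", "terai", "pre", 48), PriceRecord("wheat_flour", "terai", "post", 50),
    PriceRecord("dry_maize", "terai", "pre", 52), PriceRecord("dry_maize", "terai", "post", 80),
])
groups = {"rice": "cereals", "wheat_flour": "cereals", "dry_maize": "cereals"}

gc = group_price_change(table, "terai", "cereals", groups)
print(f"cereals group change: {gc.percent:+.1f} %  (means {gc.mean_pre:.1f} -> {gc.mean_post:.1f} NPR/kg)")
for food in gc.foods:
    print(f"  {food:12s} {item_price_change(table, 'terai', food):+6.1f} %")
print("A moderate group average can hide a single commodity inflating by half.")
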