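"""Household basket: weighted expenditure reduction and budget conservation."""

import pytest

from nutribasket import (
    DEFAULT_WEIGHTS,
    Household,
    HouseholdBasket,
    apply_reductions,
    compare_thfb,
    cost_difference,
    household_requirement,
    unit_sensitivity_10npr,
    weighted_reductions,
)
from nutribasket.errors import AllWeightsZero, InfeasibleReduction, ZeroCostChange
from nutribasket.simulate import DEFAULT_HOUSEHOLD_MEMBERS
from nutribasket.thfb import basket_cost

from conftest import TOY_PRE_PRICES, make_prices


def basket(items: dict[str, float], groups: dict[str, str] | None = None) -> HouseholdBasket:
    default_groups = {"rice": "cereals_grains", "lentils": "pulses_legumes_nuts",
                      "spinach": "vegetables", "milk": "dairy",
                      "potato": "roots_tubers", "oil": "oil", "sugar": "sugar"}
    return HouseholdBasket(district="d", items=items,
                           groups=groups or {f: default_groups[f] for f in items})


def test_cost_difference_is_post_minus_pre():
    table = make_prices("d", {"rice": 50}, {"rice": 55})
    b = basket({"rice": 6000})
    assert cost_difference(b, table) == pytest.approx(30.0)  # 300 -> 330
    flat = make_prices("d", {"rice": 50})
    assert cost_difference(b, flat) == pytest.approx(0.0)


def test_weighted_reduction_hand_example():
    """dairy e=50 (W 2.5), cereal e=100 (W 0.5), oil e=20 (W 0), D=30:
    pool = 125 + 50, cuts 21.43 / 8.57 / 0."""
    post = {"milk": 100, "rice": 100, "oil": 200}
    table = make_prices("d", post, post)
    b = basket({"milk": 500, "rice": 1000, "oil": 100})
    red = weighted_reductions(b, table, DEFAULT_WEIGHTS, 30.0)
    assert red["milk"] == pytest.approx(30 * 125 / 175, rel=1e-12)   # 21.4286
    assert red["rice"] == pytest.approx(30 * 50 / 175, rel=1e-12)    # 8.5714
    assert red["oil"] == 0.0
    assert sum(red.values()) == pytest.approx(30.0, rel=1e-12)


def test_zero_difference_means_zero_reductions():
    table = make_prices("d", TOY_PRE_PRICES)
    b = basket({"rice": 1000, "oil": 50})
    assert all(v == 0 for v in weighted_reductions(b, table, DEFAULT_WEIGHTS, 0.0).values())


def test_single_weighted_item_absorbs_everything():
    table = make_prices("d", TOY_PRE_PRICES)
    b = basket({"spinach": 2000, "oil": 100})
    red = weighted_reductions(b, table, DEFAULT_WEIGHTS, 10.0)
    assert red["spinach"] == pytest.approx(10.0) and red["oil"] == 0.0


def test_all_protected_basket_errors():
    table = make_prices("d", TOY_PRE_PRICES)
    b = basket({"oil": 100, "sugar": 200})
    with pytest.raises(AllWeightsZero):
        weighted_reductions(b, table, DEFAULT_WEIGHTS, 5.0)


def test_infeasible_reduction_raises_then_redistributes():
    table = make_prices("d", TOY_PRE_PRICES)
    # spinach expenditure 40*0.1=4 NPR; rice 50 NPR; D=20 overloads spinach?
    b = basket({"spinach": 100, "rice": 1000})
    # weights make spinach carry 2.0*4 / (2.0*4 + 0.5*50) = 8/33 of 20 NPR = 4.85 > 4
    with pytest.raises(InfeasibleReduction):
        weighted_reductions(b, table, DEFAULT_WEIGHTS, 20.0)
    red = weighted_reductions(b, table, DEFAULT_WEIGHTS, 20.0, redistribute=True)
    assert red["spinach"] == pytest.approx(4.0, rel=1e-9)  # capped at expenditure
    assert sum(red.values()) == pytest.approx(20.0, rel=1e-9)


def test_apply_reductions_arithmetic_and_protected_grams_bit_identical():
    post = {"milk": 100, "rice": 100, "oil": 200}
    table = make_prices("d", post, post)
    b = basket({"milk": 500, "rice": 1000, "oil": 100})
    red = weighted_reductions(b, table, DEFAULT_WEIGHTS, 30.0)
    adj = apply_reductions(b, red, table)
    # e=50 NPR at 100 NPR/kg, cut 21.4286 -> 285.714 g
    assert adj.items["milk"] == pytest.approx(1000 * (50 - 30 * 125 / 175) / 100, rel=1e-12)
    assert adj.items["oil"] == b.items["oil"]  # bit-identical, never touched
    # post cost drops by exactly the allocated difference
    assert basket_cost(adj, table, "post") == pytest.approx(
        basket_cost(b, table, "post") - 30.0, rel=1e-12)


def test_equal_weights_reduce_proportionally_to_expenditure():
    table = make_prices("d", TOY_PRE_PRICES)
    b = basket({"rice": 2000, "spinach": 500, "milk": 300})
    flat = {k: 1.0 for k in DEFAULT_WEIGHTS}
    red = weighted_reductions(b, table, flat, 12.0)
    exp = {f: g / 1000 * TOY_PRE_PRICES[f] for f, g in b.items.items()}
    total = sum(exp.values())
    for f in b.items:  # oracle: direct proportional allocation
        assert red[f] == pytest.approx(12.0 * exp[f] / total, rel=1e-12)


def test_raising_a_class_weight_raises_its_reduction_share():
    table = make_prices("d", TOY_PRE_PRICES)
    b = basket({"rice": 2000, "spinach": 500, "milk": 300})
    lo = weighted_reductions(b, table, DEFAULT_WEIGHTS, 15.0)
    heavier = {**DEFAULT_WEIGHTS, "vegetables": 4.0}
    hi = weighted_reductions(b, table, heavier, 15.0)
    assert hi["spinach"] / 15.0 > lo["spinach"] / 15.0


def test_compare_thfb_zero_inflation_changes_nothing(toy_fct, refs):
    table = make_prices("d", TOY_PRE_PRICES)
    hh = Household(members=DEFAULT_HOUSEHOLD_MEMBERS)
    req = household_requirement(hh, refs)
    b = basket({"rice": 1500, "spinach": 400, "oil": 80})
    res = compare_thfb(b, table, toy_fct, req)
    assert res.cost_difference == pytest.approx(0.0)
    assert all(v == pytest.approx(0.0) for v in res.pct_decrease.values())
    assert res.basket_post.items == res.basket_pre.items


def test_protected_only_inflation_cuts_weighted_groups(toy_fct, refs):
    """Oil/sugar price spikes raise D, but the grams cut fall entirely on the
    weighted groups; protected grams stay identical."""
    post = {**TOY_PRE_PRICES, "oil": 260, "sugar": 130}
    table = make_prices("d", TOY_PRE_PRICES, post)
    hh = Household(members=DEFAULT_HOUSEHOLD_MEMBERS)
    req = household_requirement(hh, refs)
    b = basket({"rice": 1800, "lentils": 200, "spinach": 500, "oil": 90, "sugar": 80})
    res = compare_thfb(b, table, toy_fct, req)
    assert res.cost_difference > 0
    assert res.basket_post.items["oil"] == b.items["oil"]
    assert res.basket_post.items["sugar"] == b.items["sugar"]
    assert res.basket_post.items["rice"] < b.items["rice"]
    assert res.reductions["oil"] == 0.0 and res.reductions["sugar"] == 0.0
    assert basket_cost(res.basket_post, table, "post") == pytest.approx(
        res.cost_pre, rel=1e-9)


def test_deflation_leaves_basket_unchanged_by_default(toy_fct, refs):
    post = {f: p * 0.9 for f, p in TOY_PRE_PRICES.items()}
    table = make_prices("d", TOY_PRE_PRICES, post)
    hh = Household(members=DEFAULT_HOUSEHOLD_MEMBERS)
    req = household_requirement(hh, refs)
    b = basket({"rice": 1500, "spinach": 400})
    res = compare_thfb(b, table, toy_fct, req)
    assert res.cost_difference < 0
    assert res.basket_post.items == b.items
    sym = compare_thfb(b, table, toy_fct, req, adjust_deflation=True)
    assert sym.basket_post.items["rice"] > b.items["rice"]
    assert basket_cost(sym.basket_post, table, "post") == pytest.approx(
        sym.cost_pre, rel=1e-9)


def test_nutrient_change_matches_brute_force_recompute(toy_fct, refs):
    post = {**TOY_PRE_PRICES, "milk": 110, "spinach": 55, "rice": 56}
    table = make_prices("d", TOY_PRE_PRICES, post)
    hh = Household(members=DEFAULT_HOUSEHOLD_MEMBERS)
    req = household_requirement(hh, refs)
    b = basket({"rice": 1800, "lentils": 200, "spinach": 500, "milk": 250, "oil": 90})
    res = compare_thfb(b, table, toy_fct, req)
    for n in res.pct_decrease:  # recompute from adjusted grams by hand
        pre = sum(toy_fct.resolve(f).per_100g[n] * g / 100 for f, g in b.items.items())
        post_v = sum(toy_fct.resolve(f).per_100g[n] * g / 100
                     for f, g in res.basket_post.items.items())
        if pre > 0:
            assert res.pct_decrease[n] == pytest.approx(100 * (pre - post_v) / pre, rel=1e-9)


def test_sensitivity_per_10npr_and_delta_1_convention(toy_fct, refs):
    post = {f: p * 1.08 for f, p in TOY_PRE_PRICES.items()}
    table = make_prices("d", TOY_PRE_PRICES, post)
    hh = Household(members=DEFAULT_HOUSEHOLD_MEMBERS)
    req = household_requirement(hh, refs)
    b = basket({"rice": 1800, "lentils": 200, "spinach": 500, "milk": 250, "oil": 90})
    res = compare_thfb(b, table, toy_fct, req)
    sens10 = unit_sensitivity_10npr(res)
    sens1 = unit_sensitivity_10npr(res, delta=1.0)
    for n in sens10:
        assert sens10[n] == pytest.approx(10 * sens1[n], rel=1e-12)
        assert sens10[n] * res.cost_difference / 10 == pytest.approx(
            res.pct_decrease[n], rel=1e-12)


def test_sensitivity_requires_cost_increase(toy_fct, refs):
    table = make_prices("d", TOY_PRE_PRICES)
    hh = Household(members=DEFAULT_HOUSEHOLD_MEMBERS)
    req = household_requirement(hh, refs)
    res = compare_thfb(basket({"rice": 1000}), table, toy_fct, req)
    with pytest.raises(ZeroCostChange):
        unit_sensitivity_10npr(res)
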