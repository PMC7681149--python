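"""Multi-district orchestration and report serialisation.

Runs the whole analysis — group price changes, school-meal adjustment,
household-basket adjustment, per-unit-cost sensitivities — for each
district and aggregates unweighted cross-district averages. Reports are
plain nested dicts; rounding (2 decimals) happens only at serialisation.
"""

from __future__ import annotations

import hashlib
import json
from collections.abc import Mapping
from pathlib import Path

import pandas as pd

from . import __version__
from .errors import ConfigError, ZeroCostChange
from .nutrition import (
    CORE_PRICE_GROUPS,
    FoodCompositionTable,
    Household,
    RequirementProfile,
    household_requirement,
)
from .prices import EmptyGroup, PriceTable, group_price_change
from .smfb import SchoolMealBasket, compare_smfb, unit_cost_sensitivity
from .thfb import (
    DEFAULT_WEIGHTS,
    HouseholdBasket,
    compare_thfb,
    unit_sensitivity_10npr,
)


def run_pipeline(fct: FoodCompositionTable, prices: PriceTable,
                 smfbs: Mapping[str, SchoolMealBasket],
                 thfbs: Mapping[str, HouseholdBasket],
                 household: Household, refs: Mapping,
                 school_requirement: RequirementProfile | None = None,
                 weights: Mapping[str, float] = DEFAULT_WEIGHTS,
                 districts: list[str] | None = None,
                 *, redistribute: bool = False,
                 missing_policy: str = "error") -> dict:
    """Run the full analysis for every district and aggregate averages.

    Deterministic given its inputs; warnings (skipped foods, carried
    prices) are collected into the provenance block.
    """
    districts = list(districts or sorted(set(smfbs) | set(thfbs)))
    price_districts = set(prices.districts())
    unknown = [d for d in districts if d not in price_districts]
    if unknown:
        raise ConfigError(f"districts absent from price table: {unknown}")
    if school_requirement is None:
        raise ConfigError("a school-meal requirement profile is required")
    hh_requirement = household_requirement(household, refs)
    price_groups = fct.price_groups()
    carried: list[str] = []
    warnings: list[str] = []

    per_district: dict[str, dict] = {}
    for district in districts:
        block: dict = {}
        changes = {}
        for group in CORE_PRICE_GROUPS:
            try:
                gc = group_price_change(prices, district, group, price_groups)
            except EmptyGroup:
                warnings.append(f"{district}: no two-period foods in group {group}")
                continue
            changes[group] = {"pct_change": gc.percent, "n_foods": len(gc.foods),
                              "skipped": list(gc.skipped)}
            if gc.skipped:
                warnings.append(f"{district}/{group}: skipped {list(gc.skipped)}")
        block["group_price_changes"] = changes

        if district in smfbs:
            sres = compare_smfb(smfbs[district], prices, fct, school_requirement,
                                district, missing_policy=missing_policy,
                                carried=carried)
            block["smfb"] = sres.to_dict()
            try:
                block["smfb"]["sensitivity_per_1npr"] = unit_cost_sensitivity(sres, 1.0)
            except ZeroCostChange:
                warnings.append(f"{district}: SMFB unit cost did not rise; no sensitivity")
        if district in thfbs:
            tres = compare_thfb(thfbs[district], prices, fct, hh_requirement,
                                weights, redistribute=redistribute,
                                missing_policy=missing_policy, carried=carried)
            block["thfb"] = tres.to_dict()
            try:
                block["thfb"]["sensitivity_per_10npr"] = unit_sensitivity_10npr(tres, 10.0)
            except ZeroCostChange:
                warnings.append(f"{district}: THFB cost did not rise; no sensitivity")
        per_district[district] = block

    report = {
        "districts": per_district,
        "averages": _cross_district_averages(per_district),
        "provenance": {
            "version": __version__,
            "districts": districts,
            "weights": dict(weights),
            "carried_prices": sorted(set(carried)),
            "warnings": warnings,
            "input_hash": _input_hash(fct, prices, districts),
        },
    }
    return report


def _mean_over_districts(blocks: list[dict], section: str, key: str) -> dict[str, float]:
    rows = [b[section][key] for b in blocks if section in b]
    if not rows:
        return {}
    nutrients = rows[0].keys()
    return {n: sum(r[n] for r in rows) / len(rows) for n in nutrients}


def _cross_district_averages(per_district: dict[str, dict]) -> dict:
    """Unweighted means across districts (matching the averages the per-
    district tables are summarised with)."""
    blocks = list(per_district.values())
    group_rows: dict[str, list[float]] = {}
    for b in blocks:
        for group, rec in b.get("group_price_changes", {}).items():
            group_rows.setdefault(group, []).append(rec["pct_change"])
    smfb_costs = [b["smfb"]["unit_cost"]["pct_increase"] for b in blocks if "smfb" in b]
    thfb_costs = [b["thfb"]["cost"]["pct_increase"] for b in blocks if "thfb" in b]
    return {
        "group_price_changes_pct": {g: sum(v) / len(v) for g, v in group_rows.items()},
        "smfb_pct_decrease": _mean_over_districts(blocks, "smfb", "pct_decrease"),
        "thfb_pct_decrease": _mean_over_districts(blocks, "thfb", "pct_decrease"),
        "smfb_unit_cost_pct_increase": (sum(smfb_costs) / len(smfb_costs)) if smfb_costs else None,
        "thfb_cost_pct_increase": (sum(thfb_costs) / len(thfb_costs)) if thfb_costs else None,
    }


def _input_hash(fct: FoodCompositionTable, prices: PriceTable,
                districts: list[str]) -> str:
    h = hashlib.sha256()
    h.update(",".join(sorted(fct.food_ids)).encode())
    for d in sorted(districts):
        for period in ("pre", "post"):
            for f in prices.foods(d, period):
                h.update(f"{d}|{period}|{f}|{prices.get(d, period, f):.9g}".encode())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def _round(obj, ndigits=2):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    return obj


def write_report(report: dict, out_dir: str | Path,
                 formats: tuple[str, ...] = ("json", "csv_bundle", "markdown"),
                 precision: int = 2) -> list[Path]:
    """Serialise a report: full-precision JSON, tidy CSVs, markdown tables."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    if "json" in formats:
        path = out / "report.json"
        path.write_text(json.dumps(report, indent=2, sort_keys=True))
        written.append(path)
    if "csv_bundle" in formats:
        written += _write_csvs(report, out, precision)
    if "markdown" in formats:
        path = out / "report.md"
        path.write_text(_render_markdown(report, precision))
        written.append(path)
    return written


def _tidy_rows(report: dict):
    for district, block in report["districts"].items():
        for group, rec in block.get("group_price_changes", {}).items():
            yield "group_price_change", district, group, "pct_change", rec["pct_change"]
        for section in ("smfb", "thfb"):
            if section not in block:
                continue
            sec = block[section]
            for metric in ("pct_decrease", "rda_pre", "rda_post"):
                for nutrient, val in sec[metric].items():
                    yield section, district, nutrient, metric, val
            sens_key = "sensitivity_per_1npr" if section == "smfb" else "sensitivity_per_10npr"
            for nutrient, val in sec.get(sens_key, {}).items():
                yield section, district, nutrient, sens_key, val
        if "smfb" in block:
            for k, v in block["smfb"]["unit_cost"].items():
                yield "smfb", district, "unit_cost", k, v
        if "thfb" in block:
            for k, v in block["thfb"]["cost"].items():
                yield "thfb", district, "cost", k, v
    for section in ("smfb_pct_decrease", "thfb_pct_decrease"):
        for nutrient, val in report["averages"].get(section, {}).items():
            yield section.split("_")[0], "AVERAGE", nutrient, "pct_decrease", val
    for group, val in report["averages"].get("group_price_changes_pct", {}).items():
        yield "group_price_change", "AVERAGE", group, "pct_change", val


def _write_csvs(report: dict, out: Path, precision: int) -> list[Path]:
    df = pd.DataFrame(_tidy_rows(report),
                      columns=["section", "district", "item", "metric", "value"])
    df["value"] = df["value"].round(precision)
    written = []
    for section, chunk in df.groupby("section"):
        path = out / f"report_{section}.csv"
        chunk.to_csv(path, index=False)
        written.append(path)
    return written


def _render_markdown(report: dict, precision: int) -> str:
    lines = ["# Price-shock nutrition report", ""]
    avg = _round(report["averages"], precision)
    lines += ["## Cross-district averages", "",
              "| group | price change (%) |", "|---|---|"]
    for g, v in avg["group_price_changes_pct"].items():
        lines.append(f"| {g} | {v} |")
    for section, title in (("smfb_pct_decrease", "School-meal basket"),
                           ("thfb_pct_decrease", "Household basket")):
        if not avg.get(section):
            continue
        lines += ["", f"## {title}: average nutrient change", "",
                  "| nutrient | %age change |", "|---|---|"]
        for n, v in avg[section].items():
            lines.append(f"| {n} | {v} |")
    for district, block in report["districts"].items():
        lines += ["", f"## District: {district}", ""]
        for section in ("smfb", "thfb"):
            if section not in block:
                continue
            sec = _round(block[section], precision)
            lines += [f"### {section.upper()}", "",
                      "| nutrient | pre %RDA | post %RDA | %age change |", "|---|---|---|---|"]
            for n in sec["pct_decrease"]:
                lines.append(f"| {n} | {sec['rda_pre'][n]} | {sec['rda_post'][n]} "
                             f"| {sec['pct_decrease'][n]} |")
            lines.append("")
    return "\n".join(lines) + "\n"
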