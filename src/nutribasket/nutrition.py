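"""Food composition resolution, nutrient arithmetic and reference intakes.

This module is the nutritional core of the pipeline:

* :class:`NutrientVector` — an immutable componentwise vector of nutrient
  quantities (energy in kcal, macronutrients in g, micronutrients in mg/µg).
* :class:`FoodCompositionTable` — per-100 g nutrient content of foods, with
  an ordered fallback chain of regional tables used to fill nutrients that
  the primary table does not report (a national table may, for instance,
  omit zinc entirely; neighbouring-country tables then supply it).
* Reference intakes — estimated energy requirements (basal rate × weight ×
  physical activity level), safe protein levels and RDAs, read from a
  table-driven config so that guideline values are data, not code.
  Low-bioavailability RDA columns for iron and zinc model plant-heavy diets
  in which only a small fraction of the ingested mineral is absorbed.

Quantities are always per day unless a ``days`` argument says otherwise;
masses of food are grams, composition is per 100 g edible portion.
"""

from __future__ import annotations

import json
import math
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import (
    IncompleteNutrients,
    MissingReference,
    NegativeQuantity,
    UnknownFood,
    ZeroReference,
)

#: Default nutrient components, named with their unit. The set is extensible:
#: a NutrientVector accepts any keys, these are merely the canonical eight.
DEFAULT_NUTRIENTS: tuple[str, ...] = (
    "energy_kcal",
    "protein_g",
    "fat_g",
    "vitamin_a_mcg",
    "vitamin_c_mg",
    "iron_mg",
    "zinc_mg",
    "calcium_mg",
)


class NutrientVector(Mapping):
    """Immutable componentwise vector of nutrient quantities.

    Supports ``+`` (componentwise sum over the union of keys) and scalar
    ``*``. All components must be finite and non-negative: this type holds
    physical quantities, never differences.
    """

    __slots__ = ("_data",)

    def __init__(self, values: Mapping[str, float] | None = None,
                 nutrients: Iterable[str] = DEFAULT_NUTRIENTS):
        data = {n: 0.0 for n in nutrients}
        if values:
            for key, val in values.items():
                val = float(val)
                if not math.isfinite(val) or val < 0:
                    raise ValueError(f"nutrient {key!r} must be finite and >= 0, got {val}")
                data[key] = val
        object.__setattr__(self, "_data", data)

    @classmethod
    def zero(cls, nutrients: Iterable[str] = DEFAULT_NUTRIENTS) -> "NutrientVector":
        return cls({}, nutrients=nutrients)

    # Mapping protocol
    def __getitem__(self, key: str) -> float:
        return self._data[key]

    def __iter__(self):
        return iter(self._data)

    def __len__(self) -> int:
        return len(self._data)

    # vector arithmetic
    def __add__(self, other: "NutrientVector") -> "NutrientVector":
        if not isinstance(other, Mapping):
            return NotImplemented
        keys = dict.fromkeys([*self._data, *other])
        return NutrientVector(
            {k: self._data.get(k, 0.0) + other.get(k, 0.0) for k in keys},
            nutrients=keys,
        )

    def __mul__(self, factor: float) -> "NutrientVector":
        factor = float(factor)
        return NutrientVector({k: v * factor for k, v in self._data.items()},
                              nutrients=self._data)

    __rmul__ = __mul__

    def __eq__(self, other) -> bool:
        return isinstance(other, Mapping) and dict(self._data) == dict(other)

    def __repr__(self) -> str:
        inner = ", ".join(f"{k}={v:g}" for k, v in self._data.items())
        return f"NutrientVector({inner})"

    def to_dict(self) -> dict[str, float]:
        return dict(self._data)


def sum_nutrients(vectors: Iterable[NutrientVector]) -> NutrientVector:
    """Componentwise sum; the empty list sums to the zero vector."""
    total = NutrientVector.zero()
    for vec in vectors:
        total = total + vec
    return total


# ---------------------------------------------------------------------------
# Food groups
# ---------------------------------------------------------------------------

#: Fine-grained food-group labels carried by every food item.
FINE_GROUPS: tuple[str, ...] = (
    "cereals_grains",
    "pulses_legumes_nuts",
    "vegetables",
    "fruits",
    "roots_tubers",
    "animal_protein",
    "dairy",
    "oil",
    "sugar",
)

#: Price-analysis groups. The five canonical groups drive the group-level
#: price-change analysis; ``oils_sugar`` exists so that cooking oil and sugar
#: have prices for basket costing without polluting the five-group statistics.
PRICE_GROUPS: tuple[str, ...] = (
    "cereals", "pulses", "veg_fruits", "roots_tubers", "animal_proteins", "oils_sugar",
)

#: The five groups reported in the price-change analysis.
CORE_PRICE_GROUPS: tuple[str, ...] = PRICE_GROUPS[:5]

PRICE_GROUP_OF: dict[str, str] = {
    "cereals_grains": "cereals",
    "pulses_legumes_nuts": "pulses",
    "vegetables": "veg_fruits",
    "fruits": "veg_fruits",
    "roots_tubers": "roots_tubers",
    "animal_protein": "animal_proteins",
    "dairy": "animal_proteins",
    "oil": "oils_sugar",
    "sugar": "oils_sugar",
}

#: Expenditure-reduction classes for the household coping model. Oil and
#: sugar are protected (never reduced: cheap calories are kept); animal
#: protein joins fruits/dairy at the top of the price-sensitivity ranking.
WEIGHT_CLASSES: tuple[str, ...] = (
    "fruits_dairy", "vegetables", "roots_pulses", "cereals", "protected",
)

WEIGHT_CLASS_OF: dict[str, str] = {
    "cereals_grains": "cereals",
    "pulses_legumes_nuts": "roots_pulses",
    "vegetables": "vegetables",
    "fruits": "fruits_dairy",
    "roots_tubers": "roots_pulses",
    "animal_protein": "fruits_dairy",
    "dairy": "fruits_dairy",
    "oil": "protected",
    "sugar": "protected",
}


def price_group(fine_label: str) -> str:
    """Map a fine food-group label to its price-analysis group."""
    try:
        return PRICE_GROUP_OF[fine_label]
    except KeyError:
        raise ValueError(f"unknown food group {fine_label!r}") from None


def weight_class(fine_label: str) -> str:
    """Map a fine food-group label to its expenditure-reduction class."""
    try:
        return WEIGHT_CLASS_OF[fine_label]
    except KeyError:
        raise ValueError(f"unknown food group {fine_label!r}") from None


# ---------------------------------------------------------------------------
# Food composition tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoodItem:
    """A fully resolved food: no nutrient component is missing.

    ``source`` records the deepest table in the fallback chain that
    contributed any component ("primary", "fallback_1", ...);
    ``component_sources`` records, per nutrient, which table supplied it.
    """

    id: str
    name: str
    group: str
    per_100g: NutrientVector
    source: str = "primary"
    component_sources: Mapping[str, str] = field(default_factory=dict)


@dataclass(frozen=True)
class _RawEntry:
    """Unresolved table row: ``values`` may hold None for missing nutrients."""

    name: str
    group: str
    values: Mapping[str, float | None]


#: Expected CSV columns for a composition table, per 100 g edible portion.
FCT_COLUMNS: tuple[str, ...] = ("food_id", "name", "fine_group", *DEFAULT_NUTRIENTS)


class FoodCompositionTable:
    """Per-100 g nutrient content of foods, with an ordered fallback chain.

    Lookups never return a partially specified vector: a component missing
    from the primary table is filled from the first fallback table that has
    it; a component missing everywhere raises :class:`IncompleteNutrients`.
    An empty CSV cell means *missing*; an explicit ``0`` is a true zero and
    is never overridden by a fallback.
    """

    def __init__(self, entries: Mapping[str, _RawEntry],
                 fallback_chain: Iterable["FoodCompositionTable"] = (),
                 nutrients: Iterable[str] = DEFAULT_NUTRIENTS):
        self._entries = dict(entries)
        self.fallback_chain = list(fallback_chain)
        self.nutrients = tuple(nutrients)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[Mapping], **kwargs) -> "FoodCompositionTable":
        """Build from dicts with keys ``food_id``, ``name``, ``fine_group``
        and one key per nutrient (value ``None`` marks a missing component)."""
        entries: dict[str, _RawEntry] = {}
        nutrients = tuple(kwargs.pop("nutrients", DEFAULT_NUTRIENTS))
        for rec in records:
            fid = str(rec["food_id"])
            if fid in entries:
                raise ValueError(f"duplicate food id {fid!r}")
            group = str(rec["fine_group"])
            if group not in FINE_GROUPS:
                raise ValueError(f"food {fid!r}: unknown fine_group {group!r}")
            values = {}
            for n in nutrients:
                v = rec.get(n)
                values[n] = None if v is None or (isinstance(v, float) and math.isnan(v)) else float(v)
            entries[fid] = _RawEntry(str(rec.get("name", fid)), group, values)
        return cls(entries, nutrients=nutrients, **kwargs)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "FoodCompositionTable":
        df = pd.read_csv(path, dtype={"food_id": str})
        missing_cols = [c for c in ("food_id", "name", "fine_group") if c not in df.columns]
        if missing_cols:
            raise ValueError(f"composition CSV {path}: missing columns {missing_cols}")
        nutrients = tuple(kwargs.pop("nutrients", None)
                          or [c for c in df.columns if c not in ("food_id", "name", "fine_group")])
        return cls.from_records(df.to_dict("records"), nutrients=nutrients, **kwargs)

    def to_csv(self, path: str | Path) -> None:
        rows = []
        for fid, entry in self._entries.items():
            row = {"food_id": fid, "name": entry.name, "fine_group": entry.group}
            row.update(entry.values)
            rows.append(row)
        pd.DataFrame(rows, columns=["food_id", "name", "fine_group", *self.nutrients]) \
            .to_csv(path, index=False)

    def with_fallbacks(self, *tables: "FoodCompositionTable") -> "FoodCompositionTable":
        """Return a copy whose fallback chain is ``tables`` (in order)."""
        return FoodCompositionTable(self._entries, fallback_chain=tables,
                                    nutrients=self.nutrients)

    # -- queries -------------------------------------------------------------

    def __contains__(self, food_id: str) -> bool:
        return food_id in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def food_ids(self) -> list[str]:
        return list(self._entries)

    def group_of(self, food_id: str) -> str:
        """Fine group of a food, searching the fallback chain if needed."""
        for table in (self, *self.fallback_chain):
            if food_id in table._entries:
                return table._entries[food_id].group
        raise UnknownFood(food_id)

    def price_groups(self) -> dict[str, str]:
        """food_id -> price-analysis group, over this table and its chain."""
        out: dict[str, str] = {}
        for table in (self, *self.fallback_chain):
            for fid, entry in table._entries.items():
                out.setdefault(fid, price_group(entry.group))
        return out

    def resolve(self, food_id: str) -> FoodItem:
        """Resolve a food to a complete nutrient vector via the fallback chain.

        Missing components are filled per-nutrient from the first table in
        the chain that reports them; the item-level ``source`` tag is the
        deepest table actually used. Deterministic for a fixed chain order.
        """
        tables = [self, *self.fallback_chain]
        labels = ["primary"] + [f"fallback_{i}" for i in range(1, len(tables))]
        hits = [(labels[i], t._entries[food_id]) for i, t in enumerate(tables)
                if food_id in t._entries]
        if not hits:
            raise UnknownFood(food_id)
        base_label, base = hits[0]
        values: dict[str, float] = {}
        comp_sources: dict[str, str] = {}
        missing: list[str] = []
        depth = {label: i for i, label in enumerate(labels)}
        for nutrient in self.nutrients:
            for label, entry in hits:
                val = entry.values.get(nutrient)
                if val is not None:
                    values[nutrient] = val
                    comp_sources[nutrient] = label
                    break
            else:
                missing.append(nutrient)
        if missing:
            raise IncompleteNutrients(food_id, missing)
        deepest = max(comp_sources.values(), key=depth.__getitem__)
        return FoodItem(id=food_id, name=base.name, group=base.group,
                        per_100g=NutrientVector(values, nutrients=self.nutrients),
                        source=deepest, component_sources=comp_sources)


def resolve_food(fct: FoodCompositionTable, food_id: str) -> FoodItem:
    """Functional alias for :meth:`FoodCompositionTable.resolve`."""
    return fct.resolve(food_id)


def nutrients_of_quantity(item: FoodItem, grams: float) -> NutrientVector:
    """Nutrients in ``grams`` of a food (composition is per 100 g)."""
    if grams < 0:
        raise NegativeQuantity(f"{item.id}: grams must be >= 0, got {grams}")
    return item.per_100g * (grams / 100.0)


# ---------------------------------------------------------------------------
# People, households and reference intakes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PersonProfile:
    """Age (years), sex, body weight (kg) and physical activity level.

    PAL multiplies the basal energy rate: ~1.6 is sedentary, 1.7–1.9
    moderately active.
    """

    age: float
    sex: str
    weight: float
    pal: float

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise ValueError(f"sex must be 'female' or 'male', got {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        if not 1.0 <= self.pal <= 2.5:
            raise ValueError(f"pal must be in [1.0, 2.5], got {self.pal}")


@dataclass(frozen=True)
class Household:
    """A set of people sharing a food basket (default modelling unit: six)."""

    members: tuple[PersonProfile, ...]
    district: str = ""

    def __post_init__(self):
        if not self.members:
            raise ValueError("household must have at least one member")

    @classmethod
    def from_json(cls, path: str | Path, district: str = "") -> "Household":
        raw = json.loads(Path(path).read_text())
        members = tuple(
            PersonProfile(age=m["age"], sex=m["sex"], weight=m["weight_kg"], pal=m["pal"])
            for m in raw
        )
        return cls(members=members, district=district)


@dataclass(frozen=True)
class RequirementProfile:
    """Daily reference intakes for a person or household.

    ``daily`` holds the estimated energy requirement, safe protein level and
    micronutrient RDAs; the fat component is the ceiling implied by the
    acceptable macronutrient distribution range (fat ≤ a fraction of energy,
    at 9 kcal/g). ``bioavailability`` records which RDA column was selected
    for iron and zinc.
    """

    daily: NutrientVector
    fat_energy_fraction_max: float = 0.30
    bioavailability: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not 0 < self.fat_energy_fraction_max <= 1:
            raise ValueError("fat_energy_fraction_max must be in (0, 1]")


def load_reference_config(path: str | Path) -> dict:
    """Load a reference-intake config from YAML or JSON."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _find_stratum(config: Mapping, person: PersonProfile) -> Mapping:
    strata = config.get("strata", {}).get(person.sex, [])
    for band in strata:
        if band["age_min"] <= person.age <= band["age_max"]:
            return band
    raise MissingReference(
        f"no reference stratum for sex={person.sex}, age={person.age}"
    )


def _bioavailable_rda(table: Mapping, fraction: float, nutrient: str) -> float:
    for key, value in table.items():
        if math.isclose(float(key), fraction, rel_tol=1e-9):
            return float(value)
    raise MissingReference(
        f"{nutrient}: no RDA column for bioavailability {fraction}"
    )


def person_requirement(person: PersonProfile, config: Mapping) -> RequirementProfile:
    """Daily reference intakes for one person from a table-driven config.

    Energy = basal rate (kcal/kg/day, per age/sex stratum) × weight × PAL,
    hence strictly increasing in PAL. Protein = safe level (g/kg) × weight.
    Iron and zinc come from the RDA column matching the configured
    bioavailability fraction (low availability ⇒ higher reference).
    """
    band = _find_stratum(config, person)
    bio = {k: float(v) for k, v in config.get("bioavailability", {}).items()}
    fat_frac = float(config.get("fat_energy_fraction_max", 0.30))

    energy = float(band["bmr_kcal_per_kg"]) * person.weight * person.pal
    values: dict[str, float] = {
        "energy_kcal": energy,
        "protein_g": float(band["protein_safe_g_per_kg"]) * person.weight,
        "fat_g": fat_frac * energy / 9.0,  # AMDR ceiling, 9 kcal per g fat
    }
    for nutrient, val in band.get("rda", {}).items():
        values[nutrient] = float(val)
    for nutrient, table in band.get("rda_by_bioavailability", {}).items():
        frac = bio.get(nutrient)
        if frac is None:
            raise MissingReference(f"no bioavailability selector for {nutrient}")
        values[nutrient] = _bioavailable_rda(table, frac, nutrient)
    return RequirementProfile(daily=NutrientVector(values),
                              fat_energy_fraction_max=fat_frac,
                              bioavailability=bio)


def household_requirement(household: Household, config: Mapping) -> RequirementProfile:
    """Componentwise sum of member requirements (fat cap stays a fraction)."""
    profiles = [person_requirement(m, config) for m in household.members]
    return RequirementProfile(
        daily=sum_nutrients([p.daily for p in profiles]),
        fat_energy_fraction_max=profiles[0].fat_energy_fraction_max,
        bioavailability=profiles[0].bioavailability,
    )


def percent_of_reference(supply: NutrientVector, requirement: RequirementProfile,
                         days: int = 1) -> dict[str, float]:
    """Supply as a percentage of the cumulative reference over ``days`` days.

    ``days=1`` is a daily %RDA; a school week uses ``days=6``.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    out: dict[str, float] = {}
    for nutrient, ref in requirement.daily.items():
        if ref <= 0:
            raise ZeroReference(f"reference for {nutrient} must be > 0")
        out[nutrient] = 100.0 * supply.get(nutrient, 0.0) / (ref * days)
    return out
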