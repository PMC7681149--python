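# Methods

## Problem setting

A two-period price shock is observed for food commodities in one or more
districts: each food has a "pre" and a "post" price in NPR/kg. Given a food
basket — a week of school meals, or a household's daily consumption — the
question is how much nutrition is lost if the food budget cannot grow. Both
adjustment models below hold the budget fixed and convert the price change
into quantity (hence nutrient) changes; they differ in *who* absorbs the
cut.

## Nutrient accounting

Nutrient content comes from food composition tables (FCTs) giving
quantities per 100 g edible portion for eight default components: energy
(kcal), protein and fat (g), vitamin A (µg), vitamin C, iron, zinc and
calcium (mg). The set is extensible; all arithmetic is componentwise and
linear in grams.

FCT resolution uses an ordered fallback chain. National tables commonly
omit whole nutrients (zinc is the canonical case) or individual cells;
merging is **per nutrient**: a missing component is filled from the first
fallback table that reports it, while present values — including explicit
zeros — are never overridden. An empty CSV cell means *missing*; `0` means
a true zero. A food absent from the primary table entirely may be supplied
whole by a fallback table. Resolution is deterministic for a fixed chain
order, records per-component provenance, and fails loudly
(`UnknownFood` / `IncompleteNutrients`) rather than returning partial
vectors.

## Reference intakes and %RDA

Reference intakes are table-driven (YAML/JSON config), not hardcoded
formulas: guideline bodies publish tables, tables change, and a config
keeps the pipeline auditable. Per sex and age band the config supplies

* a basal energy rate (kcal/kg/day); the estimated energy requirement is
  `rate × weight × PAL`, monotone in the physical activity level
  (sedentary ≈ 1.6, moderate 1.7–1.9);
* a safe protein level (g/kg/day);
* micronutrient RDAs, with iron and zinc keyed by **bioavailability
  fraction**. Plant-heavy, antinutrient-rich diets absorb little of these
  minerals, so the low-availability columns (iron 5 %, zinc 15 %) are the
  defaults and give the highest references.

Fat has no RDA; its reference is the ceiling implied by the acceptable
macronutrient distribution range, 30 % of energy at 9 kcal/g, carried as a
fraction (not summed) when household members are aggregated. A household's
requirement is the componentwise sum of member requirements.

`percent_of_reference(supply, requirement, days)` expresses a supply as a
percentage of the cumulative reference over `days` days: school-meal
analysis uses the six-day school week (`days=6`), household analysis the
daily basket (`days=1`). The choice of horizon rescales %RDA but never the
percent *changes*, which share the denominator.

The shipped default config is illustrative: magnitudes follow FAO/WHO-style
guideline tables, but the values are rounded synthetic defaults so that
tests and examples run closed-box, and the six-member household (two
moderately active adults, one sedentary older female, three children) is a
documented modelling default, not a survey household.

## Price analysis

Group-level change uses the **mean-of-prices** convention: pre and post
prices are averaged (unweighted) over the group's foods and the change is
the relative change of the means. The alternative — averaging item-level
changes — weights cheap and expensive foods equally and is *not* used for
the group statistic, but item-level changes are exposed separately because
group averages mask large intra-group dispersion (a staple can inflate by
half inside a moderately inflating group). Foods missing either period are
excluded from the group statistic and reported. Consumption-share
weighting is deliberately not applied (shares are unknown at survey time).

Base prices collected earlier than the pre reference point can be brought
forward by compounding monthly inflation rates
(`price × Π(1 + rate_m)`).

Costing is `Σ grams/1000 × price`. A missing price is a hard error by
default; the opt-in `carry_pre` policy substitutes the pre price with a
logged warning — silent imputation would bias measured inflation downward,
so it is never the default.

Five price-analysis groups (cereals, pulses, vegetables & fruits, roots &
tubers, animal proteins) drive the group statistics. Cooking oil and sugar
belong to none of them; they carry a sixth, costing-only label
(`oils_sugar`) so baskets can be priced without distorting the five-group
analysis.

## School-meal adjustment (SMFB)

Each of the six meals is adjusted independently (per-meal, not per-basket,
ratios): r = pre cost / post cost, every ingredient × r. Consequences,
asserted as invariants rather than re-derived:

* the adjusted meal's post-price cost equals its pre-shock cost
  (budget conservation, |rel err| < 1e-9);
* ingredient proportions are preserved exactly;
* "scale grams then recompute nutrients" equals "scale the pre-shock
  nutrient vector by r" (linearity, 1e-12 relative);
* if all meals share r, every weekly nutrient changes by exactly
  100 (1 − r) %. With meal-specific ratios the weekly change of a nutrient
  is the ratio mix weighted by each meal's share of that nutrient, which
  is why per-nutrient changes differ.

Deflation (r > 1, prices fell) scales quantities up and is flagged
(`deflation=True`), never clamped — district-level price *decreases* occur
and must flow through. The basket's unit cost is the mean of the six meal
costs; its change is reported alongside the nutrient changes.

## Household adjustment (THFB)

The coping chain is: cost difference D → weighted expenditure cuts →
adjusted grams → nutrient comparison. The weights express relative
sacrifice propensity under price stress (regional price-sensitivity
evidence ranks dairy and fruits highest, cereals lowest, with energy-dense
oil and sugar protected). The allocation
`reduction_i ∝ W_c(i) × e_i`, normalised to sum to D, was chosen because
it (a) restores the pre-shock budget exactly, (b) reduces to plain
proportional cuts when all weights are equal, and (c) keeps W
interpretable as a multiplier on an item's natural (expenditure-share)
cut. Post-shock expenditures e_i are used as the base; using pre-shock
shares instead would misprice the clawback at the new prices.

Animal-source foods are not named in the canonical weight list; they are
assigned to the top class (with fruits and dairy, W 2.5), consistent with
the price-sensitivity ranking that puts animal-source foods first. This is
a package design choice.

Feasibility: a cut larger than an item's whole expenditure raises
`InfeasibleReduction`. The optional `redistribute` mode caps exhausted
items at their full expenditure and re-allocates the remainder over the
remaining weighted items — an extension beyond the plain weighted scheme,
off by default. If D ≤ 0 (the basket got cheaper) quantities are left
unchanged by default: coping is one-directional; `adjust_deflation=True`
enables symmetric proportional scale-up.

## Sensitivities

Per-unit-cost sensitivity is linear attribution: observed percent nutrient
decrease divided by the observed cost increase, rescaled to the convention
unit — 1 NPR for a school meal's unit cost, 10 NPR for the (much larger)
household daily cost. By construction sensitivity × observed cost rise
reproduces the total change; it is a reporting convention, not an
extrapolation model, and is undefined (error) when cost did not rise.

## Synthetic scenarios

The generator emulates a district food-price survey: ~27 commodities (5
per price group across five groups, two fine groups interleaved where a
price group spans them, plus oil and sugar), uniform pre-shock prices from
per-group NPR/kg ranges, and post prices
`pre × (1 + g_group) × lognormal(−σ²/2, σ)` — multiplicative unit-mean
noise keeps prices positive and the expected group change equal to the
configured inflation. Default group inflations are the study conditions
(pulses 0.18, vegetables & fruits 0.14, roots & tubers 0.10, cereals 0.10,
animal proteins 0.02; oil/sugar 0.08 as a mid-range costing-only value);
the default item noise σ = 0.05 reflects documented wide intra-group
dispersion while keeping group recovery informative. Negative inflation is
supported.

Nutrient values are drawn from documented per-group ranges chosen only for
their *signatures* (cereals zinc-rich, leafy vegetables and dairy
vitamin-A-rich, pulses protein/iron-rich, oil pure fat); they are labelled
synthetic and claim no fidelity to any national FCT. `drop_zinc_fraction`
blanks zinc in part of the primary table and generates a matching regional
fallback, exercising the resolution chain.

Baskets: six meals of 3–7 ingredients spanning ≥ 3 food groups
(staple + pulse + vegetable + oil, with optional fruit/animal/dairy
extras); the household basket covers all five weight classes including
protected items, at quantities plausible for six people (≈1.8 kg cereals,
0.5 kg vegetables, 90 g oil per day, etc.). Every draw flows from one seed
through named substreams; an entire bundle is a pure function of its spec.

What the generator does **not** emulate: seasonality, purchasing-power
changes, consumption-share price weighting, correlated cross-district
shocks, and real FCT covariance between nutrients. Tests passing on
synthetic bundles therefore demonstrate the *mechanics* (conservation
laws, recovery, directionality) — not empirical accuracy for any real
district.

## Numerical choices

* Internal arithmetic is full precision; rounding (2 decimals) happens
  only at report serialisation.
* Budget-conservation tolerances are 1e-9 relative; linearity identities
  1e-12 relative.
* Percent change of a nutrient with zero pre-shock supply is reported as 0
  (the only consistent value under proportional scaling).
* Group price-change recovery under the default Monte-Carlo conditions
  (σ = 0.02, 12 foods/group) has an analytic weighted-mean noise sd of
  ≈ 0.7 percentage points, so a ±2 pp band is a ≈ 3σ criterion.
* Problem sizes in tests and the acceptance script (27 foods, 3 districts,
  200-replicate conservation sweeps, 500-replicate recovery sweeps) were
  chosen so the full suite runs in seconds while keeping Monte-Carlo
  standard errors well inside the asserted bands.

## Known limitations

* The coping-weight normalisation is an interpretation: the weighted
  scheme is stated in the literature without its normalisation; other
  allocations (e.g. ∝ W alone, ignoring expenditure) would also sum to D
  but lose property (b) above.
* Single-unit price model: everything must be NPR/kg on ingest; foods
  priced per piece or litre must be converted upstream.
* No intra-household allocation: the household is a single pooled consumer.
* Reference configs are illustrative defaults, not clinical guidance.
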