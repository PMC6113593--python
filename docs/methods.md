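# Methods

## The measurement model

`dietledger` treats a meal as a set of *plate events*. Each event is one
consumer taking one RFID-tagged plate carrying one dish; the plate encodes
the dish name, a price, and a serving weight fixed by the kitchen per
plate type. The package therefore measures *served* food, not the portion
actually eaten: plate-waste estimation is out of scope, and every
downstream number inherits that assumption.

Nutrient content is computed by recipe decomposition. A recipe lists raw
ingredient weights; for a serving of weight `w`, ingredient `i` with raw
weight `w_i` contributes `w_i / Σ_j w_j × w` grams, where the sum runs
over the *counted* ingredients. Per 100 g of dish,

```
c_x = Σ_i (scaled_weight_i / 100 g) × (nutrient x of i per 100 g)
```

Two modelling simplifications are deliberate and should be kept in mind
when interpreting output:

* **Raw-weight basis.** The 100 g basis is 100 g of total *raw* counted
  ingredient weight. No cooking-yield, water-loss, or nutrient-retention
  correction is applied, although preparation methods are recorded and
  reported. Stir-fried and steamed dishes are therefore treated alike at
  the nutrient level.
* **Auxiliary ingredients excluded.** Condiment-scale components (ginger,
  garlic, scallion) are flagged by the recipe author and skipped by
  default — both in the denominator `Σ_j w_j` and in the nutrient sum.
  Every engine entry point takes `include_auxiliary=True` to opt in. The
  flag is author-supplied, never inferred from a weight threshold: a
  helper heuristic would make behavior depend on portioning conventions.

## Absent is not zero

Composition tables rarely report all nutrients for all ingredients. An
empty cell parses to an explicit absent marker (`None`), and absence is
*contagious*: a dish nutrient is absent if any counted ingredient lacks
it, and an aggregate is absent if any summand is. Each propagation leaves
a note in the result vector's `warnings` attachment. The alternative —
coercing to zero — silently understates intake and was rejected.

## Record selection

Four filter stages mirror the data-collection pipeline: meal-slot match
(default lunch), valid plate type (1–3), dish resolvable in the recipe
database, and full composition coverage of the recipe. Filtering is
total, order-preserving, and reported per stage as (entering, surviving)
pairs with a chained-count invariant. The meal slot is a categorical
field of the record; for timestamped inputs a clock-time classifier is
provided (`meal_slot_from_time`, default lunch window 11:00–14:00,
half-open).

The `PlateEvent` container itself does not enforce plate-type or
meal-slot validity: file ingestion (`parse_events`) rejects malformed
rows with per-row reasons (and refuses a file once a majority of rows are
rejected, treating it as a schema mismatch), while stage 2 of the filter
screens in-memory streams. Enforcing validity in the constructor would
make the filter stage unreachable and untestable.

## Validation statistic

Calculated content is compared with chemical reference measurements by
per-nutrient absolute percentage deviation,
`MAPD_x = |c_x − m_x| / m_x × 100`. The deviation is undefined when
`m_x = 0` (rendered as an em dash, not 0.00 — a both-zero pair carries no
information about relative error), and `c_x = 0` against `m_x > 0` gives
exactly 100. The statistic is asymmetric by design: the chemical
measurement is the baseline. Display rounding is half-up at 2 decimals;
full precision is retained internally. A per-dish mean over the defined
cells is available (`DeviationReport.mean_deviation`) for summary use.

The packaged reference fixture provides the three dishes' published
calculated/measured pairs (energy, protein, fat, carbohydrate per 100 g).
The matching recipe file carries the published ingredient lists and
preparation methods but *synthetic* raw weights, since the originals are
not public; it supports structural tests only, and no attempt is made to
re-derive the published calculated values from recipes (the weight basis
behind them is unknown).

## Reporting conventions

Distribution reports carry (label, count, percentage) rows ordered by
descending count with alphabetical tie-breaks; percentages are half-up at
one decimal and counts always accompany them, so rounding is recoverable.
Dish-type and method distributions tally *unique* dishes by default (an
events-weighted variant sits behind `unique=False`); the method
distribution restricts to cooked dishes by default, where preparation
method is most informative. The ingredient-category distribution counts
*distinct ingredient kinds* over the union of the dish set's counted
ingredients — duplicating a dish in the input cannot change it. With a
closed vocabulary and a non-empty input, zero-count labels are still
listed; an empty input yields an empty report with total 0.

Food-frequency windows are closed intervals `[start, end]`; adjacent
windows add row-wise.

## Synthetic data: what it emulates, what it does not

The generator emulates a canteen deployment: a menu over the three dish
types, a composition table covering it (23 nutrient columns; energy of
synthetic ingredients follows Atwater factors, 4·protein + 9·fat +
4·carbohydrate, so generated rows are internally consistent), and a
stream of lunchtime plate events in which each consumer draws dishes from
a personal categorical preference (Dirichlet-distributed unless pinned
explicitly). Default scale is 50 consumers × 30 days × a 50-dish menu
with an 80-ingredient pool — the same code paths as a full deployment
(489 dishes, ~1400 ingredients, which dedicated tests exercise) at a size
suited to routine runs. Serving weights are uniform per plate type
(staple 100–250 g, cooked 150–300 g, soup 200–400 g), in the range of
typical canteen portions.

Corruptions are injected per event at a configured rate, one kind per
affected event, drawn from a taxonomy that mirrors the four filter stages
(wrong meal slot, invalid plate type, unknown dish, recipe with an
uncovered ingredient), and ledgered exactly — filter tests assert that
the removed rows equal the ledger. The uncovered-ingredient kind requires
a planted off-menu dish, which is added only when that corruption is
enabled, keeping clean configurations fully covered.

What the generator does *not* model: realistic dish co-occurrence and
culinary structure, demographic covariates, seasonal menu drift, price
elasticity, or measurement noise on serving weights. Passing tests
demonstrate correctness of the pipeline's arithmetic and bookkeeping
under known ground truth, not nutritional realism of any particular menu.

All generators are pure functions of the configuration and seed (one
`numpy` Generator per stream, seeded as `(seed, stream_index)`), so every
simulated dataset is reproducible byte for byte.

The single-consumer scenario plants a 15-of-20-working-days rice-and-soup
habit against a hand-set six-dish menu with realistic core-nutrient
values, providing exact ground truth for food-frequency recovery and a
full 20-entry daily intake series.

## Numerical choices

* Weighted sums run over ingredients in sorted-name order and aggregation
  pre-sorts records on a stable key, so floating-point results do not
  depend on input order.
* Mass conservation of decomposition and engine-vs-oracle agreement are
  asserted at 1e-9 relative tolerance — slack for reordering error only.
* Display rounding is decimal half-up (1 decimal for percentages, 2 for
  deviations) computed via `decimal.Decimal`, not binary `round`.
* Dish and ingredient names are matched exactly after trim / case-fold /
  whitespace-collapse normalization. Fuzzy matching is a non-goal; a
  misspelled dish is a stage-3 filter drop, visible in the report.
* Composition values are documented as per 100 g *edible portion*; the
  package applies no edible-portion conversion of its own.

## Known limitations

Serving weight is the kitchen's nominal plate weight, not the consumed
amount; cooking transformations are ignored; auxiliary ingredients are
ignored by default; composition coverage gaps surface as absent nutrients
rather than estimates. These are faithful properties of the measurement
design the package implements, not bugs to be corrected downstream.
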