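# File formats

All inputs are plain text, UTF-8. Delimited files require a header row.

## Plate events — CSV

Columns, in any order:

| column             | type    | notes                                   |
|--------------------|---------|-----------------------------------------|
| `consumer_id`      | string  | opaque, non-empty                       |
| `dish_name`        | string  | normalized (trim/case-fold/collapse)    |
| `plate_type`       | int     | 1 staple, 2 cooked dish, 3 soup         |
| `serving_weight_g` | float   | > 0                                     |
| `price`            | float   | ≥ 0, currency units                     |
| `meal_slot`        | string  | `breakfast` \| `lunch` \| `supper`      |
| `date`             | string  | ISO-8601 calendar date                  |

Invalid rows are reported with line number and offending field; a file
with a majority of invalid rows is rejected as schema-mismatched.

## Recipe database — JSON or YAML

```yaml
schema_version: 1
source: optional free text
recipes:
  - dish: dry-fried string beans
    dish_type: cooked            # staple | cooked | porridge_soup (aliases accepted)
    method: stir-fry             # stir-fry | steam | boil | roast | deep-fry
                                 # | braise | raw | other (aliases accepted)
    ingredients:
      - {name: string beans, weight_g: 400}
      - {name: minced pork, weight_g: 80}
      - {name: garlic, weight_g: 10, auxiliary: true}
```

A bare list of recipe records is also accepted. Every recipe needs at
least one non-auxiliary ingredient with positive weight; dish names must
be unique after normalization. Alias spellings such as `steaming`,
`stir frying`, `porridge and soup` resolve to the controlled tokens.

## Food-composition table — CSV or TSV (by extension)

Required columns: `ingredient`, `category`, `energy_kcal`, `protein_g`,
`fat_g`, `carbohydrate_g`, `fiber_g`. Any additional columns are treated
as further nutrients (the packaged generator emits the full 23-nutrient
set). Values are per 100 g edible portion. An empty cell means *not
measured* (absent), which is distinct from `0`. `category` is one of:

vegetables and vegetable products; tubers, starches and their products;
meat and meat products; poultry and poultry products; fungi and algae;
fish, shellfish and molluscs; cereals; legumes; eggs; fruits; other.

Rows with negative values or unknown categories are excluded and recorded
on the loaded table's `rejected_rows`; duplicate ingredient names are a
hard error.

## Reference measurements — CSV

Long format: `dish, nutrient, measured_per_100g, method`, one row per
(dish, nutrient) pair; `method` is free-text assay annotation and may be
empty. The packaged `reference_dishes_measured.csv` / `reference_dishes_calculated.csv`
carry the three reference dishes' published measured and calculated
values.

## Simulation config — YAML (CLI `simulate --config`)

Any subset of `SimulationConfig` fields, e.g.

```yaml
n_consumers: 50
start_date: 2016-01-05
n_days: 30
menu_size: {staple: 8, cooked: 38, porridge_soup: 4}
corruption_rate: 0.02
```

The `--seed` option overrides the config seed.
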