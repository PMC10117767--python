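# cmnutricycle

Nutrient-cycling and nutrient-management cost models for cultured meat (CM)
compared with swine, beef, and broiler production.

In conventional meat systems, manure nitrogen is land-applied back to the
corn and soybean fields that grow the feed, closing a nutrient loop.
Cultured meat grown on soybean hydrolysate (protein) and corn-starch
glucose (energy) produces a spent-media waste stream instead of manure, and
most published analyses stop before asking what happens to it. This package
puts numbers on that question, for bioprocess and agricultural-systems
modellers:

- **growth** — specific growth rate μ = ln(m_f/m_i)/t, feed conversion
  ratio (FCR), and protein conversion efficiency
  (PCE = edible protein out / protein fed) for each system;
- **areal** — cropland per kg of meat with price-based co-product
  allocation (meal/oil, starch/gluten), inverted into areal protein
  (g m⁻² yr⁻¹) and energy (MJ m⁻² yr⁻¹) productivities;
- **nbalance** — exact per-batch protein/nitrogen, glucose/COD, water, and
  oxygen ledgers, scaled to revenue-driven annual production;
- **costs** — land-application geometry and cost (circular service
  territory, beyond-one-mile surcharge), wastewater-treatment cost
  ($ kg⁻¹ N + $ kg⁻¹ COD), and manure comparators;
- **nue** — retained/recoverable/lost partitions of fed nitrogen and the
  recovery rates CM needs to match each animal system;
- **sampler** — seeded Monte-Carlo ensembles and one-at-a-time tornado
  sensitivities over published parameter ranges.

## Worked example

```python
from cmnutricycle import nbalance, costs, nue
from cmnutricycle.params import default_scenario

sc = default_scenario()                      # packaged presets
batch = nbalance.batch_balance(sc.cm_batch)  # one 15 m3, 345 kg batch
print(f"protein fed   {batch.protein_fed:7.1f} kg")
print(f"waste N       {batch.nitrogen_waste:7.1f} kg  "
      f"({batch.nitrogen_concentration:.2f} kg N/m3)")
print(f"respired      {batch.glucose_respired:7.1f} kg glucose "
      f"({100 * batch.glucose_respired / batch.glucose_fed:.1f}% of fed)")

scen = nbalance.scale_scenario(sc.cm_batch, meat_price=10.0,
                               revenue_target=1e7, batch=batch)
plan = costs.application_plan(scen, sc.economics)
print(f"annual N      {scen.annual_nitrogen:,.0f} kg over {scen.batches_per_year} batches")
print(f"service area  {plan.adjusted_area_ha:,.0f} ha "
      f"(radius {plan.service_radius_km:.1f} km, "
      f"{100 * plan.fraction_beyond_threshold:.0f}% beyond one mile)")
print(f"application   ${plan.specific_cost:.2f} per kg CM")
print(f"lost N        {100 * nue.cm_partition(0.24).lost_fraction:.0f}% of fed N")
```

prints

```
protein fed     258.8 kg
waste N          31.5 kg  (1.06 kg N/m3)
respired         80.1 kg glucose (11.3% of fed)
annual N      91,214 kg over 2899 batches
service area  1,551 ha (radius 2.2 km, 48% beyond one mile)
application   $0.32 per kg CM
lost N        76% of fed N
```

Reading: a $10 kg⁻¹ facility earning $10M yr⁻¹ must run 2,899 batches,
leaving ~91 t of nitrogen per year in spent media at 1.06 kg N m⁻³ — about
19,000 person-equivalents of nitrogen waste. Land-applying it serves a
2.2 km-radius circle of corn land and costs $0.32 per kg of meat, several
times the equivalent cost for manure, because spent media is far more
dilute. Without nitrogen recovery, CM loses 76% of its fed nitrogen —
worse than swine (47%) or broilers (55%), better only than beef (84%).

## Command line

```sh
cmnutricycle growth-table            # growth/feed comparison
cmnutricycle nitrogen                # annual N/COD scenario table
cmnutricycle areal                   # land use and productivities
cmnutricycle costs                   # management cost comparison
cmnutricycle nue                     # NUE partitions + parity targets
cmnutricycle report --out out/       # all tables + metadata
cmnutricycle sensitivity --n 1000 --seed 1 --out sens/
```

All subcommands accept `--config scenario.yaml`, a YAML/JSON document whose
sections (`animals`, `cm_batch`, `feedstocks`, `economics`, `meat_prices`,
`revenue_target`) override the packaged presets field by field; unknown
keys are rejected by name.

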