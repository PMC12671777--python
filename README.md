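# aquabatch

Headless processing, visualization and analysis of AquaCrop-style
crop-water simulation outputs — plus a seeded synthetic fixture
generator so the whole pipeline runs without the simulation engine.

## The problem

Crop-water productivity models such as FAO's AquaCrop write each
simulation run's results into a handful of plain-text files (10 per run
in GUI mode, 3 in batch "plug-in" mode). A factorial climate-impact
study — locations × sowing dates × management practices × emission
scenarios × climate models, over decades — produces hundreds of runs
and thousands of files. `aquabatch` is for the modeller who has that
pile of files and wants tidy tables, trend statistics and plots without
hand-rolling parsers:

* **readers** — discover and match files into runs by their shared
  filename prefix, decode underscore-separated metadata tokens from the
  prefix (`Maize_Soroca_RCP26` → crop/location/scenario), and parse
  project, daily and seasonal files (missing-value sentinel `-9.00`
  handled throughout).
* **assembly** — combine everything into three tidy tables (project,
  seasonal, daily) with the metadata joined on, plus filtering,
  renaming, and RFC-4180 CSV export.
* **analysis** — time-window summaries (n, mean, SD, CV = SD/mean per
  group and window) and per-group simple linear regression
  (slope = Sxy/Sxx, R², two-sided slope t-test at df = n−2).
* **plotting** — scatter/time-series plots with optional LOESS smooth
  (tricube local linear regression), boxplots, color grouping and
  faceting; every image comes with a JSON sidecar of the plotted data
  summaries.
* **fixturegen** — seeded synthetic weather (seasonal cycle + linear
  warming trend + noise), a toy crop-water simulator built on the
  water-driven production relations `B = ΣTr × WP*` and `Y = HI × B`
  with GDD-driven cycle length and a binary 9–30 °C temperature-stress
  rule, and writers that emit complete, dialect-valid GUI or plug-in
  file sets for full factorial designs.

The toy simulator closes its daily root-zone water balance exactly
(rain = E + Tr + runoff + drainage + Δstorage) and warmer weather
shortens its crop cycles, so generated studies have the statistical
structure real climate-impact studies show.

## Worked example

Generate a small 30-year factorial study (2 locations × 2 emission
scenarios), combine it, and regress crop cycle length on year:

```sh
cat > design.yaml <<'EOF'
crop: Maize
factors:
  location: [Soroca, Cahul]
  scenario: [RCP26, RCP85]
overrides:
  location:
    Soroca: {base_tmax: 15.0}
    Cahul: {base_tmax: 17.0}
  scenario:
    RCP26: {warming_trend: 0.1}
    RCP85: {warming_trend: 0.5}
weather: {n_years: 30}
EOF

aquabatch generate --design design.yaml --out fx --seed 11
aquabatch combine fx/* --tokens crop,location,scenario --out combined
aquabatch regress --table combined/seasonal.csv --y Cycle --x Year --group scenario --out reg.csv
```

which prints the per-run match report and table sizes:

```
4 run file sets written to fx
run Maize_Cahul_RCP26 [plugin]: 3 file(s) (day, project, season)
...
project: 4 row(s) -> combined/project.csv
seasonal: 120 row(s) -> combined/seasonal.csv
daily: 13234 row(s) -> combined/daily.csv
2 regression row(s) -> reg.csv
```

and `reg.csv` holds:

```
scenario  n     slope   intercept  r_squared  p_value
   RCP26 60 -0.172525  462.993585   0.036159 0.145598
   RCP85 60 -0.536930 1193.864627   0.316559 0.000003
```

Under the strong-warming scenario the crop cycle shortens by about half
a day per year (slope −0.54, p ≈ 3×10⁻⁶) because growing degree days
accumulate faster, while the low-warming scenario shows no significant
trend — the qualitative signature such studies look for. The same table
feeds `aquabatch summarize` (20-year window means of, say, water
productivity `WPet`) and `aquabatch plot` (scatter with LOESS smooth,
faceted by scenario).

Everything the CLI does is also a library call
(`aquabatch.readers.discover_runs`, `aquabatch.assembly.combine`,
`aquabatch.analysis.linear_regression`, ...).

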