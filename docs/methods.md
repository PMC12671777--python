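# Methods

## What this package computes

`aquabatch` is a headless toolkit for the batch-analysis workflow that
surrounds a crop-water productivity simulator such as AquaCrop: many
simulation runs, each dropping a handful of plain-text output files,
combined into tidy tables and then summarized, regressed and plotted.
Because the simulation engine itself is out of scope, the package ships
a synthetic fixture generator — a deliberately simple crop-water model
with the right file formats and the right statistical structure — so
the entire pipeline is exercisable and testable end to end.

## The output dialect

Real engine output layouts vary by version; this package defines one
normative dialect (documented in `aquabatch/dialect.py`) that its
writers emit and its readers accept: a title line, a blank line, a
variable-name header, a units header, then whitespace-aligned numeric
rows printed to 2 decimals. Daily files lead with `Day Month Year DAP
Stage`; seasonal files with `Run Year`. Plug-in daily files with more
than one season delimit seasons with `Run: N` block headers; GUI daily
files do not, and the reader recovers the season index from the DAP
column resetting to 1. Undefined cells (here: all salinity variables,
since the toy model carries no salt) hold the sentinel `-9.00`, which
readers always surface as missing — a cell that legitimately rounds to
-9.00 would be absorbed by the sentinel, an accepted quirk of the
convention that cannot arise under the default growing-season
conditions. Header-driven parsing means column sets may differ between
files without any reader changes.

The seasonal summary schema has exactly 41 variable columns after the
keys, spanning simulation-period, climatic, soil-water, soil-salinity,
stress and production categories; GUI mode partitions the daily
variables over 8 category files plus a project file and a seasonal
`Run.OUT` (10 files per run), plug-in mode writes project + `day.OUT` +
`season.OUT` (3 files per run). `Run.OUT` and `season.OUT` contain
identical values for the same simulation.

## The toy crop-water model

One season is a daily loop over a weather window starting at the sowing
day:

* **Thermal time.** `GDD_day = max(0, (Tmax+Tmin)/2 − T_base)` (average
  method, `T_base` default 10 °C). The season ends on the first day
  cumulative GDD reaches `gdd_maturity` (default 1150 °C·day), or after
  `max_cycle_days` (180) as a cap. Warmer years therefore give shorter
  cycles, the central qualitative behaviour the fixtures must have.
* **Canopy.** Cover ramps linearly to `cc_max` over `cc_ramp_days` then
  holds — a plausible shape standing in for the logistic canopy growth
  of a real model; the fixtures need structure, not fidelity.
* **Temperature stress.** `Ks = 0` when the daily mean leaves the
  optimal band [9, 30] °C, else 1 (binary by design; only the band, not
  a response shape, is specified for the crops emulated). A stress day
  is any day with `Ks < 1`.
* **Transpiration and evaporation.** Demand is `Tr = Ks·Kc·CC·ETo` and
  `E = (1−CC)·0.5·ETo`; both are scaled down proportionally when the
  root-zone store plus the day's infiltration cannot supply them.
* **Water balance.** A single root-zone bucket (capacity 150 mm,
  initially half full, infiltration capped at 40 mm/day with the excess
  as surface runoff, overflow as drainage) closes exactly every day:
  `rain = E + Tr + runoff + drainage + Δstorage`. The test suite checks
  closure to 1e−9 mm.
* **Production.** `B = WP* · ΣTr` (water-driven biomass with `WP*` in
  t/ha per mm; the normalization of transpiration by ETo that a full
  model applies is intentionally omitted — the fixture implements the
  plain proportional form) and `Y = HI · B`. Both identities hold
  exactly, by construction, on every simulated season.
  Evapotranspiration water productivity is `WPet = 100·Y/ΣET` in kg of
  yield per m³ of evapotranspired water (Y in t/ha, ΣET in mm).

## Synthetic weather

Years are idealized 365-day years (no leap days), which keeps
day-of-year and trend arithmetic exact over decades. Daily temperature
is `base + A·cos(2π(doy−196)/365) + (trend/10)·(t/365) + ε`, with one
noise draw per day added to both extremes so the diurnal gap is
preserved. ETo follows the same seasonal shape around `eto_base`
(floor 0.1 mm/day); rainfall is a wet-day process (probability 0.35,
exponential amounts). With a trend of `w` °C/decade the mean of year
`k` exceeds year 0 by exactly `k·w/10` — the closed form the trend
tests use.

### Default study conditions

Defaults emulate a multi-decade factorial climate-impact study in a
temperate continental setting (Moldova-like): 90 years from 2010;
annual-mean Tmin/Tmax 4/16 °C, seasonal amplitude 12 °C (July mean
≈ 22 °C), noise SD 2 °C; warming 0.1 °C/decade for a low-emission
scenario and 0.5 °C/decade for a high-emission one; ETo base 3 mm/day;
mean rainfall 1.5 mm/day (≈ 550 mm/yr, so maize is water-limited and
rainfed yields land in the 3–8 t/ha range). The reference maize
parameters are Kc 1.05, `cc_max` 0.9 (0.75 non-optimal management),
WP* 0.04 t/ha/mm, HI 0.48 (0.44 non-optimal), sowing 26 Apr / 11 May /
26 May (day-of-year 116/131/146). The reference design —
3 locations × 3 sowing dates × 2 managements × 2 scenarios × 3 climate
models — yields 108 runs per crop; each cell derives its weather seed
from the base seed and its position in the factor product, so repeated
generation is byte-identical.

What the generator does **not** emulate: spatial correlation between
locations, autocorrelated weather, CO₂ fertilization, soil
heterogeneity, salinity and fertility dynamics, or any calibrated
engine physics. Passing tests demonstrate that the *pipeline* —
matching, parsing, combining, summarizing, regressing, plotting — is
correct on files with realistic structure; they say nothing about the
agronomic fidelity of any particular engine run.

## Statistics

* **Time-window summary.** Windows of user width start at the minimum
  observed time value over the whole table (so windows align across
  groups) and step by the width; the final window may be partial,
  visible through its clipped `window_end`. Per group and window the
  report holds the non-missing count `n`, mean, sample SD (n−1
  denominator) and CV = SD/mean; CV is reported missing (never ±inf)
  when the mean is 0 or n < 2. Anchoring at the data minimum is a
  documented choice, not asserted behaviour of any other tool.
* **Simple linear regression.** Per group, closed-form OLS:
  `slope = Sxy/Sxx`, `intercept = ȳ − slope·x̄`,
  `R² = Sxy²/(Sxx·Syy)`, and a two-sided t-test on the slope with
  df = n−2 (p from the Student-t survival function). Degenerate cases:
  zero x-variance gives a missing slope plus a logged warning; constant
  y makes R² a 0/0 and it is reported missing; an exact fit with a
  nonzero slope reports p = 0. p-values are raw — no multiplicity
  correction, matching how per-group regression screens are usually
  read. Tests verify equality with an independent statsmodels oracle to
  1e−9.
* **LOESS.** Locally weighted linear regression with tricube weights
  over the `ceil(span·n)` nearest neighbours (span default 0.75),
  evaluated on a 100-point grid across the x-range. When the window
  covers the whole sample (span = 1) the weights are taken uniform, so
  the smooth degenerates to the global least-squares line — the natural
  limit, and the reason a full-span smooth of 3 points equals their OLS
  line. Zero local x-spread falls back to the weighted mean.
* **Boxplots.** Five-number summaries use linear-interpolation
  (type-7) quartiles and the 1.5·IQR whisker rule. Every plot also
  emits a JSON sidecar (panel list, per-series point counts, box
  summaries) so tests compare data, not pixels.

## Problem sizes and determinism

The acceptance script regenerates everything from scratch per
invocation: the 108-run factorial study uses 30 weather years (the
counts and schema widths it measures do not depend on the series
length) and the warming sign-recovery study uses 40 zero-noise years —
sizes chosen to make the whole script run in well under a minute while
leaving dozens of seasons per regression group. All randomness flows
from the single `--seed`; derived per-run seeds stay below 2³¹.

## Known limitations

* The dialect is normative for this package, not byte-compatible with
  any particular engine version; readers are header-driven specifically
  so that near-dialect files still parse.
* Binary temperature stress makes `stress_pct` a step function of
  temperature; smooth stress responses cannot be emulated.
* The daily water balance is a single bucket; no layered soil water
  movement, groundwater, or capillary rise (`Upflow` is always 0).
* Filtering supports conjunctions of simple comparisons only;
  disjunctions require two passes.
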