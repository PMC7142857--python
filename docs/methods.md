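# Methods note

## Scope

`tmaexpo` computes population exposure to NO2 and PM2.5 on a fine
receptor grid from externally supplied hourly concentration fields. The
chemistry-transport modelling that produces those fields is out of
scope; the package consumes them (or generates synthetic ones) and
implements the exposure layer: microenvironment construction,
time-resolved population distribution, infiltration, exposure metrics,
source contribution, emission downscaling and model-evaluation
statistics.

## Exposure model

Let C_{i,t} be the ambient concentration in grid cell *i* at hour *t*,
P_{i,j,t} the number of people in cell *i* and microenvironment *j* at
hour *t*, and F_inf,j the infiltration factor of environment *j*
(resolved per pollutant and season). Then

- total exposure: E = Σ_j F_inf,j Σ_t Σ_i C_{i,t} · P_{i,j,t}
  (µg/m³·persons),
- population-weighted exposure: PWE = E / Σ_j Σ_t Σ_i P_{i,j,t}
  (µg/m³), optionally restricted to a scope of environments (e.g. a
  single transport mode).

Exposure is linear in each of C, P and F_inf separately and additive
over superposed concentration fields; the test suite checks these
properties against brute-force loop oracles.

Per-environment accumulation uses a fixed-order einsum
(`np.einsum('t,tyx,tyx->yx', ..., optimize=False)`) so results are
bit-reproducible across runs and independent of dictionary iteration
order.

## Approaches

- **static** — the whole population sits at home around the clock; the
  home stack is the (growth-scaled) residential raster frozen in time.
- **dynamic** — an hourly activity profile moves the population between
  home, work, other and an undivided transport environment.
- **dynamic_transport** — as dynamic, but the transport total is split
  over seven modes (walking, cycling, in_car, buses, subway_trains,
  suburban_trains, regional_trains) by a modal split.

The home total is distributed over cells in proportion to the
residential raster; all other environments are spread uniformly over
their mask. This makes the model exactly degenerate: with an all-home
activity profile and equal infiltration factors, the dynamic approaches
reproduce the static result cell by cell (verified at 1e-12 relative).

Population is conserved by construction: at every hour the environment
totals sum to residents plus scheduled commuters, and the seven mode
totals sum to the undivided transport total (verified at 1e-9 relative
over a 14-day run).

## Microenvironments

Base environments come from land-use polygons via a configurable
mapping (residential → home; industrial/commercial → work; public
services → work and other; green/leisure → other; roads-associated land
→ transport). A cell belongs to an environment if any mapped polygon
intersects it. Transport-mode masks come from tagged network polylines:
per-mode tag queries (e.g. in_car: motorway/trunk/primary/secondary;
buses: the same minus motorways; walking: footways, paths, residential
streets; rail modes from rail tags) are rasterised with a closed
cell-square intersection rule, validated in tests against a 1 m
supersampling oracle.

## Population dynamics

- Activity profiles are 24 × 4 tables (weekday and weekend variants)
  whose rows sum to 1; a plausible generic European profile is the
  default and profiles can be loaded from CSV.
- Commuters (e.g. 223,000 on workdays for a Hamburg-sized city) are
  added to transport during rush windows (default 07–09 and 16–19) and
  to work during working hours (default 09–16), weekdays only;
  configured holidays count as weekends.
- The default modal split is the Hamburg 2017 household-survey split —
  car 36%, walking 27%, cycling 15%, public transport 22% with a
  bus/subway/suburban/regional sub-split of 36/32/25/6 — with the 1%
  ferry share dropped and the remainder renormalised by 0.99.
- A census-to-study-year growth factor (e.g. 1.043) scales the
  residential raster.

## Infiltration

F_inf = C_indoor,ambient / C_ambient per (environment, pollutant,
season). The built-in table gives homes 0.5/0.6 (PM2.5 winter/summer)
and 0.7/0.8 (NO2), workplaces similarly, 0.8/1.0 for other
environments, 1 for open-air modes (walking, cycling), and intermediate
values for vehicle cabins and trains (e.g. in_car 0.7/0.8 PM2.5 and
0.9 NO2, subway 0.7 PM2.5 / 0.6 NO2). Winter is October–March by
default (4392 h of the 8784-hour leap year 2016) and the month mapping
is configurable. Values are validated to [0, 1.5] with a warning above
1. Scenario bands (reference/minimum/maximum tables with entrywise
ordering) support sensitivity runs; the default derivation perturbs the
reference by ±30%.

## Emissions

Gridded inventory cells inside an urban-core mask are scaled ×3 before
disaggregation to road links. Each cell's emission is allocated to the
link segments clipped to that cell in proportion to segment length ×
road-type weight (defaults motorway 4, trunk 3, primary 2,
secondary 1). Cells with emissions but no intersecting road are kept in
a residual ledger so that allocated + residual equals the grid total
exactly (verified at 1e-9 on random fixtures, invariant to link order
and collinear splitting). Scenario scaling multiplies line emissions by
per-pollutant factors; the reference scenario corresponds to ×1.3 (NO2)
and ×1.2 (PM2.5) relative to the raw inventory and the maximum scenario
to ×1.4 / ×1.3, so the minimum-relative-to-reference factor is 1/1.3
resp. 1/1.2.

## Source contribution (zero-out)

Given a full concentration stack and a stack with one source category
removed, the difference field is the source's contribution; its
exposure divided by full exposure is the relative contribution per
environment. Negative differences (possible with nonlinear chemistry
upstream) are kept, with a warning if they exceed 1% of cells. On
synthetic fields built as background + known road increment, the
recovered contribution equals the injected increment's exposure
(verified at 1e-9).

## Evaluation statistics

MB, NMB (sum-ratio form), RMSE, Pearson r (reported as missing for
constant series), Willmott index of agreement, and FAC2 with an
inclusive [0.5, 2] band and observation-zero pairs excluded. The
FAIRMODE-style check FAC2 ≥ 0.3 is boundary-inclusive. Daily means
require ≥ 75% hourly coverage. All statistics are tested against
independent spreadsheet-style oracles at 1e-12.

## Synthetic city generator

The generator exists to exercise the pipeline end to end with known
ground truth, not to emulate any real city. From a single seed it
builds a 3 × 3 km domain at 100 m resolution with a grid-shaped major
road network (motorway/trunk spine, primary/secondary cross streets),
residential streets, footways, cycleways and three rail lines; 12
residential blocks on a peripheral ring and 6 work blocks near the
centre; a 500 m emission grid proportional to road length; and hourly
concentration stacks composed of a lognormally perturbed background
plus a road-proximal increment peak·exp(−d/decay)·shape(hour) with a
bimodal diurnal traffic shape peaking at 08:00 and 17:00. The full
field equals zero-out + increment by construction, giving an exact
target for the source-contribution path, and emission scenarios scale
the increment linearly.

## Numerical choices and limitations

- All randomness flows through `numpy.random.default_rng` from a single
  seed; repeated runs are bit-identical.
- Raster grids are row-0-south, half-open cells, centres at
  origin + (k + 0.5)·cell_size.
- File formats: classic NetCDF3 stacks (via scipy), TIFF rasters with
  grid metadata in the description tag, plain-JSON GeoJSON, and CSV
  fallbacks with round-trip float precision.
- Uniform within-mask population spreading ignores within-environment
  density variation; activity profiles are population-averaged, not
  individual; transport populations occupy the whole mode network each
  hour rather than moving along routes.
- Infiltration factors are deterministic per season; no building-stock
  variability is modelled.
- Concentrations are taken as given; no chemistry, meteorology or
  boundary conditions are computed here, so absolute exposure levels
  are only as good as the supplied fields.
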