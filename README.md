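# tmaexpo — dynamic population exposure to urban air pollution

`tmaexpo` implements a time–microenvironment–activity (TMA) model of
population exposure to NO2 and PM2.5 on an urban receptor grid. Instead
of assigning every person the concentration at their home address (the
*static* approach), the model moves the population hour by hour between
microenvironments — home, work, other indoor/outdoor locations, and
seven transport modes (walking, cycling, car, bus, subway, suburban and
regional trains) — and attenuates ambient concentrations with
environment-, pollutant- and season-specific infiltration factors
(F_inf). This captures two effects the static picture misses: people
spend their days closer to traffic than their nights, and enclosed
environments filter out part of the ambient pollution.

## Model

For pollutant concentration fields C_{i,t} (cell *i*, hour *t*),
population distributions P_{i,j,t} (environment *j*) and infiltration
factors F_inf,j:

- **Total exposure** (µg/m³·persons):
  E = Σ_j F_inf,j Σ_t Σ_i C_{i,t} · P_{i,j,t}
- **Population-weighted exposure** (µg/m³):
  PWE = E / Σ_j Σ_t Σ_i P_{i,j,t}

The package provides, as composable modules:

- `grid` / `io` — the receptor grid, rasterisation of polylines and
  population polygons, raster/stack/GeoJSON file round-trips,
- `microenv` — land-use → environment mapping and per-mode road/rail
  network masks,
- `population` — activity profiles, commuter scheduling, modal split,
  hourly population stacks for the static, dynamic and
  transport-resolved approaches,
- `infiltration` — seasonal F_inf tables with scenario bands,
- `exposure` — total exposure, PWE, environment shares, and zero-out
  source contributions,
- `emissions` — urban-core emission scaling and area-to-line
  disaggregation of gridded inventories onto road links,
- `evalstats` — model-evaluation statistics (MB, NMB, RMSE, r, IOA,
  FAC2) with the FAIRMODE FAC2 ≥ 0.3 criterion,
- `synthetic` — a fully seeded synthetic city (land use, network,
  emissions, concentration fields with a known road increment) for
  testing and demonstration,
- `workflow` / `cli` — end-to-end file-driven runs and sensitivity
  scenarios (`tmaexpo --help`).

## Worked example

```python
import pandas as pd
import tmaexpo as t
from tmaexpo.grid import rasterize_population_polygons
from tmaexpo.infiltration import DEFAULT_INFILTRATION
from tmaexpo.microenv import (DEFAULT_LULC_MAPPING, build_base_environments,
                              build_transport_environments)
from tmaexpo.population import PopulationInventory
from tmaexpo.workflow import assemble_population, run_exposure

# a seeded 3 km x 3 km synthetic city at 100 m resolution
city = t.generate_city(t.SyntheticCitySpec(seed=7))
ts = pd.date_range("2016-01-04", periods=48, freq="h")
fields = t.generate_concentration_fields(city, ts)["NO2"]

masks = build_base_environments(city.lulc, DEFAULT_LULC_MAPPING, city.grid).merged(
    build_transport_environments(city.network, city.grid))
homes = [(g, p["population"]) for g, p in city.lulc if p["class"] == "residential"]
inventory = PopulationInventory(rasterize_population_polygons(homes, city.grid))

pop = assemble_population(inventory, masks, "dynamic_transport", ts)
bundle = run_exposure(fields.full, pop, DEFAULT_INFILTRATION, "NO2",
                      "dynamic_transport", fields.zero_out)
print(bundle.summary_frame())
```

On this city (seed 7, 48 h) the transport-resolved run gives a total
NO2 exposure of 7.21 × 10⁷ µg/m³·persons versus 7.09 × 10⁷ for the
static approach (+1.6%), with the in-car environment carrying the
largest share of transport-scope exposure (39.2%, ahead of walking
26.4% and cycling 15.6%) and an in-car PWE of 24.7 µg/m³.

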