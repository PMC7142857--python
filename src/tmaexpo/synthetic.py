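"""Self-contained synthetic city and concentration fields.

Everything the exposure pipeline consumes — land-use polygons with
population, a tagged transport network, an urban-core mask, a coarse
emission grid, and paired hourly concentration stacks with and without
the road-traffic component — is generated here from a seed, so the whole
model is testable without any external download.

The synthetic city is deliberately schematic: a square domain with a
rectangular major-road grid (one motorway, one trunk road, alternating
primary/secondary roads), residential streets and footpaths between
them, three rail lines, residential blocks towards the periphery, work
blocks near the centre, and green space in between.  Concentrations are
a smooth diurnal background (lognormal multiplicative noise, hence
non-negative) plus a road increment that decays exponentially with
distance to the nearest major road and follows a bimodal diurnal
traffic shape.  The "full" field is background plus increment and the
"zero-out" field is the background alone, so the full field dominates
the zero-out field everywhere by construction and the injected road
contribution is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, box

from .emissions import EmissionGrid, RoadLink
from .grid import DomainGrid, HourlyFieldStack, RasterField, make_grid

#: Bimodal diurnal traffic activity (fraction of peak), morning and
#: evening rush maxima.
DEFAULT_TRAFFIC_SHAPE = np.array(
    [
        0.10, 0.06, 0.05, 0.05, 0.08, 0.20,
        0.55, 0.95, 1.00, 0.75, 0.60, 0.60,
        0.65, 0.65, 0.70, 0.80, 0.95, 1.00,
        0.90, 0.65, 0.45, 0.35, 0.25, 0.15,
    ]
)

#: Mild diurnal modulation of the urban background level.
DEFAULT_BACKGROUND_SHAPE = np.array(
    [
        0.85, 0.80, 0.78, 0.78, 0.80, 0.88,
        1.00, 1.10, 1.15, 1.10, 1.05, 1.00,
        1.00, 1.00, 1.00, 1.05, 1.10, 1.15,
        1.10, 1.05, 1.00, 0.95, 0.90, 0.88,
    ]
)


@dataclass
class SyntheticCitySpec:
    """Parameters of the synthetic city.

    Defaults describe a 3 x 3 km core sampled at the 100 m receptor
    resolution — a scaled-down town with the structure of the study
    setting (the full 30 x 30 km domain is available by raising ``n_x``
    / ``n_y`` to 300).  Background levels and road increments are chosen
    so that annual-mean concentrations land in the 10-30 ug/m3 NO2 and
    6-12 ug/m3 PM2.5 range typical of a northern European city, with the
    road increment strongest on the major roads.
    """

    seed: int = 0
    x_origin: float = 0.0
    y_origin: float = 0.0
    n_x: int = 30
    n_y: int = 30
    cell_size: float = 100.0
    emission_cell_size: float = 500.0
    n_home_blocks: int = 12
    n_work_blocks: int = 6
    road_spacing: float = 600.0
    rail_line_count: int = 3
    total_population: float = 100_000.0
    background_levels: dict = field(
        default_factory=lambda: {"NO2": 12.0, "PM2.5": 8.0}
    )
    road_increment_peak: dict = field(
        default_factory=lambda: {"NO2": 25.0, "PM2.5": 5.0}
    )
    increment_decay_length: float = 150.0
    noise_sigma: float = 0.15
    diurnal_traffic_shape: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRAFFIC_SHAPE.copy()
    )

    def __post_init__(self) -> None:
        if min(self.n_x, self.n_y, self.cell_size, self.road_spacing) <= 0:
            raise ValueError("grid dimensions and road spacing must be positive")
        if self.road_spacing > min(self.n_x, self.n_y) * self.cell_size:
            raise ValueError("road spacing exceeds the domain extent")
        if self.total_population <= 0:
            raise ValueError("total population must be positive")
        self.diurnal_traffic_shape = np.asarray(self.diurnal_traffic_shape, dtype=float)
        if self.diurnal_traffic_shape.shape != (24,):
            raise ValueError("diurnal traffic shape must have 24 entries")

    @property
    def grid(self) -> DomainGrid:
        return make_grid(
            self.x_origin, self.y_origin, self.n_x, self.n_y, self.cell_size, "synthetic-metric"
        )


@dataclass
class SyntheticCity:
    """All vector/raster inputs of one generated city."""

    spec: SyntheticCitySpec
    grid: DomainGrid
    lulc: list          # (polygon, {"class": ..., "population": ...})
    network: list       # (polyline, {"highway"/"railway": value})
    road_links: list    # RoadLink for the major (car) roads
    urban_mask: RasterField      # on the emission grid
    emission_grid: EmissionGrid


def _major_road_positions(extent: float, spacing: float) -> list[float]:
    n = max(1, int(np.floor(extent / spacing)))
    return [extent * (k + 1) / (n + 1) for k in range(n)]


def generate_city(spec: SyntheticCitySpec) -> SyntheticCity:
    """Deterministic synthetic city for a spec (same seed, same city)."""
    rng = np.random.default_rng(spec.seed)
    grid = spec.grid
    x0, y0 = spec.x_origin, spec.y_origin
    width = grid.n_x * grid.cell_size
    height = grid.n_y * grid.cell_size

    # --- major road grid ------------------------------------------------
    xs = _major_road_positions(width, spec.road_spacing)
    ys = _major_road_positions(height, spec.road_spacing)
    major_types_v = ["motorway" if k == len(xs) // 2 else ("primary" if k % 2 == 0 else "secondary") for k in range(len(xs))]
    major_types_h = ["trunk" if k == len(ys) // 2 else ("secondary" if k % 2 == 0 else "primary") for k in range(len(ys))]

    network: list = []
    road_links: list = []
    for k, x in enumerate(xs):
        geom = LineString([(x0 + x, y0), (x0 + x, y0 + height)])
        network.append((geom, {"highway": major_types_v[k]}))
        road_links.append(RoadLink(f"v{k}", geom, major_types_v[k]))
    for k, y in enumerate(ys):
        geom = LineString([(x0, y0 + y), (x0 + width, y0 + y)])
        network.append((geom, {"highway": major_types_h[k]}))
        road_links.append(RoadLink(f"h{k}", geom, major_types_h[k]))

    # residential streets midway between major roads; footways/cycleways
    # shadow a subset of streets and roads
    minor_xs = [x - spec.road_spacing / 2 for x in xs] + [xs[-1] + spec.road_spacing / 2]
    for k, x in enumerate(minor_xs):
        if 0 < x < width:
            geom = LineString([(x0 + x, y0), (x0 + x, y0 + height)])
            network.append((geom, {"highway": "residential"}))
    for k, y in enumerate(ys):
        off = spec.road_spacing / 3
        if y + off < height:
            network.append(
                (
                    LineString([(x0, y0 + y + off), (x0 + width, y0 + y + off)]),
                    {"highway": "footway"},
                )
            )
        if y - off > 0:
            network.append(
                (
                    LineString([(x0, y0 + y - off), (x0 + width, y0 + y - off)]),
                    {"highway": "cycleway"},
                )
            )

    # --- rail lines -----------------------------------------------------
    rail_tags = ["subway", "light_rail", "rail"]
    for k in range(spec.rail_line_count):
        tag = rail_tags[k % len(rail_tags)]
        frac = (k + 1) / (spec.rail_line_count + 1)
        geom = LineString(
            [(x0, y0 + height * frac), (x0 + width, y0 + height * (1 - frac))]
        )
        network.append((geom, {"railway": tag}))

    # --- land-use blocks -------------------------------------------------
    lulc: list = []
    cx, cy = x0 + width / 2, y0 + height / 2
    block = max(2 * grid.cell_size, spec.road_spacing / 3)

    def _block_at(px: float, py: float, cls: str, population: float = 0.0):
        geom = box(
            min(max(px - block / 2, x0), x0 + width - block),
            min(max(py - block / 2, y0), y0 + height - block),
            min(max(px + block / 2, x0 + block), x0 + width),
            min(max(py + block / 2, y0 + block), y0 + height),
        )
        props = {"class": cls}
        if population:
            props["population"] = population
        lulc.append((geom, props))

    # homes on a peripheral ring, persons split evenly over blocks
    per_block = spec.total_population / spec.n_home_blocks
    ring_r = 0.38 * min(width, height)
    for k in range(spec.n_home_blocks):
        angle = 2 * np.pi * k / spec.n_home_blocks + rng.uniform(-0.1, 0.1)
        _block_at(cx + ring_r * np.cos(angle), cy + ring_r * np.sin(angle), "residential", per_block)
    # work near the centre (close to the motorway/trunk crossing)
    for k in range(spec.n_work_blocks):
        angle = 2 * np.pi * k / spec.n_work_blocks + rng.uniform(-0.15, 0.15)
        r = 0.12 * min(width, height)
        _block_at(cx + r * np.cos(angle), cy + r * np.sin(angle), "industrial_commercial")
    # green / other between home ring and centre
    for k in range(max(3, spec.n_work_blocks // 2)):
        angle = 2 * np.pi * k / max(3, spec.n_work_blocks // 2) + 0.4
        r = 0.25 * min(width, height)
        _block_at(cx + r * np.cos(angle), cy + r * np.sin(angle), "green_urban")
    # roads and associated land: buffered major roads
    for lnk in road_links:
        lulc.append((lnk.geometry.buffer(grid.cell_size / 2), {"class": "roads_associated_land"}))

    # --- emission grid and urban mask ------------------------------------
    n_ex = max(1, int(round(width / spec.emission_cell_size)))
    n_ey = max(1, int(round(height / spec.emission_cell_size)))
    egrid = make_grid(x0, y0, n_ex, n_ey, spec.emission_cell_size, "synthetic-metric")
    road_union = shapely.union_all([lnk.geometry for lnk in road_links])
    totals = {pol: np.zeros(egrid.shape) for pol in spec.road_increment_peak}
    lengths = np.zeros(egrid.shape)
    for row in range(n_ey):
        for col in range(n_ex):
            seg = road_union.intersection(egrid.cell_box(col, row))
            lengths[row, col] = seg.length
    # annual totals proportional to road length; arbitrary but positive
    # only in road-bearing cells, in tonnes/year
    for pol, peak in spec.road_increment_peak.items():
        totals[pol] = lengths / 1000.0 * peak
    emission_grid = EmissionGrid(egrid, totals)

    urban = np.zeros(egrid.shape)
    for row in range(n_ey):
        for col in range(n_ex):
            ex, ey = egrid.cell_center(col, row)
            if abs(ex - cx) < width / 4 and abs(ey - cy) < height / 4:
                urban[row, col] = 1.0
    urban_mask = RasterField(egrid, urban, units="bool", name="urban_core")

    return SyntheticCity(spec, grid, lulc, network, road_links, urban_mask, emission_grid)


@dataclass
class ConcentrationScenario:
    """Paired full / zero-out stacks with the known road increment."""

    full: HourlyFieldStack
    zero_out: HourlyFieldStack
    increment: HourlyFieldStack

    def scaled_full(self, emission_factor: float) -> HourlyFieldStack:
        """Full field with the road increment scaled linearly by an
        emission factor (linear source-receptor approximation)."""
        return HourlyFieldStack(
            self.full.grid,
            self.full.timestamps,
            self.zero_out.values + emission_factor * self.increment.values,
            self.full.units,
            self.full.name,
        )


def road_distance_field(city: SyntheticCity) -> np.ndarray:
    """Distance (m) from each receptor-cell centre to the nearest major road."""
    gx, gy = city.grid.cell_centers()
    points = shapely.points(gx.ravel(), gy.ravel())
    road_union = shapely.union_all([lnk.geometry for lnk in city.road_links])
    return shapely.distance(points, road_union).reshape(city.grid.shape)


def write_fixture(city: SyntheticCity, scenarios, out_dir) -> None:
    """Write a complete fixture directory in the pipeline's input formats.

    Produces ``lulc.geojson``, ``network.geojson``, ``urban_mask.tif``,
    per-pollutant emission rasters, ``conc_<pol>.nc`` /
    ``conc_<pol>_zero.nc`` stacks and a ``manifest.json`` recording the
    seed and spec.
    """
    import dataclasses
    import json
    from pathlib import Path

    from . import io as tio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tio.write_geojson(out_dir / "lulc.geojson", city.lulc)
    tio.write_geojson(out_dir / "network.geojson", city.network)
    tio.write_geojson(
        out_dir / "road_links.geojson",
        [
            (lnk.geometry, {"id": lnk.link_id, "road_type": lnk.road_type})
            for lnk in city.road_links
        ],
    )
    tio.write_raster(out_dir / "urban_mask.tif", city.urban_mask)
    for pol, arr in city.emission_grid.totals.items():
        tio.write_raster(
            out_dir / f"emissions_{pol}.tif",
            RasterField(city.emission_grid.grid, arr, "t/yr", f"emissions_{pol}"),
        )
    for pol, scenario in scenarios.items():
        tio.write_stack(out_dir / f"conc_{pol}.nc", scenario.full)
        tio.write_stack(out_dir / f"conc_{pol}_zero.nc", scenario.zero_out)
    spec_dict = dataclasses.asdict(city.spec)
    spec_dict["diurnal_traffic_shape"] = list(map(float, spec_dict["diurnal_traffic_shape"]))
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump({"seed": city.spec.seed, "spec": spec_dict}, fh, indent=2)


def generate_concentration_fields(
    city: SyntheticCity,
    timestamps,
    emission_factors: dict[str, float] | None = None,
) -> dict[str, ConcentrationScenario]:
    """Hourly full and zero-out concentration stacks per pollutant.

    The zero-out stack is the smooth noisy background alone; the full
    stack adds the road increment
    ``peak * exp(-d / decay_length) * traffic_shape(hour)`` with ``d``
    the distance to the nearest major road, optionally scaled by a
    per-pollutant emission factor.  Noise is lognormal multiplicative on
    the background, so all concentrations stay non-negative and the full
    field is >= the zero-out field everywhere.
    """
    spec = city.spec
    rng = np.random.default_rng(spec.seed + 1)
    timestamps = pd.DatetimeIndex(timestamps)
    emission_factors = emission_factors or {}
    dist = road_distance_field(city)
    decay = np.exp(-dist / spec.increment_decay_length)
    hours = timestamps.hour.to_numpy()

    # weak east-west gradient so the background is not spatially flat
    gx, _gy = city.grid.cell_centers()
    width = city.grid.n_x * city.grid.cell_size
    gradient = 1.0 + 0.1 * (gx - gx.min()) / max(width, 1.0)

    out: dict[str, ConcentrationScenario] = {}
    for pol, level in spec.background_levels.items():
        noise = rng.lognormal(mean=0.0, sigma=spec.noise_sigma, size=len(timestamps))
        bg_hour = level * DEFAULT_BACKGROUND_SHAPE[hours] * noise
        zero_values = bg_hour[:, None, None] * gradient[None, :, :]
        factor = emission_factors.get(pol, 1.0)
        peak = spec.road_increment_peak.get(pol, 0.0) * factor
        inc_values = peak * spec.diurnal_traffic_shape[hours][:, None, None] * decay[None, :, :]
        full_values = zero_values + inc_values
        grid = city.grid
        out[pol] = ConcentrationScenario(
            full=HourlyFieldStack(grid, timestamps, full_values, "ug/m3", f"conc_{pol}"),
            zero_out=HourlyFieldStack(grid, timestamps, zero_values, "ug/m3", f"conc_{pol}_zero"),
            increment=HourlyFieldStack(grid, timestamps, inc_values, "ug/m3", f"conc_{pol}_inc"),
        )
    return out
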