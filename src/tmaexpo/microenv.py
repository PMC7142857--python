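"""Microenvironment definitions and mask construction.

Three approaches to locating the population are supported:

* *static* — everyone at their residential address (home environment only);
* *dynamic* — four base environments (home, work, other, transport)
  derived from land-use/land-cover polygons;
* *dynamic transport* — the transport environment split into seven
  transport modes (walking, cycling, in-car, buses, subway / suburban /
  regional trains) derived from tagged network polylines.

Base-environment masks come from land-use polygons, mode masks from
polylines; the two sources are never conflated.  Mode masks may overlap:
one street typically hosts walking, cycling, car and bus traffic.
Public transport by ferry is not modelled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import DomainGrid, RasterField, rasterize_polylines

logger = logging.getLogger(__name__)

BASE_ENVIRONMENTS: tuple[str, ...] = ("home", "work", "other", "transport")
TRANSPORT_MODES: tuple[str, ...] = (
    "walking",
    "cycling",
    "in_car",
    "buses",
    "subway_trains",
    "suburban_trains",
    "regional_trains",
)
ALL_ENVIRONMENTS: tuple[str, ...] = BASE_ENVIRONMENTS + TRANSPORT_MODES


def category_of(env: str) -> str:
    """``"base"`` or ``"transport_mode"``; unknown names raise."""
    if env in BASE_ENVIRONMENTS:
        return "base"
    if env in TRANSPORT_MODES:
        return "transport_mode"
    raise KeyError(f"unknown environment {env!r}")


def parent_of(mode: str) -> str:
    """Every transport mode rolls up to the base transport environment."""
    if mode not in TRANSPORT_MODES:
        raise KeyError(f"{mode!r} is not a transport mode")
    return "transport"


@dataclass
class LULCMapping:
    """Maps land-use class codes to base environments.

    One class code may feed several environments; the home mapping must
    be non-empty because every approach needs a residential layer.
    """

    table: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.table = {code: frozenset(envs) for code, envs in self.table.items()}
        for code, envs in self.table.items():
            unknown = envs - set(BASE_ENVIRONMENTS)
            if unknown:
                raise ValueError(f"class {code!r} maps to unknown environments {sorted(unknown)}")
        if not any("home" in envs for envs in self.table.values()):
            raise ValueError("mapping must assign at least one class to the home environment")

    def environments_for(self, code: str) -> frozenset[str]:
        return self.table.get(code, frozenset())


#: Generic land-use classes in the spirit of the Urban Atlas nomenclature.
DEFAULT_LULC_MAPPING = LULCMapping(
    {
        "residential": frozenset({"home"}),
        "industrial_commercial": frozenset({"work"}),
        "public_services": frozenset({"work", "other"}),
        "green_urban": frozenset({"other"}),
        "sports_leisure": frozenset({"other"}),
        "roads_associated_land": frozenset({"transport"}),
    }
)


@dataclass
class ModeQueryConfig:
    """Per-mode tag filters for selecting network polylines.

    Each mode is defined by a list of ``(key, value)`` pairs; a polyline
    belongs to the mode if any pair matches its tag map.  The defaults
    follow the qualitative rules of the field: the in-car environment
    spans the full major-road network including motorways, buses use
    major roads but never motorways, walking and cycling combine
    dedicated paths with ordinary streets, and the three rail
    environments are disjoint by the ``railway`` tag.
    """

    filters: dict[str, tuple[tuple[str, str], ...]]

    def __post_init__(self) -> None:
        for mode in self.filters:
            if mode not in TRANSPORT_MODES:
                raise ValueError(f"unknown transport mode {mode!r}")

    def filters_for(self, mode: str) -> tuple[tuple[str, str], ...]:
        if mode not in self.filters or not self.filters[mode]:
            raise KeyError(f"no tag filters configured for mode {mode!r}")
        return self.filters[mode]


DEFAULT_MODE_QUERIES = ModeQueryConfig(
    {
        "walking": (
            ("highway", "footway"),
            ("highway", "path"),
            ("highway", "pedestrian"),
            ("highway", "living_street"),
            ("highway", "residential"),
        ),
        "cycling": (
            ("highway", "cycleway"),
            ("highway", "residential"),
            ("highway", "secondary"),
        ),
        "in_car": (
            ("highway", "motorway"),
            ("highway", "trunk"),
            ("highway", "primary"),
            ("highway", "secondary"),
        ),
        "buses": (
            ("highway", "trunk"),
            ("highway", "primary"),
            ("highway", "secondary"),
        ),
        "subway_trains": (("railway", "subway"),),
        "suburban_trains": (("railway", "light_rail"), ("railway", "suburban")),
        "regional_trains": (("railway", "rail"),),
    }
)


@dataclass
class EnvironmentMaskSet:
    """Boolean membership rasters per environment, on one shared grid."""

    masks: dict[str, RasterField]

    def __post_init__(self) -> None:
        grids = {id(m.grid) for m in self.masks.values()}
        if self.masks:
            ref = next(iter(self.masks.values())).grid
            for env, m in self.masks.items():
                if m.grid != ref:
                    raise ValueError(f"mask for {env!r} is on a different grid")

    def __getitem__(self, env: str) -> RasterField:
        return self.masks[env]

    def __contains__(self, env: str) -> bool:
        return env in self.masks

    def environments(self) -> list[str]:
        return list(self.masks)

    def empty_environments(self) -> list[str]:
        return [env for env, m in self.masks.items() if not m.values.any()]

    def merged(self, other: "EnvironmentMaskSet") -> "EnvironmentMaskSet":
        out = dict(self.masks)
        out.update(other.masks)
        return EnvironmentMaskSet(out)


def build_base_environments(
    lulc_polygons,
    mapping: LULCMapping,
    grid: DomainGrid,
) -> EnvironmentMaskSet:
    """Masks for home/work/other/transport from classed land-use polygons.

    ``lulc_polygons`` yields ``(geometry, properties)`` with a ``class``
    property.  A cell belongs to an environment iff at least one polygon
    of a mapped class intersects it.  Unmapped classes are skipped with
    a warning.
    """
    by_env: dict[str, list] = {env: [] for env in BASE_ENVIRONMENTS}
    for geom, props in lulc_polygons:
        code = props.get("class", "")
        envs = mapping.environments_for(code)
        if not envs:
            logger.warning("land-use class %r not in mapping; polygon ignored", code)
            continue
        for env in envs:
            by_env[env].append(geom)

    masks: dict[str, RasterField] = {}
    cs = grid.cell_size
    for env in BASE_ENVIRONMENTS:
        values = np.zeros(grid.shape)
        for geom in by_env[env]:
            minx, miny, maxx, maxy = geom.bounds
            c0 = max(0, int(np.floor((minx - grid.x_origin) / cs)))
            c1 = min(grid.n_x - 1, int(np.floor((maxx - grid.x_origin) / cs)))
            r0 = max(0, int(np.floor((miny - grid.y_origin) / cs)))
            r1 = min(grid.n_y - 1, int(np.floor((maxy - grid.y_origin) / cs)))
            for row in range(r0, r1 + 1):
                for col in range(c0, c1 + 1):
                    if not values[row, col] and geom.intersects(grid.cell_box(col, row)):
                        values[row, col] = 1.0
        masks[env] = RasterField(grid, values, units="bool", name=f"mask_{env}")
    return EnvironmentMaskSet(masks)


def select_mode_links(network, mode: str, config: ModeQueryConfig = DEFAULT_MODE_QUERIES):
    """Polylines of the network matching any of the mode's tag filters.

    ``network`` yields ``(geometry, tags)`` pairs; tags is a mapping of
    string keys to string values.
    """
    if mode not in TRANSPORT_MODES:
        raise KeyError(f"{mode!r} is not a transport mode")
    filters = config.filters_for(mode)
    selected = []
    for geom, tags in network:
        if any(tags.get(key) == value for key, value in filters):
            selected.append((geom, tags))
    return selected


def build_transport_environments(
    network,
    grid: DomainGrid,
    config: ModeQueryConfig = DEFAULT_MODE_QUERIES,
) -> EnvironmentMaskSet:
    """Seven mode masks: tag selection followed by polyline rasterization."""
    network = list(network)
    masks: dict[str, RasterField] = {}
    for mode in TRANSPORT_MODES:
        links = [geom for geom, _tags in select_mode_links(network, mode, config)]
        raster = rasterize_polylines(links, grid)
        raster.name = f"mask_{mode}"
        masks[mode] = raster
    return EnvironmentMaskSet(masks)
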