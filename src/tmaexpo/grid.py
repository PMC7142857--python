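"""Planar receptor grid, raster containers and geometry-to-raster operations.

The exposure model works on a regular receptor grid in a projected,
metric CRS.  Cell (0, 0) sits at the lower-left (south-west) corner;
arrays are stored row-major with row 0 at the south edge, so
``values[row, col]`` addresses the cell whose centre is at
``(x_origin + (col + 0.5) * cell_size, y_origin + (row + 0.5) * cell_size)``.
All indices are 0-based and cell intervals are half-open
``[origin, origin + n * cell_size)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely import STRtree
from shapely.geometry import box
from shapely.geometry.base import BaseGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "DomainGrid",
    "RasterField",
    "HourlyFieldStack",
    "make_grid",
    "rasterize_polylines",
    "rasterize_population_polygons",
]


@dataclass(frozen=True)
class DomainGrid:
    """Regular planar grid in a projected CRS.

    Parameters
    ----------
    x_origin, y_origin
        Coordinates of the lower-left corner, metres.
    n_x, n_y
        Number of columns / rows.
    cell_size
        Cell edge length, metres.
    crs_id
        Free-text identifier of the projected CRS (e.g. ``"EPSG:25832"``).
        The grid performs no reprojection; all inputs must already be in
        this CRS.
    """

    x_origin: float
    y_origin: float
    n_x: int
    n_y: int
    cell_size: float
    crs_id: str = "local-metric"

    def __post_init__(self) -> None:
        if self.n_x <= 0 or self.n_y <= 0:
            raise ValueError(f"grid dimensions must be positive, got {self.n_x}x{self.n_y}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")

    @property
    def shape(self) -> tuple[int, int]:
        """Array shape ``(n_y, n_x)``."""
        return (self.n_y, self.n_x)

    @property
    def x_max(self) -> float:
        return self.x_origin + self.n_x * self.cell_size

    @property
    def y_max(self) -> float:
        return self.y_origin + self.n_y * self.cell_size

    @property
    def n_cells(self) -> int:
        return self.n_x * self.n_y

    def cell_center(self, col: int, row: int) -> tuple[float, float]:
        """Centre coordinates of cell ``(col, row)``."""
        return (
            self.x_origin + (col + 0.5) * self.cell_size,
            self.y_origin + (row + 0.5) * self.cell_size,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid of cell-centre x and y coordinates, shape ``(n_y, n_x)``."""
        xs = self.x_origin + (np.arange(self.n_x) + 0.5) * self.cell_size
        ys = self.y_origin + (np.arange(self.n_y) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_box(self, col: int, row: int):
        """Closed shapely square of cell ``(col, row)``."""
        x0 = self.x_origin + col * self.cell_size
        y0 = self.y_origin + row * self.cell_size
        return box(x0, y0, x0 + self.cell_size, y0 + self.cell_size)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(col, row) of the cell containing the point, half-open convention."""
        col = int(np.floor((x - self.x_origin) / self.cell_size))
        row = int(np.floor((y - self.y_origin) / self.cell_size))
        return col, row

    def contains_index(self, col: int, row: int) -> bool:
        return 0 <= col < self.n_x and 0 <= row < self.n_y


@dataclass
class RasterField:
    """A single 2-D field on a :class:`DomainGrid`."""

    grid: DomainGrid
    values: np.ndarray
    units: str = "1"
    name: str = "field"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not self.units:
            raise ValueError("units must be non-empty")

    def copy(self) -> "RasterField":
        return RasterField(self.grid, self.values.copy(), self.units, self.name)

    @property
    def total(self) -> float:
        return float(self.values.sum())


def _as_datetime_index(timestamps) -> pd.DatetimeIndex:
    idx = pd.DatetimeIndex(timestamps)
    if len(idx) > 1:
        deltas = np.diff(idx.asi8)
        hour_ns = 3_600_000_000_000
        if not np.all(deltas == hour_ns):
            bad = int(np.argmax(deltas != hour_ns))
            raise ValueError(
                "timestamps must be strictly increasing with 1-hour spacing; "
                f"gap after {idx[bad]} (next is {idx[bad + 1]})"
            )
    return idx


@dataclass
class HourlyFieldStack:
    """Hourly time series of 2-D fields: shape ``(time, n_y, n_x)``.

    The time axis must be strictly increasing with exactly one hour
    between consecutive instants; the year length (8784 h for a leap
    year) is a property of the axis, never assumed.
    """

    grid: DomainGrid
    timestamps: pd.DatetimeIndex
    values: np.ndarray
    units: str = "1"
    name: str = "stack"

    def __post_init__(self) -> None:
        self.timestamps = _as_datetime_index(self.timestamps)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.timestamps), self.grid.n_y, self.grid.n_x)
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape}, expected {expected}")

    @property
    def n_hours(self) -> int:
        return len(self.timestamps)

    def copy(self) -> "HourlyFieldStack":
        return HourlyFieldStack(self.grid, self.timestamps, self.values.copy(), self.units, self.name)

    def aligned_with(self, other: "HourlyFieldStack") -> bool:
        return self.grid == other.grid and self.timestamps.equals(other.timestamps)


def require_aligned(*stacks: HourlyFieldStack) -> None:
    """Raise if the stacks do not share one grid and one time axis."""
    ref = stacks[0]
    for s in stacks[1:]:
        if s.grid != ref.grid:
            raise ValueError(f"grid mismatch: {s.grid} vs {ref.grid}")
        if not s.timestamps.equals(ref.timestamps):
            raise ValueError("timestamp axes differ between stacks")


def make_grid(
    x_origin: float,
    y_origin: float,
    n_x: int,
    n_y: int,
    cell_size: float,
    crs_id: str = "local-metric",
) -> DomainGrid:
    """Create a :class:`DomainGrid`; see the class for conventions."""
    return DomainGrid(x_origin, y_origin, int(n_x), int(n_y), float(cell_size), crs_id)


def rasterize_polylines(lines, grid: DomainGrid) -> RasterField:
    """Boolean membership raster: a cell is true iff at least one polyline
    intersects the cell's closed square.

    Geometry entirely outside the grid is silently clipped (a warning is
    logged).  An empty line set yields an all-false raster.
    """
    mask = np.zeros(grid.shape, dtype=float)
    lines = [g for g in lines if isinstance(g, BaseGeometry) and not g.is_empty]
    if not lines:
        return RasterField(grid, mask, units="bool", name="polyline_mask")

    cs = grid.cell_size
    any_outside = False
    for geom in lines:
        minx, miny, maxx, maxy = geom.bounds
        if maxx < grid.x_origin or minx >= grid.x_max or maxy < grid.y_origin or miny >= grid.y_max:
            any_outside = True
            continue
        c0 = max(0, int(np.floor((minx - grid.x_origin) / cs)))
        c1 = min(grid.n_x - 1, int(np.floor((maxx - grid.x_origin) / cs)))
        r0 = max(0, int(np.floor((miny - grid.y_origin) / cs)))
        r1 = min(grid.n_y - 1, int(np.floor((maxy - grid.y_origin) / cs)))
        if c0 > c1 or r0 > r1:
            any_outside = True
            continue
        for row in range(r0, r1 + 1):
            for col in range(c0, c1 + 1):
                if mask[row, col]:
                    continue
                if geom.intersects(grid.cell_box(col, row)):
                    mask[row, col] = 1.0
    if any_outside:
        logger.warning("some polylines fall (partly) outside the grid and were clipped")
    return RasterField(grid, mask, units="bool", name="polyline_mask")


def rasterize_population_polygons(polygons, grid: DomainGrid) -> RasterField:
    """Allocate each polygon's population to cells by overlap area.

    ``polygons`` is an iterable of ``(geometry, population)`` pairs.  A
    polygon's count is split over the cells it overlaps in proportion to
    intersection area, which conserves the total for polygons fully
    inside the domain.  Polygons (partly) outside the domain lose the
    share of their count falling outside; this is logged.
    """
    values = np.zeros(grid.shape, dtype=float)
    cs = grid.cell_size
    lost = 0.0
    for geom, pop in polygons:
        pop = float(pop)
        if pop < 0:
            raise ValueError(f"negative population count: {pop}")
        if pop == 0 or geom.is_empty:
            continue
        area = geom.area
        if area <= 0:
            continue
        minx, miny, maxx, maxy = geom.bounds
        c0 = max(0, int(np.floor((minx - grid.x_origin) / cs)))
        c1 = min(grid.n_x - 1, int(np.floor((maxx - grid.x_origin) / cs)))
        r0 = max(0, int(np.floor((miny - grid.y_origin) / cs)))
        r1 = min(grid.n_y - 1, int(np.floor((maxy - grid.y_origin) / cs)))
        allocated = 0.0
        if c0 <= c1 and r0 <= r1:
            for row in range(r0, r1 + 1):
                for col in range(c0, c1 + 1):
                    inter = geom.intersection(grid.cell_box(col, row)).area
                    if inter > 0:
                        share = pop * inter / area
                        values[row, col] += share
                        allocated += share
        lost += pop - allocated
    if lost > 1e-9:
        logger.warning(
            "%.6g persons of polygon population fall outside the grid and were dropped", lost
        )
    return RasterField(grid, values, units="persons", name="population")


def polyline_mask_bulk(lines, grid: DomainGrid) -> RasterField:
    """STRtree-accelerated variant of :func:`rasterize_polylines` for large inputs."""
    lines = [g for g in lines if not g.is_empty]
    if not lines:
        return RasterField(grid, np.zeros(grid.shape), units="bool", name="polyline_mask")
    tree = STRtree(lines)
    mask = np.zeros(grid.shape, dtype=float)
    for row in range(grid.n_y):
        for col in range(grid.n_x):
            cell = grid.cell_box(col, row)
            idx = tree.query(cell, predicate="intersects")
            if len(idx):
                mask[row, col] = 1.0
    return RasterField(grid, mask, units="bool", name="polyline_mask")
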