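"""File I/O for rasters, hourly stacks and vector inputs.

Formats
-------
* :class:`~tmaexpo.grid.RasterField` — single-band float64 TIFF with the
  grid geometry embedded as JSON in the image description tag, or a CSV
  fallback with ``# key = value`` header lines.
* :class:`~tmaexpo.grid.HourlyFieldStack` — classic NetCDF with CF-style
  ``(time, y, x)`` dimensions and a ``units`` attribute, or a long-form
  CSV fallback.
* Vector inputs (tagged polylines, population polygons) — GeoJSON
  FeatureCollections with a ``properties`` map of string tags.

Round-trips preserve grid geometry, units and float64 values exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy.io import netcdf_file
from shapely.geometry import mapping, shape

from .grid import DomainGrid, HourlyFieldStack, RasterField

__all__ = [
    "write_raster",
    "read_raster",
    "write_stack",
    "read_stack",
    "read_geojson",
    "write_geojson",
]

_EPOCH_FMT = "%Y-%m-%d %H:%M:%S"


def _grid_meta(grid: DomainGrid) -> dict:
    return {
        "x_origin": grid.x_origin,
        "y_origin": grid.y_origin,
        "n_x": grid.n_x,
        "n_y": grid.n_y,
        "cell_size": grid.cell_size,
        "crs_id": grid.crs_id,
    }


def _grid_from_meta(meta: dict) -> DomainGrid:
    return DomainGrid(
        float(meta["x_origin"]),
        float(meta["y_origin"]),
        int(meta["n_x"]),
        int(meta["n_y"]),
        float(meta["cell_size"]),
        str(meta["crs_id"]),
    )


def _check_expected(found: DomainGrid, expected: DomainGrid | None, path) -> None:
    if expected is not None and found != expected:
        raise ValueError(f"grid in {path} is {found}, expected {expected}")


# ---------------------------------------------------------------------------
# RasterField


def write_raster(path, raster: RasterField) -> None:
    """Write a raster as single-band float64 TIFF (.tif) or CSV (.csv)."""
    path = Path(path)
    meta = {"grid": _grid_meta(raster.grid), "units": raster.units, "name": raster.name}
    if path.suffix.lower() in {".tif", ".tiff"}:
        # row 0 is the south edge in memory; TIFF stores top-down, so flip.
        tifffile.imwrite(
            path,
            raster.values[::-1].astype(np.float64),
            description=json.dumps(meta),
        )
    elif path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            for key, val in meta["grid"].items():
                fh.write(f"# {key} = {val}\n")
            fh.write(f"# units = {raster.units}\n")
            fh.write(f"# name = {raster.name}\n")
            np.savetxt(fh, raster.values, delimiter=",", fmt="%.17g")
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")


def read_raster(path, expected_grid: DomainGrid | None = None) -> RasterField:
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            meta = json.loads(page.description)
            values = page.asarray()[::-1]
    elif path.suffix.lower() == ".csv":
        header: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            values = np.loadtxt(fh, delimiter=",", ndmin=2)
        meta = {
            "grid": header,
            "units": header.get("units", "1"),
            "name": header.get("name", "field"),
        }
    else:
        raise ValueError(f"unsupported raster format: {path.suffix}")
    grid = _grid_from_meta(meta["grid"])
    _check_expected(grid, expected_grid, path)
    return RasterField(grid, np.asarray(values, dtype=float), meta["units"], meta["name"])


# ---------------------------------------------------------------------------
# HourlyFieldStack


def write_stack(path, stack: HourlyFieldStack) -> None:
    """Write an hourly stack as classic NetCDF (.nc) or long CSV (.csv)."""
    path = Path(path)
    if path.suffix.lower() == ".nc":
        epoch = stack.timestamps[0].strftime(_EPOCH_FMT)
        hours = ((stack.timestamps.asi8 - stack.timestamps.asi8[0]) // 3_600_000_000_000).astype(
            np.int32
        )
        with netcdf_file(str(path), "w") as nc:
            nc.createDimension("time", stack.n_hours)
            nc.createDimension("y", stack.grid.n_y)
            nc.createDimension("x", stack.grid.n_x)
            tvar = nc.createVariable("time", "i", ("time",))
            tvar[:] = hours
            tvar.units = f"hours since {epoch}".encode()
            yvar = nc.createVariable("y", "d", ("y",))
            yvar[:] = stack.grid.y_origin + (np.arange(stack.grid.n_y) + 0.5) * stack.grid.cell_size
            yvar.units = b"m"
            xvar = nc.createVariable("x", "d", ("x",))
            xvar[:] = stack.grid.x_origin + (np.arange(stack.grid.n_x) + 0.5) * stack.grid.cell_size
            xvar.units = b"m"
            dvar = nc.createVariable(stack.name or "data", "d", ("time", "y", "x"))
            dvar[:] = stack.values
            dvar.units = stack.units.encode()
            nc.grid_meta = json.dumps(_grid_meta(stack.grid)).encode()
            nc.variable_name = (stack.name or "data").encode()
    elif path.suffix.lower() == ".csv":
        with open(path, "w") as fh:
            for key, val in _grid_meta(stack.grid).items():
                fh.write(f"# {key} = {val}\n")
            fh.write(f"# units = {stack.units}\n")
            fh.write(f"# name = {stack.name}\n")
            fh.write("timestamp,row,col,value\n")
            for t_i, ts in enumerate(stack.timestamps):
                frame = stack.values[t_i]
                for row in range(stack.grid.n_y):
                    for col in range(stack.grid.n_x):
                        fh.write(f"{ts.isoformat()},{row},{col},{frame[row, col]:.17g}\n")
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")


def read_stack(path, expected_grid: DomainGrid | None = None) -> HourlyFieldStack:
    path = Path(path)
    if path.suffix.lower() == ".nc":
        with netcdf_file(str(path), "r", mmap=False) as nc:
            grid = _grid_from_meta(json.loads(nc.grid_meta.decode()))
            var_name = nc.variable_name.decode()
            tvar = nc.variables["time"]
            units = tvar.units.decode()
            epoch = pd.Timestamp(units.replace("hours since ", ""))
            hours = np.asarray(tvar[:], dtype=np.int64)
            gaps = np.diff(hours)
            if len(gaps) and not np.all(gaps == 1):
                missing = [
                    str(epoch + pd.Timedelta(hours=int(h) + 1))
                    for h, g in zip(hours[:-1], gaps)
                    if g != 1
                ]
                raise ValueError(f"stack in {path} has missing hours after: {missing}")
            timestamps = epoch + pd.to_timedelta(hours, unit="h")
            dvar = nc.variables[var_name]
            values = np.array(dvar[:], dtype=float)
            data_units = dvar.units.decode()
    elif path.suffix.lower() == ".csv":
        header: dict[str, str] = {}
        with open(path) as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition("=")
                header[key.strip()] = val.strip()
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            table = pd.read_csv(fh, parse_dates=["timestamp"], float_precision="round_trip")
        grid = _grid_from_meta(header)
        timestamps = pd.DatetimeIndex(sorted(table["timestamp"].unique()))
        values = np.zeros((len(timestamps), grid.n_y, grid.n_x))
        t_index = {ts: i for i, ts in enumerate(timestamps)}
        for rec in table.itertuples(index=False):
            values[t_index[rec.timestamp], rec.row, rec.col] = rec.value
        data_units = header.get("units", "1")
        var_name = header.get("name", "data")
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")
    _check_expected(grid, expected_grid, path)
    return HourlyFieldStack(grid, pd.DatetimeIndex(timestamps), values, data_units, var_name)


# ---------------------------------------------------------------------------
# GeoJSON vectors


def write_geojson(path, features) -> None:
    """Write ``(geometry, properties)`` pairs as a GeoJSON FeatureCollection."""
    collection = {
        "type": "FeatureCollection",
        "features": [
            {"type": "Feature", "geometry": mapping(geom), "properties": dict(props)}
            for geom, props in features
        ],
    }
    with open(path, "w") as fh:
        json.dump(collection, fh)


def read_geojson(path) -> list[tuple]:
    """Read a GeoJSON FeatureCollection as ``(geometry, properties)`` pairs."""
    with open(path) as fh:
        collection = json.load(fh)
    return [
        (shape(feat["geometry"]), feat.get("properties") or {})
        for feat in collection["features"]
    ]
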