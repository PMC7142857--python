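"""Shared fixtures: a small synthetic city, masks, population stacks."""

import numpy as np
import pandas as pd
import pytest

import tmaexpo as t
from tmaexpo.grid import rasterize_population_polygons
from tmaexpo.microenv import (
    DEFAULT_LULC_MAPPING,
    build_base_environments,
    build_transport_environments,
)
from tmaexpo.population import PopulationInventory


@pytest.fixture(scope="session")
def city():
    return t.generate_city(t.SyntheticCitySpec(seed=7))


@pytest.fixture(scope="session")
def timestamps_48h():
    # starts on a Monday so weekday behaviour is exercised
    return pd.date_range("2016-01-04", periods=48, freq="h")


@pytest.fixture(scope="session")
def conc_fields(city, timestamps_48h):
    return t.generate_concentration_fields(city, timestamps_48h)


@pytest.fixture(scope="session")
def residential_raster(city):
    polys = [
        (geom, props.get("population", 0.0))
        for geom, props in city.lulc
        if props.get("class") == "residential"
    ]
    return rasterize_population_polygons(polys, city.grid)


@pytest.fixture(scope="session")
def inventory(residential_raster):
    return PopulationInventory(residential_raster)


@pytest.fixture(scope="session")
def masks(city):
    base = build_base_environments(city.lulc, DEFAULT_LULC_MAPPING, city.grid)
    modes = build_transport_environments(city.network, city.grid)
    return base.merged(modes)
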