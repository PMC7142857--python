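"""Hourly population: activity profiles, commuters, modal split,
spatial distribution and conservation."""

import numpy as np
import pandas as pd
import pytest

from tmaexpo.grid import RasterField, make_grid
from tmaexpo.microenv import BASE_ENVIRONMENTS, TRANSPORT_MODES, EnvironmentMaskSet
from tmaexpo.population import (
    ActivityProfile,
    CommuterSpec,
    ModalSplit,
    PopulationInventory,
    apply_growth,
    build_hourly_population,
    day_type_of,
    distribute_to_mask,
    hourly_environment_totals,
    split_transport_total,
)


def _uniform_profile(home, work, other, transport):
    row = np.tile([home, work, other, transport], (24, 1))
    return ActivityProfile({"weekday": row.copy(), "weekend": row.copy()})


@pytest.fixture
def small_inventory():
    grid = make_grid(0, 0, 2, 2, 100)
    raster = RasterField(grid, np.array([[400.0, 100.0], [300.0, 200.0]]), "persons")
    return PopulationInventory(raster)


class TestGrowth:
    def test_study_growth_factor(self):
        grid = make_grid(0, 0, 2, 1, 100)
        raster = RasterField(grid, np.array([[600000.0, 400000.0]]), "persons")
        grown = apply_growth(raster, 1.043)
        assert grown.total == pytest.approx(1_043_000)

    def test_identity(self, small_inventory):
        grown = apply_growth(small_inventory.residential_raster, 1.0)
        np.testing.assert_array_equal(grown.values, small_inventory.residential_raster.values)

    def test_cellwise_linearity(self):
        rng = np.random.default_rng(0)
        grid = make_grid(0, 0, 5, 5, 100)
        raster = RasterField(grid, rng.uniform(0, 100, (5, 5)), "persons")
        np.testing.assert_array_equal(apply_growth(raster, 2.0).values, raster.values * 2)

    def test_nonpositive_factor_rejected(self, small_inventory):
        with pytest.raises(ValueError):
            apply_growth(small_inventory.residential_raster, 0.0)


class TestActivityProfile:
    def test_row_not_summing_to_one_rejected(self):
        bad = np.tile([0.5, 0.3, 0.1, 0.05], (24, 1))
        with pytest.raises(ValueError, match="sums to"):
            ActivityProfile({"weekday": bad})

    def test_csv_round_trip(self, tmp_path):
        profile = ActivityProfile.generic_default()
        profile.to_csv(tmp_path / "p.csv")
        back = ActivityProfile.from_csv(tmp_path / "p.csv")
        for day_type in profile.fractions:
            np.testing.assert_allclose(back.fractions[day_type], profile.fractions[day_type])


class TestHourlyTotals:
    def test_all_home(self, small_inventory):
        totals = hourly_environment_totals(
            small_inventory, ActivityProfile.all_home(), CommuterSpec(0), "2016-01-04 10:00"
        )
        assert totals["home"] == small_inventory.total_population
        assert totals["work"] == totals["other"] == totals["transport"] == 0

    def test_hand_multiplication(self, small_inventory):
        profile = _uniform_profile(0.5, 0.3, 0.1, 0.1)
        inv = PopulationInventory(
            RasterField(small_inventory.residential_raster.grid, np.full((2, 2), 250.0), "persons")
        )
        totals = hourly_environment_totals(inv, profile, CommuterSpec(0), "2016-01-04 10:00")
        assert totals == pytest.approx(
            {"home": 500, "work": 300, "other": 100, "transport": 100}
        )

    def test_commuters_in_transport_during_rush(self, small_inventory):
        profile = _uniform_profile(0.7, 0.2, 0.05, 0.05)
        commuters = CommuterSpec(count=223_000)
        # Monday 08:00 is inside the default 07-09 rush window
        totals = hourly_environment_totals(small_inventory, profile, commuters, "2016-01-04 08:00")
        resident_share = small_inventory.total_population * 0.05
        assert totals["transport"] == pytest.approx(resident_share + 223_000)
        # conservation incl. commuters
        assert sum(totals.values()) == pytest.approx(
            small_inventory.total_population + 223_000
        )

    def test_commuters_at_work_midday_and_absent_weekend(self, small_inventory):
        profile = _uniform_profile(0.7, 0.2, 0.05, 0.05)
        commuters = CommuterSpec(count=1000)
        midday = hourly_environment_totals(small_inventory, profile, commuters, "2016-01-04 12:00")
        assert midday["work"] == pytest.approx(small_inventory.total_population * 0.2 + 1000)
        saturday = hourly_environment_totals(small_inventory, profile, commuters, "2016-01-09 08:00")
        assert sum(saturday.values()) == pytest.approx(small_inventory.total_population)

    def test_day_type_calendar(self):
        assert day_type_of("2016-01-04") == "weekday"  # Monday
        assert day_type_of("2016-01-09") == "weekend"  # Saturday
        assert day_type_of("2016-01-04", holidays=["2016-01-04"]) == "weekend"


class TestModalSplit:
    def test_hamburg_split_hand_oracle(self):
        split = ModalSplit.hamburg_2017()
        totals = split_transport_total(10_000, split)
        assert totals["in_car"] == pytest.approx(3600)
        assert totals["walking"] == pytest.approx(2700)
        assert totals["cycling"] == pytest.approx(1500)
        # public transport sub-split renormalized after dropping the 1% ferry share
        assert totals["buses"] == pytest.approx(10_000 * 0.22 * 0.36 / 0.99)
        assert totals["subway_trains"] == pytest.approx(10_000 * 0.22 * 0.32 / 0.99)
        assert totals["suburban_trains"] == pytest.approx(10_000 * 0.22 * 0.25 / 0.99)
        assert totals["regional_trains"] == pytest.approx(10_000 * 0.22 * 0.06 / 0.99)
        assert sum(totals.values()) == pytest.approx(10_000)

    def test_single_mode(self):
        split = ModalSplit({"walking": 1.0})
        totals = split_transport_total(750, split)
        assert totals["walking"] == 750
        assert sum(totals.values()) == 750

    def test_unnormalized_split_rejected(self):
        with pytest.raises(ValueError, match="sums to"):
            ModalSplit({"walking": 0.5, "cycling": 0.4})

    def test_product_is_exact(self):
        split = ModalSplit.hamburg_2017()
        totals = split_transport_total(1000, split)
        assert totals["in_car"] == pytest.approx(360)


class TestDistribute:
    def test_uniform_over_mask(self):
        grid = make_grid(0, 0, 2, 2, 100)
        mask = RasterField(grid, np.ones((2, 2)), "bool")
        out = distribute_to_mask(100, mask)
        np.testing.assert_allclose(out, 25)

    def test_zero_total(self):
        grid = make_grid(0, 0, 2, 2, 100)
        mask = RasterField(grid, np.ones((2, 2)), "bool")
        assert not distribute_to_mask(0, mask).any()

    def test_fractional_conservation(self):
        grid = make_grid(0, 0, 3, 1, 100)
        mask = RasterField(grid, np.array([[1.0, 1.0, 1.0]]), "bool")
        out = distribute_to_mask(17, mask)
        np.testing.assert_allclose(out, 17 / 3)
        assert out.sum() == pytest.approx(17, rel=1e-9)

    def test_empty_mask_with_population_errors(self):
        grid = make_grid(0, 0, 2, 2, 100)
        mask = RasterField(grid, np.zeros((2, 2)), "bool")
        with pytest.raises(ValueError, match="walking"):
            distribute_to_mask(5, mask, env="walking")


class TestBuildHourlyPopulation:
    @pytest.fixture
    def setup(self, small_inventory):
        grid = small_inventory.residential_raster.grid
        full = RasterField(grid, np.ones((2, 2)), "bool")
        masks = EnvironmentMaskSet(
            {env: full.copy() for env in BASE_ENVIRONMENTS + TRANSPORT_MODES}
        )
        ts = pd.date_range("2016-01-04", periods=24, freq="h")
        return small_inventory, masks, ts

    def test_static_frozen_at_residential(self, setup):
        inv, masks, ts = setup
        stacks = build_hourly_population(
            inv, ActivityProfile.generic_default(), CommuterSpec(0), ModalSplit.hamburg_2017(),
            masks, "static", ts,
        )
        assert set(stacks) == {"home"}
        for frame in stacks["home"].values:
            np.testing.assert_array_equal(frame, inv.grown_raster.values)

    def test_dynamic_shares_home_work_other_with_dynamic_transport(self, setup):
        inv, masks, ts = setup
        args = (inv, ActivityProfile.generic_default(), CommuterSpec(500),
                ModalSplit.hamburg_2017(), masks)
        dyn = build_hourly_population(*args, "dynamic", ts)
        dyn_t = build_hourly_population(*args, "dynamic_transport", ts)
        for env in ("home", "work", "other"):
            np.testing.assert_array_equal(dyn[env].values, dyn_t[env].values)

    def test_per_hour_conservation_with_accounting_oracle(self, setup):
        inv, masks, ts = setup
        profile = ActivityProfile.generic_default()
        commuters = CommuterSpec(count=223_000)
        stacks = build_hourly_population(
            inv, profile, commuters, ModalSplit.hamburg_2017(), masks, "dynamic_transport", ts
        )
        for t_i, t in enumerate(ts):
            grand = sum(float(s.values[t_i].sum()) for s in stacks.values())
            expected = inv.total_population
            placed = commuters.placement(day_type_of(t), t.hour)
            if placed is not None:
                expected += commuters.count
            assert grand == pytest.approx(expected, rel=1e-9), str(t)

    def test_mode_totals_sum_to_transport_total(self, setup):
        inv, masks, ts = setup
        profile = ActivityProfile.generic_default()
        dyn = build_hourly_population(
            inv, profile, CommuterSpec(0), ModalSplit.hamburg_2017(), masks, "dynamic", ts
        )
        dyn_t = build_hourly_population(
            inv, profile, CommuterSpec(0), ModalSplit.hamburg_2017(), masks, "dynamic_transport", ts
        )
        mode_sum = sum(dyn_t[m].values.sum(axis=(1, 2)) for m in TRANSPORT_MODES)
        np.testing.assert_allclose(mode_sum, dyn["transport"].values.sum(axis=(1, 2)), rtol=1e-12)

    def test_static_degeneracy_of_dynamic(self, setup):
        inv, masks, ts = setup
        static = build_hourly_population(
            inv, ActivityProfile.all_home(), CommuterSpec(0), ModalSplit.hamburg_2017(),
            masks, "static", ts,
        )
        dynamic = build_hourly_population(
            inv, ActivityProfile.all_home(), CommuterSpec(0), ModalSplit.hamburg_2017(),
            masks, "dynamic", ts,
        )
        np.testing.assert_allclose(
            dynamic["home"].values, static["home"].values, rtol=1e-12
        )

    def test_missing_mask_errors(self, small_inventory):
        ts = pd.date_range("2016-01-04", periods=2, freq="h")
        empty = EnvironmentMaskSet({})
        with pytest.raises(ValueError, match="requires a mask"):
            build_hourly_population(
                small_inventory, ActivityProfile.generic_default(), CommuterSpec(0),
                ModalSplit.hamburg_2017(), empty, "dynamic", ts,
            )
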