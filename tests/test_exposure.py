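"""Exposure metrics against hand calculations and brute-force loops."""

import numpy as np
import pandas as pd
import pytest

from tmaexpo.exposure import (
    cell_exposure,
    environment_shares,
    population_weighted_exposure,
    source_contribution,
    total_exposure,
)
from tmaexpo.grid import HourlyFieldStack, make_grid
from tmaexpo.infiltration import InfiltrationTable, season_of


def _flat_table(envs, pollutant="X", value=1.0):
    return InfiltrationTable(
        {(env, pollutant, season): value for env in envs for season in ("winter", "summer")}
    )


def _stack(grid, ts, values):
    return HourlyFieldStack(grid, ts, np.asarray(values, dtype=float), "ug/m3")


def brute_force_exposure(conc, pop, table, pollutant):
    """Independent triple loop over environments, time and cells."""
    out = {}
    for env, p in pop.items():
        acc = np.zeros(conc.grid.shape)
        for t_i, ts in enumerate(conc.timestamps):
            finf = table.get(env, pollutant, season_of(ts))
            for row in range(conc.grid.n_y):
                for col in range(conc.grid.n_x):
                    acc[row, col] += finf * conc.values[t_i, row, col] * p.values[t_i, row, col]
        out[env] = acc
    return out


def _random_instance(rng, n=3, n_env=4, hours=24):
    grid = make_grid(0, 0, n, n, 100)
    start = pd.Timestamp("2016-03-30")  # spans the winter/summer boundary
    ts = pd.date_range(start, periods=hours, freq="h")
    conc = _stack(grid, ts, rng.uniform(0, 40, (hours, n, n)))
    envs = [f"e{k}" for k in range(n_env)]
    pop = {env: _stack(grid, ts, rng.uniform(0, 100, (hours, n, n))) for env in envs}
    table = InfiltrationTable(
        {
            (env, "X", season): rng.uniform(0.2, 1.0)
            for env in envs
            for season in ("winter", "summer")
        }
    )
    return conc, pop, table


class TestCellExposure:
    @pytest.mark.parametrize(
        "c,p,f,expected", [(10, 5, 1, 50), (10, 5, 0.5, 25), (0, 123, 0.9, 0)]
    )
    def test_closed_form(self, c, p, f, expected):
        assert cell_exposure(c, p, f) == expected

    def test_negative_population_rejected(self):
        with pytest.raises(ValueError):
            cell_exposure(10, -1, 1)


class TestTotalExposure:
    def test_two_hour_hand_sum(self):
        grid = make_grid(0, 0, 1, 1, 100)
        ts = pd.date_range("2016-01-04", periods=2, freq="h")
        conc = _stack(grid, ts, [[[10]], [[20]]])
        pop = {"home": _stack(grid, ts, [[[1]], [[1]]])}
        result = total_exposure(conc, pop, _flat_table(["home"]), "X")
        assert result.per_environment_total["home"] == pytest.approx(30)

    def test_zero_population_zero_exposure(self):
        rng = np.random.default_rng(0)
        conc, pop, table = _random_instance(rng)
        zero_pop = {
            env: _stack(s.grid, s.timestamps, np.zeros_like(s.values)) for env, s in pop.items()
        }
        result = total_exposure(conc, zero_pop, table, "X")
        assert result.total == 0

    def test_matches_brute_force_loops(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            conc, pop, table = _random_instance(rng)
            result = total_exposure(conc, pop, table, "X")
            oracle = brute_force_exposure(conc, pop, table, "X")
            for env in pop:
                np.testing.assert_allclose(result.per_cell[env], oracle[env], rtol=1e-9)

    def test_timestamp_mismatch_rejected(self):
        grid = make_grid(0, 0, 1, 1, 100)
        ts_a = pd.date_range("2016-01-04", periods=2, freq="h")
        ts_b = pd.date_range("2016-01-05", periods=2, freq="h")
        conc = _stack(grid, ts_a, np.ones((2, 1, 1)))
        pop = {"home": _stack(grid, ts_b, np.ones((2, 1, 1)))}
        with pytest.raises(ValueError, match="timestamp"):
            total_exposure(conc, pop, _flat_table(["home"]), "X")

    def test_linearity_in_each_factor(self):
        rng = np.random.default_rng(2)
        conc, pop, table = _random_instance(rng, n=2, n_env=2, hours=12)
        base = total_exposure(conc, pop, table, "X")
        conc2 = _stack(conc.grid, conc.timestamps, 3.0 * conc.values)
        assert total_exposure(conc2, pop, table, "X").total == pytest.approx(3 * base.total)
        pop2 = {e: _stack(s.grid, s.timestamps, 2.0 * s.values) for e, s in pop.items()}
        assert total_exposure(conc, pop2, table, "X").total == pytest.approx(2 * base.total)
        assert total_exposure(conc, pop, table.scaled(0.5), "X").total == pytest.approx(
            0.5 * base.total
        )

    def test_superposition_in_concentration(self):
        rng = np.random.default_rng(3)
        conc_a, pop, table = _random_instance(rng, n=2, hours=12)
        conc_b = _stack(conc_a.grid, conc_a.timestamps,
                        rng.uniform(0, 40, conc_a.values.shape))
        conc_sum = _stack(conc_a.grid, conc_a.timestamps, conc_a.values + conc_b.values)
        total_sum = total_exposure(conc_sum, pop, table, "X").total
        assert total_sum == pytest.approx(
            total_exposure(conc_a, pop, table, "X").total
            + total_exposure(conc_b, pop, table, "X").total,
            rel=1e-12,
        )


class TestPWE:
    def test_uniform_concentration_invariance(self):
        grid = make_grid(0, 0, 2, 2, 100)
        ts = pd.date_range("2016-01-04", periods=3, freq="h")
        conc = _stack(grid, ts, np.full((3, 2, 2), 17.0))
        pop = {"home": _stack(grid, ts, np.random.default_rng(0).uniform(1, 9, (3, 2, 2)))}
        assert population_weighted_exposure(conc, pop, _flat_table(["home"]), "X").pwe == (
            pytest.approx(17.0)
        )
        half = _flat_table(["home"], value=0.5)
        assert population_weighted_exposure(conc, pop, half, "X").pwe == pytest.approx(8.5)

    def test_weighted_mean_hand_calculation(self):
        grid = make_grid(0, 0, 2, 1, 100)
        ts = pd.date_range("2016-01-04", periods=1, freq="h")
        conc = _stack(grid, ts, [[[10, 30]]])
        pop = {"home": _stack(grid, ts, [[[3, 1]]])}
        result = population_weighted_exposure(conc, pop, _flat_table(["home"]), "X")
        assert result.pwe == pytest.approx(15.0)
        assert result.person_hours == 4

    def test_zero_population_reported_missing(self):
        grid = make_grid(0, 0, 1, 1, 100)
        ts = pd.date_range("2016-01-04", periods=1, freq="h")
        conc = _stack(grid, ts, [[[10]]])
        pop = {"home": _stack(grid, ts, [[[0]]])}
        result = population_weighted_exposure(conc, pop, _flat_table(["home"]), "X")
        assert result.pwe is None

    def test_bounded_by_visited_finf_scaled_concentrations(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            conc, pop, table = _random_instance(rng, n=3, n_env=3, hours=12)
            result = population_weighted_exposure(conc, pop, table, "X")
            lo, hi = np.inf, -np.inf
            for env, p in pop.items():
                for t_i, ts in enumerate(conc.timestamps):
                    finf = table.get(env, "X", season_of(ts))
                    visited = p.values[t_i] > 0
                    if visited.any():
                        fc = finf * conc.values[t_i][visited]
                        lo, hi = min(lo, fc.min()), max(hi, fc.max())
            assert lo - 1e-9 <= result.pwe <= hi + 1e-9


class TestSourceContribution:
    def _setup(self, rng):
        conc, pop, table = _random_instance(rng, n=3, n_env=2, hours=12)
        zero = _stack(conc.grid, conc.timestamps, conc.values * rng.uniform(0.3, 0.9))
        return conc, zero, pop, table

    def test_identical_fields_zero_contribution(self):
        rng = np.random.default_rng(5)
        conc, _, pop, table = self._setup(rng)
        result = source_contribution(conc, conc, pop, table, "X")
        assert result.exposure.total == 0
        for rel in result.relative.values():
            assert rel == pytest.approx(0)

    def test_zero_field_full_relative_contribution(self):
        rng = np.random.default_rng(6)
        conc, _, pop, table = self._setup(rng)
        zero = _stack(conc.grid, conc.timestamps, np.zeros_like(conc.values))
        result = source_contribution(conc, zero, pop, table, "X")
        for rel in result.relative.values():
            assert rel == pytest.approx(1)

    def test_additivity(self):
        rng = np.random.default_rng(7)
        conc, zero, pop, table = self._setup(rng)
        contrib = source_contribution(conc, zero, pop, table, "X")
        full = total_exposure(conc, pop, table, "X")
        base = total_exposure(zero, pop, table, "X")
        for env in pop:
            assert contrib.exposure.per_environment_total[env] + base.per_environment_total[
                env
            ] == pytest.approx(full.per_environment_total[env], rel=1e-12)

    def test_constructed_increment_recovered(self):
        rng = np.random.default_rng(8)
        conc, zero, pop, table = self._setup(rng)
        increment = _stack(conc.grid, conc.timestamps, rng.uniform(0, 10, conc.values.shape))
        full = _stack(conc.grid, conc.timestamps, zero.values + increment.values)
        result = source_contribution(full, zero, pop, table, "X")
        expected = total_exposure(increment, pop, table, "X")
        for env in pop:
            np.testing.assert_allclose(
                result.exposure.per_cell[env], expected.per_cell[env], rtol=1e-9
            )


class TestEnvironmentShares:
    def test_single_environment(self):
        rng = np.random.default_rng(9)
        conc, pop, table = _random_instance(rng, n=2, n_env=1, hours=6)
        result = total_exposure(conc, pop, table, "X")
        assert environment_shares(result) == {list(pop)[0]: pytest.approx(1.0)}

    def test_hand_ratio(self):
        grid = make_grid(0, 0, 1, 1, 100)
        ts = pd.date_range("2016-01-04", periods=1, freq="h")
        conc = _stack(grid, ts, [[[1]]])
        pop = {"a": _stack(grid, ts, [[[3]]]), "b": _stack(grid, ts, [[[1]]])}
        shares = environment_shares(total_exposure(conc, pop, _flat_table(["a", "b"]), "X"))
        assert shares == {"a": pytest.approx(0.75), "b": pytest.approx(0.25)}

    def test_shares_sum_to_one(self):
        rng = np.random.default_rng(10)
        conc, pop, table = _random_instance(rng, n=3, n_env=7, hours=12)
        shares = environment_shares(total_exposure(conc, pop, table, "X"))
        assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_total_reported_missing(self):
        grid = make_grid(0, 0, 1, 1, 100)
        ts = pd.date_range("2016-01-04", periods=1, freq="h")
        conc = _stack(grid, ts, [[[0]]])
        pop = {"a": _stack(grid, ts, [[[3]]])}
        assert environment_shares(total_exposure(conc, pop, _flat_table(["a"]), "X")) == {}
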