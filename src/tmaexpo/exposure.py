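"""Exposure metrics: total exposure, population-weighted exposure,
environment shares, and zero-out source contributions.

Total exposure in cell ``i`` is

    E_i = sum_j F_inf,j * sum_t C_{i,t} * P_{i,j,t}

with concentration C in ug/m3, population P in persons and the
dimensionless infiltration factor F resolved per season of ``t``; the
result carries units ug/m3 * persons summed over hours.  Population-
weighted exposure divides by the cumulative person-hours,

    PWE_i = E_i / sum_j sum_t P_{i,j,t}

giving the average concentration the population experiences (ug/m3).
The contribution of one emission source (e.g. road traffic) is obtained
from a paired "zero-out" concentration field without that source: the
difference of the two fields, propagated through the exposure sum.

Summation runs over time first with float64 accumulation in a fixed
order, so domain totals are bit-reproducible across runs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .grid import HourlyFieldStack, require_aligned
from .infiltration import InfiltrationTable, DEFAULT_WINTER_MONTHS, season_of

logger = logging.getLogger(__name__)


@dataclass
class ExposureResult:
    """Per-environment exposure maps (ug/m3 * persons, hour-summed)."""

    per_cell: dict[str, np.ndarray]
    approach: str
    pollutant: str

    @property
    def per_environment_total(self) -> dict[str, float]:
        return {env: float(arr.sum()) for env, arr in self.per_cell.items()}

    @property
    def total(self) -> float:
        return float(sum(self.per_environment_total.values()))

    def total_map(self) -> np.ndarray:
        """Sum over environments, per cell."""
        arrays = list(self.per_cell.values())
        out = np.zeros_like(arrays[0])
        for arr in arrays:
            out += arr
        return out


@dataclass
class PWEResult:
    """Population-weighted exposure (ug/m3) per scope, with denominators."""

    pwe: float | None
    person_hours: float
    per_cell: np.ndarray | None = None
    scope: tuple[str, ...] = ()
    pollutant: str = ""


@dataclass
class ContributionResult:
    """Absolute and relative contribution of one source to exposure."""

    concentration_mean_contribution: np.ndarray
    exposure: ExposureResult
    relative: dict[str, float]


def cell_exposure(concentration: float, population: float, finf: float) -> float:
    """Pointwise exposure C * P * F (ug/m3 * persons)."""
    if population < 0:
        raise ValueError("population must be non-negative")
    return concentration * population * finf


def _finf_series(
    table: InfiltrationTable, env: str, pollutant: str, timestamps, winter_months
) -> np.ndarray:
    return np.array(
        [table.get(env, pollutant, season_of(ts, winter_months)) for ts in timestamps]
    )


def total_exposure(
    conc: HourlyFieldStack,
    pop: dict[str, HourlyFieldStack],
    finf_table: InfiltrationTable,
    pollutant: str,
    approach: str = "",
    winter_months=DEFAULT_WINTER_MONTHS,
) -> ExposureResult:
    """Hour-summed exposure per cell and environment.

    ``pop`` maps environment name to its P_{i,j,t} stack; all stacks must
    share the concentration stack's grid and time axis.
    """
    for env, p in pop.items():
        require_aligned(conc, p)
    per_cell: dict[str, np.ndarray] = {}
    for env, p in pop.items():
        finf = _finf_series(finf_table, env, pollutant, conc.timestamps, winter_months)
        # time-innermost fixed-order accumulation
        per_cell[env] = np.einsum("t,tyx,tyx->yx", finf, conc.values, p.values, optimize=False)
    return ExposureResult(per_cell=per_cell, approach=approach, pollutant=pollutant)


def population_weighted_exposure(
    conc: HourlyFieldStack,
    pop: dict[str, HourlyFieldStack],
    finf_table: InfiltrationTable,
    pollutant: str,
    scope=None,
    per_cell: bool = False,
    winter_months=DEFAULT_WINTER_MONTHS,
) -> PWEResult:
    """Total exposure divided by cumulative person-hours.

    ``scope`` restricts the environments entering both numerator and
    denominator (default: all environments present in ``pop``).  A scope
    with zero cumulative population has no defined PWE; it is reported
    as missing (``None``) with a warning, never as 0.
    """
    scope = tuple(scope) if scope is not None else tuple(pop)
    missing = [env for env in scope if env not in pop]
    if missing:
        raise KeyError(f"scope environments without population stacks: {missing}")
    sub = {env: pop[env] for env in scope}
    result = total_exposure(conc, sub, finf_table, pollutant, winter_months=winter_months)

    denom_map = np.zeros(conc.grid.shape)
    for env in scope:
        denom_map += sub[env].values.sum(axis=0)
    person_hours = float(denom_map.sum())

    if person_hours <= 0:
        logger.warning("PWE undefined: zero cumulative population in scope %s", scope)
        return PWEResult(None, 0.0, None, scope, pollutant)

    numerator_map = result.total_map()
    pwe = float(numerator_map.sum()) / person_hours
    cell_map = None
    if per_cell:
        with np.errstate(invalid="ignore", divide="ignore"):
            cell_map = np.where(denom_map > 0, numerator_map / denom_map, np.nan)
    return PWEResult(pwe, person_hours, cell_map, scope, pollutant)


def source_contribution(
    conc_full: HourlyFieldStack,
    conc_zero_out: HourlyFieldStack,
    pop: dict[str, HourlyFieldStack],
    finf_table: InfiltrationTable,
    pollutant: str,
    winter_months=DEFAULT_WINTER_MONTHS,
) -> ContributionResult:
    """Contribution of the zeroed-out source to concentration and exposure.

    The concentration contribution is ``full - zero_out`` per cell and
    hour; its exposure follows by running the exposure sum on the
    difference field.  Negative local differences (possible through
    nonlinear chemistry upstream) are kept, not clipped; if the zero-out
    field exceeds the full field in more than 1% of values a warning is
    logged.
    """
    require_aligned(conc_full, conc_zero_out)
    diff = conc_full.values - conc_zero_out.values
    frac_negative = float((diff < 0).mean())
    if frac_negative > 0.01:
        logger.warning(
            "zero-out field exceeds the full field in %.1f%% of values", 100 * frac_negative
        )
    diff_stack = HourlyFieldStack(
        conc_full.grid, conc_full.timestamps, diff, conc_full.units, "contribution"
    )
    contrib = total_exposure(diff_stack, pop, finf_table, pollutant, winter_months=winter_months)
    full = total_exposure(conc_full, pop, finf_table, pollutant, winter_months=winter_months)
    relative = {}
    for env in pop:
        denom = full.per_environment_total[env]
        if denom > 0:
            relative[env] = contrib.per_environment_total[env] / denom
    return ContributionResult(
        concentration_mean_contribution=diff.mean(axis=0),
        exposure=contrib,
        relative=relative,
    )


def environment_shares(result: ExposureResult, scope=None) -> dict[str, float]:
    """Fractions of scope total exposure per environment; sum to 1.

    A zero scope total means the shares are undefined; an empty dict is
    returned with a warning.
    """
    scope = tuple(scope) if scope is not None else tuple(result.per_cell)
    totals = {env: result.per_environment_total[env] for env in scope}
    grand = sum(totals.values())
    if grand <= 0:
        logger.warning("environment shares undefined: zero total exposure in scope %s", scope)
        return {}
    return {env: value / grand for env, value in totals.items()}
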