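"""Hourly population fields P_{i,j,t} from activity profiles, commuters
and modal split.

The time-microenvironment-activity (TMA) scheme works in two stages:

1. a scalar total per environment and hour — residents are divided over
   the four base environments by a diurnal activity profile (weekday or
   weekend), commuters are added to the transport environments during
   rush hours and to the work environment during working hours on
   workdays;
2. spatial distribution — the home total is spread over the residential
   raster in proportion to where people live, every other environment
   receives its total uniformly over the cells of its mask.

Population totals are real-valued: hourly fractions make integer person
counts impossible.  Conservation (sum over environments and cells equals
residents plus scheduled commuters) holds exactly at every hour.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DomainGrid, HourlyFieldStack, RasterField
from .microenv import (
    BASE_ENVIRONMENTS,
    TRANSPORT_MODES,
    EnvironmentMaskSet,
)

logger = logging.getLogger(__name__)

APPROACHES = ("static", "dynamic", "dynamic_transport")


@dataclass
class ActivityProfile:
    """Hourly fractions of the resident population per base environment.

    ``fractions`` maps ``day_type`` (``"weekday"``/``"weekend"``) to a
    (24, 4) array in base-environment order (home, work, other,
    transport).  Each hourly row must sum to 1.
    """

    fractions: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for day_type, arr in self.fractions.items():
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (24, len(BASE_ENVIRONMENTS)):
                raise ValueError(
                    f"{day_type} profile must be 24x{len(BASE_ENVIRONMENTS)}, got {arr.shape}"
                )
            if np.any(arr < 0) or np.any(arr > 1):
                raise ValueError(f"{day_type} profile fractions must lie in [0, 1]")
            row_sums = arr.sum(axis=1)
            if not np.allclose(row_sums, 1.0, atol=1e-9):
                bad = int(np.argmax(np.abs(row_sums - 1.0)))
                raise ValueError(
                    f"{day_type} profile row for hour {bad} sums to {row_sums[bad]!r}, not 1"
                )
            self.fractions[day_type] = arr

    def row(self, day_type: str, hour: int) -> np.ndarray:
        return self.fractions[day_type][hour]

    @classmethod
    def all_home(cls) -> "ActivityProfile":
        """Degenerate profile: the whole population at home at all hours."""
        row = np.zeros((24, len(BASE_ENVIRONMENTS)))
        row[:, 0] = 1.0
        return cls({"weekday": row.copy(), "weekend": row.copy()})

    @classmethod
    def generic_default(cls) -> "ActivityProfile":
        """A plausible generic European diurnal pattern.

        Not calibrated against any survey — intended for demonstrations
        and synthetic runs; real studies should supply their own CSV.
        """
        weekday = np.zeros((24, 4))
        for hour in range(24):
            if hour < 6:
                home, work, other, transport = 0.97, 0.02, 0.01, 0.00
            elif hour < 7:
                home, work, other, transport = 0.85, 0.05, 0.02, 0.08
            elif hour < 9:
                home, work, other, transport = 0.55, 0.25, 0.08, 0.12
            elif hour < 12:
                home, work, other, transport = 0.35, 0.45, 0.15, 0.05
            elif hour < 14:
                home, work, other, transport = 0.33, 0.42, 0.18, 0.07
            elif hour < 16:
                home, work, other, transport = 0.35, 0.43, 0.17, 0.05
            elif hour < 19:
                home, work, other, transport = 0.45, 0.20, 0.23, 0.12
            elif hour < 22:
                home, work, other, transport = 0.70, 0.07, 0.18, 0.05
            else:
                home, work, other, transport = 0.92, 0.04, 0.03, 0.01
            weekday[hour] = (home, work, other, transport)
        weekend = np.zeros((24, 4))
        for hour in range(24):
            if hour < 8:
                home, work, other, transport = 0.96, 0.01, 0.02, 0.01
            elif hour < 11:
                home, work, other, transport = 0.75, 0.03, 0.16, 0.06
            elif hour < 18:
                home, work, other, transport = 0.50, 0.05, 0.37, 0.08
            elif hour < 22:
                home, work, other, transport = 0.70, 0.03, 0.23, 0.04
            else:
                home, work, other, transport = 0.93, 0.02, 0.04, 0.01
            weekend[hour] = (home, work, other, transport)
        return cls({"weekday": weekday, "weekend": weekend})

    @classmethod
    def from_csv(cls, path) -> "ActivityProfile":
        """Load from CSV columns ``day_type, hour, environment, fraction``."""
        table = pd.read_csv(path)
        fractions = {}
        for day_type, part in table.groupby("day_type"):
            arr = np.zeros((24, len(BASE_ENVIRONMENTS)))
            env_index = {env: k for k, env in enumerate(BASE_ENVIRONMENTS)}
            for rec in part.itertuples(index=False):
                arr[int(rec.hour), env_index[rec.environment]] = float(rec.fraction)
            fractions[str(day_type)] = arr
        return cls(fractions)

    def to_csv(self, path) -> None:
        rows = []
        for day_type, arr in self.fractions.items():
            for hour in range(24):
                for k, env in enumerate(BASE_ENVIRONMENTS):
                    rows.append((day_type, hour, env, arr[hour, k]))
        pd.DataFrame(rows, columns=["day_type", "hour", "environment", "fraction"]).to_csv(
            path, index=False
        )


@dataclass
class ModalSplit:
    """Fraction of the transport population per transport mode; sums to 1."""

    fractions: dict[str, float]

    def __post_init__(self) -> None:
        unknown = set(self.fractions) - set(TRANSPORT_MODES)
        if unknown:
            raise ValueError(f"unknown transport modes {sorted(unknown)}")
        vals = np.array([self.fractions.get(m, 0.0) for m in TRANSPORT_MODES])
        if np.any(vals < 0):
            raise ValueError("modal-split fractions must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"modal split sums to {vals.sum()!r}, expected 1")
        self.fractions = {m: float(self.fractions.get(m, 0.0)) for m in TRANSPORT_MODES}

    @classmethod
    def hamburg_2017(cls) -> "ModalSplit":
        """Hamburg urban-area modal split: 27% walking, 15% cycling, 36% car,
        22% public transport.  Within public transport: 36% bus, 32% subway,
        25% suburban trains, 6% regional trains; the 1% ferry share is
        dropped and the remaining public-transport shares renormalized.
        """
        pt = 0.22
        pt_sub = {"buses": 0.36, "subway_trains": 0.32, "suburban_trains": 0.25, "regional_trains": 0.06}
        norm = sum(pt_sub.values())  # 0.99 after removing the 1% ferry share
        fractions = {"walking": 0.27, "cycling": 0.15, "in_car": 0.36}
        fractions.update({mode: pt * share / norm for mode, share in pt_sub.items()})
        return cls(fractions)

    @classmethod
    def from_csv(cls, path) -> "ModalSplit":
        table = pd.read_csv(path)
        return cls({str(r.mode): float(r.fraction) for r in table.itertuples(index=False)})

    def to_csv(self, path) -> None:
        pd.DataFrame(
            [(m, f) for m, f in self.fractions.items()], columns=["mode", "fraction"]
        ).to_csv(path, index=False)


@dataclass
class CommuterSpec:
    """Commuters entering the city on workdays.

    They appear in the transport environments during rush-hour windows
    and in the work environment during working hours; at other hours
    they are outside the domain.  Windows are half-open hour-of-day
    intervals ``[start, end)``.
    """

    count: float = 0.0
    rush_windows: tuple[tuple[int, int], ...] = ((7, 9), (16, 19))
    working_hours: tuple[int, int] = (9, 16)
    workday_only: bool = True

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("commuter count must be non-negative")
        for start, end in self.rush_windows:
            if not (0 <= start < end <= 24):
                raise ValueError(f"bad rush window [{start}, {end})")

    def placement(self, day_type: str, hour: int) -> str | None:
        """``"transport"``, ``"work"`` or ``None`` for the given hour."""
        if self.count == 0:
            return None
        if self.workday_only and day_type != "weekday":
            return None
        if any(start <= hour < end for start, end in self.rush_windows):
            return "transport"
        lo, hi = self.working_hours
        if lo <= hour < hi:
            return "work"
        return None


@dataclass
class PopulationInventory:
    """Residential population raster plus a growth factor to the study year."""

    residential_raster: RasterField
    growth_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.growth_factor <= 0:
            raise ValueError("growth factor must be positive")

    @property
    def grown_raster(self) -> RasterField:
        return apply_growth(self.residential_raster, self.growth_factor)

    @property
    def total_population(self) -> float:
        return float(self.residential_raster.values.sum()) * self.growth_factor


def apply_growth(raster: RasterField, factor: float) -> RasterField:
    """Scale every cell by a population growth factor (e.g. 1.043 for a
    +4.3% trend between the census year and the study year)."""
    if factor <= 0:
        raise ValueError(f"growth factor must be positive, got {factor}")
    return RasterField(raster.grid, raster.values * factor, raster.units, raster.name)


def day_type_of(timestamp: pd.Timestamp, holidays=()) -> str:
    """``weekday`` Mon-Fri, ``weekend`` Sat-Sun; configured holidays count
    as weekends."""
    ts = pd.Timestamp(timestamp)
    if ts.normalize() in {pd.Timestamp(h).normalize() for h in holidays}:
        return "weekend"
    return "weekend" if ts.dayofweek >= 5 else "weekday"


def hourly_environment_totals(
    inventory: PopulationInventory,
    profile: ActivityProfile,
    commuters: CommuterSpec,
    timestamp,
    holidays=(),
) -> dict[str, float]:
    """Scalar population total per base environment at one instant.

    Residents follow the activity profile; commuters are added per
    :meth:`CommuterSpec.placement`.  The values sum exactly to residents
    plus scheduled commuters.
    """
    ts = pd.Timestamp(timestamp)
    day_type = day_type_of(ts, holidays)
    row = profile.row(day_type, ts.hour)
    total = inventory.total_population
    totals = {env: total * row[k] for k, env in enumerate(BASE_ENVIRONMENTS)}
    placed = commuters.placement(day_type, ts.hour)
    if placed is not None:
        totals[placed] += commuters.count
    return totals


def split_transport_total(transport_total: float, split: ModalSplit) -> dict[str, float]:
    """Divide the transport-environment population over the seven modes."""
    if transport_total < 0:
        raise ValueError("transport total must be non-negative")
    return {mode: transport_total * frac for mode, frac in split.fractions.items()}


def distribute_to_mask(total: float, mask: RasterField, env: str = "?") -> np.ndarray:
    """Spread a total uniformly over the true cells of a mask."""
    if total < 0:
        raise ValueError("total must be non-negative")
    member = mask.values > 0
    n_true = int(member.sum())
    out = np.zeros(mask.grid.shape)
    if total == 0:
        return out
    if n_true == 0:
        raise ValueError(f"cannot distribute {total} persons: mask for {env!r} is empty")
    out[member] = total / n_true
    return out


def distribute_proportional(total: float, weights: np.ndarray) -> np.ndarray:
    """Spread a total over cells in proportion to a non-negative weight
    raster (used for the home environment, weighted by residence)."""
    if total < 0:
        raise ValueError("total must be non-negative")
    weights = np.asarray(weights, dtype=float)
    wsum = weights.sum()
    if total == 0:
        return np.zeros_like(weights)
    if wsum <= 0:
        raise ValueError("cannot distribute population: weight raster sums to zero")
    return weights * (total / wsum)


def build_hourly_population(
    inventory: PopulationInventory,
    profile: ActivityProfile,
    commuters: CommuterSpec,
    split: ModalSplit,
    masks: EnvironmentMaskSet,
    approach: str,
    timestamps,
    holidays=(),
) -> dict[str, HourlyFieldStack]:
    """P_{i,j,t} stacks per environment for one approach.

    * ``static`` — the home stack frozen at the (grown) residential
      raster; no other environments.
    * ``dynamic`` — home/work/other/transport; transport undivided.
    * ``dynamic_transport`` — home/work/other plus the seven mode
      stacks; mode totals from the modal split.

    The home total is distributed in proportion to the residential
    raster, all other environments uniformly over their mask.
    """
    if approach not in APPROACHES:
        raise ValueError(f"unknown approach {approach!r}")
    timestamps = pd.DatetimeIndex(timestamps)
    grid = inventory.residential_raster.grid
    home_weights = inventory.residential_raster.values

    if approach == "static":
        frozen = inventory.grown_raster.values
        values = np.broadcast_to(frozen, (len(timestamps),) + grid.shape).copy()
        return {
            "home": HourlyFieldStack(grid, timestamps, values, units="persons", name="pop_home")
        }

    if approach == "dynamic":
        spatial_envs = ["home", "work", "other", "transport"]
    else:
        spatial_envs = ["home", "work", "other"] + list(TRANSPORT_MODES)
    for env in spatial_envs:
        if env != "home" and env not in masks:
            raise ValueError(f"approach {approach!r} requires a mask for {env!r}")

    stacks = {
        env: np.zeros((len(timestamps),) + grid.shape) for env in spatial_envs
    }
    # Pre-compute uniform distribution templates (mask geometry is static).
    templates: dict[str, np.ndarray] = {}
    for env in spatial_envs:
        if env == "home":
            templates[env] = distribute_proportional(1.0, home_weights)
        else:
            templates[env] = distribute_to_mask(1.0, masks[env], env)

    for t_i, ts in enumerate(timestamps):
        totals = hourly_environment_totals(inventory, profile, commuters, ts, holidays)
        if approach == "dynamic":
            env_totals = totals
        else:
            env_totals = {env: totals[env] for env in ("home", "work", "other")}
            env_totals.update(split_transport_total(totals["transport"], split))
        for env, total in env_totals.items():
            if total:
                stacks[env][t_i] = total * templates[env]

    return {
        env: HourlyFieldStack(grid, timestamps, arr, units="persons", name=f"pop_{env}")
        for env, arr in stacks.items()
    }
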