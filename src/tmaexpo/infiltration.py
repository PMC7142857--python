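"""Outdoor-to-indoor infiltration factors F_inf.

F_inf is the ratio of the indoor concentration of ambient origin to the
outdoor concentration (C_ai / C_a).  It modulates exposure in enclosed
microenvironments: a home with F_inf = 0.5 exposes its occupants to half
the ambient concentration, while walking and cycling have F_inf = 1.
Factors are resolved per environment, pollutant and season; the season
of an hour follows a configurable month mapping (default: winter is
October-March, summer April-September).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import logging

import pandas as pd

logger = logging.getLogger(__name__)

SEASONS = ("winter", "summer")

#: Months mapped to winter under the default season convention.
DEFAULT_WINTER_MONTHS = frozenset({10, 11, 12, 1, 2, 3})


def season_of(timestamp, winter_months=DEFAULT_WINTER_MONTHS) -> str:
    """Season of a timestamp: ``winter`` or ``summer``."""
    return "winter" if pd.Timestamp(timestamp).month in winter_months else "summer"


@dataclass
class InfiltrationTable:
    """F_inf per (environment, pollutant, season).

    Values above 1 are physically unusual (indoor enrichment of ambient
    pollution) and are logged; values outside [0, 1.5] are rejected.
    """

    entries: dict[tuple[str, str, str], float]

    def __post_init__(self) -> None:
        clean: dict[tuple[str, str, str], float] = {}
        for (env, pollutant, season), value in self.entries.items():
            value = float(value)
            if season not in SEASONS:
                raise ValueError(f"unknown season {season!r}")
            if not (0.0 <= value <= 1.5):
                raise ValueError(
                    f"F_inf for ({env}, {pollutant}, {season}) = {value} outside [0, 1.5]"
                )
            if value > 1.0:
                logger.warning(
                    "F_inf > 1 for (%s, %s, %s): %.3g", env, pollutant, season, value
                )
            clean[(env, pollutant, season)] = value
        self.entries = clean

    def get(self, env: str, pollutant: str, season: str) -> float:
        try:
            return self.entries[(env, pollutant, season)]
        except KeyError:
            raise KeyError(
                f"no infiltration factor for environment={env!r}, "
                f"pollutant={pollutant!r}, season={season!r}"
            ) from None

    def scaled(self, alpha: float) -> "InfiltrationTable":
        """Every entry multiplied by ``alpha`` (clipped into the validity
        band is NOT applied; out-of-band products raise)."""
        return InfiltrationTable({k: v * alpha for k, v in self.entries.items()})

    def with_entries(self, overrides: dict[tuple[str, str, str], float]) -> "InfiltrationTable":
        merged = dict(self.entries)
        merged.update(overrides)
        return InfiltrationTable(merged)

    @classmethod
    def from_csv(cls, path) -> "InfiltrationTable":
        """Load from CSV columns ``environment, pollutant, season, finf``."""
        table = pd.read_csv(path)
        return cls(
            {
                (str(r.environment), str(r.pollutant), str(r.season)): float(r.finf)
                for r in table.itertuples(index=False)
            }
        )

    def to_csv(self, path) -> None:
        rows = [(env, pol, season, v) for (env, pol, season), v in self.entries.items()]
        pd.DataFrame(rows, columns=["environment", "pollutant", "season", "finf"]).to_csv(
            path, index=False
        )


def _table(data: dict[str, dict[str, tuple[float, float]]]) -> dict:
    """Helper: {env: {pollutant: (winter, summer)}} -> flat entries."""
    entries = {}
    for env, per_pol in data.items():
        for pollutant, (winter, summer) in per_pol.items():
            entries[(env, pollutant, "winter")] = winter
            entries[(env, pollutant, "summer")] = summer
    return entries


#: Literature-aggregated seasonal infiltration factors for PM2.5 and NO2.
#: Residential and workplace buildings keep out roughly half the ambient
#: PM2.5; open-air transport modes (walking, cycling) see the full
#: ambient concentration; vehicle cabins and trains fall in between.
DEFAULT_INFILTRATION = InfiltrationTable(
    _table(
        {
            "home": {"PM2.5": (0.5, 0.6), "NO2": (0.7, 0.8)},
            "work": {"PM2.5": (0.5, 0.6), "NO2": (0.75, 0.85)},
            "other": {"PM2.5": (0.8, 1.0), "NO2": (0.8, 1.0)},
            "transport": {"PM2.5": (1.0, 1.0), "NO2": (1.0, 1.0)},
            "walking": {"PM2.5": (1.0, 1.0), "NO2": (1.0, 1.0)},
            "cycling": {"PM2.5": (1.0, 1.0), "NO2": (1.0, 1.0)},
            "in_car": {"PM2.5": (0.7, 0.8), "NO2": (0.9, 0.9)},
            "buses": {"PM2.5": (0.9, 0.9), "NO2": (0.9, 0.9)},
            "subway_trains": {"PM2.5": (0.7, 0.7), "NO2": (0.6, 0.6)},
            "suburban_trains": {"PM2.5": (0.7, 0.7), "NO2": (0.7, 0.7)},
            "regional_trains": {"PM2.5": (0.6, 0.6), "NO2": (0.6, 0.6)},
        }
    )
)


def resolve_finf(
    table: InfiltrationTable,
    env: str,
    pollutant: str,
    timestamp,
    winter_months=DEFAULT_WINTER_MONTHS,
) -> float:
    """Seasonal F_inf for the month of the timestamp."""
    return table.get(env, pollutant, season_of(timestamp, winter_months))


@dataclass
class ScenarioFinfSet:
    """Reference / minimum / maximum infiltration variants.

    Used in sensitivity runs: the minimum and maximum tables bracket the
    reference entrywise.  When no measured variant tables are supplied,
    :meth:`from_reference` derives them as reference scaled by
    ``1 - fraction`` / ``1 + fraction`` for the selected environments
    (values capped at the table's validity bound of 1.5).
    """

    reference: InfiltrationTable
    minimum: InfiltrationTable
    maximum: InfiltrationTable

    def __post_init__(self) -> None:
        keys = set(self.reference.entries)
        if set(self.minimum.entries) != keys or set(self.maximum.entries) != keys:
            raise ValueError("scenario variants must share one key set")
        for key in keys:
            lo, ref, hi = (
                self.minimum.entries[key],
                self.reference.entries[key],
                self.maximum.entries[key],
            )
            if not (lo <= ref <= hi):
                raise ValueError(f"variant ordering violated for {key}: {lo} <= {ref} <= {hi}")

    def __getitem__(self, name: str) -> InfiltrationTable:
        return {"reference": self.reference, "minimum": self.minimum, "maximum": self.maximum}[name]

    @classmethod
    def from_reference(
        cls,
        reference: InfiltrationTable,
        fraction: float = 0.3,
        environments=None,
    ) -> "ScenarioFinfSet":
        """Derive min/max tables as reference -/+ ``fraction`` (relative).

        ``environments`` restricts the perturbation (e.g. the enclosed
        transport modes); unlisted environments keep the reference value
        in both variants.
        """
        if not (0 <= fraction < 1):
            raise ValueError("fraction must be in [0, 1)")
        lo, hi = {}, {}
        for key, value in reference.entries.items():
            if environments is None or key[0] in environments:
                lo[key] = value * (1 - fraction)
                hi[key] = min(value * (1 + fraction), 1.5)
            else:
                lo[key] = value
                hi[key] = value
        return cls(reference, InfiltrationTable(lo), InfiltrationTable(hi))
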