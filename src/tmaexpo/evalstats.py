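"""Model-versus-observation evaluation statistics.

Standard air-quality benchmarking measures over paired hourly or daily
concentration series:

* MB   — mean bias, ``mean(mod - obs)``;
* NMB  — normalized mean bias, ``sum(mod - obs) / sum(obs)``
  (equivalently MB / mean(obs));
* RMSE — root mean square error;
* r    — Pearson correlation coefficient (undefined for constant
  series; reported missing, never 0);
* IOA  — Willmott index of agreement,
  ``1 - sum((mod-obs)^2) / sum((|mod - mean(obs)| + |obs - mean(obs)|)^2)``;
* FAC2 — fraction of pairs with ``0.5 <= mod/obs <= 2`` (inclusive).
  Pairs with ``obs == 0`` have no defined ratio and are excluded from
  the FAC2 count (logged), following the usual convention.

The FAIRMODE screening criterion for urban dispersion models accepts a
model when FAC2 >= 0.3 (boundary inclusive).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

FAIRMODE_FAC2_THRESHOLD = 0.3


@dataclass
class PairedSeries:
    """Aligned observed/modelled concentration pairs.

    Pairs where either side is missing (NaN) are dropped at
    construction; ``n`` counts the valid pairs.
    """

    observed: np.ndarray
    modelled: np.ndarray
    timestamps: pd.DatetimeIndex | None = None

    def __post_init__(self) -> None:
        obs = np.asarray(self.observed, dtype=float)
        mod = np.asarray(self.modelled, dtype=float)
        if obs.shape != mod.shape:
            raise ValueError("observed and modelled series must have equal length")
        valid = np.isfinite(obs) & np.isfinite(mod)
        self.observed = obs[valid]
        self.modelled = mod[valid]
        if self.timestamps is not None:
            self.timestamps = pd.DatetimeIndex(np.asarray(self.timestamps)[valid])

    @property
    def n(self) -> int:
        return len(self.observed)

    @classmethod
    def from_csv(cls, path) -> "PairedSeries":
        """Read CSV with columns ``timestamp, observed, modelled``."""
        table = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(
            table["observed"].to_numpy(),
            table["modelled"].to_numpy(),
            pd.DatetimeIndex(table["timestamp"]),
        )


def stats(series: PairedSeries) -> dict:
    """The full statistics vector {MB, NMB, RMSE, r, IOA, FAC2, n}."""
    if series.n < 2:
        raise ValueError(f"need at least 2 valid pairs, got {series.n}")
    obs, mod = series.observed, series.modelled
    diff = mod - obs
    mb = float(diff.mean())
    obs_sum = obs.sum()
    nmb = float(diff.sum() / obs_sum) if obs_sum != 0 else math.nan
    rmse = float(np.sqrt((diff**2).mean()))

    if np.ptp(obs) == 0 or np.ptp(mod) == 0:
        r = None
    else:
        r = float(np.corrcoef(obs, mod)[0, 1])

    obs_mean = obs.mean()
    pot = (np.abs(mod - obs_mean) + np.abs(obs - obs_mean)) ** 2
    pot_sum = pot.sum()
    ioa = float(1.0 - (diff**2).sum() / pot_sum) if pot_sum > 0 else 1.0

    nonzero = obs != 0
    n_excluded = int((~nonzero).sum())
    if n_excluded:
        logger.info("FAC2: excluded %d pairs with observed = 0", n_excluded)
    if nonzero.any():
        ratio = mod[nonzero] / obs[nonzero]
        fac2 = float(((ratio >= 0.5) & (ratio <= 2.0)).mean())
    else:
        fac2 = math.nan

    return {"MB": mb, "NMB": nmb, "RMSE": rmse, "r": r, "IOA": ioa, "FAC2": fac2, "n": series.n}


def fairmode_fac2_check(fac2: float) -> bool:
    """FAIRMODE urban-dispersion acceptance: FAC2 >= 0.3, inclusive."""
    if not (0.0 <= fac2 <= 1.0):
        raise ValueError(f"FAC2 must lie in [0, 1], got {fac2}")
    return fac2 >= FAIRMODE_FAC2_THRESHOLD


def daily_means(
    timestamps: pd.DatetimeIndex, values: np.ndarray, min_coverage: float = 0.75
) -> tuple[pd.DatetimeIndex, np.ndarray]:
    """Resample an hourly series to daily means.

    Days with fewer than ``min_coverage`` of 24 valid hours are dropped
    (the usual data-completeness rule before computing daily PM2.5
    statistics).
    """
    frame = pd.Series(np.asarray(values, dtype=float), index=pd.DatetimeIndex(timestamps))
    grouped = frame.groupby(frame.index.normalize())
    counts = grouped.apply(lambda s: s.notna().sum())
    means = grouped.mean()
    keep = counts >= min_coverage * 24
    kept = means[keep]
    return pd.DatetimeIndex(kept.index), kept.to_numpy()


def stats_table(sites: dict[str, PairedSeries]) -> pd.DataFrame:
    """Statistics for several monitoring sites as one DataFrame
    (columns: site, n, FAC2, MB, NMB, RMSE, r, IOA)."""
    rows = []
    for site, series in sites.items():
        s = stats(series)
        rows.append(
            (site, s["n"], s["FAC2"], s["MB"], s["NMB"], s["RMSE"], s["r"], s["IOA"])
        )
    return pd.DataFrame(rows, columns=["site", "n", "FAC2", "MB", "NMB", "RMSE", "r", "IOA"])
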