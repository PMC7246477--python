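"""Equivalent continuous sound levels and descriptive noise/air summaries.

The equivalent level over a period is an energy mean, not a decibel mean:

    Leq = 10 log10( (1/N) sum_i 10^(Leq,10s(t_i)/10) )

computed from A-weighted 10-s logger samples.  Stratified levels (total,
daytime 07-22, night 22-07, weekday, weekend) are computed over whole days
only — calendar days with essentially complete 10-s coverage — so that a
partially logged day cannot bias a stratum.  Intensities are ratios to the
threshold of hearing I0 = 1e-12 W/m^2; level <-> intensity-ratio conversions
are exact inverses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

#: expected 10-s samples in a complete calendar day, and the completeness
#: floor for a "whole day" (tolerates a few samples of logger jitter)
SAMPLES_PER_DAY = 8640
WHOLE_DAY_MIN_SAMPLES = 8630

DAYTIME_START_HOUR = 7   # day 07:00-22:00, night 22:00-07:00
NIGHT_START_HOUR = 22

EPA_LIMIT_DBA = 70.0

STRATA = ("tot", "daytime", "night", "weekday", "weekend")


@dataclass(frozen=True)
class EquivalentLevel:
    """Energy-averaged equivalent level for one period or stratum."""

    period: str
    leq: float
    n_samples: int
    n_whole_days: int | None = None


def intensity_ratio(leq_dba: float | np.ndarray) -> float | np.ndarray:
    """Convert a level in dBA to a dimensionless intensity ratio I/I0."""
    return 10.0 ** (np.asarray(leq_dba, dtype=float) / 10.0)


def level(ratio: float | np.ndarray) -> float | np.ndarray:
    """Convert an intensity ratio I/I0 back to a level in dBA."""
    arr = np.asarray(ratio, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("intensity ratio must be positive")
    return 10.0 * np.log10(arr)


def leq_aggregate(samples: Iterable[float]) -> float:
    """Energy-mean equivalent level of a set of 10-s levels, in dBA."""
    arr = np.asarray(list(samples) if not isinstance(samples, np.ndarray) else samples,
                     dtype=float)
    if arr.size == 0:
        raise ValueError("equivalent level is undefined for an empty sample set")
    return float(10.0 * np.log10(np.mean(10.0 ** (arr / 10.0))))


def whole_days(samples: pd.DataFrame,
               min_samples: int = WHOLE_DAY_MIN_SAMPLES) -> pd.DatetimeIndex:
    """Calendar days with (essentially) complete 10-s coverage."""
    counts = samples.groupby(samples["timestamp"].dt.normalize()).size()
    return pd.DatetimeIndex(counts.index[counts >= min_samples])


def leq_strata(samples: pd.DataFrame,
               min_samples: int = WHOLE_DAY_MIN_SAMPLES) -> dict[str, EquivalentLevel]:
    """Stratified equivalent levels over whole days.

    Strata: ``tot`` (all whole-day samples), ``daytime`` (07:00-22:00),
    ``night`` (22:00-07:00, i.e. complementary hours), ``weekday`` (Mon-Fri),
    ``weekend`` (Sat-Sun).  Stratum membership is decided by each sample's
    own timestamp; a day with any missing coverage is excluded from every
    stratum.  With zero whole days every level is NaN and n_whole_days is 0.
    """
    days = whole_days(samples, min_samples)
    n_days = len(days)
    ts = pd.to_datetime(samples["timestamp"])
    keep = ts.dt.normalize().isin(days)
    sub = samples.loc[keep]
    ts = ts[keep]
    hours = ts.dt.hour
    dows = ts.dt.dayofweek
    masks = {
        "tot": np.ones(len(sub), dtype=bool),
        "daytime": ((hours >= DAYTIME_START_HOUR) & (hours < NIGHT_START_HOUR)).to_numpy(),
        "night": ((hours < DAYTIME_START_HOUR) | (hours >= NIGHT_START_HOUR)).to_numpy(),
        "weekday": (dows < 5).to_numpy(),
        "weekend": (dows >= 5).to_numpy(),
    }
    out: dict[str, EquivalentLevel] = {}
    levels = sub["leq_dba"].to_numpy(dtype=float)
    for name, mask in masks.items():
        vals = levels[mask]
        leq = leq_aggregate(vals) if vals.size else float("nan")
        out[name] = EquivalentLevel(name, leq, int(vals.size), n_days)
    return out


def leq_15min(samples: pd.DataFrame, drop_partial_edges: bool = True,
              expected_per_window: int = 90) -> pd.DataFrame:
    """Per-15-min equivalent levels and intensity ratios.

    Edge windows with fewer than the expected 90 10-s samples are dropped by
    default (they would otherwise mix deployment boundaries into the
    regression series).
    """
    ts = pd.to_datetime(samples["timestamp"])
    win = ts.dt.floor("15min").rename("window_start")
    inten = pd.Series(10.0 ** (samples["leq_dba"].to_numpy(dtype=float) / 10.0), index=win)
    grp = inten.groupby(level=0)
    out = pd.DataFrame({"intensity_ratio": grp.mean(), "n_samples": grp.size()})
    if drop_partial_edges:
        out = out[out["n_samples"] >= expected_per_window]
    out["leq"] = 10.0 * np.log10(out["intensity_ratio"])
    return out


def exceedance(levels: Mapping[str, float], limit: float = EPA_LIMIT_DBA) -> set[str]:
    """Sites whose total equivalent level strictly exceeds the limit."""
    return {site for site, leq in levels.items() if leq > limit}


@dataclass(frozen=True)
class AirSummary:
    """Pooled concentration statistics and per-site BC-PM2.5 correlations."""

    bc_mean: float
    bc_sd: float
    pm_mean: float
    pm_sd: float
    n_periods: int
    correlations: pd.DataFrame  # index site, columns r / n / defined


def summarize_air(measurements: pd.DataFrame) -> AirSummary:
    """Pooled mean/SD of BC and PM2.5 and the per-site Pearson correlation.

    The pooled statistics run over all site-periods; the correlation needs at
    least two periods at a site and non-degenerate variance, otherwise the
    site is flagged undefined (r = NaN).
    """
    bc = measurements["bc_ugm3"].to_numpy(dtype=float)
    pm = measurements["pm25_ugm3"].to_numpy(dtype=float)
    rows = []
    for site, g in measurements.groupby("site"):
        b, p = g["bc_ugm3"].to_numpy(dtype=float), g["pm25_ugm3"].to_numpy(dtype=float)
        ok = len(g) >= 2 and np.std(b) > 0 and np.std(p) > 0
        r = float(stats.pearsonr(b, p).statistic) if ok else float("nan")
        rows.append({"site": site, "r": r, "n": len(g), "defined": ok})
    corr = pd.DataFrame(rows).set_index("site")
    return AirSummary(
        bc_mean=float(np.mean(bc)), bc_sd=float(np.std(bc, ddof=1)) if len(bc) > 1 else 0.0,
        pm_mean=float(np.mean(pm)), pm_sd=float(np.std(pm, ddof=1)) if len(pm) > 1 else 0.0,
        n_periods=len(measurements), correlations=corr,
    )


def sound_level_table(samples_by_site: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Descriptive sound-level table: one row per site.

    Columns: median and IQR of the 15-min equivalent levels, the five
    stratified whole-day levels, and the whole-day count.
    """
    rows = []
    for site, samples in samples_by_site.items():
        quarter = leq_15min(samples)["leq"]
        strata = leq_strata(samples)
        rows.append({
            "site": site,
            "leq_15min_median": float(quarter.median()) if len(quarter) else float("nan"),
            "leq_15min_q1": float(quarter.quantile(0.25)) if len(quarter) else float("nan"),
            "leq_15min_q3": float(quarter.quantile(0.75)) if len(quarter) else float("nan"),
            **{f"leq_{s}": strata[s].leq for s in STRATA},
            "n_whole_days": strata["tot"].n_whole_days,
        })
    return pd.DataFrame(rows).set_index("site")
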