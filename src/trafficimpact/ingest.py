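"""Reading and windowing of radar, sound-logger, and filter-period air data.

Radar counters log one row per detected vehicle (timestamp, speed, length).
Vehicles are classified by length: small (< 4 m), medium (4-7 m), large
(> 7 m).  Large vehicles are "trucks"; small plus medium are "cars"; total is
everything.  Counts are aggregated into fixed windows (15 min for the noise
regressions, 3 h for the interrupted time series) aligned to local midnight,
with per-window coverage accounting for logger downtime: a partially covered
window's flow *rate* is scaled by its coverage rather than extrapolating the
count, and windows below a coverage threshold are flagged excluded.

All timestamps are naive local clock time.  Daylight-saving transitions make
two clock windows per year whose true duration differs from the nominal one;
these are handled by the coverage machinery (pass the transition as a gap),
never by shifting clocks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: class boundaries in metres; small < SMALL_MAX <= medium <= TRUCK_MIN < large
SMALL_MAX = 4.0
TRUCK_MIN = 7.0

#: vehicle classes counted as "cars"
CAR_CLASSES = ("small", "medium")

RADAR_COLUMNS = ["timestamp", "speed_mph", "length_m"]
NOISE_COLUMNS = ["timestamp", "leq_dba"]
AIR_COLUMNS = ["site", "period_start", "period_end", "bc_ugm3", "pm25_ugm3"]


def classify_vehicle(length_m: float) -> str:
    """Classify a single vehicle by radar length.

    Boundary convention: exactly 4 m -> medium, exactly 7 m -> medium
    (a truck requires length strictly greater than 7 m).
    """
    if not np.isfinite(length_m) or length_m <= 0:
        raise ValueError(f"vehicle length must be positive, got {length_m!r}")
    if length_m < SMALL_MAX:
        return "small"
    if length_m <= TRUCK_MIN:
        return "medium"
    return "large"


def classify_lengths(lengths: Iterable[float]) -> pd.Categorical:
    """Vectorised :func:`classify_vehicle`; rejects non-positive lengths."""
    arr = np.asarray(list(lengths) if not isinstance(lengths, np.ndarray) else lengths, dtype=float)
    if arr.size and (np.min(arr) <= 0 or not np.all(np.isfinite(arr))):
        raise ValueError("vehicle lengths must be positive and finite")
    labels = np.where(arr < SMALL_MAX, "small", np.where(arr <= TRUCK_MIN, "medium", "large"))
    return pd.Categorical(labels, categories=["small", "medium", "large"])


@dataclass(frozen=True)
class FlowSeries:
    """Classified counts and flow rates for one aligned time window."""

    window_start: pd.Timestamp
    duration: pd.Timedelta
    trucks: int
    cars: int
    coverage: float
    excluded: bool

    @property
    def total(self) -> int:
        return self.trucks + self.cars

    def _rate(self, count: int) -> float:
        hours = self.duration.total_seconds() / 3600.0 * self.coverage
        if hours == 0:
            return float("nan")
        return count / hours

    @property
    def q_tr(self) -> float:
        """Truck flow in vehicles per hour, coverage-adjusted."""
        return self._rate(self.trucks)

    @property
    def q_car(self) -> float:
        return self._rate(self.cars)

    @property
    def q_tot(self) -> float:
        return self._rate(self.total)


def _window_coverage(starts: pd.DatetimeIndex, duration: pd.Timedelta,
                     gaps: Sequence[tuple[datetime, datetime]]) -> np.ndarray:
    cov = np.ones(len(starts))
    for g0, g1 in gaps:
        g0, g1 = pd.Timestamp(g0), pd.Timestamp(g1)
        if g1 <= g0:
            raise ValueError("gap end must follow gap start")
        overlap = (np.minimum((starts + duration).asi8, g1.value)
                   - np.maximum(starts.asi8, g0.value))
        cov -= np.clip(overlap, 0, None) / duration.value
    return np.clip(cov, 0.0, 1.0)


def compute_flows(events: pd.DataFrame, duration: str = "3h",
                  gaps: Sequence[tuple[datetime, datetime]] = (),
                  min_coverage: float = 0.8,
                  span: tuple[datetime, datetime] | None = None) -> pd.DataFrame:
    """Aggregate classified vehicle events into aligned flow windows.

    Parameters
    ----------
    events
        DataFrame with a ``timestamp`` column (sorted ascending) and either a
        ``vehicle_class`` or a ``length_m`` column.
    duration
        Window length, ``"15min"`` or ``"3h"``; windows are aligned to local
        midnight (both durations divide 24 h).
    gaps
        Known recording outages as (start, end) pairs; they reduce the
        coverage of overlapping windows.
    min_coverage
        Windows with coverage below this fraction are flagged ``excluded``.
    span
        Optional (start, end) of the recording period; defaults to the span
        of the events.  Windows with no events inside the span are emitted
        with zero counts.

    Returns
    -------
    DataFrame indexed by ``window_start`` with columns ``trucks, cars, total,
    coverage, q_tr, q_car, q_tot, excluded``.  Rates are vehicles/h, scaled
    by coverage (counts are never extrapolated).
    """
    dur = pd.Timedelta(duration)
    if dur not in (pd.Timedelta("15min"), pd.Timedelta("3h")):
        raise ValueError("duration must be '15min' or '3h'")
    ts = pd.to_datetime(events["timestamp"])
    if len(ts) and not ts.is_monotonic_increasing:
        raise ValueError("events must be sorted by timestamp")
    if "vehicle_class" in events.columns:
        vclass = events["vehicle_class"].astype(str)
    else:
        vclass = pd.Series(classify_lengths(events["length_m"].to_numpy()).astype(str),
                           index=events.index)

    if span is None:
        if len(ts) == 0:
            raise ValueError("no events and no span given")
        first = ts.iloc[0].floor(dur)
        last_win = ts.iloc[-1].floor(dur)
    else:
        # span end is exclusive: a window starting exactly at the end is out
        first = pd.Timestamp(span[0]).floor(dur)
        last_win = (pd.Timestamp(span[1]) - pd.Timedelta(1, "ns")).floor(dur)
    starts = pd.date_range(first, max(last_win, first), freq=dur, name="window_start")

    binned = ts.dt.floor(dur)
    is_truck = (vclass == "large").to_numpy()
    trucks = pd.Series(np.where(is_truck, 1, 0), index=binned).groupby(level=0).sum()
    cars = pd.Series(np.where(is_truck, 0, 1), index=binned).groupby(level=0).sum()

    out = pd.DataFrame(index=starts)
    out["trucks"] = trucks.reindex(starts, fill_value=0).astype(int)
    out["cars"] = cars.reindex(starts, fill_value=0).astype(int)
    out["total"] = out["trucks"] + out["cars"]
    out["coverage"] = _window_coverage(starts, dur, gaps)
    hours = dur.total_seconds() / 3600.0
    with np.errstate(divide="ignore", invalid="ignore"):
        eff = hours * out["coverage"].to_numpy()
        for col, q in (("trucks", "q_tr"), ("cars", "q_car"), ("total", "q_tot")):
            out[q] = np.where(eff > 0, out[col] / np.where(eff > 0, eff, 1.0), np.nan)
    out["excluded"] = out["coverage"] < min_coverage
    return out


def flows_to_records(flows: pd.DataFrame, duration: str = "3h") -> list[FlowSeries]:
    """Convert a :func:`compute_flows` frame into typed records."""
    dur = pd.Timedelta(duration)
    return [FlowSeries(idx, dur, int(r.trucks), int(r.cars), float(r.coverage), bool(r.excluded))
            for idx, r in flows.iterrows()]


def _require_columns(df: pd.DataFrame, cols: Sequence[str], path) -> None:
    for c in cols:
        if c not in df.columns:
            raise ValueError(f"{path}: missing required column {c!r}")


def _parse_timestamps(df: pd.DataFrame, col: str, path) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    bad = parsed.isna()
    if bad.any():
        logger.warning("%s: dropped %d malformed row(s)", path, int(bad.sum()))
    df = df.loc[~bad].copy()
    df[col] = parsed[~bad]
    return df


def read_radar_csv(path) -> pd.DataFrame:
    """Read a radar event log (``timestamp,speed_mph,length_m``).

    Malformed rows (unparseable timestamps, non-positive lengths) are dropped
    and logged.  Returns events sorted by timestamp with a derived
    ``vehicle_class`` column.
    """
    df = pd.read_csv(path)
    _require_columns(df, RADAR_COLUMNS, path)
    df = _parse_timestamps(df, "timestamp", path)
    df["length_m"] = pd.to_numeric(df["length_m"], errors="coerce")
    df["speed_mph"] = pd.to_numeric(df["speed_mph"], errors="coerce")
    bad = df["length_m"].isna() | (df["length_m"] <= 0)
    if bad.any():
        logger.warning("%s: rejected %d row(s) with invalid length", path, int(bad.sum()))
        df = df.loc[~bad]
    df = df.sort_values("timestamp", kind="stable").reset_index(drop=True)
    df["vehicle_class"] = classify_lengths(df["length_m"].to_numpy())
    return df


def read_noise_csv(path) -> pd.DataFrame:
    """Read a sound-logger export (``timestamp,leq_dba``, 10-s cadence)."""
    df = pd.read_csv(path)
    _require_columns(df, NOISE_COLUMNS, path)
    df = _parse_timestamps(df, "timestamp", path)
    df["leq_dba"] = pd.to_numeric(df["leq_dba"], errors="coerce")
    bad = ~np.isfinite(df["leq_dba"].to_numpy(dtype=float))
    if bad.any():
        logger.warning("%s: rejected %d row(s) with non-finite level", path, int(bad.sum()))
        df = df.loc[~bad]
    return df.sort_values("timestamp", kind="stable").reset_index(drop=True)


def read_air_csv(path) -> pd.DataFrame:
    """Read filter-period integrated air measurements.

    Columns: ``site,period_start,period_end,bc_ugm3,pm25_ugm3``.  Periods are
    site visits 12-28 days apart; lengths outside that range are kept but
    logged, negative concentrations are rejected.
    """
    df = pd.read_csv(path)
    _require_columns(df, AIR_COLUMNS, path)
    df = _parse_timestamps(df, "period_start", path)
    df = _parse_timestamps(df, "period_end", path)
    for c in ("bc_ugm3", "pm25_ugm3"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    bad = df["bc_ugm3"].isna() | df["pm25_ugm3"].isna() | (df["bc_ugm3"] < 0) | (df["pm25_ugm3"] < 0)
    if bad.any():
        logger.warning("%s: rejected %d row(s) with invalid concentrations", path, int(bad.sum()))
        df = df.loc[~bad]
    days = (df["period_end"] - df["period_start"]).dt.total_seconds() / 86400.0
    odd = (days < 12) | (days > 28)
    if odd.any():
        logger.warning("%s: %d period(s) outside the 12-28 day range", path, int(odd.sum()))
    return df.reset_index(drop=True)
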