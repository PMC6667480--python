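"""Minute-epoch actigraphy ingestion, rest scoring and non-photic input.

Reads wrist-actigraph exports (timestamp, white-light photopic lux, activity
counts/min, wear status), scores main rest intervals and naps from smoothed
activity and concurrent light, imputes off-wrist gaps that align with the
expected sleep episode, computes circular mid-sleep, and builds the
square-wave non-photic drive from main rest intervals only.

The commercial scoring thresholds used in the original field software are
proprietary; the defaults here (activity < 40 counts/min on an 11-minute
centred median, mean lux < 10) are documented, configurable stand-ins that
are validated against this package's synthetic generator, not claimed to
replicate any vendor algorithm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ModelParameters
from .timeutils import circular_mean_hours, clock_hours

log = logging.getLogger(__name__)

ACTIVITY_THRESHOLD = 40.0   # counts/min, on the smoothed series
LUX_THRESHOLD = 10.0        # mean photopic lux over a candidate interval
SMOOTH_WINDOW_MIN = 11      # centred median window, minutes
MIN_MAIN_HOURS = 3.0        # shorter intervals are naps
BOUNDARY_GAP_MIN = 60       # max gap bridged by boundary adjustment


@dataclass
class RestInterval:
    """A scored rest episode. ``kind`` is main, nap or imputed_offwrist."""

    start: pd.Timestamp
    end: pd.Timestamp
    kind: str = "main"

    def __post_init__(self) -> None:
        self.start = pd.Timestamp(self.start)
        self.end = pd.Timestamp(self.end)
        if self.end <= self.start:
            raise ValueError("rest interval must have end > start")
        if self.kind not in ("main", "nap", "imputed_offwrist"):
            raise ValueError(f"unknown rest kind {self.kind!r}")

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)

    @property
    def midpoint(self) -> pd.Timestamp:
        return self.start + (self.end - self.start) / 2

    @property
    def is_main(self) -> bool:
        return self.kind in ("main", "imputed_offwrist")


class EpochSeries:
    """Uniform one-minute series of lux, activity counts and wear flag."""

    def __init__(self, df: pd.DataFrame):
        required = {"lux", "activity", "worn"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"EpochSeries missing columns {sorted(missing)}")
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValueError("EpochSeries needs a DatetimeIndex")
        df = df.sort_index()
        deltas = df.index.to_series().diff().dropna()
        if len(deltas) and not (deltas == pd.Timedelta(minutes=1)).all():
            raise ValueError("epoch grid is not uniform at 1 minute")
        worn = df["worn"].astype(bool).to_numpy()
        for col in ("lux", "activity"):
            vals = df[col].to_numpy(dtype=float)
            bad = ~np.isfinite(vals) | (vals < 0)
            if np.any(bad & worn):
                raise ValueError(f"negative or non-finite {col} in worn epochs")
            vals = np.where(bad, 0.0, vals)
            df[col] = vals
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def index(self) -> pd.DatetimeIndex:
        return self.df.index

    @property
    def start(self) -> pd.Timestamp:
        return self.df.index[0]

    @property
    def start_clock_h(self) -> float:
        return float(clock_hours(self.start))

    @property
    def hours(self) -> np.ndarray:
        """Hours since series start for every epoch."""
        return ((self.index - self.start) / pd.Timedelta(hours=1)).to_numpy()

    @property
    def lux(self) -> np.ndarray:
        return self.df["lux"].to_numpy(dtype=float)

    @property
    def activity(self) -> np.ndarray:
        return self.df["activity"].to_numpy(dtype=float)

    @property
    def worn(self) -> np.ndarray:
        return self.df["worn"].to_numpy(dtype=bool)

    def copy(self) -> "EpochSeries":
        return EpochSeries(self.df.copy())

    def mask(self, start, end) -> np.ndarray:
        """Boolean epoch mask for [start, end)."""
        return (self.index >= pd.Timestamp(start)) & (
            self.index < pd.Timestamp(end))

    def to_csv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "timestamp", out.index.strftime("%Y-%m-%d %H:%M:%S"))
        out["worn"] = out["worn"].astype(int)
        out.to_csv(path, index=False)


_GENERIC_COLUMNS = {
    "timestamp": "timestamp", "lux": "lux",
    "activity": "activity", "worn": "worn",
}
_SPECTRUM_COLUMNS = {
    "timestamp": "timestamp", "lux": "white_light",
    "activity": "activity", "worn": "off_wrist",  # inverted below
}


def read_actigraphy(path, dialect: str = "generic",
                    column_map: dict | None = None) -> EpochSeries:
    """Read a delimited actigraphy export into an EpochSeries.

    ``dialect`` selects a column profile: ``generic``
    (timestamp, lux, activity[, worn]) or ``spectrum`` (an
    Actiwatch-Spectrum-style export with white_light and off_wrist
    columns).  ``column_map`` overrides individual column names.  Epochs at
    a regular multiple of one minute are upsampled by value repetition.
    """
    profile = dict(_SPECTRUM_COLUMNS if dialect == "spectrum"
                   else _GENERIC_COLUMNS)
    if column_map:
        profile.update(column_map)
    raw = pd.read_csv(path)
    for role in ("timestamp", "lux", "activity"):
        if profile[role] not in raw.columns:
            raise ValueError(
                f"{path}: column {profile[role]!r} ({role}) not found; "
                f"have {list(raw.columns)}")
    ts = pd.to_datetime(raw[profile["timestamp"]], errors="coerce")
    if ts.isna().any():
        bad = raw[profile["timestamp"]][ts.isna()].iloc[0]
        raise ValueError(f"{path}: unparseable timestamp {bad!r}")
    df = pd.DataFrame({
        "lux": pd.to_numeric(raw[profile["lux"]], errors="raise"),
        "activity": pd.to_numeric(raw[profile["activity"]], errors="raise"),
    })
    df.index = pd.DatetimeIndex(ts)
    if profile["worn"] in raw.columns:
        flags = raw[profile["worn"]].astype(float).to_numpy() > 0
        df["worn"] = ~flags if dialect == "spectrum" else flags
    else:
        df["worn"] = True
    df = df[~df.index.duplicated(keep="first")].sort_index()

    deltas = df.index.to_series().diff().dropna().unique()
    if len(deltas) == 1 and deltas[0] > pd.Timedelta(minutes=1):
        mult = deltas[0] / pd.Timedelta(minutes=1)
        if abs(mult - round(mult)) > 1e-9:
            raise ValueError(f"{path}: epoch spacing {deltas[0]} is not a "
                             "whole-minute multiple")
        df = df.resample("1min").ffill()
        log.info("%s: upsampled %d-min epochs to 1-min grid", path, int(mult))
    n_unworn = int((~df["worn"]).sum())
    if n_unworn:
        log.info("%s: %d off-wrist epochs", path, n_unworn)
    return EpochSeries(df)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i, j) runs of True."""
    out = []
    i = 0
    n = len(mask)
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            out.append((i, j))
            i = j
        else:
            i += 1
    return out


def score_rest_intervals(
    series: EpochSeries,
    expected_sleep_windows: list[tuple] | None = None,
    activity_threshold: float = ACTIVITY_THRESHOLD,
    lux_threshold: float = LUX_THRESHOLD,
    smooth_window: int = SMOOTH_WINDOW_MIN,
    min_main_h: float = MIN_MAIN_HOURS,
    boundary_gap_min: int = BOUNDARY_GAP_MIN,
) -> list[RestInterval]:
    """Score rest intervals from smoothed activity and concurrent light.

    Candidates are maximal runs with centred-median activity below the
    activity threshold.  Candidates separated by short gaps (< the boundary
    gap, default 60 min) whose epochs remain dim are merged — an automated
    stand-in for the manual boundary adjustment applied when the scored
    interval disagrees with the activity/light distributions by an hour or
    more.  Candidates whose mean lux exceeds the lux threshold are dropped;
    runs of at least ``min_main_h`` become main intervals, shorter runs are
    naps (excluded later from the non-photic input).
    """
    if len(series) < 24 * 60:
        raise ValueError("need at least 24 h of data to score rest")
    smooth = (
        series.df["activity"]
        .rolling(smooth_window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )
    below = smooth < activity_threshold
    runs = _runs(below)
    lux = series.lux

    merged: list[tuple[int, int]] = []
    for run in runs:
        if merged:
            gap = (run[0] - merged[-1][1])
            if gap < boundary_gap_min and np.all(
                    lux[merged[-1][1]:run[0]] < lux_threshold):
                merged[-1] = (merged[-1][0], run[1])
                continue
        merged.append(run)

    idx = series.index
    intervals: list[RestInterval] = []
    for i, j in merged:
        if np.mean(lux[i:j]) >= lux_threshold:
            continue
        dur_h = (j - i) / 60.0
        kind = "main" if dur_h >= min_main_h else "nap"
        end = idx[j] if j < len(idx) else idx[-1] + pd.Timedelta(minutes=1)
        intervals.append(RestInterval(idx[i], end, kind))
    if not intervals:
        log.warning("no rest intervals found in %s epochs", len(series))
    return intervals


def impute_offwrist_sleep(
    series: EpochSeries,
    intervals: list[RestInterval],
    expected_sleep_windows: list[tuple],
    min_overlap_frac: float = 0.5,
) -> tuple[EpochSeries, list[RestInterval]]:
    """Treat off-wrist gaps aligned with expected sleep as rest.

    An off-wrist gap overlapping an expected sleep window by at least
    ``min_overlap_frac`` of that window's duration has its lux and activity
    zeroed and becomes an ``imputed_offwrist`` main interval.  Other gaps
    keep lux carried as 0 (a conservative no-light assumption) with a
    logged warning.
    """
    out = series.copy()
    df = out.df
    new_intervals = list(intervals)
    for i, j in _runs(~series.worn):
        gap_start, gap_end = series.index[i], (
            series.index[j - 1] + pd.Timedelta(minutes=1))
        imputed = False
        for ws, we in expected_sleep_windows:
            ws, we = pd.Timestamp(ws), pd.Timestamp(we)
            overlap = (min(gap_end, we) - max(gap_start, ws)) / pd.Timedelta(
                hours=1)
            win_h = (we - ws) / pd.Timedelta(hours=1)
            if overlap >= min_overlap_frac * win_h:
                cols = df.columns.get_indexer(["lux", "activity"])
                df.iloc[i:j, cols] = 0.0
                new_intervals.append(
                    RestInterval(gap_start, gap_end, "imputed_offwrist"))
                imputed = True
                break
        if not imputed:
            df.iloc[i:j, df.columns.get_loc("lux")] = 0.0
            log.warning("off-wrist gap %s-%s not matched to expected sleep; "
                        "lux carried as 0", gap_start, gap_end)
    new_intervals.sort(key=lambda r: r.start)
    return out, new_intervals


def mid_sleep(intervals: list[RestInterval]) -> float:
    """Circular mean of main-rest midpoints, as clock hours in [0, 24)."""
    mids = [clock_hours(r.midpoint) for r in intervals if r.is_main]
    if not mids:
        raise ValueError("no main rest intervals; cannot compute mid-sleep")
    return circular_mean_hours(mids)


def build_nonphotic_input(series: EpochSeries,
                          intervals: list[RestInterval],
                          params: ModelParameters) -> np.ndarray:
    """Square-wave non-photic drive Nhat = rho (1/3 - sigma) per epoch.

    ``sigma`` is 1 inside main rest intervals (including imputed off-wrist
    sleep) and 0 elsewhere; naps are excluded by construction.
    """
    sigma = np.zeros(len(series))
    for r in intervals:
        if r.is_main:
            sigma[series.mask(r.start, r.end)] = 1.0
    return params.rho * (1.0 / 3.0 - sigma)
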