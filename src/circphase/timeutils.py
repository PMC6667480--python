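"""Clock-time arithmetic on the 24 h circle.

All phase-like quantities in this package are clock times in decimal hours.
Differences between two clock times are ambiguous modulo 24 h; every
difference exposed to users is wrapped to the half-open interval (-12, 12],
so that a marker moving later (a phase delay) yields a negative
diurnal-minus-night difference, matching the shift-work sign convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

HOURS_PER_DAY = 24.0


def wrap_phase_h(delta_h):
    """Wrap an hour difference (scalar or array) to (-12, 12]."""
    return ((np.asarray(delta_h, dtype=float) - 12.0) % -24.0) + 12.0


def wrap_clock_h(hours):
    """Reduce hours to clock time in [0, 24)."""
    return np.asarray(hours, dtype=float) % 24.0


def circular_mean_hours(hours) -> float:
    """Vector mean of clock times on the 24 h circle, in [0, 24).

    Minimises the summed squared chord distance to the data points, which is
    the natural analogue of the arithmetic mean for times that may straddle
    midnight.
    """
    h = np.asarray(hours, dtype=float)
    if h.size == 0:
        raise ValueError("circular mean of empty collection")
    ang = h * (2.0 * np.pi / HOURS_PER_DAY)
    s, c = np.sin(ang).mean(), np.cos(ang).mean()
    if np.hypot(s, c) < 1e-12:
        raise ValueError("clock times are uniformly spread; mean undefined")
    return float(np.arctan2(s, c) * (HOURS_PER_DAY / (2.0 * np.pi)) % HOURS_PER_DAY)


def clock_hours(ts) -> float | np.ndarray:
    """Decimal clock hours since that day's midnight for timestamp(s)."""
    if isinstance(ts, (pd.DatetimeIndex, pd.Series)):
        idx = pd.DatetimeIndex(ts)
        return (
            idx.hour + idx.minute / 60.0 + idx.second / 3600.0
        ).to_numpy(dtype=float)
    t = pd.Timestamp(ts)
    return t.hour + t.minute / 60.0 + t.second / 3600.0


def duration_h(start_clock_h: float, end_clock_h: float) -> float:
    """Elapsed hours from one clock time to the next occurrence of another.

    ``duration_h(23.0, 7.0)`` is 8.0: an interval crossing midnight.
    """
    return float((end_clock_h - start_clock_h) % HOURS_PER_DAY)


def hours_since(ts, origin) -> np.ndarray:
    """Hours elapsed between ``origin`` and timestamp(s) ``ts``."""
    delta = pd.DatetimeIndex(ts) - pd.Timestamp(origin)
    return (delta / pd.Timedelta(hours=1)).to_numpy(dtype=float)
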