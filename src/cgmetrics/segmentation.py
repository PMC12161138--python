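"""Day/night and calendar-day splits of a reconstructed trace.

Night is the half-open clock window [00:00, end_of_night_hour); day is
the complement.  Splits are purely timestamp-driven, so they partition
the sample set whatever the glucose values are.
"""

from __future__ import annotations

import numpy as np

from .model import RunConfig
from .preprocess import RegularTrace

_SEC = np.timedelta64(1, "s")


def clock_seconds(timestamps: np.ndarray) -> np.ndarray:
    """Seconds since local midnight for each timestamp."""
    ts = np.asarray(timestamps, dtype="datetime64[s]")
    midnight = ts.astype("datetime64[D]").astype("datetime64[s]")
    return np.asarray((ts - midnight) / _SEC, dtype=float)


def night_mask(timestamps: np.ndarray, end_of_night_hour: int) -> np.ndarray:
    """True for samples with clock time in [00:00, end_of_night_hour)."""
    return clock_seconds(timestamps) < end_of_night_hour * 3600.0


def split_day_night(trace: RegularTrace, config: RunConfig) -> tuple[np.ndarray, np.ndarray]:
    """Index arrays of the (night, day) sample subsets; a partition."""
    night = night_mask(trace.timestamps, config.end_of_night_hour)
    return np.flatnonzero(night), np.flatnonzero(~night)


def split_calendar_days(trace: RegularTrace) -> list[np.ndarray]:
    """Index arrays of samples per calendar date, chronological order."""
    dates = trace.timestamps.astype("datetime64[D]")
    unique_dates = np.unique(dates)  # np.unique sorts -> chronological
    return [np.flatnonzero(dates == d) for d in unique_dates]
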