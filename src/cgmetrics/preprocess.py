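"""Missing-period detection and signal reconstruction.

A CGM sensor nominally samples on a fixed grid (e.g. every 5 min) but
drops readings during signal loss, warm-up or compression lows.  This
module finds the missing periods by thresholding the inter-sample
interval, then either reconstructs the signal on the expected grid with
a shape-preserving piecewise cubic Hermite interpolant (PCHIP,
Fritsch-Carlson slope limiting, so filled values never overshoot the
bracketing observations) or drops the missing spans and keeps the
observed segments on per-segment grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator

from .model import GlucoseTrace, RunConfig

logger = logging.getLogger("cgmetrics")

_SEC = np.timedelta64(1, "s")


@dataclass
class GapRecord:
    """One detected missing period.

    ``start_time`` is the last observed sample before the gap and
    ``end_time`` the first observed sample after it, so the missing grid
    samples lie strictly between the two.
    """

    start_time: np.datetime64
    end_time: np.datetime64
    duration_min: float
    n_missing_expected: int


@dataclass
class RegularTrace:
    """A fixed-interval reconstructed signal.

    Under the interpolate policy the grid is anchored at the first
    observation and runs contiguously to the last; ``imputed`` marks the
    grid samples produced by interpolation rather than observation.
    Under the remove policy (or when a gap exceeds the interpolation
    cap) the signal consists of several observed segments, each snapped
    to its own regular grid; ``segment_ids`` labels them and lag-based
    metrics must not difference across segment boundaries.
    """

    timestamps: np.ndarray  # datetime64[s]
    values: np.ndarray  # mg/dL
    imputed: np.ndarray  # bool mask
    interval_min: float
    segment_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.values = np.asarray(self.values, dtype=float)
        self.imputed = np.asarray(self.imputed, dtype=bool)
        if self.segment_ids is None:
            self.segment_ids = np.zeros(len(self.values), dtype=int)
        self.segment_ids = np.asarray(self.segment_ids, dtype=int)
        n = len(self.values)
        if not (len(self.timestamps) == len(self.imputed) == len(self.segment_ids) == n):
            raise ValueError("RegularTrace arrays must have equal length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def grid_start(self) -> np.datetime64:
        return self.timestamps[0]

    @property
    def n_segments(self) -> int:
        return int(self.segment_ids.max()) + 1 if len(self) else 0

    @property
    def kept_segments(self) -> list[tuple[np.datetime64, np.datetime64]]:
        """(start, end) of each contiguous segment, chronological."""
        out = []
        for sid in range(self.n_segments):
            mask = self.segment_ids == sid
            ts = self.timestamps[mask]
            out.append((ts[0], ts[-1]))
        return out

    def segment_slices(self) -> list[np.ndarray]:
        """Index arrays of the contiguous segments, chronological."""
        return [np.flatnonzero(self.segment_ids == sid) for sid in range(self.n_segments)]


def _minutes_between(later: np.ndarray, earlier: np.ndarray) -> np.ndarray:
    return (later - earlier) / _SEC / 60.0


def detect_gaps(trace: GlucoseTrace, config: RunConfig) -> list[GapRecord]:
    """Find consecutive-sample intervals exceeding the permitted range.

    A pair of consecutive readings is a gap when their separation exceeds
    ``interval + tolerance`` (tolerance as configured, fraction-of-interval
    by default).  The expected number of absent grid samples is
    ``round(dt / interval) - 1``.
    """
    if len(trace) < 2:
        logger.warning("%s: fewer than 2 samples, gap detection skipped", trace.subject_id)
        return []
    dt = _minutes_between(trace.timestamps[1:], trace.timestamps[:-1])
    threshold = config.gap_threshold_min
    gaps: list[GapRecord] = []
    for i in np.flatnonzero(dt > threshold):
        gaps.append(
            GapRecord(
                start_time=trace.timestamps[i],
                end_time=trace.timestamps[i + 1],
                duration_min=float(dt[i]),
                n_missing_expected=max(0, int(round(dt[i] / config.sampling_interval_min)) - 1),
            )
        )
    return gaps


def _match_grid_to_observations(
    grid_sec: np.ndarray, obs_sec: np.ndarray, tol_sec: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest observation per grid point and whether it is within tolerance."""
    idx = np.searchsorted(obs_sec, grid_sec)
    idx_right = np.clip(idx, 0, obs_sec.size - 1)
    idx_left = np.clip(idx - 1, 0, obs_sec.size - 1)
    d_right = np.abs(obs_sec[idx_right] - grid_sec)
    d_left = np.abs(obs_sec[idx_left] - grid_sec)
    nearest = np.where(d_left <= d_right, idx_left, idx_right)
    dist = np.minimum(d_left, d_right)
    return nearest, dist <= tol_sec


def pchip_reconstruct(trace: GlucoseTrace, config: RunConfig) -> RegularTrace:
    """Reconstruct the signal on the expected regular grid.

    The grid is anchored at the first observed timestamp and never
    extends beyond the last (no extrapolation).  Grid points that
    coincide with an observation (within the sampling tolerance) carry
    the observed value; the remainder are filled by the
    monotonicity-preserving cubic Hermite interpolant and flagged
    ``imputed``.  When ``config.max_gap_min`` is set, grid points inside
    longer gaps are excluded, splitting the output into segments.
    """
    if len(trace) < 2:
        raise ValueError(f"{trace.subject_id}: need at least 2 observations to reconstruct")
    obs_sec = (trace.timestamps - trace.timestamps[0]) / _SEC
    obs_sec = np.asarray(obs_sec, dtype=float)
    if np.any(np.diff(obs_sec) <= 0):
        raise ValueError(f"{trace.subject_id}: timestamps must be strictly increasing")

    step = config.sampling_interval_min * 60.0
    n_grid = int(np.floor(obs_sec[-1] / step)) + 1
    grid_sec = np.arange(n_grid) * step

    tol_sec = config.tolerance_minutes * 60.0
    nearest, observed = _match_grid_to_observations(grid_sec, obs_sec, tol_sec)

    interpolant = PchipInterpolator(obs_sec, trace.values, extrapolate=False)
    values = interpolant(grid_sec)
    values[observed] = trace.values[nearest[observed]]
    imputed = ~observed

    keep = np.ones(n_grid, dtype=bool)
    segment_ids = np.zeros(n_grid, dtype=int)
    if config.max_gap_min is not None:
        for gap in detect_gaps(trace, config):
            if gap.duration_min > config.max_gap_min:
                lo = (gap.start_time - trace.timestamps[0]) / _SEC
                hi = (gap.end_time - trace.timestamps[0]) / _SEC
                inside = (grid_sec > float(lo) + tol_sec) & (grid_sec < float(hi) - tol_sec)
                keep &= ~inside
                segment_ids[grid_sec >= float(hi) - tol_sec] += 1
        if not keep.all():
            logger.info(
                "gaps longer than %.1f min left unfilled (%d grid points dropped)",
                config.max_gap_min,
                int((~keep).sum()),
            )

    timestamps = trace.timestamps[0] + (grid_sec[keep]).astype("timedelta64[s]")
    segment_ids = segment_ids[keep]
    # renumber segments consecutively from zero
    _, segment_ids = np.unique(segment_ids, return_inverse=True)
    return RegularTrace(
        timestamps=timestamps,
        values=values[keep],
        imputed=imputed[keep],
        interval_min=config.sampling_interval_min,
        segment_ids=segment_ids,
    )


def remove_missing_periods(
    trace: GlucoseTrace, gaps: Sequence[GapRecord], config: RunConfig
) -> RegularTrace:
    """Drop the missing periods; keep observed segments on regular grids.

    Each gap-free run of observations becomes one segment, snapped to a
    regular grid anchored at its own first sample (each grid point takes
    the nearest observation's value).  The imputed mask is all false.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    step = config.sampling_interval_min * 60.0
    obs_sec = np.asarray((trace.timestamps - trace.timestamps[0]) / _SEC, dtype=float)

    boundaries = sorted(
        int(np.searchsorted(trace.timestamps, gap.end_time, side="left")) for gap in gaps
    )
    starts = [0] + boundaries
    ends = boundaries + [len(trace)]

    ts_parts, val_parts, seg_parts = [], [], []
    for sid, (a, b) in enumerate(zip(starts, ends)):
        seg_obs = obs_sec[a:b]
        n_seg = int(np.floor((seg_obs[-1] - seg_obs[0]) / step)) + 1
        grid = seg_obs[0] + np.arange(n_seg) * step
        nearest, _ = _match_grid_to_observations(grid, seg_obs, np.inf)
        ts_parts.append(trace.timestamps[0] + grid.astype("timedelta64[s]"))
        val_parts.append(trace.values[a:b][nearest])
        seg_parts.append(np.full(n_seg, sid, dtype=int))

    return RegularTrace(
        timestamps=np.concatenate(ts_parts),
        values=np.concatenate(val_parts),
        imputed=np.zeros(sum(len(p) for p in val_parts), dtype=bool),
        interval_min=config.sampling_interval_min,
        segment_ids=np.concatenate(seg_parts),
    )


def reconstruct(trace: GlucoseTrace, gaps: Sequence[GapRecord], config: RunConfig) -> RegularTrace:
    """Apply the configured missing-data policy."""
    if config.missing_policy == "remove":
        return remove_missing_periods(trace, gaps, config)
    return pchip_reconstruct(trace, config)


def completeness_rate(trace: GlucoseTrace, config: RunConfig) -> float:
    """Percent of expected grid samples that were observed.

    Expected count is taken over the first-to-last observation span:
    ``floor(span / interval) + 1``.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    if len(trace) == 1:
        logger.warning("%s: single sample, completeness set to 100%%", trace.subject_id)
        return 100.0
    span_min = trace.span_minutes
    expected = int(np.floor(span_min / config.sampling_interval_min)) + 1
    return min(100.0, 100.0 * len(trace) / expected)


def monitoring_days(trace: GlucoseTrace) -> int:
    """Number of distinct calendar dates with at least one observation."""
    if len(trace) == 0:
        return 0
    return int(np.unique(trace.timestamps.astype("datetime64[D]")).size)
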