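"""Glycemic control indicators and the multiscale complexity index.

Control indicators: a fasting-glucose proxy (FGxP, the mean of the
lowest 30 consecutive nighttime minutes), the glucose management
indicator (GMI, a linear map of mean glucose to an estimated HbA1c
percentage), and hypoglycemia episode detection (<70 mg/dL sustained
for at least 15 min, closed only after 15 min of recovery).

Complexity: multiscale sample entropy.  The series is coarse-grained
into non-overlapping block means at scales 1..7 and the sample entropy
(m = 2, Chebyshev distance, tolerance r = 0.15 x SD of the scale-1
series, held fixed across scales) is summed over scales to give the
multiscale complexity index (MCI).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist

from .descriptive import NAN
from .model import RunConfig
from .preprocess import RegularTrace
from .segmentation import night_mask

logger = logging.getLogger("cgmetrics")

HYPO_THRESHOLD_MGDL = 70.0
EPISODE_MIN_DURATION_MIN = 15.0
FGXP_WINDOW_MIN = 30.0

GMI_INTERCEPT = 3.31
GMI_SLOPE = 0.02392


# ---------------------------------------------------------------------------
# Control indicators
# ---------------------------------------------------------------------------


def gmi(mean_glucose: float) -> float:
    """Glucose management indicator (%) from mean glucose in mg/dL."""
    return GMI_INTERCEPT + GMI_SLOPE * mean_glucose


@dataclass
class EpisodeRecord:
    """One hypoglycemic episode."""

    start: np.datetime64
    end: np.datetime64
    duration_min: float
    nadir: float


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) half-open index runs where mask is True."""
    out = []
    n = mask.size
    i = 0
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


def detect_hypo_episodes(trace: RegularTrace) -> tuple[list[EpisodeRecord], int]:
    """Detect hypoglycemic episodes on the regular grid.

    An episode opens at the first sample of a run of readings <70 mg/dL
    whose duration (samples x interval) reaches 15 min, and closes at
    the first sample of the next run of readings >=70 mg/dL that itself
    lasts >=15 min (shorter recoveries do not end the episode, per the
    consensus event definition).  A segment boundary or the end of the
    trace closes any open episode.
    """
    interval = trace.interval_min
    min_samples = int(np.ceil(EPISODE_MIN_DURATION_MIN / interval))
    interval_td = np.timedelta64(int(round(interval * 60)), "s")
    episodes: list[EpisodeRecord] = []

    def close(v, ts, below, open_start, end_i, end_time) -> EpisodeRecord:
        span = v[open_start:end_i]
        return EpisodeRecord(
            start=ts[open_start],
            end=end_time,
            duration_min=float((end_time - ts[open_start]) / np.timedelta64(1, "s")) / 60.0,
            nadir=float(np.min(span[span < HYPO_THRESHOLD_MGDL])),
        )

    for idx in trace.segment_slices():
        v = trace.values[idx]
        ts = trace.timestamps[idx]
        below = v < HYPO_THRESHOLD_MGDL
        runs = _runs(below)
        open_start: int | None = None
        prev_below_end = 0
        for a, b in runs:
            if open_start is not None and a - prev_below_end >= min_samples:
                # qualifying recovery run: episode ended at its first sample
                episodes.append(close(v, ts, below, open_start, prev_below_end, ts[prev_below_end]))
                open_start = None
            if open_start is None and b - a >= min_samples:
                open_start = a
            prev_below_end = b
        if open_start is not None:
            if v.size - prev_below_end >= min_samples:
                # trailing qualifying recovery closes the episode normally
                episodes.append(close(v, ts, below, open_start, prev_below_end, ts[prev_below_end]))
            else:
                # segment ends with the episode still open: close it one
                # interval after the last below-threshold sample
                end_time = ts[prev_below_end - 1] + interval_td
                episodes.append(close(v, ts, below, open_start, prev_below_end, end_time))
    return episodes, len(episodes)


def fgxp(trace: RegularTrace, config: RunConfig) -> float:
    """Fasting glucose proxy.

    Per night (the [00:00, end_of_night) window of one calendar date),
    take the minimum over all 30-consecutive-minute windows of the
    window-mean glucose; FGxP is the mean of those per-night minima.
    Windows never span a segment boundary; nights without a full window
    are skipped.  NaN when no night qualifies.
    """
    window = FGXP_WINDOW_MIN / trace.interval_min
    if abs(window - round(window)) > 1e-9:
        raise ValueError(
            f"the {FGXP_WINDOW_MIN:.0f}-min fasting window is not a multiple of the "
            f"{trace.interval_min:g}-min sampling interval"
        )
    w = int(round(window))
    night = night_mask(trace.timestamps, config.end_of_night_hour)
    dates = trace.timestamps.astype("datetime64[D]")
    idx_all = np.arange(len(trace))

    minima = []
    for d in np.unique(dates):
        sel = idx_all[(dates == d) & night]
        if sel.size < w:
            continue
        # split the night selection into grid-contiguous, same-segment runs
        brk = np.flatnonzero((np.diff(sel) != 1) | (np.diff(trace.segment_ids[sel]) != 0))
        night_min = np.inf
        for run in np.split(sel, brk + 1):
            if run.size < w:
                continue
            means = np.convolve(trace.values[run], np.ones(w) / w, mode="valid")
            night_min = min(night_min, float(np.min(means)))
        if np.isfinite(night_min):
            minima.append(night_min)
    return float(np.mean(minima)) if minima else NAN


# ---------------------------------------------------------------------------
# Multiscale complexity
# ---------------------------------------------------------------------------


@dataclass
class MciConfig:
    """Multiscale-entropy parameters (embedding length, tolerance, scales)."""

    m: int = 2
    r_factor: float = 0.15
    scales: tuple[int, ...] = field(default=tuple(range(1, 8)))


def coarse_grain(series: np.ndarray, scale: int) -> np.ndarray:
    """Means of consecutive non-overlapping blocks of length ``scale``."""
    series = np.asarray(series, dtype=float)
    if scale < 1:
        raise ValueError("scale must be a positive integer")
    if scale > series.size:
        raise ValueError(f"scale {scale} exceeds series length {series.size}")
    n_blocks = series.size // scale
    return series[: n_blocks * scale].reshape(n_blocks, scale).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int, r: float) -> float:
    """Sample entropy SampEn(m, r) with Chebyshev distance.

    ``B`` counts unordered template pairs (i < j, self-matches excluded)
    of length m within tolerance r; ``A`` the same for length m+1; both
    over the first ``n - m`` templates so the conditional probability is
    well formed.  Returns ``-ln(A/B)``; NaN when either count is zero or
    the series is too short.
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if r <= 0:
        raise ValueError("tolerance r must be positive")
    if n <= m + 1:
        return NAN
    templates_m = np.lib.stride_tricks.sliding_window_view(x, m)[: n - m]
    templates_m1 = np.lib.stride_tricks.sliding_window_view(x, m + 1)
    b = int(np.count_nonzero(pdist(templates_m, metric="chebyshev") <= r))
    a = int(np.count_nonzero(pdist(templates_m1, metric="chebyshev") <= r))
    if a == 0 or b == 0:
        return NAN
    return float(-np.log(a / b))


def mci(trace: RegularTrace, cfg: MciConfig | None = None) -> float:
    """Multiscale complexity index: summed sample entropy over scales.

    The tolerance ``r = r_factor x SD`` is computed once from the
    original (scale-1) series and held fixed across scales.  A constant
    series has zero entropy at every scale, hence MCI 0.  If any scale
    is undefined (no template matches, or too few points) the index is
    missing-coded with a warning.
    """
    cfg = cfg or MciConfig()
    x = trace.values
    if x.size <= (max(cfg.scales) * (cfg.m + 2)):
        logger.warning("series too short for multiscale entropy (n=%d)", x.size)
        return NAN
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        return 0.0
    r = cfg.r_factor * sd
    total = 0.0
    for scale in cfg.scales:
        e = sample_entropy(coarse_grain(x, scale), cfg.m, r)
        if not np.isfinite(e):
            logger.warning("sample entropy undefined at scale %d; MCI missing", scale)
            return NAN
        total += e
    return total
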