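"""Glycemic variability: CONGA, MAGE, signal mobility, distance per minute.

All four are computed on the reconstructed regular-grid signal.  When
the trace consists of several kept segments (remove policy, or capped
gaps), no metric differences values across a segment boundary.
"""

from __future__ import annotations

import logging

import numpy as np

from .descriptive import NAN
from .preprocess import RegularTrace

logger = logging.getLogger("cgmetrics")


def conga(trace: RegularTrace, lag_hours: float) -> float:
    """Continuous overall net glycemic action for a given lag.

    Sample SD of ``D_t = G(t) - G(t - lag)`` over every grid time t for
    which both samples exist within one kept segment.  NaN when fewer
    than two valid pairs exist (e.g. span shorter than the lag).
    """
    k_float = lag_hours * 60.0 / trace.interval_min
    k = int(round(k_float))
    if k < 1 or abs(k_float - k) > 1e-9:
        logger.warning("CONGA lag %.3g h is not a grid multiple; metric undefined", lag_hours)
        return NAN
    diffs = []
    for idx in trace.segment_slices():
        v = trace.values[idx]
        if v.size > k:
            diffs.append(v[k:] - v[:-k])
    if not diffs:
        return NAN
    d = np.concatenate(diffs)
    if d.size < 2:
        return NAN
    return float(np.std(d, ddof=1))


def find_turning_points(values: np.ndarray, sigma: float) -> list[int]:
    """Alternating nadir/peak indices of a series, merged at scale sigma.

    Classic turning-point scan: track the running candidate extremum and
    commit it once the signal has reversed by at least ``sigma`` from the
    candidate, so adjacent retained extrema always differ by >= sigma and
    sub-sigma wiggles are absorbed.  The trailing candidate extremum is
    appended so the final monotone run is represented; plateaus collapse
    to a single extremum (the first index of the extreme value).
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    if n < 2 or sigma <= 0:
        return []
    turning: list[int] = []
    i_min = i_max = 0
    direction = 0  # +1 rising (last committed a nadir), -1 falling, 0 unknown
    for i in range(1, n):
        v = values[i]
        if v > values[i_max]:
            i_max = i
        if v < values[i_min]:
            i_min = i
        if direction >= 0 and values[i_max] - v >= sigma:
            turning.append(i_max)
            direction = -1
            i_min = i_max + int(np.argmin(values[i_max : i + 1]))
        elif direction <= 0 and v - values[i_min] >= sigma:
            turning.append(i_min)
            direction = 1
            i_max = i_min + int(np.argmax(values[i_min : i + 1]))
    # trailing candidate: the extremum of the final unreversed run
    tail = i_min if direction < 0 else i_max
    if direction == 0:
        # never reversed by sigma: at most the global extremes qualify
        if values[i_max] - values[i_min] >= sigma:
            turning = sorted({i_min, i_max})
        return turning
    if tail != turning[-1]:
        turning.append(tail)
    return turning


def mage(trace: RegularTrace) -> float:
    """Mean amplitude of glycemic excursions.

    sigma is the sample SD of the whole reconstructed signal; excursions
    are the differences between consecutive detected extrema (within one
    segment), and MAGE averages the absolute excursions that reach sigma,
    counting both rises and falls.  NaN when no excursion qualifies.
    """
    if len(trace) < 2:
        return NAN
    sigma = float(np.std(trace.values, ddof=1))
    if sigma == 0:
        return NAN
    lambdas: list[float] = []
    for idx in trace.segment_slices():
        v = trace.values[idx]
        tp = find_turning_points(v, sigma)
        for a, b in zip(tp[:-1], tp[1:]):
            lambdas.append(abs(v[b] - v[a]))
    qualifying = [x for x in lambdas if x >= sigma]
    if not qualifying:
        return NAN
    return float(np.mean(qualifying))


def mobility(trace: RegularTrace) -> float:
    """Variance of consecutive-sample differences over variance of signal.

    Both are sample (n-1) variances; differences are taken within
    segments only.  NaN when the signal variance is zero.
    """
    if len(trace) < 3:
        return NAN
    var_signal = float(np.var(trace.values, ddof=1))
    if var_signal == 0:
        return NAN
    diffs = [np.diff(trace.values[idx]) for idx in trace.segment_slices() if idx.size > 1]
    if not diffs:
        return NAN
    d = np.concatenate(diffs)
    if d.size < 2:
        return NAN
    return float(np.var(d, ddof=1) / var_signal)


def dtpm(trace: RegularTrace) -> float:
    """Distance traveled per minute: sum |dG| over monitoring duration.

    Differences and durations are per segment; the denominator is the
    summed first-to-last span of the kept segments, in minutes.
    """
    if len(trace) < 2:
        return NAN
    total_abs = 0.0
    total_min = 0.0
    for idx in trace.segment_slices():
        if idx.size < 2:
            continue
        total_abs += float(np.sum(np.abs(np.diff(trace.values[idx]))))
        total_min += (idx.size - 1) * trace.interval_min
    if total_min == 0:
        return NAN
    return total_abs / total_min
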