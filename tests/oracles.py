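"""Independent brute-force reference implementations.

Each function here recomputes a metric by the most direct route possible
(explicit loops, direct enumeration, or an independently coded formula)
and is used to cross-check the package's vectorized implementations.
They deliberately share no code with the package.
"""

from __future__ import annotations

import math

import numpy as np


# --- preprocessing ---------------------------------------------------------


def oracle_gap_indices(timestamps_min: list[float], interval: float, threshold: float) -> list[int]:
    """Indices i where the (i, i+1) sample pair spans a gap (dt > threshold)."""
    out = []
    for i in range(len(timestamps_min) - 1):
        if timestamps_min[i + 1] - timestamps_min[i] > threshold:
            out.append(i)
    return out


def oracle_completeness(timestamps_min: list[float], interval: float) -> float:
    span = timestamps_min[-1] - timestamps_min[0]
    expected = math.floor(span / interval) + 1
    return 100.0 * len(timestamps_min) / expected


def fritsch_carlson_eval(x: np.ndarray, y: np.ndarray, xq: np.ndarray) -> np.ndarray:
    """Independently coded shape-preserving cubic Hermite interpolation.

    Derivatives follow the Fritsch-Carlson rule: zero at sign changes of
    the secant slopes, otherwise the weighted harmonic mean; one-sided
    three-point endpoint formula with monotonicity clipping.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    h = np.diff(x)
    delta = np.diff(y) / h
    n = x.size
    d = np.zeros(n)
    for i in range(1, n - 1):
        if delta[i - 1] * delta[i] <= 0:
            d[i] = 0.0
        else:
            w1 = 2 * h[i] + h[i - 1]
            w2 = h[i] + 2 * h[i - 1]
            d[i] = (w1 + w2) / (w1 / delta[i - 1] + w2 / delta[i])

    def endpoint(h0, h1, d0, d1):
        de = ((2 * h0 + h1) * d0 - h0 * d1) / (h0 + h1)
        if de * d0 <= 0:
            return 0.0
        if d0 * d1 <= 0 and abs(de) > 3 * abs(d0):
            return 3 * d0
        return de

    d[0] = endpoint(h[0], h[1], delta[0], delta[1]) if n > 2 else delta[0]
    d[-1] = endpoint(h[-1], h[-2], delta[-1], delta[-2]) if n > 2 else delta[-1]

    out = np.empty(len(xq))
    for k, xv in enumerate(np.asarray(xq, float)):
        i = int(np.clip(np.searchsorted(x, xv, side="right") - 1, 0, n - 2))
        t = (xv - x[i]) / h[i]
        h00 = 2 * t**3 - 3 * t**2 + 1
        h10 = t**3 - 2 * t**2 + t
        h01 = -2 * t**3 + 3 * t**2
        h11 = t**3 - t**2
        out[k] = h00 * y[i] + h10 * h[i] * d[i] + h01 * y[i + 1] + h11 * h[i] * d[i + 1]
    return out


# --- descriptive -----------------------------------------------------------


def oracle_descriptive(values: list[float]) -> dict[str, float]:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    srt = sorted(values)

    def pct(q):
        pos = q / 100 * (n - 1)
        lo = math.floor(pos)
        frac = pos - lo
        return srt[lo] if lo == n - 1 else srt[lo] * (1 - frac) + srt[lo + 1] * frac

    return {
        "Mean": mean,
        "Median": pct(50),
        "Std": math.sqrt(var),
        "CV": 100 * math.sqrt(var) / mean,
        "Pctile25": pct(25),
        "Pctile75": pct(75),
        "IQR": pct(75) - pct(25),
    }


def oracle_time_in_ranges(values: list[float]) -> dict[str, float]:
    n = len(values)
    c = {"TIR": 0, "TITR": 0, "TBR1": 0, "TBR2": 0, "TAR1": 0, "TAR2": 0}
    for v in values:
        if 70 <= v <= 180:
            c["TIR"] += 1
        if 70 <= v <= 140:
            c["TITR"] += 1
        if 54 <= v < 70:
            c["TBR1"] += 1
        if v < 54:
            c["TBR2"] += 1
        if 180 < v <= 250:
            c["TAR1"] += 1
        if v > 250:
            c["TAR2"] += 1
    out = {k: 100.0 * v / n for k, v in c.items()}
    out["TBR"] = out["TBR1"] + out["TBR2"]
    out["TAR"] = out["TAR1"] + out["TAR2"]
    return out


# --- risk ------------------------------------------------------------------


def oracle_bgri(values: list[float]) -> tuple[float, float]:
    lo = hi = 0.0
    for g in values:
        f = 1.509 * (math.log(g) ** 1.084 - 5.381)
        r = 10 * f * f
        if f < 0:
            lo += r
        elif f > 0:
            hi += r
    return lo / len(values), hi / len(values)


def oracle_grade(values: list[float]) -> tuple[float, float, float, float]:
    scores, hypo, eu, hyper = [], 0.0, 0.0, 0.0
    for g in values:
        gm = g / 18.016
        s = 50.0 if gm <= 1 else min(50.0, 425 * (math.log10(math.log10(gm)) + 0.16) ** 2)
        scores.append(s)
        if gm < 3.9:
            hypo += s
        elif gm <= 7.8:
            eu += s
        else:
            hyper += s
    total = sum(scores)
    med = float(np.median(scores))
    return med, 100 * hypo / total, 100 * eu / total, 100 * hyper / total


def oracle_gri(values: list[float]) -> tuple[float, float, float]:
    n = len(values)
    vlow = 100 * sum(1 for v in values if v < 54) / n
    low = 100 * sum(1 for v in values if 54 <= v < 70) / n
    high = 100 * sum(1 for v in values if 180 < v <= 250) / n
    vhigh = 100 * sum(1 for v in values if v > 250) / n
    hypo = vlow + 0.8 * low
    hyper = vhigh + 0.5 * high
    return hypo, hyper, min(100.0, 3.0 * hypo + 1.6 * hyper)


# --- variability -----------------------------------------------------------


def oracle_conga(values: list[float], segment_ids: list[int], lag_samples: int) -> float:
    diffs = [
        values[i] - values[i - lag_samples]
        for i in range(lag_samples, len(values))
        if segment_ids[i] == segment_ids[i - lag_samples]
        and all(segment_ids[j] == segment_ids[i] for j in range(i - lag_samples, i))
    ]
    if len(diffs) < 2:
        return float("nan")
    mean = sum(diffs) / len(diffs)
    return math.sqrt(sum((d - mean) ** 2 for d in diffs) / (len(diffs) - 1))


def oracle_conga_pair_count(values: list[float], segment_ids: list[int], lag_samples: int) -> int:
    return sum(
        1
        for i in range(lag_samples, len(values))
        if all(segment_ids[j] == segment_ids[i] for j in range(i - lag_samples, i + 1))
    )


def oracle_turning_points(values: list[float], sigma: float) -> list[int]:
    """Alternating-scan turning points: commit the running candidate
    extremum once the signal reverses from it by at least sigma; append
    the trailing candidate of the final run."""
    n = len(values)
    if n < 2 or sigma <= 0:
        return []
    tps: list[int] = []
    cand_min = cand_max = 0
    direction = 0
    for i in range(1, n):
        if values[i] > values[cand_max]:
            cand_max = i
        if values[i] < values[cand_min]:
            cand_min = i
        if direction >= 0 and values[cand_max] - values[i] >= sigma:
            tps.append(cand_max)
            direction = -1
            cand_min = min(range(cand_max, i + 1), key=lambda j: values[j])
        elif direction <= 0 and values[i] - values[cand_min] >= sigma:
            tps.append(cand_min)
            direction = 1
            cand_max = max(range(cand_min, i + 1), key=lambda j: values[j])
    if direction == 0:
        return []
    tail = cand_min if direction < 0 else cand_max
    if tail != tps[-1]:
        tps.append(tail)
    return tps


def oracle_mage(values: list[float], segment_ids: list[int] | None = None) -> float:
    vals = list(values)
    n = len(vals)
    mean = sum(vals) / n
    sigma = math.sqrt(sum((v - mean) ** 2 for v in vals) / (n - 1))
    if sigma == 0:
        return float("nan")
    if segment_ids is None:
        segment_ids = [0] * n
    lambdas: list[float] = []
    for sid in sorted(set(segment_ids)):
        seg = [v for v, s in zip(vals, segment_ids) if s == sid]
        tps = oracle_turning_points(seg, sigma)
        for a, b in zip(tps[:-1], tps[1:]):
            lam = abs(seg[b] - seg[a])
            if lam >= sigma:
                lambdas.append(lam)
    return sum(lambdas) / len(lambdas) if lambdas else float("nan")


def oracle_mobility(values: list[float]) -> float:
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / (n - 1)
    diffs = [values[i + 1] - values[i] for i in range(n - 1)]
    dmean = sum(diffs) / len(diffs)
    dvar = sum((d - dmean) ** 2 for d in diffs) / (len(diffs) - 1)
    return dvar / var


def oracle_dtpm(values: list[float], interval_min: float) -> float:
    total = sum(abs(values[i + 1] - values[i]) for i in range(len(values) - 1))
    return total / ((len(values) - 1) * interval_min)


# --- control / complexity --------------------------------------------------


def oracle_fgxp(values: list[float], clock_hours: list[float], dates: list[int],
                end_of_night: int, window: int) -> float:
    """Brute-force sliding-window minimum of means per night, averaged."""
    minima = []
    for d in sorted(set(dates)):
        idx = [i for i in range(len(values)) if dates[i] == d and clock_hours[i] < end_of_night]
        runs: list[list[int]] = []
        for i in idx:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        best = None
        for run in runs:
            for s in range(len(run) - window + 1):
                w = [values[j] for j in run[s : s + window]]
                mean = sum(w) / window
                if best is None or mean < best:
                    best = mean
        if best is not None:
            minima.append(best)
    return sum(minima) / len(minima) if minima else float("nan")


def oracle_episode_count(values: list[float], interval_min: float) -> int:
    """Walk the series by hand applying onset/closure run rules."""
    need = math.ceil(15.0 / interval_min)
    count = 0
    i = 0
    n = len(values)
    in_episode = False
    while i < n:
        if not in_episode:
            if values[i] < 70:
                j = i
                while j < n and values[j] < 70:
                    j += 1
                if j - i >= need:
                    in_episode = True
                    count += 1
                i = j
            else:
                i += 1
        else:
            if values[i] >= 70:
                j = i
                while j < n and values[j] >= 70:
                    j += 1
                if j - i >= need:
                    in_episode = False
                i = j
            else:
                i += 1
    return count


def oracle_sample_entropy(series: list[float], m: int, r: float) -> float:
    """O(n^2) double-loop template pair counting."""
    n = len(series)
    if n <= m + 1:
        return float("nan")
    nt = n - m  # number of templates of both lengths
    b = a = 0
    for i in range(nt):
        for j in range(i + 1, nt):
            if max(abs(series[i + k] - series[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(series[i + m] - series[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def oracle_sample_entropy_rowloop(series: np.ndarray, m: int, r: float) -> float:
    """Row-at-a-time counting (vector inner loop); independent of pdist."""
    x = np.asarray(series, float)
    n = x.size
    if n <= m + 1:
        return float("nan")
    nt = n - m
    tm = np.array([x[i : i + m] for i in range(nt)])
    tm1 = np.array([x[i : i + m + 1] for i in range(nt)])
    b = a = 0
    for i in range(nt - 1):
        db = np.max(np.abs(tm[i + 1 :] - tm[i]), axis=1)
        da = np.max(np.abs(tm1[i + 1 :] - tm1[i]), axis=1)
        b += int(np.sum(db <= r))
        a += int(np.sum(da <= r))
    if a == 0 or b == 0:
        return float("nan")
    return -math.log(a / b)


def oracle_coarse_grain(series: list[float], scale: int) -> list[float]:
    return [
        sum(series[i : i + scale]) / scale
        for i in range(0, (len(series) // scale) * scale, scale)
    ]
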