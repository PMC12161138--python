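"""Descriptive statistics, the time-in-range family, and day-to-day SDs.

Time-in-range thresholds follow the international consensus bands, and
the six bands are arranged as an exact partition of the glucose axis so
TIR + TBR + TAR is identically 100:

=======  ====================
TIR      [70, 180] mg/dL
TITR     [70, 140] mg/dL
TBR1     [54, 70)
TBR2     (-inf, 54)
TAR1     (180, 250]
TAR2     (250, inf)
=======  ====================
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NAN = float("nan")


@dataclass(frozen=True)
class RangeThresholds:
    """Clinical range boundaries, mg/dL."""

    tir_low: float = 70.0
    tir_high: float = 180.0
    titr_high: float = 140.0
    tbr2_cut: float = 54.0
    tar2_cut: float = 250.0


DEFAULT_THRESHOLDS = RangeThresholds()


def descriptive_stats(values: np.ndarray) -> dict[str, float]:
    """Mean, median, SD (n-1), CV (%), IQR and quartiles of a sample set.

    Empty input yields all-NaN; a single sample leaves Std and CV NaN.
    Percentiles use linear interpolation between order statistics.
    """
    values = np.asarray(values, dtype=float)
    n = values.size
    out = {k: NAN for k in ("Mean", "Median", "Std", "CV", "IQR", "Pctile75", "Pctile25")}
    out["sample_n"] = float(n)
    if n == 0:
        return out
    out["Mean"] = float(np.mean(values))
    out["Median"] = float(np.median(values))
    p25, p75 = np.percentile(values, [25, 75])
    out["Pctile25"], out["Pctile75"] = float(p25), float(p75)
    out["IQR"] = float(p75 - p25)
    if n >= 2:
        std = float(np.std(values, ddof=1))
        out["Std"] = std
        out["CV"] = 100.0 * std / out["Mean"]
    return out


def time_in_ranges(
    values: np.ndarray, thresholds: RangeThresholds = DEFAULT_THRESHOLDS
) -> dict[str, float]:
    """Percent of samples in each clinical band (an exact partition)."""
    values = np.asarray(values, dtype=float)
    n = values.size
    keys = ("TIR", "TITR", "TBR1", "TBR2", "TBR", "TAR1", "TAR2", "TAR")
    if n == 0:
        return {k: NAN for k in keys}
    t = thresholds
    pct = lambda mask: 100.0 * float(np.count_nonzero(mask)) / n  # noqa: E731
    tir = pct((values >= t.tir_low) & (values <= t.tir_high))
    titr = pct((values >= t.tir_low) & (values <= t.titr_high))
    tbr1 = pct((values >= t.tbr2_cut) & (values < t.tir_low))
    tbr2 = pct(values < t.tbr2_cut)
    tar1 = pct((values > t.tir_high) & (values <= t.tar2_cut))
    tar2 = pct(values > t.tar2_cut)
    return {
        "TIR": tir,
        "TITR": titr,
        "TBR1": tbr1,
        "TBR2": tbr2,
        "TBR": tbr1 + tbr2,
        "TAR1": tar1,
        "TAR2": tar2,
        "TAR": tar1 + tar2,
    }


def daily_then_average(per_day_values: list[float]) -> float:
    """Unweighted mean across qualifying days, ignoring undefined days."""
    arr = np.asarray(per_day_values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(np.mean(arr)) if arr.size else NAN


def day_to_day_sd(per_day_values: list[float]) -> float:
    """Sample SD across qualifying days; NaN for fewer than two days."""
    arr = np.asarray(per_day_values, dtype=float)
    arr = arr[np.isfinite(arr)]
    return float(np.std(arr, ddof=1)) if arr.size >= 2 else NAN
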