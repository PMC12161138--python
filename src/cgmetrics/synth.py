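"""Deterministic synthetic CGM traces for testing and demos.

The generator emulates the statistical structure of a multi-day sensor
trace from an adult with insulin-treated type 2 diabetes: a basal level,
a circadian sinusoid, exponential-decay meal excursions, and AR(1)
sensor/physiology noise, clipped to the 40-400 mg/dL sensor reporting
range.  ``degrade_trace`` then injects the artifacts real exports show:
missing periods and duplicated timestamps.  Everything is seeded and
bit-reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .model import GlucoseTrace

logger = logging.getLogger("cgmetrics")

CLIP_LOW = 40.0
CLIP_HIGH = 400.0


@dataclass
class SynthParams:
    """Parameters of the synthetic trace generator.

    Defaults approximate a 7-day, 5-min-sampled profile with a basal
    level of 140 mg/dL, a 20 mg/dL circadian swing, three daily meals
    of 60 mg/dL peak excursion decaying over ~90 min, and AR(1) noise
    with 10 mg/dL stationary SD.
    """

    days: int = 7
    interval_min: float = 5.0
    basal: float = 140.0
    circadian_amplitude: float = 20.0
    meal_times: tuple[float, ...] = (8.0, 13.0, 19.0)  # clock hours
    meal_amplitude: float = 60.0
    meal_decay_min: float = 90.0
    noise_sd: float = 10.0
    ar_coefficient: float = 0.7
    seed: int = 0
    start: np.datetime64 = field(default_factory=lambda: np.datetime64("2024-01-01T00:00:00"))
    subject_id: str = "synthetic"


def generate_trace(params: SynthParams) -> GlucoseTrace:
    """Generate a regular-grid synthetic trace; deterministic per seed."""
    step_s = int(round(params.interval_min * 60))
    n = int(round(params.days * 24 * 60 / params.interval_min))
    t_sec = np.arange(n, dtype=float) * step_s
    t_hours = t_sec / 3600.0

    g = np.full(n, params.basal, dtype=float)
    g += params.circadian_amplitude * np.sin(2.0 * np.pi * t_hours / 24.0)

    clock_h = t_hours % 24.0
    for meal_h in params.meal_times:
        # minutes since this day's meal; pulses do not wrap across midnight
        dt_min = (clock_h - meal_h) * 60.0
        active = dt_min >= 0
        g[active] += params.meal_amplitude * np.exp(-dt_min[active] / params.meal_decay_min)

    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        phi = params.ar_coefficient
        innov_sd = params.noise_sd * np.sqrt(max(0.0, 1.0 - phi**2))
        eps = rng.normal(0.0, innov_sd, size=n)
        noise = np.empty(n)
        noise[0] = rng.normal(0.0, params.noise_sd)
        for k in range(1, n):
            noise[k] = phi * noise[k - 1] + eps[k]
        g += noise

    g = np.clip(g, CLIP_LOW, CLIP_HIGH)
    timestamps = params.start.astype("datetime64[s]") + (t_sec.astype("timedelta64[s]"))
    return GlucoseTrace(timestamps=timestamps, values=g, subject_id=params.subject_id)


def degrade_trace(
    trace: GlucoseTrace,
    gap_spec: list[tuple[np.datetime64, float]] | None = None,
    duplicate_n: int = 0,
    seed: int = 0,
) -> GlucoseTrace:
    """Inject missing periods and duplicated rows into a trace.

    ``gap_spec`` is a list of (window start, duration in minutes); all
    samples strictly inside a window are removed.  Overlapping windows
    are merged with a warning.  ``duplicate_n`` rows at seeded random
    positions are duplicated in place (identical timestamp and value).
    """
    ts = trace.timestamps
    values = trace.values

    if gap_spec:
        windows = sorted(
            (np.datetime64(start, "s"), np.datetime64(start, "s") + np.timedelta64(int(round(dur * 60)), "s"))
            for start, dur in gap_spec
        )
        merged: list[tuple[np.datetime64, np.datetime64]] = []
        for lo, hi in windows:
            if merged and lo <= merged[-1][1]:
                logger.warning("overlapping gap windows merged: %s", lo)
                merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
            else:
                merged.append((lo, hi))
        keep = np.ones(len(trace), dtype=bool)
        for lo, hi in merged:
            keep &= ~((ts > lo) & (ts < hi))
        ts, values = ts[keep], values[keep]

    if duplicate_n > 0:
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.integers(0, ts.size, size=duplicate_n))
        ts = np.insert(ts, pos, ts[pos])
        values = np.insert(values, pos, values[pos])

    return replace(trace, timestamps=ts, values=values)


def write_trace_csv(trace: GlucoseTrace, path: str | Path) -> None:
    """Write the two-column CSV dialect the reader consumes."""
    import pandas as pd

    ts = pd.to_datetime(trace.timestamps).strftime("%Y-%m-%d %H:%M:%S")
    pd.DataFrame({"timestamp": ts, "glucose": trace.values}).to_csv(path, index=False)
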