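"""Core domain types and CSV input/output.

A raw continuous-glucose-monitoring (CGM) export is a two-column CSV:
a timestamp (``YYYY-MM-DD HH:MM:SS``) and a glucose reading in mg/dL or
mmol/L.  Everything downstream works in mg/dL on a :class:`GlucoseTrace`,
an irregular, time-sorted series for one subject.  The per-subject output
is a :class:`MetricsRow`, one named value per metric in the panel, with
``_day`` / ``_night`` variants for the metrics computed separately on the
diurnal and nocturnal sample subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("cgmetrics")

#: Conversion factor mmol/L -> mg/dL (molar mass of glucose, 180.16 g/mol,
#: divided by 10).  Single source of truth for the whole package.
MMOL_TO_MGDL = 18.016

#: Strict timestamp format of the input contract.
TIMESTAMP_FORMAT = "%Y-%m-%d %H:%M:%S"


class Unit(str, Enum):
    """Glucose measurement unit of the raw file."""

    MG_DL = "mg_dl"
    MMOL_L = "mmol_l"


def mmol_to_mgdl(values: np.ndarray | float) -> np.ndarray | float:
    return np.asarray(values, dtype=float) * MMOL_TO_MGDL


def mgdl_to_mmol(values: np.ndarray | float) -> np.ndarray | float:
    return np.asarray(values, dtype=float) / MMOL_TO_MGDL


@dataclass
class GlucoseTrace:
    """An irregular glucose time series for one subject, in mg/dL.

    Invariants (after :func:`remove_duplicates`): timestamps strictly
    increasing, values finite and positive, equal lengths.
    """

    timestamps: np.ndarray  # datetime64[s], time-sorted
    values: np.ndarray  # float64, mg/dL
    source_unit: Unit = Unit.MG_DL
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype="datetime64[s]")
        self.values = np.asarray(self.values, dtype=float)
        if self.timestamps.shape != self.values.shape:
            raise ValueError("timestamps and values must have equal length")
        if self.values.size and (
            not np.all(np.isfinite(self.values)) or np.any(self.values <= 0)
        ):
            raise ValueError("glucose values must be finite and > 0")

    def __len__(self) -> int:
        return self.values.size

    @property
    def span_minutes(self) -> float:
        """Monitoring span first-to-last observation, in minutes."""
        if len(self) < 2:
            return 0.0
        delta = self.timestamps[-1] - self.timestamps[0]
        return float(delta / np.timedelta64(1, "s")) / 60.0

    def sorted(self) -> "GlucoseTrace":
        """Return a time-sorted copy (stable, preserves file order on ties)."""
        order = np.argsort(self.timestamps, kind="stable")
        return replace(self, timestamps=self.timestamps[order], values=self.values[order])


@dataclass
class RunConfig:
    """Run parameters for a single analysis.

    Parameters
    ----------
    sampling_interval_min
        Expected sampling interval of the sensor, minutes (5 for the usual
        288-samples-per-day devices).
    sampling_tolerance
        Allowed deviation of the inter-sample interval before a pair of
        consecutive readings is declared a gap.  Interpreted according to
        ``tolerance_unit``: as a *fraction* of the interval (default;
        0.05 with a 5-min interval means gaps are Δt > 5.25 min) or
        literally in *minutes*.
    end_of_night_hour
        Clock hour (0-24) at which morning begins; night is the half-open
        window [00:00, end_of_night_hour).
    convert_units
        If true, input glucose is mmol/L and is converted to mg/dL on read.
    missing_policy
        ``"interpolate"`` reconstructs gaps with a shape-preserving cubic
        (default); ``"remove"`` drops the missing periods and keeps the
        observed segments.
    max_gap_min
        Optional cap on the gap length that is interpolated; longer gaps
        are left out of the grid (splitting the signal into segments) even
        under the interpolate policy.  ``None`` interpolates every gap.
    qualifying_day_completeness
        Minimum per-day completeness (%) for a calendar day to enter the
        daily-average and day-to-day computations.
    tir_aggregation
        ``"daily_average"`` (default) computes descriptive and
        time-in-range metrics per calendar day and averages across
        qualifying days; ``"pooled"`` computes them once over all samples.
    """

    sampling_interval_min: float = 5.0
    sampling_tolerance: float = 0.05
    tolerance_unit: str = "fraction"  # "fraction" | "minutes"
    end_of_night_hour: int = 6
    convert_units: bool = False
    missing_policy: str = "interpolate"  # "interpolate" | "remove"
    plot_qc: bool = False
    plot_dir: str | None = None
    compute_mci: bool = True
    rng_seed: int = 0
    timestamp_format: str = "strict"  # "strict" | "iso"
    max_gap_min: float | None = None
    qualifying_day_completeness: float = 70.0
    tir_aggregation: str = "daily_average"  # "daily_average" | "pooled"

    def __post_init__(self) -> None:
        if self.sampling_interval_min <= 0:
            raise ValueError("sampling_interval_min must be positive")
        if self.sampling_tolerance < 0:
            raise ValueError("sampling_tolerance must be non-negative")
        if not 0 <= self.end_of_night_hour <= 24:
            raise ValueError("end_of_night_hour must be in [0, 24]")
        if self.tolerance_unit not in ("fraction", "minutes"):
            raise ValueError("tolerance_unit must be 'fraction' or 'minutes'")
        if self.missing_policy not in ("interpolate", "remove"):
            raise ValueError("missing_policy must be 'interpolate' or 'remove'")
        if self.tir_aggregation not in ("daily_average", "pooled"):
            raise ValueError("tir_aggregation must be 'daily_average' or 'pooled'")

    @property
    def tolerance_minutes(self) -> float:
        """The sampling tolerance expressed in minutes."""
        if self.tolerance_unit == "fraction":
            return self.sampling_interval_min * self.sampling_tolerance
        return self.sampling_tolerance

    @property
    def gap_threshold_min(self) -> float:
        """Δt above which a consecutive pair of readings is a gap."""
        return self.sampling_interval_min + self.tolerance_minutes


# ---------------------------------------------------------------------------
# Metric panel column layout
# ---------------------------------------------------------------------------

#: Metrics reported for the whole signal only, in panel order.
WHOLE_ONLY_METRICS: tuple[str, ...] = (
    "MonitoringDays",
    "CompletenessRate",
)

#: Metrics additionally reported for the day and night sample subsets.
DAY_NIGHT_METRICS: tuple[str, ...] = (
    "sample_n",
    "Mean",
    "Median",
    "Std",
    "CV",
    "IQR",
    "Pctile75",
    "Pctile25",
    "TIR",
    "TITR",
    "TBR1",
    "TBR2",
    "TBR",
    "TAR1",
    "TAR2",
    "TAR",
)

_WHOLE_TAIL: tuple[str, ...] = (
    "Hypo_episodes_n",
    "GRI_Hypo",
    "GRI_Hyper",
    "GRI",
    "CONGA_1H",
    "CONGA_2H",
    "CONGA_6H",
    "CONGA_24H",
    "MAGE",
    "Mobility",
    "DTpM",
    "FGxP",
    "GMI",
    "LBGI",
    "HBGI",
    "MCI",
    "GRADE",
    "GRADE_hypo",
    "GRADE_eu",
    "GRADE_hyper",
    "D2d_mean",
    "D2d_TIR",
)

#: Full ordered column set of the output CSV (besides subject_id).
METRIC_COLUMNS: tuple[str, ...] = (
    WHOLE_ONLY_METRICS
    + DAY_NIGHT_METRICS
    + _WHOLE_TAIL
    + tuple(m + "_day" for m in DAY_NIGHT_METRICS)
    + tuple(m + "_night" for m in DAY_NIGHT_METRICS)
)


@dataclass
class MetricsRow:
    """The full metric vector for one subject.

    Missing metrics (undefined on the input, or skipped by configuration)
    are NaN and serialize to empty CSV cells.
    """

    subject_id: str
    metrics: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.metrics) - set(METRIC_COLUMNS)
        if unknown:
            raise ValueError(f"unknown metric names: {sorted(unknown)}")

    def __getitem__(self, name: str) -> float:
        return self.metrics.get(name, float("nan"))

    def to_series(self) -> pd.Series:
        data = {c: self.metrics.get(c, np.nan) for c in METRIC_COLUMNS}
        return pd.Series(data, name=self.subject_id)


def rows_to_frame(rows: Sequence[MetricsRow]) -> pd.DataFrame:
    """Stack metric rows into a subjects x metrics DataFrame."""
    if not rows:
        raise ValueError("no metric rows to stack")
    df = pd.DataFrame([r.to_series() for r in rows])
    df.index.name = "subject_id"
    return df


# ---------------------------------------------------------------------------
# CSV input
# ---------------------------------------------------------------------------


def _parse_timestamps(raw: pd.Series, config: RunConfig) -> pd.Series:
    if config.timestamp_format == "strict":
        return pd.to_datetime(raw, format=TIMESTAMP_FORMAT, errors="coerce")
    return pd.to_datetime(raw, format="ISO8601", errors="coerce")


def read_cgm_csv(path: str | Path, config: RunConfig) -> GlucoseTrace:
    """Read a two-column (timestamp, glucose) CSV into a mg/dL trace.

    The header row is auto-detected: if the first cell of the first row
    does not parse as a timestamp the row is treated as a header.  Rows
    with an unparseable timestamp or non-numeric glucose are dropped with
    a logged count.  When ``config.convert_units`` is set, glucose is
    converted from mmol/L to mg/dL.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If no valid data rows remain.
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(f"CGM input file not found: {path}")
    try:
        df = pd.read_csv(path, header=None, dtype=str, usecols=[0, 1], skipinitialspace=True)
    except Exception as exc:  # malformed beyond recovery
        raise ValueError(f"unreadable CGM file {path}: {exc}") from exc
    if df.empty:
        raise ValueError(f"no data rows in CGM file {path}")

    first_cell = df.iloc[0, 0]
    if pd.isna(_parse_timestamps(pd.Series([first_cell]), config).iloc[0]):
        df = df.iloc[1:]

    ts = _parse_timestamps(df.iloc[:, 0], config)
    glucose = pd.to_numeric(df.iloc[:, 1], errors="coerce")
    valid = ts.notna() & glucose.notna() & (glucose > 0) & np.isfinite(glucose)
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning("%s: dropped %d unparseable row(s)", path.name, n_dropped)
    ts, glucose = ts[valid], glucose[valid]
    if ts.empty:
        raise ValueError(f"no valid (timestamp, glucose) rows in {path}")

    values = glucose.to_numpy(dtype=float)
    unit = Unit.MG_DL
    if config.convert_units:
        values = mmol_to_mgdl(values)
        unit = Unit.MMOL_L

    trace = GlucoseTrace(
        timestamps=ts.to_numpy().astype("datetime64[s]"),
        values=values,
        source_unit=unit,
        subject_id=path.stem,
    )
    return trace.sorted()


def remove_duplicates(trace: GlucoseTrace) -> GlucoseTrace:
    """Keep at most one sample per timestamp (first occurrence wins).

    Duplicate timestamps arise from export glitches and device syncing.
    When duplicates disagree in value the first occurrence in file order
    is retained and a warning is logged.  Idempotent.
    """
    if len(trace) == 0:
        return trace
    ts = trace.timestamps
    keep = np.ones(len(trace), dtype=bool)
    keep[1:] = ts[1:] != ts[:-1]
    n_removed = int((~keep).sum())
    if n_removed:
        dropped = ~keep
        conflicting = int(np.sum(trace.values[dropped] != trace.values[np.flatnonzero(dropped) - 1]))
        if conflicting:
            logger.warning(
                "%s: %d duplicate timestamp(s) removed, %d with conflicting values "
                "(first occurrence kept)",
                trace.subject_id,
                n_removed,
                conflicting,
            )
        else:
            logger.info("%s: %d duplicate timestamp(s) removed", trace.subject_id, n_removed)
    return replace(trace, timestamps=ts[keep], values=trace.values[keep])


# ---------------------------------------------------------------------------
# CSV output
# ---------------------------------------------------------------------------


def write_metrics_csv(rows: Sequence[MetricsRow], path: str | Path) -> None:
    """Write one CSV row per subject, header of metric names, NaN as empty.

    Floats are written at full repr precision so a read-back round trip
    reproduces the numeric payload.
    """
    if not rows:
        raise ValueError("refusing to write an empty metrics CSV")
    df = rows_to_frame(rows)
    path = Path(path)
    try:
        df.to_csv(path, float_format="%.12g", na_rep="")
    except OSError as exc:
        raise OSError(f"cannot write metrics CSV to {path}: {exc}") from exc


def read_metrics_csv(path: str | Path) -> pd.DataFrame:
    """Read a metrics CSV written by :func:`write_metrics_csv`."""
    df = pd.read_csv(path, index_col="subject_id")
    return df
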