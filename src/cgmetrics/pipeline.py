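"""End-to-end metric derivation and the cross-metric R-squared analysis.

``run_single`` takes one raw CSV through the full pipeline — read,
deduplicate, detect gaps, reconstruct (or remove missing periods),
segment, derive every metric — and returns one :class:`MetricsRow`.
``run_batch`` maps it over a directory and writes the wide metrics CSV.
``r_squared_matrix`` computes the pairwise coefficients of determination
between metrics across subjects, the basis for judging which metrics
carry independent information.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import control, descriptive, risk, variability
from .model import (
    DAY_NIGHT_METRICS,
    GlucoseTrace,
    MetricsRow,
    RunConfig,
    read_cgm_csv,
    remove_duplicates,
    rows_to_frame,
    write_metrics_csv,
)
from .preprocess import (
    RegularTrace,
    completeness_rate,
    detect_gaps,
    monitoring_days,
    reconstruct,
)
from .segmentation import night_mask, split_calendar_days

logger = logging.getLogger("cgmetrics")

NAN = float("nan")

#: Metrics of the whole-signal category used by default in the
#: cross-metric R-squared analysis (day/night variants excluded).
WHOLE_SIGNAL_METRICS: tuple[str, ...] = (
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


def _subset_stats(values: np.ndarray, suffix: str, metrics: dict[str, float]) -> None:
    stats = descriptive.descriptive_stats(values)
    ranges = descriptive.time_in_ranges(values)
    for k, v in {**stats, **ranges}.items():
        if k != "sample_n":
            metrics[k + suffix] = v


def _daily_averaged_stats(
    rt: RegularTrace, config: RunConfig, qualifying: list[np.ndarray]
) -> dict[str, float]:
    """Per-day descriptive + range stats averaged across qualifying days."""
    night = night_mask(rt.timestamps, config.end_of_night_hour)
    per_day: dict[str, list[float]] = {}
    for idx in qualifying:
        subsets = {
            "": idx,
            "_night": idx[night[idx]],
            "_day": idx[~night[idx]],
        }
        for suffix, sel in subsets.items():
            v = rt.values[sel]
            stats = descriptive.descriptive_stats(v)
            ranges = descriptive.time_in_ranges(v)
            for k, val in {**stats, **ranges}.items():
                if k == "sample_n":
                    continue
                per_day.setdefault(k + suffix, []).append(val)
    return {k: descriptive.daily_then_average(v) for k, v in per_day.items()}


def compute_metrics(
    rt: RegularTrace,
    observed: GlucoseTrace,
    config: RunConfig,
) -> MetricsRow:
    """Derive the full metric panel from a reconstructed trace.

    ``observed`` is the deduplicated raw trace (pre-reconstruction) used
    for monitoring-span bookkeeping and observed sample counts.
    """
    m: dict[str, float] = {}
    m["MonitoringDays"] = float(monitoring_days(observed))
    m["CompletenessRate"] = completeness_rate(observed, config)

    night = night_mask(rt.timestamps, config.end_of_night_hour)
    not_imputed = ~rt.imputed
    m["sample_n"] = float(np.count_nonzero(not_imputed))
    m["sample_n_night"] = float(np.count_nonzero(not_imputed & night))
    m["sample_n_day"] = float(np.count_nonzero(not_imputed & ~night))

    # descriptive + time-in-range: per calendar day, averaged across
    # qualifying days (default), or pooled over all samples
    days = split_calendar_days(rt)
    expected_per_day = 24 * 60 / config.sampling_interval_min
    day_completeness = [
        100.0 * float(np.count_nonzero(not_imputed[idx])) / expected_per_day for idx in days
    ]
    qualifying = [
        idx
        for idx, comp in zip(days, day_completeness)
        if comp >= config.qualifying_day_completeness
    ]
    if config.tir_aggregation == "daily_average" and qualifying:
        m.update(_daily_averaged_stats(rt, config, qualifying))
    else:
        if config.tir_aggregation == "daily_average":
            logger.warning("no qualifying day; falling back to pooled statistics")
        _subset_stats(rt.values, "", m)
        _subset_stats(rt.values[night], "_night", m)
        _subset_stats(rt.values[~night], "_day", m)

    # day-to-day SDs across qualifying days
    per_day_mean = [float(np.mean(rt.values[idx])) for idx in qualifying]
    per_day_tir = [descriptive.time_in_ranges(rt.values[idx])["TIR"] for idx in qualifying]
    m["D2d_mean"] = descriptive.day_to_day_sd(per_day_mean)
    m["D2d_TIR"] = descriptive.day_to_day_sd(per_day_tir)

    # risk indices on the whole reconstructed signal
    m["GRI_Hypo"], m["GRI_Hyper"], m["GRI"] = risk.gri(rt.values)
    m["LBGI"], m["HBGI"] = risk.bgri(rt.values)
    m["GRADE"], m["GRADE_hypo"], m["GRADE_eu"], m["GRADE_hyper"] = risk.grade(rt.values)

    # variability
    for hours in (1, 2, 6, 24):
        m[f"CONGA_{hours}H"] = variability.conga(rt, hours)
    m["MAGE"] = variability.mage(rt)
    m["Mobility"] = variability.mobility(rt)
    m["DTpM"] = variability.dtpm(rt)

    # control indicators
    _, m["Hypo_episodes_n"] = control.detect_hypo_episodes(rt)
    m["Hypo_episodes_n"] = float(m["Hypo_episodes_n"])
    m["FGxP"] = control.fgxp(rt, config)
    m["GMI"] = control.gmi(float(np.mean(rt.values)))

    # complexity (optional: dominates runtime)
    m["MCI"] = control.mci(rt) if config.compute_mci else NAN

    return MetricsRow(subject_id=observed.subject_id, metrics=m)


def run_single(path: str | Path, config: RunConfig) -> MetricsRow:
    """Full pipeline for one raw two-column CSV file."""
    path = Path(path)
    trace = read_cgm_csv(path, config)
    trace = remove_duplicates(trace)
    gaps = detect_gaps(trace, config)
    logger.info(
        "%s: %d samples, %d gap(s), completeness %.1f%%",
        path.name,
        len(trace),
        len(gaps),
        completeness_rate(trace, config),
    )
    rt = reconstruct(trace, gaps, config)
    if config.plot_qc:
        from . import plots

        out_dir = Path(config.plot_dir or path.parent)
        plots.qc_plot(trace, rt, gaps, out_dir / f"{path.stem}_qc.png")
        plots.turning_points_plot(rt, out_dir / f"{path.stem}_mage.png")
    return compute_metrics(rt, trace, config)


def run_batch(
    directory: str | Path, config: RunConfig, out_csv: str | Path | None = None
) -> list[MetricsRow]:
    """Process every ``*.csv`` in a directory; skip and log failures."""
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no CSV files in {directory}")
    rows: list[MetricsRow] = []
    for f in files:
        try:
            rows.append(run_single(f, config))
        except Exception as exc:
            logger.error("skipping %s: %s", f.name, exc)
    if not rows:
        raise ValueError(f"no file in {directory} could be processed")
    if out_csv is not None:
        write_metrics_csv(rows, out_csv)
    return rows


# ---------------------------------------------------------------------------
# Cross-metric R-squared analysis
# ---------------------------------------------------------------------------

#: Tier edges used for the heatmap binning of R-squared values.
RSQ_TIERS: tuple[float, ...] = (0.0, 0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class RSquaredMatrix:
    """Pairwise coefficients of determination between metrics.

    ``values[i, j]`` is the squared Pearson correlation of metrics i and
    j across subjects (pairwise-complete); ``cumulative`` is each
    metric's sum of off-diagonal entries, the basis for ranking metrics
    by how much independent information they carry (lower = more
    independent).
    """

    metric_names: list[str]
    values: np.ndarray
    cumulative: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.metric_names, columns=self.metric_names)

    def tiers(self) -> pd.DataFrame:
        """Tier index (0..4) per cell for the five-level heatmap."""
        binned = np.digitize(self.values, RSQ_TIERS[1:-1], right=False)
        return pd.DataFrame(binned, index=self.metric_names, columns=self.metric_names)

    def ranking(self) -> pd.Series:
        """Metrics sorted by ascending cumulative off-diagonal R-squared."""
        return self.cumulative.sort_values()

    def top_partners(self, metric: str, k: int = 5) -> pd.Series:
        """The k metrics with the highest R-squared against ``metric``."""
        col = self.to_frame()[metric].drop(index=metric)
        return col.sort_values(ascending=False).head(k)


def r_squared_matrix(
    rows: Sequence[MetricsRow] | pd.DataFrame,
    metric_subset: Sequence[str] | None = None,
) -> RSquaredMatrix:
    """Squared pairwise Pearson correlations of metrics across subjects.

    Requires at least three subjects.  Metrics that are entirely missing
    or have zero variance across subjects are excluded with a warning;
    missing values are handled pairwise-complete.
    """
    df = rows if isinstance(rows, pd.DataFrame) else rows_to_frame(rows)
    if len(df) < 3:
        raise ValueError("R-squared analysis requires at least 3 subjects")
    subset = list(metric_subset) if metric_subset is not None else list(WHOLE_SIGNAL_METRICS)
    subset = [mname for mname in subset if mname in df.columns]
    data = df[subset].astype(float)

    usable = []
    for mname in subset:
        col = data[mname].dropna()
        if col.size < 3 or np.isclose(col.var(ddof=1), 0.0):
            logger.warning("metric %s excluded from R-squared (missing or zero variance)", mname)
        else:
            usable.append(mname)
    data = data[usable]

    corr = data.corr(method="pearson", min_periods=3)
    rsq = (corr**2).to_numpy()
    np.fill_diagonal(rsq, 1.0)
    cumulative = pd.Series(np.nansum(rsq, axis=1) - 1.0, index=usable, name="cumulative_r2")
    return RSquaredMatrix(metric_names=usable, values=rsq, cumulative=cumulative)
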