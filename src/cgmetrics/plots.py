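"""Quality-control and analysis plots.

Functional plots only: raw-vs-reconstructed signal with shaded missing
periods, detected turning points for the excursion metric, nightly
fasting-proxy windows, and the tiered R-squared heatmap.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.colors import BoundaryNorm, ListedColormap

from .model import GlucoseTrace, RunConfig
from .preprocess import GapRecord, RegularTrace
from .pipeline import RSQ_TIERS, RSquaredMatrix
from .segmentation import night_mask
from .variability import find_turning_points

_TIER_COLORS = ["#08306b", "#4292c6", "#9ecae1", "#fb6a4a", "#99000d"]


def qc_plot(
    trace: GlucoseTrace,
    rt: RegularTrace,
    gaps: Sequence[GapRecord],
    path: str | Path,
) -> None:
    """Raw points, reconstructed curve, and shaded missing periods."""
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.plot(rt.timestamps.astype("datetime64[ms]"), rt.values, "-", lw=0.8, label="reconstructed")
    ax.plot(
        trace.timestamps.astype("datetime64[ms]"), trace.values, ".", ms=2, alpha=0.6, label="raw"
    )
    for gap in gaps:
        ax.axvspan(
            gap.start_time.astype("datetime64[ms]"),
            gap.end_time.astype("datetime64[ms]"),
            color="0.85",
            zorder=0,
        )
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_title(f"{trace.subject_id}: signal reconstruction QC")
    ax.legend(loc="upper right", fontsize=8)
    fig.autofmt_xdate()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def turning_points_plot(rt: RegularTrace, path: str | Path) -> None:
    """Signal with the detected nadirs/peaks used for excursion analysis."""
    sigma = float(np.std(rt.values, ddof=1))
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.plot(rt.timestamps.astype("datetime64[ms]"), rt.values, "-", lw=0.8)
    if sigma > 0:
        for idx in rt.segment_slices():
            tp = find_turning_points(rt.values[idx], sigma)
            sel = idx[np.asarray(tp, dtype=int)] if tp else np.array([], dtype=int)
            ax.plot(rt.timestamps[sel].astype("datetime64[ms]"), rt.values[sel], "ro", ms=4)
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_title("Detected nadirs and peaks")
    fig.autofmt_xdate()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def fgxp_plot(rt: RegularTrace, config: RunConfig, path: str | Path) -> None:
    """Highlight the nighttime windows entering the fasting proxy."""
    night = night_mask(rt.timestamps, config.end_of_night_hour)
    fig, ax = plt.subplots(figsize=(12, 4))
    ax.plot(rt.timestamps.astype("datetime64[ms]"), rt.values, "-", lw=0.8, color="0.5")
    ax.plot(
        rt.timestamps[night].astype("datetime64[ms]"),
        rt.values[night],
        ".",
        ms=3,
        color="tab:blue",
        label="nighttime samples",
    )
    ax.set_ylabel("glucose (mg/dL)")
    ax.set_title("Nighttime windows for the fasting glucose proxy")
    ax.legend(loc="upper right", fontsize=8)
    fig.autofmt_xdate()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


def rsq_heatmap(rsq: RSquaredMatrix, path: str | Path) -> None:
    """Five-tier heatmap of the R-squared matrix, ranked rows.

    Rows/columns are ordered by ascending cumulative R-squared (most
    independent metrics first), and cells are binned into the five tiers
    0-0.2, 0.2-0.4, 0.4-0.6, 0.6-0.8, >=0.8.
    """
    order = rsq.ranking().index.tolist()
    frame = rsq.to_frame().loc[order, order]
    cmap = ListedColormap(_TIER_COLORS)
    norm = BoundaryNorm(RSQ_TIERS, cmap.N)
    n = len(order)
    fig, ax = plt.subplots(figsize=(0.35 * n + 2, 0.35 * n + 2))
    im = ax.imshow(frame.to_numpy(), cmap=cmap, norm=norm)
    ax.set_xticks(range(n), order, rotation=90, fontsize=7)
    ax.set_yticks(range(n), order, fontsize=7)
    fig.colorbar(im, ax=ax, ticks=RSQ_TIERS, shrink=0.7, label="$R^2$ tier")
    ax.set_title("Cross-metric $R^2$ (ranked by cumulative $R^2$)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
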