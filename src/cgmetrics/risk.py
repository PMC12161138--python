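"""Glycemic risk indices: GRI, LBGI/HBGI, GRADE.

All three families map the glucose distribution to scalar risk scores.
GRI weights the time spent in the hypo- and hyperglycemic bands; the
blood-glucose risk indices (LBGI/HBGI) average a log-symmetrized
quadratic risk over samples; GRADE scores each reading on the mmol/L
scale via a double-log transform centred on the euglycemic zone and
summarizes with the median, plus a hypo/eu/hyper decomposition of the
total score mass.
"""

from __future__ import annotations

import logging

import numpy as np

from .descriptive import NAN, time_in_ranges
from .model import MMOL_TO_MGDL

logger = logging.getLogger("cgmetrics")

# LBGI/HBGI symmetrization constants for glucose in mg/dL.
_BG_A = 1.509
_BG_B = 1.084
_BG_C = 5.381

# GRADE: euglycemic band (mmol/L) and per-sample score cap.
_GRADE_EU_LOW = 3.9
_GRADE_EU_HIGH = 7.8
_GRADE_CAP = 50.0


def gri(values: np.ndarray) -> tuple[float, float, float]:
    """Glycemia risk index and its hypo-/hyperglycemia components.

    ``GRI_Hypo = %(<54) + 0.8 * %(54-70)``,
    ``GRI_Hyper = %(>250) + 0.5 * %(180-250]``,
    ``GRI = min(100, 3.0 * GRI_Hypo + 1.6 * GRI_Hyper)``.
    Band percentages reuse the time-in-range partition.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return NAN, NAN, NAN
    bands = time_in_ranges(values)
    hypo = bands["TBR2"] + 0.8 * bands["TBR1"]
    hyper = bands["TAR2"] + 0.5 * bands["TAR1"]
    total = min(100.0, 3.0 * hypo + 1.6 * hyper)
    return hypo, hyper, total


def _bg_risk(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    f = _BG_A * (np.log(values) ** _BG_B - _BG_C)
    return f, 10.0 * f**2


def bgri(values: np.ndarray) -> tuple[float, float]:
    """Low and high blood-glucose indices (Kovatchev risk transform).

    ``f(g) = 1.509 * ((ln g)^1.084 - 5.381)`` for g in mg/dL;
    per-sample risk ``r = 10 f^2``.  LBGI averages r over the whole
    series counting only samples with f < 0 (zero otherwise); HBGI is
    the mirror image for f > 0.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return NAN, NAN
    if np.any(values <= 0):
        raise ValueError("glucose must be positive for the risk transform")
    f, r = _bg_risk(values)
    n = values.size
    lbgi = float(np.sum(r[f < 0]) / n)
    hbgi = float(np.sum(r[f > 0]) / n)
    return lbgi, hbgi


def grade(values: np.ndarray) -> tuple[float, float, float, float]:
    """GRADE score and its hypo/eu/hyper percentage decomposition.

    Per-sample score on the mmol/L scale:
    ``s = min(50, 425 * (log10(log10(g)) + 0.16)^2)``.
    GRADE is the median score; the decomposition splits the summed score
    mass at 3.9 and 7.8 mmol/L.  Readings at or below 1 mmol/L (where
    the double log is undefined) take the 50-point cap with a warning —
    such values sit below CGM reporting floors anyway.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return NAN, NAN, NAN, NAN
    g_mmol = values / MMOL_TO_MGDL
    s = np.full(g_mmol.shape, _GRADE_CAP)
    ok = g_mmol > 1.0
    if not ok.all():
        logger.warning(
            "%d glucose reading(s) <= 1 mmol/L: GRADE score capped at %.0f",
            int((~ok).sum()),
            _GRADE_CAP,
        )
    s[ok] = np.minimum(_GRADE_CAP, 425.0 * (np.log10(np.log10(g_mmol[ok])) + 0.16) ** 2)

    total = float(np.sum(s))
    if total > 0:
        hypo = 100.0 * float(np.sum(s[g_mmol < _GRADE_EU_LOW])) / total
        eu = 100.0 * float(np.sum(s[(g_mmol >= _GRADE_EU_LOW) & (g_mmol <= _GRADE_EU_HIGH)])) / total
        hyper = 100.0 * float(np.sum(s[g_mmol > _GRADE_EU_HIGH])) / total
    else:
        hypo = eu = hyper = NAN
    return float(np.median(s)), hypo, eu, hyper
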