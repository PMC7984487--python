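"""Prediction-success tally: empirical band coverage along the dose axis.

A clinical DVH is tallied as correctly predicted at a dose point if it lies
within the prediction error band there, or if it differs from the prediction
by less than a clinical granularity tolerance (default 0.5% of OAR volume).
The per-dose success fraction across the validation cohort is the coverage
curve; a centred boxcar moving average (default 11 points) smooths it for
presentation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .bands import BandIntegrityError, PredictionBand
from .dvh import DoseGrid, DVHCohort

__all__ = ["CoverageCurve", "point_within_band", "coverage_curve",
           "boxcar_smooth", "coverage_summary", "DEFAULT_TOLERANCE",
           "DEFAULT_WINDOW"]

#: Clinical dose-volume granularity (% OAR volume); strict "< tolerance".
DEFAULT_TOLERANCE = 0.5
#: Boxcar window (points) used for presentation smoothing.
DEFAULT_WINDOW = 11


@dataclass
class CoverageCurve:
    """Per-dose-point prediction success fraction, raw and smoothed."""

    grid: DoseGrid
    raw: np.ndarray
    smoothed: np.ndarray
    window: int
    tolerance: float
    n: int
    band_kind: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_pct": self.grid.doses,
            "raw": self.raw,
            "smoothed": self.smoothed,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def point_within_band(clinical, predicted, lower, upper,
                      tolerance: float = DEFAULT_TOLERANCE):
    """Success flag(s) for the tally rule at one or many dose points.

    Success iff ``lower <= clinical <= upper`` OR
    ``|clinical - predicted| < tolerance`` — the tolerance is a strict bound
    measured to the *prediction*, not to the nearer band edge.  Accepts
    scalars or broadcastable arrays.
    """
    clinical = np.asarray(clinical, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    lower = np.asarray(lower, dtype=float)
    upper = np.asarray(upper, dtype=float)
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    if np.any(lower > upper + 1e-9):
        raise BandIntegrityError("lower bound exceeds upper bound")
    inside = (lower <= clinical) & (clinical <= upper)
    close = np.abs(clinical - predicted) < tolerance
    out = inside | close
    return bool(out) if out.ndim == 0 else out


def coverage_curve(cohort: DVHCohort, band: PredictionBand,
                   tolerance: float = DEFAULT_TOLERANCE,
                   window: int = DEFAULT_WINDOW) -> CoverageCurve:
    """Fraction of plans tallied as correctly predicted at every grid dose.

    A cohort-scope band applies its single pair of bounds to every plan; a
    per-plan band must provide one pair per plan.  Each dose point is tallied
    independently — this is a dosewise success rate, not a whole-curve one.
    """
    if len(band.grid) != len(cohort.grid):
        raise ValueError("band and cohort grids differ")
    lower, upper = band.lower, band.upper
    if band.scope == "per_plan":
        if lower.shape[0] != cohort.n:
            raise ValueError(
                f"per-plan band has {lower.shape[0]} rows for {cohort.n} plans"
            )
    success = point_within_band(
        cohort.clinical_matrix, cohort.predicted_matrix, lower, upper,
        tolerance=tolerance,
    )
    raw = success.mean(axis=0)
    return CoverageCurve(
        grid=cohort.grid, raw=raw, smoothed=boxcar_smooth(raw, window),
        window=window, tolerance=tolerance, n=cohort.n, band_kind=band.kind,
    )


def boxcar_smooth(series: np.ndarray, window: int = DEFAULT_WINDOW) -> np.ndarray:
    """Centred unweighted moving average with symmetric shrink at the edges.

    Near the boundaries the window shrinks symmetrically to what fits, so no
    values are padded or invented; ``window=1`` is the identity.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be an odd positive integer, got {window}")
    n = series.size
    if window > n:
        raise ValueError(f"window {window} exceeds series length {n}")
    if window == 1:
        return series.copy()
    half = window // 2
    csum = np.concatenate([[0.0], np.cumsum(series)])
    out = np.empty(n)
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = (csum[i + h + 1] - csum[i - h]) / (2 * h + 1)
    return out


def coverage_summary(curve: CoverageCurve,
                     dose_range: tuple[float, float] | None = None,
                     which: str = "smoothed") -> dict[str, float]:
    """Min/max/mean of a coverage curve over a dose range, in percent.

    ``which`` selects the smoothed (default) or raw series; both are kept
    because the dose-range success figures can be read off either.
    """
    if which not in ("smoothed", "raw"):
        raise ValueError("which must be 'smoothed' or 'raw'")
    values = getattr(curve, which)
    if dose_range is None:
        sel = values
    else:
        sel = values[curve.grid.index_range(*dose_range)]
    return {
        "min": float(sel.min() * 100.0),
        "max": float(sel.max() * 100.0),
        "mean": float(sel.mean() * 100.0),
    }
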