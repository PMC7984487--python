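"""Prediction error-band formalisms.

Four ways of drawing lower/upper bound DVHs around a knowledge-based
prediction, differing in what fraction of clinical DVHs they are expected to
capture when dosewise errors are approximately Gaussian:

``rmse``
    The empirical band ``V_pred +/- RMSE_pred``.  With negligible bias, RMSE
    behaves as a standard deviation, so the band should capture ~68% of
    normally distributed clinical DVHs.
``iqr``
    The 25th-75th percentile band of the clinical-DVH distribution at each
    dose point; covers ~50% of any continuous distribution.
``median_split``
    Bounds built from the two halves of the cohort split at the median of a
    matching feature, each half contributing its mean DVH.  When the feature
    tracks the dosewise value itself, the half-means sit at ±sqrt(2/pi)·sigma
    for Gaussian data, giving expected coverage 2*Phi(sqrt(2/pi))-1 ≈ 57.5% —
    strictly between the IQR and ±sigma bands.
``model_provided``
    A band supplied by the prediction model itself, ingested and
    integrity-checked rather than constructed.

Band bounds are clipped to the physical volume range [0, 100] but never
re-monotonized: the coverage tally is pointwise, and re-monotonizing would
silently change it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dvh import DoseGrid, DVHCurve, DVHCohort

__all__ = ["PredictionBand", "BandIntegrityError", "rmse_band", "iqr_band",
           "median_split_band", "load_model_band", "model_band_from_cohort"]


class BandIntegrityError(ValueError):
    """Lower and upper band bounds cross, or a band cannot be formed."""


@dataclass
class PredictionBand:
    """Lower/upper bound DVHs around a prediction.

    ``scope`` is ``"per_plan"`` (bounds shaped ``(n_plans, n_doses)``,
    centred on each plan's own prediction) or ``"cohort"`` (one pair of
    bound curves shaped ``(n_doses,)`` shared by every plan).
    """

    kind: str  # rmse | iqr | median_split | model_provided
    grid: DoseGrid
    lower: np.ndarray
    upper: np.ndarray
    scope: str = "cohort"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lower = np.asarray(self.lower, dtype=float)
        self.upper = np.asarray(self.upper, dtype=float)
        if self.lower.shape != self.upper.shape:
            raise BandIntegrityError("lower/upper shapes differ")
        if np.any(self.lower > self.upper + 1e-9):
            bad = np.argwhere(self.lower > self.upper + 1e-9)
            raise BandIntegrityError(
                f"lower exceeds upper at {bad.shape[0]} point(s), "
                f"first at index {tuple(bad[0])}"
            )

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def widened(self, delta: float) -> "PredictionBand":
        """A copy widened pointwise by ``delta`` (% volume) on each side."""
        return PredictionBand(
            kind=self.kind, grid=self.grid,
            lower=np.clip(self.lower - delta, 0.0, 100.0),
            upper=np.clip(self.upper + delta, 0.0, 100.0),
            scope=self.scope, meta=dict(self.meta),
        )


def _clip(a: np.ndarray) -> np.ndarray:
    return np.clip(a, 0.0, 100.0)


def rmse_band(predicted, summary) -> PredictionBand:
    """The empirical ``V_pred +/- RMSE_pred`` band.

    ``predicted`` may be a single :class:`DVHCurve`, a 1-D volume vector on
    the summary grid, or an ``(n_plans, n_doses)`` matrix; the band is centred
    on each prediction with a cohort-wide dosewise width, clipped to [0, 100].
    """
    if isinstance(predicted, DVHCurve):
        pred = predicted.volume_pct
    else:
        pred = np.asarray(predicted, dtype=float)
    if pred.shape[-1] != len(summary.grid):
        raise ValueError(
            f"prediction length {pred.shape[-1]} does not match grid "
            f"({len(summary.grid)} points)"
        )
    return PredictionBand(
        kind="rmse", grid=summary.grid,
        lower=_clip(pred - summary.rmse),
        upper=_clip(pred + summary.rmse),
        scope="per_plan" if pred.ndim == 2 else "cohort",
    )


def _values_matrix(values, grid: DoseGrid | None):
    if isinstance(values, DVHCohort):
        return values.clinical_matrix, values.grid
    mat = np.atleast_2d(np.asarray(values, dtype=float))
    if grid is None:
        grid = DoseGrid(0.0, float(mat.shape[1] - 1), 1.0)
    return mat, grid


def iqr_band(values, grid: DoseGrid | None = None) -> PredictionBand:
    """25th-75th percentile band of the clinical-DVH distribution per dose point.

    ``values`` is a cohort or an ``(n_plans, n_doses)`` matrix of clinical
    volumes.  Percentiles use linear interpolation between order statistics.
    """
    mat, grid = _values_matrix(values, grid)
    if mat.shape[0] < 2:
        raise BandIntegrityError("IQR band undefined for a single-plan cohort")
    q1, q3 = np.percentile(mat, [25.0, 75.0], axis=0, method="linear")
    return PredictionBand(kind="iqr", grid=grid, lower=_clip(q1),
                          upper=_clip(q3), scope="cohort")


def median_split_band(values, feature=None,
                      grid: DoseGrid | None = None) -> PredictionBand:
    """Band from the mean DVHs of the cohort's two feature-split halves.

    Plans are split at the median of ``feature`` (one scalar per plan, e.g. an
    anatomy metric correlated with achievable sparing); for odd cohorts the
    median plan joins both halves, mirroring the inclusive [min, median] /
    [median, max] split.  Each half contributes its mean clinical DVH; at each
    dose point the band's lower/upper bound is the min/max of the two
    half-means, since the feature-value correlation may flip sign along the
    dose axis.

    With ``feature=None`` the split is performed pointwise on each dose
    point's own values (the self-split used for closed-form calibration).
    """
    mat, grid = _values_matrix(values, grid)
    n = mat.shape[0]
    if n < 2:
        raise BandIntegrityError("median-split band needs at least 2 plans")

    if feature is None:
        # Pointwise self-split: sorted half-means at every dose point.
        srt = np.sort(mat, axis=0)
        k = (n + 1) // 2
        m_lo = srt[:k].mean(axis=0)
        m_hi = srt[n - k:].mean(axis=0)
        meta = {"split": "pointwise_self"}
    else:
        feature = np.asarray(feature, dtype=float)
        if feature.shape != (n,):
            raise ValueError(f"need one finite feature per plan, got shape "
                             f"{feature.shape} for n={n}")
        if not np.all(np.isfinite(feature)):
            raise ValueError("feature values must be finite")
        med = np.median(feature)
        lo_idx = feature <= med
        hi_idx = feature >= med
        if np.ptp(feature) == 0:
            warnings.warn(
                "all feature values identical: degenerate split, halves "
                "formed by stable plan order",
                stacklevel=2,
            )
            k = (n + 1) // 2
            lo_idx = np.zeros(n, bool)
            hi_idx = np.zeros(n, bool)
            lo_idx[:k] = True
            hi_idx[n - k:] = True
        m_lo = mat[lo_idx].mean(axis=0)
        m_hi = mat[hi_idx].mean(axis=0)
        meta = {"split": "feature_median", "feature_median": float(med)}

    return PredictionBand(
        kind="median_split", grid=grid,
        lower=_clip(np.minimum(m_lo, m_hi)),
        upper=_clip(np.maximum(m_lo, m_hi)),
        scope="cohort", meta=meta,
    )


def load_model_band(lower, upper, predicted,
                    grid: DoseGrid | None = None,
                    symmetry_tol: float = 1e-6) -> PredictionBand:
    """Ingest a model-provided error band and integrity-check it.

    Inputs may be curves, vectors, or per-plan matrices on the common grid.
    Crossing bounds raise :class:`BandIntegrityError` listing the offending
    dose points; a prediction outside its own band is reported as a warning.
    The ``symmetric`` meta flag records whether upper-pred equals pred-lower
    everywhere (before clipping), as for a propagated-SD band.
    """
    def as_arr(x):
        return x.volume_pct if isinstance(x, DVHCurve) else np.asarray(x, float)

    lo, hi, pred = as_arr(lower), as_arr(upper), as_arr(predicted)
    if grid is None:
        grid = DoseGrid(0.0, float(lo.shape[-1] - 1), 1.0)
    if not (lo.shape == hi.shape == pred.shape):
        raise ValueError("lower, upper and predicted must share a shape")

    crossing = np.argwhere(np.atleast_2d(lo) > np.atleast_2d(hi) + 1e-9)
    if crossing.size:
        doses = grid.doses[np.unique(crossing[:, -1])][:10]
        raise BandIntegrityError(
            f"band bounds cross at dose point(s) {doses.tolist()}"
        )
    symmetric = bool(np.allclose(hi - pred, pred - lo, atol=symmetry_tol))
    outside = (pred < lo - 1e-9) | (pred > hi + 1e-9)
    if outside.any():
        warnings.warn(
            f"prediction lies outside its band at {int(outside.sum())} "
            "dose point(s)",
            stacklevel=2,
        )
    return PredictionBand(
        kind="model_provided", grid=grid, lower=_clip(lo), upper=_clip(hi),
        scope="per_plan" if np.asarray(lo).ndim == 2 else "cohort",
        meta={"symmetric": symmetric},
    )


def model_band_from_cohort(cohort: DVHCohort) -> PredictionBand:
    """The model-provided band a cohort carried in from file."""
    if not cohort.has_model_band:
        raise BandIntegrityError("cohort has no model-provided band")
    return load_model_band(cohort.model_band_lower, cohort.model_band_upper,
                           cohort.predicted_matrix, grid=cohort.grid)
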