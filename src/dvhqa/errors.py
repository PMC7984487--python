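"""Dosewise prediction-error statistics.

For a validation cohort of N plans with clinical DVHs ``V_clin,i(D)`` and
knowledge-based predictions ``V_pred,i(D)``, the dosewise prediction error is
``e_i(D) = V_clin,i(D) - V_pred,i(D)`` (positive = the model underpredicted
the clinical volume).  From the error distribution at each dose point:

* bias        ``mu(D)    = mean_i e_i(D)``
* variation   ``sigma(D) = sample SD of e_i(D)``  (N-1 denominator)
* accuracy    ``RMSE_pred(D) = sqrt(mean_i e_i(D)^2)``

RMSE combines bias and variation in quadrature.  With the *population* SD
(N denominator) the identity ``RMSE^2 = mu^2 + sigma_pop^2`` is exact; with
the sample SD it holds up to ``sigma^2 / N``, which vanishes for large
cohorts.  Both SDs are reported: figures use the sample SD, the identity
check uses the population SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import DoseGrid, DVHCohort

__all__ = ["ErrorSummary", "QuadratureReport", "dosewise_errors",
           "summarize_errors", "quadrature_check"]


@dataclass
class ErrorSummary:
    """Per-dose-point error statistics for one cohort (all in % OAR volume)."""

    grid: DoseGrid
    mu: np.ndarray
    sigma: np.ndarray        # sample SD (N-1); NaN when n == 1
    sigma_pop: np.ndarray    # population SD (N)
    rmse: np.ndarray
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "dose_pct": self.grid.doses,
            "mu": self.mu,
            "sigma": self.sigma,
            "sigma_pop": self.sigma_pop,
            "rmse": self.rmse,
            "n": self.n,
        })

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_json(self) -> str:
        return self.to_frame().to_json(orient="records")


def dosewise_errors(cohort: DVHCohort) -> np.ndarray:
    """Per-plan, per-dose error matrix ``V_clin,i(D) - V_pred,i(D)``.

    Shape ``(n_plans, n_doses)``, rows in ``cohort.plan_ids`` order.  Positive
    entries mean the clinical volume exceeded the prediction (underprediction,
    bias mu > 0); negative entries mean overprediction (mu < 0).
    """
    if cohort.clinical_matrix.shape != cohort.predicted_matrix.shape:
        raise ValueError("clinical and predicted matrices are not aligned")
    return cohort.clinical_matrix - cohort.predicted_matrix


def summarize_errors(errors: np.ndarray,
                     grid: DoseGrid | None = None) -> ErrorSummary:
    """Reduce an error matrix to dosewise mu, sigma, sigma_pop and RMSE.

    ``errors`` has shape ``(n_plans, n_doses)``.  For a single-plan cohort the
    sample SD is undefined and reported as NaN (never silently 0) with a
    warning; the population SD is 0 by definition.
    """
    errors = np.atleast_2d(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise ValueError("empty error matrix")
    n = errors.shape[0]
    if grid is None:
        m = errors.shape[1]
        grid = DoseGrid(0.0, float(m - 1), 1.0)
    if len(grid) != errors.shape[1]:
        raise ValueError(
            f"grid length {len(grid)} != error matrix width {errors.shape[1]}"
        )

    mu = errors.mean(axis=0)
    rmse = np.sqrt(np.mean(errors**2, axis=0))
    sigma_pop = errors.std(axis=0, ddof=0)
    if n >= 2:
        sigma = errors.std(axis=0, ddof=1)
    else:
        warnings.warn(
            "single-plan cohort: sample standard deviation is undefined "
            "(reported as NaN)",
            stacklevel=2,
        )
        sigma = np.full(errors.shape[1], np.nan)
    return ErrorSummary(grid=grid, mu=mu, sigma=sigma, sigma_pop=sigma_pop,
                        rmse=rmse, n=n)


@dataclass
class QuadratureReport:
    """Residuals of the RMSE^2 = mu^2 + sigma^2 quadrature decomposition."""

    max_abs_pop: float        # max_D |rmse^2 - (mu^2 + sigma_pop^2)| — exact identity
    max_rel_pop: float        # same, relative to rmse^2 (0 where rmse = 0)
    max_abs_sample: float     # max_D |rmse^2 - (mu^2 + sigma^2)|
    sample_bound: float       # max_D sigma^2 / (n - 1): bound on the above
    n: int

    @property
    def sample_within_bound(self) -> bool:
        return self.max_abs_sample <= self.sample_bound + 1e-9


def quadrature_check(summary: ErrorSummary) -> QuadratureReport:
    """Verify the quadrature identity of an :class:`ErrorSummary`.

    With the population SD the identity is algebraically exact, so
    ``max_abs_pop`` must be at floating-point level.  With the sample SD the
    residual equals ``sigma^2 / n`` exactly, bounded by ``sigma^2 / (n-1)``.
    """
    if summary.n < 2:
        raise ValueError("quadrature check requires at least 2 plans")
    r2 = summary.rmse**2
    res_pop = np.abs(r2 - (summary.mu**2 + summary.sigma_pop**2))
    res_sam = np.abs(r2 - (summary.mu**2 + summary.sigma**2))
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = np.where(r2 > 0, res_pop / r2, 0.0)
    return QuadratureReport(
        max_abs_pop=float(res_pop.max()),
        max_rel_pop=float(rel.max()),
        max_abs_sample=float(res_sam.max()),
        sample_bound=float((summary.sigma**2).max() / (summary.n - 1)),
        n=summary.n,
    )
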