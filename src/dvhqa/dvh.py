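"""Cumulative DVH data model: curves, dose grids, cohorts, validation, resampling.

All dose axes are expressed as a percentage of the prescription (Rx) dose and
all volumes as a percentage of the organ-at-risk (OAR) volume, so curves from
different plans and prescription levels are directly comparable.  A cumulative
DVH ``V(D)`` gives the fraction of the OAR receiving at least dose ``D``; it
therefore starts at 100% volume at zero dose and is non-increasing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DoseGrid",
    "DVHCurve",
    "DVHCohort",
    "ValidationReport",
    "DVHValidationError",
    "CohortPairingError",
    "validate_dvh",
    "resample_to_grid",
    "DEFAULT_GRID",
]

#: Numerical slack for monotonicity / range checks (volume %).
_EPS = 1e-9

#: Tolerance on the V(0) = 100 normalization check (volume %).
V0_TOLERANCE = 1e-6


class DVHValidationError(ValueError):
    """A DVH curve violates cumulative-DVH structural requirements."""


class CohortPairingError(ValueError):
    """Clinical and predicted curve sets do not match one-to-one by plan id."""


@dataclass(frozen=True)
class DoseGrid:
    """Uniform dose grid in % of prescription dose.

    The default grid spans 0-110% Rx in 1% steps so the full clinical
    interval, including doses at and slightly above prescription, is covered.
    """

    start: float = 0.0
    stop: float = 110.0
    step: float = 1.0

    def __post_init__(self) -> None:
        if self.step <= 0:
            raise ValueError(f"grid step must be positive, got {self.step}")
        if self.stop < self.start:
            raise ValueError("grid stop must not precede start")

    @property
    def doses(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)

    def __len__(self) -> int:
        return int(round((self.stop - self.start) / self.step)) + 1

    def index_range(self, lo: float, hi: float) -> np.ndarray:
        """Boolean mask selecting grid doses in the closed interval [lo, hi]."""
        if hi < lo:
            raise ValueError(f"empty dose range [{lo}, {hi}]")
        d = self.doses
        mask = (d >= lo - _EPS) & (d <= hi + _EPS)
        if not mask.any():
            raise ValueError(f"dose range [{lo}, {hi}] contains no grid points")
        return mask


DEFAULT_GRID = DoseGrid()


@dataclass
class DVHCurve:
    """One cumulative DVH: volume (% OAR volume) vs dose (% Rx dose)."""

    plan_id: str
    oar: str
    dose_pct: np.ndarray
    volume_pct: np.ndarray

    def __post_init__(self) -> None:
        self.dose_pct = np.asarray(self.dose_pct, dtype=float)
        self.volume_pct = np.asarray(self.volume_pct, dtype=float)
        if self.dose_pct.ndim != 1 or self.volume_pct.ndim != 1:
            raise DVHValidationError("dose_pct and volume_pct must be 1-D")
        if self.dose_pct.size != self.volume_pct.size:
            raise DVHValidationError(
                f"plan {self.plan_id!r}: dose and volume lengths differ "
                f"({self.dose_pct.size} vs {self.volume_pct.size})"
            )
        if self.dose_pct.size < 2:
            raise DVHValidationError(
                f"plan {self.plan_id!r}: a DVH curve needs at least 2 points"
            )
        if np.any(np.diff(self.dose_pct) <= 0):
            raise DVHValidationError(
                f"plan {self.plan_id!r}: dose_pct must be strictly increasing"
            )

    def __len__(self) -> int:
        return self.dose_pct.size


@dataclass
class ValidationReport:
    """Outcome of cumulative-DVH semantic checks on a single curve."""

    plan_id: str
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def raise_if_invalid(self) -> None:
        if not self.ok:
            raise DVHValidationError(
                f"plan {self.plan_id!r}: " + "; ".join(self.violations)
            )


def validate_dvh(curve: DVHCurve, tolerance: float = V0_TOLERANCE) -> ValidationReport:
    """Check cumulative-DVH semantics of a curve.

    Verifies that volumes lie in [0, 100], that the curve is non-increasing
    along dose, and that the volume at zero dose equals 100 within
    ``tolerance`` (curves are OAR-volume normalized).  Structural problems
    (too few points, non-monotone dose axis) raise at construction time; this
    function reports semantic violations without raising.
    """
    report = ValidationReport(plan_id=curve.plan_id)
    v = curve.volume_pct
    d = curve.dose_pct

    out = np.flatnonzero((v < -_EPS) | (v > 100.0 + _EPS))
    for i in out[:5]:
        report.violations.append(
            f"volume {v[i]:.6g} out of [0, 100] at dose {d[i]:.6g}"
        )
    if out.size > 5:
        report.violations.append(f"... and {out.size - 5} more out-of-range points")

    rising = np.flatnonzero(np.diff(v) > _EPS)
    for i in rising[:5]:
        report.violations.append(
            f"non-monotone segment: volume rises from {v[i]:.6g} to "
            f"{v[i + 1]:.6g} at dose {d[i + 1]:.6g}"
        )
    if rising.size > 5:
        report.violations.append(f"... and {rising.size - 5} more rising segments")

    # V(0) = 100: check at dose 0 if tabulated, else against the implicit
    # extension (volume below the first tabulated dose is the first value).
    v0 = v[0] if d[0] <= _EPS else v[0]
    if abs(v0 - 100.0) > tolerance:
        report.violations.append(f"V(0) = {v0:.6g}, expected 100")
    return report


def renormalize(curve: DVHCurve) -> DVHCurve:
    """Rescale volumes so V(0) = 100 exactly (for inputs normalized elsewhere)."""
    v0 = curve.volume_pct[0]
    if v0 <= 0:
        raise DVHValidationError(
            f"plan {curve.plan_id!r}: cannot renormalize, V(0) = {v0:.6g}"
        )
    return DVHCurve(
        plan_id=curve.plan_id,
        oar=curve.oar,
        dose_pct=curve.dose_pct.copy(),
        volume_pct=curve.volume_pct * (100.0 / v0),
    )


def resample_to_grid(curve: DVHCurve, grid: DoseGrid) -> DVHCurve:
    """Linearly interpolate a curve onto a uniform dose grid.

    Grid doses beyond the curve's last tabulated dose map to volume 0 (no
    part of the organ receives more than the maximum recorded dose); doses
    below the first tabulated dose map to 100.  Curves already tabulated on
    the grid pass through unchanged.
    """
    vol = np.interp(grid.doses, curve.dose_pct, curve.volume_pct,
                    left=100.0, right=0.0)
    return DVHCurve(
        plan_id=curve.plan_id,
        oar=curve.oar,
        dose_pct=grid.doses,
        volume_pct=vol,
    )


class DVHCohort:
    """Clinical and predicted DVHs for one OAR, aligned on a common dose grid.

    Curves are validated and resampled onto ``grid`` at construction, so every
    downstream statistic operates on the aligned ``clinical_matrix`` /
    ``predicted_matrix`` (shape ``(n_plans, n_doses)``, rows in ``plan_ids``
    order).  Optional model-provided error bands are stored as per-plan
    (lower, upper) matrices.
    """

    def __init__(
        self,
        oar: str,
        grid: DoseGrid,
        plan_ids: list[str],
        clinical_matrix: np.ndarray,
        predicted_matrix: np.ndarray,
        model_band_lower: np.ndarray | None = None,
        model_band_upper: np.ndarray | None = None,
    ) -> None:
        self.oar = oar
        self.grid = grid
        self.plan_ids = list(plan_ids)
        self.clinical_matrix = np.asarray(clinical_matrix, dtype=float)
        self.predicted_matrix = np.asarray(predicted_matrix, dtype=float)
        m = len(grid)
        n = len(self.plan_ids)
        if n < 1:
            raise CohortPairingError("a cohort needs at least one plan")
        for name, mat in (("clinical", self.clinical_matrix),
                          ("predicted", self.predicted_matrix)):
            if mat.shape != (n, m):
                raise ValueError(
                    f"{name} matrix shape {mat.shape} != (n_plans={n}, n_doses={m})"
                )
        self.model_band_lower = None if model_band_lower is None else np.asarray(
            model_band_lower, dtype=float)
        self.model_band_upper = None if model_band_upper is None else np.asarray(
            model_band_upper, dtype=float)
        if (self.model_band_lower is None) != (self.model_band_upper is None):
            raise ValueError("model band requires both lower and upper bounds")

    @property
    def n(self) -> int:
        return len(self.plan_ids)

    @property
    def has_model_band(self) -> bool:
        return self.model_band_lower is not None

    @classmethod
    def from_curves(
        cls,
        clinical: list[DVHCurve],
        predicted: list[DVHCurve],
        grid: DoseGrid = DEFAULT_GRID,
        model_bands: dict[str, tuple[DVHCurve, DVHCurve]] | None = None,
        strict: bool = True,
        renormalize_inputs: bool = False,
    ) -> "DVHCohort":
        """Pair, validate and resample curves into an aligned cohort.

        ``clinical`` and ``predicted`` must contain the same plan_ids exactly
        once each; a mismatch raises :class:`CohortPairingError` naming the
        offending plans.  With ``strict=False`` semantic DVH violations are
        warnings instead of errors.
        """
        clin_by_id = _index_by_plan(clinical, "clinical")
        pred_by_id = _index_by_plan(predicted, "predicted")
        only_clin = sorted(set(clin_by_id) - set(pred_by_id))
        only_pred = sorted(set(pred_by_id) - set(clin_by_id))
        if only_clin or only_pred:
            parts = []
            if only_clin:
                parts.append(f"clinical only: {only_clin}")
            if only_pred:
                parts.append(f"predicted only: {only_pred}")
            raise CohortPairingError("unpaired plans — " + "; ".join(parts))

        oars = {c.oar for c in clinical} | {c.oar for c in predicted}
        if len(oars) != 1:
            raise ValueError(f"cohort must contain exactly one OAR, got {sorted(oars)}")
        oar = oars.pop()

        plan_ids = sorted(clin_by_id)
        rows_c, rows_p = [], []
        for pid in plan_ids:
            pair = []
            for curve in (clin_by_id[pid], pred_by_id[pid]):
                if renormalize_inputs:
                    curve = renormalize(curve)
                rep = validate_dvh(curve)
                if not rep.ok:
                    if strict:
                        rep.raise_if_invalid()
                    warnings.warn(
                        f"plan {pid!r}: " + "; ".join(rep.violations),
                        stacklevel=2,
                    )
                pair.append(resample_to_grid(curve, grid).volume_pct)
            rows_c.append(pair[0])
            rows_p.append(pair[1])

        lower = upper = None
        if model_bands:
            missing = sorted(set(plan_ids) - set(model_bands))
            if missing:
                raise CohortPairingError(f"model band missing for plans: {missing}")
            lower = np.vstack([
                resample_to_grid(model_bands[pid][0], grid).volume_pct
                for pid in plan_ids
            ])
            upper = np.vstack([
                resample_to_grid(model_bands[pid][1], grid).volume_pct
                for pid in plan_ids
            ])

        return cls(oar, grid, plan_ids, np.vstack(rows_c), np.vstack(rows_p),
                   model_band_lower=lower, model_band_upper=upper)


def _index_by_plan(curves: list[DVHCurve], role: str) -> dict[str, DVHCurve]:
    out: dict[str, DVHCurve] = {}
    for c in curves:
        if c.plan_id in out:
            raise CohortPairingError(
                f"plan {c.plan_id!r} appears more than once in {role} set"
            )
        out[c.plan_id] = c
    return out
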