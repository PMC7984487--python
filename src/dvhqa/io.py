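"""Tabular I/O for DVH cohorts.

The on-disk interchange format is a long-format CSV with header
``plan_id,oar,role,dose_pct,volume_pct`` where ``role`` is one of
``clinical``, ``predicted``, ``band_lower``, ``band_upper``.  Band rows with
``plan_id == "__cohort__"`` describe a cohort-level band; band rows keyed by a
plan id describe that plan's model-provided band.  A JSON mirror of the same
fields is provided for report embedding.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dvh import DEFAULT_GRID, DoseGrid, DVHCohort, DVHCurve

__all__ = ["ROLES", "COHORT_KEY", "read_cohort", "write_cohort",
           "cohort_to_frame", "cohort_to_json"]

ROLES = ("clinical", "predicted", "band_lower", "band_upper")
COHORT_KEY = "__cohort__"
_COLUMNS = ["plan_id", "oar", "role", "dose_pct", "volume_pct"]


def _curves_from_frame(df: pd.DataFrame, role: str) -> dict[str, DVHCurve]:
    """Group rows of one role into curves keyed by plan_id.

    Duplicate dose values within a curve keep the last row (with a warning);
    rows are sorted by dose before construction.
    """
    out: dict[str, DVHCurve] = {}
    for (pid, oar), grp in df[df["role"] == role].groupby(["plan_id", "oar"],
                                                          sort=True):
        grp = grp.sort_values("dose_pct", kind="stable")
        dup = grp["dose_pct"].duplicated(keep="last")
        if dup.any():
            warnings.warn(
                f"plan {pid!r} role {role!r}: {int(dup.sum())} duplicate dose "
                "value(s); keeping last",
                stacklevel=3,
            )
            grp = grp[~dup]
        out[str(pid)] = DVHCurve(
            plan_id=str(pid),
            oar=str(oar),
            dose_pct=grp["dose_pct"].to_numpy(dtype=float),
            volume_pct=grp["volume_pct"].to_numpy(dtype=float),
        )
    return out


def read_cohort(
    source: str | Path | pd.DataFrame,
    oar: str | None = None,
    grid: DoseGrid = DEFAULT_GRID,
    strict: bool = True,
    renormalize: bool = False,
) -> DVHCohort:
    """Read a long-format DVH table into an aligned :class:`DVHCohort`.

    ``source`` is a CSV path or an equivalent DataFrame.  If the table holds
    several OARs, ``oar`` selects one.  Model-provided bands (roles
    ``band_lower``/``band_upper``) are attached when present for every plan.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source)
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"table is missing required columns: {missing}")
    bad_roles = sorted(set(df["role"]) - set(ROLES))
    if bad_roles:
        raise ValueError(f"unknown roles {bad_roles}; expected one of {ROLES}")

    oars = sorted(df["oar"].unique())
    if oar is None:
        if len(oars) != 1:
            raise ValueError(
                f"table holds multiple OARs {oars}; pass oar=... to select one"
            )
        oar = oars[0]
    df = df[df["oar"] == oar]
    if df.empty:
        raise ValueError(f"no rows for OAR {oar!r}")

    clinical = _curves_from_frame(df, "clinical")
    predicted = _curves_from_frame(df, "predicted")
    lowers = _curves_from_frame(df, "band_lower")
    uppers = _curves_from_frame(df, "band_upper")

    model_bands = None
    per_plan_lo = {k: v for k, v in lowers.items() if k != COHORT_KEY}
    per_plan_hi = {k: v for k, v in uppers.items() if k != COHORT_KEY}
    if per_plan_lo or per_plan_hi:
        if set(per_plan_lo) != set(per_plan_hi):
            raise ValueError(
                "band_lower/band_upper plan ids differ: "
                f"{sorted(set(per_plan_lo) ^ set(per_plan_hi))}"
            )
        model_bands = {k: (per_plan_lo[k], per_plan_hi[k]) for k in per_plan_lo}

    return DVHCohort.from_curves(
        list(clinical.values()),
        list(predicted.values()),
        grid=grid,
        model_bands=model_bands,
        strict=strict,
        renormalize_inputs=renormalize,
    )


def cohort_to_frame(cohort: DVHCohort) -> pd.DataFrame:
    """Serialize an aligned cohort back to the long-format table."""
    doses = cohort.grid.doses
    frames = []
    for role, mat in (("clinical", cohort.clinical_matrix),
                      ("predicted", cohort.predicted_matrix),
                      ("band_lower", cohort.model_band_lower),
                      ("band_upper", cohort.model_band_upper)):
        if mat is None:
            continue
        for i, pid in enumerate(cohort.plan_ids):
            frames.append(pd.DataFrame({
                "plan_id": pid,
                "oar": cohort.oar,
                "role": role,
                "dose_pct": doses,
                "volume_pct": mat[i],
            }))
    return pd.concat(frames, ignore_index=True)[_COLUMNS]


def write_cohort(cohort: DVHCohort, path: str | Path) -> None:
    """Write a cohort as long-format CSV in the dialect :func:`read_cohort` reads."""
    cohort_to_frame(cohort).to_csv(path, index=False)


def cohort_to_json(cohort: DVHCohort) -> str:
    """JSON mirror of the long-format fields, for report embedding."""
    doses = cohort.grid.doses
    payload: dict = {
        "oar": cohort.oar,
        "grid": {"start": cohort.grid.start, "stop": cohort.grid.stop,
                 "step": cohort.grid.step},
        "dose_pct": doses.tolist(),
        "plans": [],
    }
    for i, pid in enumerate(cohort.plan_ids):
        entry = {
            "plan_id": pid,
            "clinical": np.round(cohort.clinical_matrix[i], 10).tolist(),
            "predicted": np.round(cohort.predicted_matrix[i], 10).tolist(),
        }
        if cohort.has_model_band:
            entry["band_lower"] = np.round(cohort.model_band_lower[i], 10).tolist()
            entry["band_upper"] = np.round(cohort.model_band_upper[i], 10).tolist()
        payload["plans"].append(entry)
    return json.dumps(payload, indent=2, sort_keys=True)
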