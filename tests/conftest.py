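import numpy as np
import pytest

from dvhqa import (DoseGrid, DVHCohort, DVHCurve, SyntheticSpec,
                   generate_cohort, run_calibration)


@pytest.fixture
def grid() -> DoseGrid:
    return DoseGrid(0.0, 110.0, 1.0)


@pytest.fixture
def toy_curve() -> DVHCurve:
    return DVHCurve("p1", "bladder", [0.0, 50.0, 110.0], [100.0, 60.0, 0.0])


def make_cohort(clinical_rows, predicted_rows, grid=None, oar="bladder"):
    """Aligned cohort straight from volume matrices (rows = plans)."""
    clinical_rows = np.atleast_2d(np.asarray(clinical_rows, float))
    predicted_rows = np.atleast_2d(np.asarray(predicted_rows, float))
    if grid is None:
        grid = DoseGrid(0.0, float(clinical_rows.shape[1] - 1), 1.0)
    ids = [f"p{i}" for i in range(clinical_rows.shape[0])]
    return DVHCohort(oar, grid, ids, clinical_rows, predicted_rows)


@pytest.fixture(scope="session")
def parametric_cohort():
    """Physically valid synthetic cohort with anatomy spread and shift noise."""
    spec = SyntheticSpec(n=45, seed=11, error_mode="parametric",
                         shift_mean=0.5, shift_sd=2.0)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def calibration():
    """One shared large-cohort Monte-Carlo calibration run."""
    return run_calibration(n=2000, seed=20260920)
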