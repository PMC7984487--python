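"""Error-band construction: ±RMSE, IQR, median-split, model-provided."""

import numpy as np
import pytest
from scipy.stats import norm

from dvhqa import (BandIntegrityError, DoseGrid, iqr_band, load_model_band,
                   median_split_band, read_cohort, rmse_band,
                   summarize_errors, write_cohort)

from conftest import make_cohort


class TestRmseBand:
    def _summary(self, errors):
        return summarize_errors(np.asarray(errors, float))

    def test_band_arithmetic_and_clipping(self):
        s = self._summary([[3.0], [-3.0]])  # rmse = 3 at the single dose point
        band = rmse_band(np.array([50.0]), s)
        assert (band.lower[0], band.upper[0]) == (47.0, 53.0)
        clipped = rmse_band(np.array([1.0]), s)
        assert (clipped.lower[0], clipped.upper[0]) == (0.0, 4.0)

    def test_zero_rmse_collapses_onto_prediction(self):
        s = self._summary([[0.0], [0.0]])
        band = rmse_band(np.array([42.0]), s)
        assert band.lower[0] == band.upper[0] == 42.0

    def test_per_plan_scope_for_matrix_input(self):
        s = self._summary([[1.0], [-1.0]])
        band = rmse_band(np.array([[50.0], [60.0]]), s)
        assert band.scope == "per_plan"
        np.testing.assert_allclose(band.upper[:, 0], [51.0, 61.0])


class TestIqrBand:
    def test_hand_percentile_oracle(self):
        band = iqr_band(np.array([[1.0], [2.0], [3.0], [4.0]]))
        # linear interpolation between order statistics
        assert band.lower[0] == pytest.approx(1.75)
        assert band.upper[0] == pytest.approx(3.25)

    def test_identical_values_zero_width(self):
        band = iqr_band(np.full((5, 3), 7.0))
        assert np.all(band.width == 0.0)

    def test_single_plan_undefined(self):
        with pytest.raises(BandIntegrityError):
            iqr_band(np.array([[1.0, 2.0]]))

    def test_gaussian_half_width_matches_quantile(self):
        rng = np.random.default_rng(42)
        vals = 50.0 + rng.standard_normal((100_000, 1))
        band = iqr_band(vals)
        half = band.width[0] / 2
        assert half == pytest.approx(norm.ppf(0.75), abs=0.01)


class TestMedianSplitBand:
    def test_hand_arithmetic_oracle(self):
        vals = np.array([[10.0], [20.0], [30.0], [40.0]])
        band = median_split_band(vals, feature=np.array([1.0, 2.0, 3.0, 4.0]))
        assert band.lower[0] == pytest.approx(15.0)
        assert band.upper[0] == pytest.approx(35.0)

    def test_uncorrelated_feature_equal_values_zero_width(self):
        vals = np.full((4, 2), 25.0)
        band = median_split_band(vals, feature=np.array([4.0, 1.0, 3.0, 2.0]))
        assert np.all(band.width == 0.0)

    def test_odd_n_median_plan_in_both_halves(self):
        vals = np.array([[10.0], [20.0], [30.0]])
        band = median_split_band(vals, feature=np.array([1.0, 2.0, 3.0]))
        # halves {10,20} and {20,30} -> [15, 25]
        assert band.lower[0] == pytest.approx(15.0)
        assert band.upper[0] == pytest.approx(25.0)

    def test_degenerate_feature_warns_and_splits_by_order(self):
        vals = np.array([[10.0], [20.0], [30.0], [40.0]])
        with pytest.warns(UserWarning, match="degenerate"):
            band = median_split_band(vals, feature=np.ones(4))
        assert band.lower[0] == pytest.approx(15.0)
        assert band.upper[0] == pytest.approx(35.0)

    def test_orientation_resolved_pointwise(self):
        # feature-value correlation flips sign between the two dose points
        vals = np.array([[10.0, 40.0], [20.0, 30.0],
                         [30.0, 20.0], [40.0, 10.0]])
        band = median_split_band(vals, feature=np.array([1.0, 2.0, 3.0, 4.0]))
        assert np.all(band.lower == 15.0) and np.all(band.upper == 35.0)

    def test_self_split_half_width_reaches_half_normal_mean(self):
        """Pointwise self-split on Gaussian data: the two half-means sit at
        ±sqrt(2/pi)·sigma (mean of a half-normal)."""
        rng = np.random.default_rng(3)
        sigma = 2.0
        vals = 50.0 + sigma * rng.standard_normal((200_000, 1))
        band = median_split_band(vals, feature=None)
        assert band.width[0] / 2 == pytest.approx(np.sqrt(2 / np.pi) * sigma,
                                                  rel=0.02)


class TestModelBand:
    def test_symmetric_flag(self):
        pred = np.array([50.0, 40.0])
        band = load_model_band(pred - 3, pred + 3, pred)
        assert band.meta["symmetric"] is True
        skew = load_model_band(pred - 5, pred + 3, pred)
        assert skew.meta["symmetric"] is False

    def test_crossing_bounds_raise_with_dose_points(self):
        pred = np.array([50.0, 40.0])
        lo = np.array([47.0, 45.0])
        hi = np.array([53.0, 43.0])
        with pytest.raises(BandIntegrityError, match="cross"):
            load_model_band(lo, hi, pred, grid=DoseGrid(0, 1, 1))

    def test_file_round_trip_equals_direct_construction(self, tmp_path):
        co = make_cohort([[100, 55, 0]], [[100, 50, 0]])
        co.model_band_lower = np.array([[96.0, 46.0, 0.0]])
        co.model_band_upper = np.array([[100.0, 54.0, 4.0]])
        path = tmp_path / "c.csv"
        write_cohort(co, path)
        back = read_cohort(path, grid=co.grid)
        direct = load_model_band(co.model_band_lower, co.model_band_upper,
                                 co.predicted_matrix, grid=co.grid)
        np.testing.assert_allclose(back.model_band_lower, direct.lower)
        np.testing.assert_allclose(back.model_band_upper, direct.upper)


def test_all_bands_respect_bound_invariants(parametric_cohort):
    cohort, truth = parametric_cohort
    s = summarize_errors(cohort.clinical_matrix - cohort.predicted_matrix,
                         grid=cohort.grid)
    bands = [
        rmse_band(cohort.predicted_matrix, s),
        iqr_band(cohort),
        median_split_band(cohort, feature=truth.feature),
        median_split_band(cohort, feature=None),
    ]
    for band in bands:
        assert np.all(band.lower <= band.upper + 1e-12)
        assert np.all((band.lower >= 0) & (band.upper <= 100))
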