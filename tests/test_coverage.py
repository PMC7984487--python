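"""Prediction-success tally, boxcar smoothing and dose-range summaries."""

import numpy as np
import pytest
from scipy.stats import norm

from dvhqa import (BandIntegrityError, PredictionBand, boxcar_smooth,
                   coverage_curve, coverage_summary, point_within_band,
                   rmse_band, summarize_errors)
from dvhqa.coverage import CoverageCurve
from dvhqa.dvh import DoseGrid

from conftest import make_cohort


class TestPointTally:
    def test_inside_band_succeeds(self):
        assert point_within_band(50.0, 50.0, 47.0, 53.0, tolerance=0.0)

    def test_tolerance_rescues_point_outside_narrow_band(self):
        # clinical 0.4% from the prediction: inside clinical granularity
        assert point_within_band(50.4, 50.0, 49.8, 50.2, tolerance=0.5)

    def test_far_point_fails(self):
        assert not point_within_band(51.0, 50.0, 49.8, 50.2, tolerance=0.5)

    def test_tolerance_bound_is_strict(self):
        # exactly 0.5 away is NOT "less than 0.5" from the prediction
        assert not point_within_band(50.5, 50.0, 49.8, 50.2, tolerance=0.5)

    def test_distance_measured_to_prediction_not_band_edge(self):
        # 0.3 from the band edge but 0.7 from the prediction -> fail
        assert not point_within_band(50.9, 50.0, 49.4, 50.6, tolerance=0.5)

    def test_crossed_bounds_rejected(self):
        with pytest.raises(BandIntegrityError):
            point_within_band(50.0, 50.0, 53.0, 47.0)


class TestCoverageCurve:
    def test_counting(self):
        clin = np.array([[48.0], [52.0], [60.0], [40.0]])
        pred = np.full((4, 1), 50.0)
        co = make_cohort(clin, pred)
        band = PredictionBand("rmse", co.grid, np.full((4, 1), 47.0),
                              np.full((4, 1), 53.0), scope="per_plan")
        cov = coverage_curve(co, band, tolerance=0.0, window=1)
        assert cov.raw[0] == pytest.approx(0.5)
        assert (cov.raw[0] * cov.n) == pytest.approx(round(cov.raw[0] * cov.n))

    def test_everything_inside_gives_unity(self):
        mat = np.tile([100.0, 50.0, 0.0], (3, 1))
        co = make_cohort(mat, mat)
        s = summarize_errors(np.zeros((3, 3)), grid=co.grid)
        cov = coverage_curve(co, rmse_band(co.predicted_matrix, s),
                             tolerance=0.0, window=1)
        assert np.all(cov.raw == 1.0)

    def test_gaussian_one_sigma_band_hits_68(self):
        rng = np.random.default_rng(8)
        n = 10_000
        pred = np.full((n, 1), 50.0)
        clin = pred + rng.standard_normal((n, 1))
        co = make_cohort(clin, pred)
        band = PredictionBand("rmse", co.grid, pred - 1.0, pred + 1.0,
                              scope="per_plan")
        cov = coverage_curve(co, band, tolerance=0.0, window=1)
        assert cov.raw[0] == pytest.approx(2 * norm.cdf(1) - 1, abs=0.015)

    def test_per_plan_band_requires_matching_rows(self):
        co = make_cohort(np.tile([100.0, 0.0], (3, 1)),
                         np.tile([100.0, 0.0], (3, 1)))
        band = PredictionBand("rmse", co.grid, np.zeros((2, 2)),
                              np.full((2, 2), 100.0), scope="per_plan")
        with pytest.raises(ValueError, match="per-plan band"):
            coverage_curve(co, band)

    def test_monotone_in_tolerance_and_band_width(self, parametric_cohort):
        cohort, _ = parametric_cohort
        s = summarize_errors(cohort.clinical_matrix - cohort.predicted_matrix,
                             grid=cohort.grid)
        band = rmse_band(cohort.predicted_matrix, s)
        base = coverage_curve(cohort, band, tolerance=0.0, window=1).raw
        more_tol = coverage_curve(cohort, band, tolerance=1.0, window=1).raw
        wider = coverage_curve(cohort, band.widened(2.0), tolerance=0.0,
                               window=1).raw
        assert np.all(more_tol >= base - 1e-12)
        assert np.all(wider >= base - 1e-12)


class TestBoxcar:
    def test_constant_series_unchanged(self):
        out = boxcar_smooth(np.full(30, 0.6), 11)
        np.testing.assert_allclose(out, 0.6)

    def test_impulse_spreads_to_eleven_elevenths(self):
        series = np.zeros(21)
        series[10] = 1.0
        out = boxcar_smooth(series, 11)
        np.testing.assert_allclose(out[5:16], 1 / 11)
        # shrunk edge windows never see the impulse
        np.testing.assert_allclose(out[:5], 0.0)
        np.testing.assert_allclose(out[16:], 0.0)

    def test_window_one_is_identity(self):
        series = np.arange(7.0)
        np.testing.assert_array_equal(boxcar_smooth(series, 1), series)

    @pytest.mark.parametrize("window", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, window):
        with pytest.raises(ValueError):
            boxcar_smooth(np.zeros(10), window)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            boxcar_smooth(np.zeros(5), 7)

    def test_smoothing_stays_in_raw_range(self):
        rng = np.random.default_rng(1)
        series = rng.random(50)
        out = boxcar_smooth(series, 11)
        assert out.min() >= series.min() - 1e-12
        assert out.max() <= series.max() + 1e-12


class TestCoverageSummary:
    def _curve(self, raw, window=1):
        grid = DoseGrid(0.0, float(len(raw) - 1), 1.0)
        raw = np.asarray(raw, float)
        return CoverageCurve(grid, raw, boxcar_smooth(raw, window), window,
                             0.5, 10)

    def test_constant_curve(self):
        s = coverage_summary(self._curve([0.6] * 5))
        assert s["min"] == s["max"] == s["mean"] == pytest.approx(60.0)

    def test_toy_min_max(self):
        s = coverage_summary(self._curve([0.4, 0.5, 0.6]))
        assert s["min"] == pytest.approx(40.0)
        assert s["max"] == pytest.approx(60.0)

    def test_subrange_never_widens_extremes(self):
        curve = self._curve([0.2, 0.8, 0.5, 0.9, 0.1])
        full = coverage_summary(curve, dose_range=(0, 4))
        sub = coverage_summary(curve, dose_range=(1, 3))
        assert sub["min"] >= full["min"] and sub["max"] <= full["max"]

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            coverage_summary(self._curve([0.5, 0.5]), dose_range=(2.0, 1.0))
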