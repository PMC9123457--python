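"""Calibration-curve fitting, inversion, detection limits, and file round trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from duobeam import (
    CalibrationError,
    fit_calibration,
    limit_of_blank,
    limit_of_detection,
    load_calibration,
    predict_concentration,
    save_calibration,
)


def _ols_normal_equations(points):
    """Independent closed-form oracle: (X'X)^-1 X'y and the R^2 definition."""
    arr = np.asarray(points, float)
    X = np.column_stack([arr[:, 0], np.ones(len(arr))])
    y = arr[:, 1]
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(beta[0]), float(beta[1]), r2


class TestFitCalibration:
    def test_exact_line(self):
        curve = fit_calibration([(0, 0), (1, 0.5), (2, 1.0)])
        assert curve.slope == pytest.approx(0.5)
        assert curve.intercept == pytest.approx(0.0, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)

    def test_two_points_give_r_squared_one_by_construction(self):
        curve = fit_calibration([(0.0, 0.13), (2.0, 0.58)])
        assert curve.r_squared == 1.0
        assert curve.slope == pytest.approx((0.58 - 0.13) / 2.0)
        assert curve.n_points == 2

    @pytest.mark.parametrize("seed", range(8))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        c = rng.uniform(0, 10, n)
        c[0], c[1] = 0.0, 10.0  # guarantee spread
        a = rng.uniform(0, 2, n)
        curve = fit_calibration(np.column_stack([c, a]))
        slope, intercept, r2 = _ols_normal_equations(np.column_stack([c, a]))
        assert curve.slope == pytest.approx(slope, rel=1e-10)
        assert curve.intercept == pytest.approx(intercept, rel=1e-10, abs=1e-12)
        assert curve.r_squared == pytest.approx(r2, rel=1e-10, abs=1e-12)

    def test_r_squared_invariant_under_affine_concentration_rescale(self):
        rng = np.random.default_rng(3)
        c = np.linspace(0, 5, 7)
        a = 0.3 * c + rng.normal(0, 0.05, 7)
        base = fit_calibration(np.column_stack([c, a]))
        scaled = fit_calibration(np.column_stack([2.5 * c + 1.0, a]))
        assert scaled.r_squared == pytest.approx(base.r_squared, rel=1e-12)
        assert scaled.slope == pytest.approx(base.slope / 2.5, rel=1e-12)

    @pytest.mark.parametrize(
        "points, match",
        [
            ([(1.0, 0.5)], "insufficient"),
            ([], "insufficient"),
            ([(1.0, 0.2), (1.0, 0.4), (1.0, 0.6)], "identical"),
        ],
    )
    def test_degenerate_inputs_rejected(self, points, match):
        with pytest.raises(CalibrationError, match=match):
            fit_calibration(points)


class TestPredictConcentration:
    def test_exact_inversion(self):
        curve = fit_calibration([(0, 0), (4, 2.0)])  # slope 0.5, intercept 0
        assert predict_concentration(curve, 1.0) == pytest.approx(2.0)
        assert predict_concentration(curve, 0.0) == pytest.approx(0.0)

    @pytest.mark.filterwarnings("ignore:predicted concentration")
    def test_round_trip_within_residual_scale(self):
        rng = np.random.default_rng(9)
        c = np.linspace(0, 5, 6)
        a = 0.2 * c + 0.01 + rng.normal(0, 0.005, 6)
        curve = fit_calibration(np.column_stack([c, a]))
        resid_scale = np.abs(
            a - (curve.slope * c + curve.intercept)
        ).max() / abs(curve.slope)
        for ci, ai in zip(c, a):
            assert abs(predict_concentration(curve, ai) - ci) <= resid_scale + 1e-9

    def test_below_range_prediction_warns_but_returns(self):
        curve = fit_calibration([(0, 0.1), (2, 0.5)])
        with pytest.warns(UserWarning, match="below the calibrated range"):
            assert predict_concentration(curve, 0.0) < 0

    def test_zero_slope_rejected(self):
        curve = fit_calibration([(0, 0.5), (1, 0.5)])
        with pytest.raises(CalibrationError, match="slope is zero"):
            predict_concentration(curve, 0.5)


class TestDetectionLimits:
    def test_identical_blanks_reduce_to_the_mean(self):
        assert limit_of_blank([0.02] * 20) == pytest.approx(0.02)

    def test_hand_computation_with_sample_sd(self):
        # mean 1, sample sd 2 (n-1 denominator) -> 1 + 3*2 = 7
        assert limit_of_blank([0, 0, 0, 4]) == pytest.approx(7.0)

    def test_large_sample_converges_to_mu_plus_three_sigma(self):
        rng = np.random.default_rng(42)
        mu, sigma = 0.5, 0.1
        draws = rng.normal(mu, sigma, 1000)
        assert limit_of_blank(draws) == pytest.approx(mu + 3 * sigma, abs=0.03)

    def test_lod_formula_and_zero_sd_case(self):
        limits = limit_of_detection(0.05, [1.0, 1.0, 1.0], n_blank=20)
        assert limits.limit_of_detection == pytest.approx(0.05)
        # arithmetic sequence step 0.01 has sample sd exactly 0.01
        limits = limit_of_detection(0.05, [1.0, 1.01, 1.02], n_blank=20)
        assert limits.limit_of_detection == pytest.approx(0.08)
        assert limits.limit_of_detection >= limits.limit_of_blank
        assert (limits.n_blank, limits.n_low) == (20, 3)

    @given(st.floats(0.1, 100))
    def test_scale_equivariance(self, k):
        blanks = [0.01, 0.02, 0.015, 0.03]
        lows = [0.11, 0.09, 0.10]
        lob = limit_of_blank(blanks)
        lod = limit_of_detection(lob, lows).limit_of_detection
        lob_k = limit_of_blank([k * b for b in blanks])
        lod_k = limit_of_detection(lob_k, [k * v for v in lows]).limit_of_detection
        assert lob_k == pytest.approx(k * lob, rel=1e-9)
        assert lod_k == pytest.approx(k * lod, rel=1e-9)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(CalibrationError, match="insufficient replicates"):
            limit_of_blank([0.02])
        with pytest.raises(CalibrationError, match="insufficient replicates"):
            limit_of_detection(0.05, [0.1])


class TestCalibrationFiles:
    def test_save_load_round_trip(self, tmp_path):
        curve = fit_calibration(
            [(0, 0.01), (1, 0.21), (2, 0.40), (3, 0.62)],
            analyte="nitrate",
            reagent="acid reduction",
            wavelength_nm=535.0,
        )
        path = tmp_path / "cal.csv"
        save_calibration(curve, path)
        again = load_calibration(path)
        assert again.slope == pytest.approx(curve.slope)
        assert again.intercept == pytest.approx(curve.intercept)
        assert again.r_squared == pytest.approx(curve.r_squared)
        assert (again.analyte, again.reagent) == ("nitrate", "acid reduction")
        assert again.wavelength_nm == 535.0
        np.testing.assert_array_equal(again.points, curve.points)

    def test_handwritten_collinear_file(self, tmp_path):
        path = tmp_path / "hand.csv"
        path.write_text("concentration,absorbance\n0,0\n1,0.5\n2,1.0\n")
        curve = load_calibration(path)
        assert curve.r_squared == pytest.approx(1.0)

    def test_single_point_file_is_insufficient(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("concentration,absorbance\n1.0,0.5\n")
        with pytest.raises(CalibrationError, match="insufficient"):
            load_calibration(path)

    def test_malformed_line_reported_with_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("concentration,absorbance\n0,0\nnot-a-number,x\n")
        with pytest.raises(CalibrationError, match="bad.csv:3"):
            load_calibration(path)

    def test_tampered_slope_fails_integrity_check(self, tmp_path):
        curve = fit_calibration([(0, 0.0), (1, 0.5), (2, 1.0)])
        path = tmp_path / "cal.csv"
        save_calibration(curve, path)
        text = path.read_text().replace('"slope": 0.5', '"slope": 0.6')
        path.write_text(text)
        with pytest.raises(CalibrationError, match="disagrees with refit"):
            load_calibration(path)
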