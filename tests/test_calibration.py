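"""Calibration fits, linear-range trimming, OD conversion, plate comparison."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from picls.calibration import (
    CalibrationPoint,
    compare_plate_types,
    convert_od,
    detect_linear_range,
    fit_line,
)
from picls.errors import (
    DegenerateInputError,
    IncomparableError,
    NonInvertibleError,
)
from picls.simulate import MeasurementModel, simulate_dilution_series


def ols_oracle(x, y):
    """Brute-force normal equations: independent check for fit_line."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    A = np.column_stack([x, np.ones_like(x)])
    slope, intercept = np.linalg.solve(A.T @ A, A.T @ y)
    pred = slope * x + intercept
    r2 = 1 - np.sum((y - pred) ** 2) / np.sum((y - np.mean(y)) ** 2)
    return slope, intercept, r2


class TestFitLine:
    def test_exact_line(self):
        fit = fit_line([(x, 2.0 * x) for x in (0.5, 1, 2, 4)])
        assert fit.slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            fit_line([(1, 5.0), (2, 5.0), (3, 5.0)])

    def test_too_few_points_or_no_x_variance(self):
        with pytest.raises(DegenerateInputError):
            fit_line([(1, 1), (2, 2)])
        with pytest.raises(DegenerateInputError):
            fit_line([(1, 1), (1, 2), (1, 3)])

    def test_noisy_slope_matches_closed_form_ols(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0.5, 10, 50)
        y = 3 * x * (1 + rng.normal(0, 0.01, size=50))
        fit = fit_line(list(zip(x, y)))
        slope, intercept, r2 = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9)
        assert abs(fit.slope - 3) < 0.1 and fit.r_squared >= 0.99

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        x = rng.uniform(0, 10, size=n)
        if np.ptp(x) == 0:
            x[0] += 1.0
        y = rng.uniform(0, 100, size=n)
        if np.ptp(y) == 0:
            y[0] += 1.0
        fit = fit_line(list(zip(x, y)))
        slope, intercept, r2 = ols_oracle(x, y)
        assert fit.slope == pytest.approx(slope, rel=1e-9, abs=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9, abs=1e-9)
        assert fit.r_squared == pytest.approx(r2, rel=1e-9, abs=1e-9)


def series(cv=0.0, seed=0, knee=12.0):
    return simulate_dilution_series(
        MeasurementModel(cv=cv, od_knee=knee), seed=seed)


class TestDetectLinearRange:
    def test_perfectly_linear_series_fully_retained(self):
        pts = [CalibrationPoint(x, 0.8 * x, 100 * x)
               for x in np.linspace(0.1, 10, 10)]
        fit = detect_linear_range(pts, r2_threshold=1.0 - 1e-12)
        assert fit.excluded_points == ()
        assert fit.range_hi == pytest.approx(10.0)
        assert fit.range_lo == pytest.approx(0.1)

    def test_saturation_knee_recovered_from_seeded_series(self):
        # two-fold dilution series 0.05..48, knee at cuvette OD 12, CV 3%
        fit = detect_linear_range(series(cv=0.03, seed=1), r2_threshold=0.98)
        assert fit.range_hi == pytest.approx(12.0)
        assert sorted(p.cuvette_od for p in fit.excluded_points) == [24.0, 48.0]

    def test_noiseless_series_recovers_knee_exactly(self):
        fit = detect_linear_range(series(cv=0.0), r2_threshold=0.98)
        assert fit.range_hi == pytest.approx(12.0)

    def test_fluorescence_axis_is_linear_over_full_series(self):
        # PI signal does not saturate with plate OD; nothing is trimmed
        fit = detect_linear_range(series(cv=0.0), r2_threshold=0.999,
                                  axis="fluorescence_vs_od")
        assert fit.excluded_points == ()
        assert fit.range_hi == pytest.approx(48.0)

    def test_too_few_points(self):
        pts = [CalibrationPoint(x, x, x) for x in (1, 2, 3)]
        with pytest.raises(DegenerateInputError):
            detect_linear_range(pts)

    def test_idempotent_on_retained_subset(self):
        fit = detect_linear_range(series(cv=0.03, seed=5), r2_threshold=0.98)
        kept = [p for p in series(cv=0.03, seed=5)
                if p not in fit.excluded_points]
        again = detect_linear_range(kept, r2_threshold=0.98)
        assert again.excluded_points == ()
        assert again.range_hi == fit.range_hi

    def test_blank_sd_sets_lower_bound(self):
        pts = [CalibrationPoint(x, 0.8 * x, 100 * x)
               for x in (0.01, 0.05, 0.5, 1, 2, 4)]
        fit = detect_linear_range(pts, r2_threshold=0.98, blank_sd=1.0,
                                  axis="fluorescence_vs_od")
        # 3 * blank SD = 3 a.u.; the 0.01-OD point (signal 1) sits below it
        assert fit.range_lo == pytest.approx(0.05)


class TestConvertOD:
    def test_identity_fit(self):
        fit = fit_line([(x, x) for x in (1, 2, 5)])
        assert convert_od(5.0, fit).value == pytest.approx(5.0)

    def test_affine_algebra(self):
        fit = fit_line([(x, 0.5 * x + 0.1) for x in (1, 2, 5, 8)])
        got = convert_od(1.1, fit, direction="plate_to_cuvette")
        assert got.value == pytest.approx(2.0)
        assert not got.out_of_range

    def test_out_of_range_flagged_not_rejected(self):
        fit = fit_line([(x, 0.5 * x) for x in (0.05, 1, 6, 12)])
        got = convert_od(15.0, fit, direction="plate_to_cuvette")
        assert got.value == pytest.approx(30.0)
        assert got.out_of_range

    def test_zero_slope_not_invertible(self):
        from picls.calibration import CalibrationFit
        fit = CalibrationFit(slope=0.0, intercept=1.0, r_squared=0.0,
                             n_points=3, range_lo=0.0, range_hi=1.0)
        with pytest.raises(NonInvertibleError):
            convert_od(1.0, fit)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 12.0), st.floats(0.2, 2.0), st.floats(-0.5, 0.5))
    def test_round_trip_identity(self, value, slope, intercept):
        fit = fit_line([(x, slope * x + intercept) for x in (0.05, 1, 6, 12)])
        fwd = convert_od(value, fit, direction="cuvette_to_plate")
        back = convert_od(fwd.value, fit, direction="plate_to_cuvette")
        assert back.value == pytest.approx(value, rel=1e-9, abs=1e-9)


class TestComparePlateTypes:
    def fit_points(self, scale=1.0, cv=0.0, seed=0):
        rng = np.random.default_rng(seed)
        pts = [CalibrationPoint(x, 0.8 * x, scale * 100 * x * (1 + e))
               for x, e in zip(np.linspace(0.05, 12, 12),
                               rng.normal(0, cv, 12))]
        fit = fit_line([(p.cuvette_od, p.fluorescence) for p in pts])
        return fit, pts

    def test_identical_sets_are_equivalent(self):
        fit, pts = self.fit_points()
        cmp = compare_plate_types(fit, pts, fit, pts, seed=0)
        assert cmp.slope_ratio == pytest.approx(1.0)
        assert cmp.verdict == "equivalent"

    def test_ten_percent_dimmer_plate_detected_at_tight_margin(self):
        black_fit, black = self.fit_points(scale=1.0, cv=0.02, seed=1)
        clear_fit, clear = self.fit_points(scale=0.9, cv=0.02, seed=2)
        cmp5 = compare_plate_types(black_fit, black, clear_fit, clear,
                                   margin=0.05, seed=3)
        assert cmp5.slope_ratio == pytest.approx(0.9, abs=0.02)
        assert cmp5.verdict == "different"
        assert cmp5.ci_high < 1.0
        cmp20 = compare_plate_types(black_fit, black, clear_fit, clear,
                                    margin=0.20, seed=3)
        assert cmp20.verdict == "equivalent"

    def test_non_overlapping_ranges_incomparable(self):
        black_fit, black = self.fit_points()
        lo_pts = [CalibrationPoint(x, 0.8 * x, 100 * x)
                  for x in np.linspace(20, 48, 6)]
        lo_fit = fit_line([(p.cuvette_od, p.fluorescence) for p in lo_pts])
        with pytest.raises(IncomparableError):
            compare_plate_types(black_fit, black, lo_fit, lo_pts)
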