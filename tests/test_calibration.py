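"""Stern-Volmer forward/inverse model, fitting, and LOD/LOQ metrology."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pyoptode import (
    CalibrationCurve,
    CalibrationPoint,
    compare_calibrations,
    compute_detection_limits,
    fit_calibration,
    invert_calibration,
    load_registry,
    normalize_ratios,
    save_registry,
    stern_volmer_forward,
    summarize_lods,
)
from pyoptode.calibration import LOQ_LOD_RATIO, read_points_csv
from pyoptode.errors import (
    DegenerateCalibrationError,
    DomainError,
    InputError,
    MetrologyError,
    NormalizationError,
    OutOfRangeError,
    SuperSaturationWarning,
)

from conftest import HIGH_PH_KSV, HIGH_PH_R0, bisect_invert


class TestForwardModel:
    def test_zero_oxygen_returns_r0(self, cal_larsen):
        assert stern_volmer_forward(0.0, cal_larsen) == cal_larsen.R0

    def test_high_oxygen_approaches_nonquenchable_floor(self):
        cal = CalibrationCurve("d", R0=2.0, Ksv=0.01, alpha=0.1)
        assert stern_volmer_forward(1e9, cal) == pytest.approx(0.2, rel=1e-5)

    def test_published_disk_a_day0_coefficients(self):
        # disk a at day 0: R0=1.881, Ksv=0.012, full quench at 100% saturation
        cal = CalibrationCurve("a", R0=HIGH_PH_R0[0][0], Ksv=HIGH_PH_KSV[0][0], alpha=0.0)
        assert stern_volmer_forward(100.0, cal) == pytest.approx(1.881 / 2.2, abs=1e-12)

    def test_negative_concentration_rejected(self, cal_larsen):
        with pytest.raises(DomainError):
            stern_volmer_forward(-1.0, cal_larsen)

    def test_strictly_decreasing_in_concentration(self, cal_larsen):
        C = np.linspace(0, 200, 400)
        R = stern_volmer_forward(C, cal_larsen)
        assert np.all(np.diff(R) < 0)


class TestInversion:
    def test_ratio_at_r0_maps_to_zero(self, cal_larsen):
        assert invert_calibration(cal_larsen.R0, cal_larsen) == 0.0

    def test_round_trip(self):
        cal = CalibrationCurve("d", R0=1.9, Ksv=0.011, alpha=0.05)
        C = 37.5
        assert invert_calibration(stern_volmer_forward(C, cal), cal) == pytest.approx(
            C, rel=1e-9
        )

    def test_matches_bisection_oracle_on_published_point(self):
        cal = CalibrationCurve("a", R0=1.881, Ksv=0.012, alpha=0.0)
        closed = invert_calibration(0.855, cal)
        oracle = bisect_invert(0.855, 1.881, 0.012, 0.0)
        assert closed == pytest.approx(oracle, abs=1e-6)
        assert closed == pytest.approx(100.0, abs=1e-3)

    def test_super_saturated_ratio_clamps_with_warning(self, cal_larsen):
        with pytest.warns(SuperSaturationWarning):
            assert invert_calibration(cal_larsen.R0 * 1.05, cal_larsen) == 0.0

    def test_ratio_below_floor_rejected(self):
        cal = CalibrationCurve("d", R0=2.0, Ksv=0.01, alpha=0.1)
        with pytest.raises(OutOfRangeError):
            invert_calibration(0.19, cal)

    def test_degenerate_calibration_rejected(self):
        cal = CalibrationCurve("d", R0=2.0, Ksv=0.0, alpha=0.0)
        with pytest.raises(DegenerateCalibrationError):
            invert_calibration(1.0, cal)

    @settings(derandomize=True, max_examples=200)
    @given(
        R0=st.floats(0.5, 3.0),
        Ksv=st.floats(1e-3, 0.05),
        alpha=st.floats(0.0, 0.5),
        C=st.floats(0.0, 150.0),
    )
    def test_inverse_property_random_parameters(self, R0, Ksv, alpha, C):
        """Closed-form inversion undoes the forward model across the domain."""
        cal = CalibrationCurve("d", R0=R0, Ksv=Ksv, alpha=alpha)
        R = stern_volmer_forward(C, cal)
        assert invert_calibration(R, cal) == pytest.approx(C, rel=1e-9, abs=1e-9)


class TestFit:
    TRUTH = dict(R0=1.95, Ksv=0.010, alpha=0.08)
    GRID = np.array([0.0, 20.0, 40.0, 60.0, 80.0, 100.0])

    def _points(self, R0, Ksv, alpha, grid=None, noise=None):
        grid = self.GRID if grid is None else grid
        cal = CalibrationCurve("t", R0=R0, Ksv=Ksv, alpha=alpha)
        R = stern_volmer_forward(grid, cal)
        if noise is not None:
            R = R + noise
        return [CalibrationPoint(c, r) for c, r in zip(grid, R)]

    def test_exact_recovery_from_noiseless_points(self):
        fit = fit_calibration(self._points(**self.TRUTH), fix_alpha_zero=False)
        assert fit.R0 == pytest.approx(1.95, abs=1e-6)
        assert fit.Ksv == pytest.approx(0.010, abs=1e-6)
        assert fit.alpha == pytest.approx(0.08, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_round_trip_through_published_disk_b(self):
        # disk b day 0: two-parameter row (R0=1.948, Ksv=0.009)
        fit = fit_calibration(self._points(R0=1.948, Ksv=0.009, alpha=0.0))
        assert fit.R0 == pytest.approx(1.948, abs=1e-6)
        assert fit.Ksv == pytest.approx(0.009, abs=1e-6)
        assert fit.alpha == 0.0

    def test_deterministic_given_identical_inputs(self):
        pts = self._points(**self.TRUTH, noise=0.003 * np.sin(self.GRID))
        a = fit_calibration(pts, fix_alpha_zero=False)
        b = fit_calibration(pts, fix_alpha_zero=False)
        assert (a.R0, a.Ksv, a.alpha) == (b.R0, b.Ksv, b.alpha)

    def test_too_few_distinct_concentrations_rejected(self):
        pts = self._points(**self.TRUTH)[:2]
        with pytest.raises(InputError):
            fit_calibration(pts)
        with pytest.raises(InputError):
            fit_calibration(self._points(**self.TRUTH)[:3], fix_alpha_zero=False)

    def test_bias_shrinks_with_noise(self):
        """Ksv estimator error decreases as ratio noise goes to zero."""
        errs = {}
        for sd in (0.01, 0.001):
            e = []
            for seed in range(30):
                rng = np.random.default_rng(seed)
                pts = self._points(**self.TRUTH, noise=rng.normal(0, sd, self.GRID.size))
                fit = fit_calibration(pts, fix_alpha_zero=False)
                e.append(abs(fit.Ksv - 0.010))
            errs[sd] = np.median(e)
        assert errs[0.001] < errs[0.01]


class TestDetectionLimits:
    def test_direct_substitution(self):
        # population sd of {3.0, 3.6} is 0.3; unit slope => LOD = 3.3*0.3 = 0.99
        lin = [(c, c) for c in np.linspace(0.4, 40, 20)]
        dl = compute_detection_limits([3.0, 3.6], lin, (0.4, 40.0))
        assert dl.sigma == pytest.approx(0.3)
        assert dl.slope_m == pytest.approx(1.0)
        assert dl.lod == pytest.approx(0.99, abs=1e-12)

    def test_noiseless_replicates_give_zero_limits(self):
        lin = [(c, c) for c in np.linspace(0.4, 40, 10)]
        dl = compute_detection_limits([3.5, 3.5, 3.5], lin)
        assert dl.lod == 0.0 and dl.loq == 0.0

    def test_loq_lod_ratio_exact(self):
        lin = [(c, 0.97 * c) for c in np.linspace(0.4, 40, 10)]
        dl = compute_detection_limits([3.1, 3.4, 3.6], lin)
        assert dl.loq == dl.lod * LOQ_LOD_RATIO

    def test_mixed_concentration_replicates_rejected(self):
        lin = [(c, c) for c in np.linspace(0.4, 40, 10)]
        with pytest.raises(InputError):
            compute_detection_limits([(3.3, 3.1), (5.0, 5.2)], lin)

    def test_zero_slope_rejected(self):
        lin = [(c, 1.0) for c in np.linspace(0.4, 40, 10)]
        with pytest.raises(MetrologyError):
            compute_detection_limits([3.0, 3.6], lin)

    def test_points_outside_linear_range_excluded(self):
        # points beyond 40% have a different slope and must not bias m
        inside = [(c, c) for c in np.linspace(0.4, 40, 10)]
        outside = [(c, 0.5 * c) for c in (60.0, 80.0)]
        dl = compute_detection_limits([3.0, 3.6], inside + outside, (0.4, 40.0))
        assert dl.slope_m == pytest.approx(1.0)


class TestLodSummary:
    def test_published_per_disk_values(self):
        mean, sd = summarize_lods([1.15, 0.58, 1.61])
        assert round(mean, 1) == 1.1
        assert round(sd, 1) == 0.4

    def test_constant_input_zero_sd(self):
        _, sd = summarize_lods([0.9, 0.9, 0.9])
        assert sd == 0.0

    def test_single_value_rejected(self):
        with pytest.raises(InputError):
            summarize_lods([1.0])


class TestCompareCalibrations:
    def test_identical_samples_not_rejected(self):
        a = np.linspace(0, 100, 50)
        stat, p, reject = compare_calibrations(a, a)
        assert stat == 0.0 and not reject

    def test_disjoint_support_maximal_statistic(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 1, 50)
        b = rng.uniform(10, 11, 50)
        stat, p, reject = compare_calibrations(a, b)
        assert stat == 1.0 and reject

    def test_small_samples_rejected(self):
        with pytest.raises(InputError):
            compare_calibrations([1.0], [1.0, 2.0])

    def test_type_i_error_controlled_at_nominal_level(self):
        """Null rejection rate stays at or below ~5% (KS is conservative at n=30)."""
        rng = np.random.default_rng(42)
        rejections = 0
        n_reps = 400
        for _ in range(n_reps):
            a = rng.normal(50, 5, 30)
            b = rng.normal(50, 5, 30)
            rejections += compare_calibrations(a, b)[2]
        rate = rejections / n_reps
        assert 0.01 <= rate <= 0.075


class TestNormalize:
    @pytest.mark.parametrize(
        "raw, expected",
        [([2.0, 1.0, 0.5], [1.0, 0.5, 0.25]), ([1.0], [1.0])],
    )
    def test_examples(self, raw, expected):
        assert normalize_ratios(raw) == pytest.approx(expected)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1e6), min_size=1, max_size=30))
    def test_max_is_always_one(self, raw):
        assert np.max(normalize_ratios(raw)) == pytest.approx(1.0)

    def test_all_zero_rejected(self):
        with pytest.raises(NormalizationError):
            normalize_ratios([0.0, 0.0])


class TestPersistence:
    def test_registry_round_trip_lossless(self, tmp_path):
        import math

        d1 = CalibrationCurve(
            "d1", R0=1.9000000000000004, Ksv=0.011, alpha=0.05,
            r_squared=0.99871234567890123, resid_sd=3.2e-3, temperature_C=21.0,
        )
        nan_diag = CalibrationCurve("d2", R0=1.881, Ksv=0.012, ratio_def="simple")
        path = tmp_path / "registry.json"
        save_registry(path, {"d1": d1, "d2": nan_diag}, provenance={"operator": "mk"})
        loaded = load_registry(path)
        assert loaded["d1"] == d1  # bit-exact floats through JSON
        assert math.isnan(loaded["d2"].r_squared)
        assert loaded["d2"].created_at == nan_diag.created_at

    def test_points_csv_reports_bad_line(self, tmp_path):
        path = tmp_path / "pts.csv"
        path.write_text(
            "disk_id,true_saturation_pct,ratio,replicate_id\n"
            "a,0,1.9,0\n"
            "a,not_a_number,1.5,0\n"
        )
        with pytest.raises(InputError, match="row 3"):
            read_points_csv(path)
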