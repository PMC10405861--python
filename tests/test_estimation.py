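"""Bias estimators: smoothing, DvM fitting, resampling inference, model-free."""

import numpy as np
import pytest
from scipy.stats import kstest

from serialdep.circular import circ_mean
from serialdep.dvm import DvMParams, dvm_value, params_from_amplitude_fwhm
from serialdep.estimation import (
    X_GRID,
    bootstrap_sd,
    estimate_bias,
    estimate_with_inference,
    fit_dvm,
    model_free_bias,
    model_free_permutation,
    moving_average_curve,
    permutation_test,
    range_covering_area,
)


class TestMovingAverageCurve:
    def test_constant_errors_give_constant_curve(self):
        rng = np.random.default_rng(0)
        d = rng.uniform(-90, 90, 200)
        curve = moving_average_curve(d, np.full(200, 3.5))
        defined = ~np.isnan(curve.y_smooth)
        np.testing.assert_allclose(curve.y_smooth[defined], 3.5, atol=1e-9)

    def test_single_trial_defines_only_its_window(self):
        curve = moving_average_curve([0.0], [2.0])
        defined = ~np.isnan(curve.y_smooth)
        assert set(X_GRID[defined]) == set(np.arange(-10.0, 11.0))
        np.testing.assert_allclose(curve.y_smooth[defined], 2.0)

    def test_matches_brute_force_windowed_circular_mean(self):
        rng = np.random.default_rng(1)
        p = params_from_amplitude_fwhm(3.0, 35.0)
        d = rng.uniform(-90, 90, 400)
        e = dvm_value(d, p) + rng.normal(0, 4, 400)
        curve = moving_average_curve(d, e)
        for x in (-85.0, -30.0, 0.0, 42.0, 88.0):
            delta = np.mod(d - x + 90.0, 180.0) - 90.0
            members = np.abs(delta) <= 10.0
            i = int(np.where(X_GRID == x)[0][0])
            if members.any():
                assert curve.y_smooth[i] == pytest.approx(
                    circ_mean(e[members]), abs=1e-9
                )
                assert curve.n_per_point[i] == members.sum()

    def test_window_wraps_across_90(self):
        # distances near +90 and -90 are physically adjacent
        curve = moving_average_curve([88.0, -88.0], [4.0, 4.0])
        i = int(np.where(X_GRID == 90.0)[0][0])
        assert curve.n_per_point[i] == 2


class TestFitDvM:
    def test_all_zero_errors_give_flat_fit(self):
        fit = fit_dvm(np.linspace(-90, 90, 50), np.zeros(50))
        assert fit.amplitude_deg == 0.0
        assert fit.fwhm_deg is None
        assert np.isnan(fit.r2)

    @pytest.mark.parametrize("amp, fwhm", [(3.0, 35.0), (-2.0, 28.0), (8.0, 20.0)])
    def test_noiseless_pooled_recovery(self, amp, fwhm):
        p = params_from_amplitude_fwhm(amp, fwhm)
        rng = np.random.default_rng(2)
        x = rng.uniform(-90, 90, 400)
        fit = fit_dvm(x, dvm_value(x, p), "pooled")
        assert fit.params.a == pytest.approx(p.a, rel=1e-3)
        assert fit.params.kappa == pytest.approx(p.kappa, rel=1e-3)
        assert fit.amplitude_deg == pytest.approx(amp, rel=1e-3)
        assert fit.r2 > 1 - 1e-9

    def test_noiseless_subject_pipeline_recovery(self):
        """The smoothing-aware subject fit undoes the moving-average
        attenuation: noiseless data return the generating parameters."""
        p = params_from_amplitude_fwhm(4.0, 18.0)
        rng = np.random.default_rng(3)
        d = rng.uniform(-90, 90, 600)
        fit = estimate_bias(d, dvm_value(d, p), "subject")
        assert fit.amplitude_deg == pytest.approx(4.0, rel=2e-3)
        assert fit.fwhm_deg == pytest.approx(18.0, rel=2e-3)

    def test_repulsive_observer_yields_negative_amplitude(self):
        p = params_from_amplitude_fwhm(-2.0, 30.0)
        rng = np.random.default_rng(4)
        d = rng.uniform(-90, 90, 480)
        e = dvm_value(d, p) + rng.normal(0, 5, 480)
        assert estimate_bias(d, e, "subject").amplitude_deg < 0

    def test_too_few_points_signalled(self):
        with pytest.raises(ValueError, match="at least 10"):
            fit_dvm([0.0] * 5, [1.0] * 5)

    def test_amplitude_consistent_with_curve_readout(self):
        from serialdep.dvm import curve_amplitude

        rng = np.random.default_rng(5)
        d = rng.uniform(-90, 90, 300)
        e = rng.normal(0, 8, 300)
        fit = estimate_bias(d, e, "subject")
        assert fit.amplitude_deg == pytest.approx(curve_amplitude(fit.params))


class TestPermutationTest:
    def test_all_zero_errors_give_p_one(self):
        rng = np.random.default_rng(6)
        d = rng.uniform(-90, 90, 100)
        assert permutation_test(d, np.zeros(100), "subject", n_perm=100, seed=1) == 1.0

    def test_strong_effect_detected(self):
        """A 3-deg attractive bias at low noise is clearly significant.

        The permutation null of the DvM amplitude is heavy-tailed (shallow
        small-kappa boundary fits latch onto broad noise undulations, the
        'spurious fits' known for this model), so even strong effects do
        not reach arbitrarily small p-values at single-subject trial
        counts; the check is detection well below alpha.
        """
        p = params_from_amplitude_fwhm(3.0, 35.0)
        rng = np.random.default_rng(7)
        d = rng.uniform(-90, 90, 480)
        e = dvm_value(d, p) + rng.normal(0, 5, 480)
        assert (
            permutation_test(d, e, "subject", n_perm=1000, sided="two", seed=8)
            <= 0.02
        )
        # the pooled group-level route at larger n is unambiguous
        d2 = rng.uniform(-90, 90, 5000)
        e2 = dvm_value(d2, p) + rng.normal(0, 5, 5000)
        assert (
            permutation_test(d2, e2, "group", n_perm=1000, sided="one", seed=9)
            <= 0.001
        )

    def test_one_sided_counts_upper_tail_only(self):
        p = params_from_amplitude_fwhm(-3.0, 35.0)  # strongly repulsive
        rng = np.random.default_rng(9)
        d = rng.uniform(-90, 90, 480)
        e = dvm_value(d, p) + rng.normal(0, 5, 480)
        p_one = permutation_test(d, e, "subject", n_perm=200, sided="one", seed=10)
        p_two = permutation_test(d, e, "subject", n_perm=200, sided="two", seed=10)
        assert p_two <= 0.01 and p_one > 0.5

    def test_null_p_values_uniform(self):
        """Under exchangeability the permutation p-values are (super-)
        uniform; a KS test against U(0,1) must not reject wildly."""
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(200):
            d = rng.uniform(-90, 90, 200)
            e = rng.normal(0, 11, 200)
            ps.append(
                permutation_test(
                    d, e, "subject", n_perm=100, sided="two",
                    seed=int(rng.integers(2**31)),
                )
            )
        assert kstest(ps, "uniform").pvalue > 0.01
        assert 0.01 <= np.mean(np.asarray(ps) < 0.05) <= 0.12


class TestBootstrap:
    def test_zero_errors_zero_sd(self):
        rng = np.random.default_rng(12)
        d = rng.uniform(-90, 90, 100)
        assert bootstrap_sd(d, np.zeros(100), "group", n_boot=50, seed=1) == 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(13)
        d = rng.uniform(-90, 90, 200)
        e = rng.normal(0, 8, 200)
        a = bootstrap_sd(d, e, "group", n_boot=100, seed=5)
        b = bootstrap_sd(d, e, "group", n_boot=100, seed=5)
        assert a == b

    def test_sd_shrinks_with_sample_size(self):
        p = params_from_amplitude_fwhm(2.0, 35.0)
        rng = np.random.default_rng(14)
        d = rng.uniform(-90, 90, 1920)
        e = dvm_value(d, p) + rng.normal(0, 11, 1920)
        small = bootstrap_sd(d[:480], e[:480], "group", n_boot=300, seed=6)
        large = bootstrap_sd(d, e, "group", n_boot=300, seed=6)
        assert small > 1.5 * large  # roughly 1/sqrt(n): factor 2 expected


class TestModelFree:
    def test_small_angle_example(self):
        mf = model_free_bias([30.0, 40.0, -30.0, -40.0], [2.0, 4.0, -1.0, -3.0], 54.0)
        assert mf.bias_deg == pytest.approx(5.0, abs=1e-9)
        assert (mf.n_cw, mf.n_ccw) == (2, 2)

    def test_sign_symmetric_errors_give_zero_bias(self):
        rng = np.random.default_rng(15)
        d = np.concatenate([rng.uniform(1, 54, 5000), -rng.uniform(1, 54, 5000)])
        e = rng.normal(0, 11, 10000)
        assert abs(model_free_bias(d, e, 54.0).bias_deg) < 0.5

    def test_matches_two_bin_oracle_on_attractive_observer(self):
        p = params_from_amplitude_fwhm(3.0, 35.0)
        rng = np.random.default_rng(16)
        d = rng.uniform(-90, 90, 2000)
        e = dvm_value(d, p) + rng.normal(0, 11, 2000)
        mf = model_free_bias(d, e, 54.0)
        cw = (d > 0) & (d <= 54.0)
        ccw = (d < 0) & (d >= -54.0)
        oracle = circ_mean(e[cw]) - circ_mean(e[ccw])
        assert mf.bias_deg == pytest.approx(oracle, abs=1e-9)
        assert mf.bias_deg > 0

    def test_zero_distance_joins_neither_bin(self):
        mf = model_free_bias([0.0, 10.0, -10.0], [99.0, 2.0, -2.0], 54.0)
        assert mf.bias_deg == pytest.approx(4.0)
        assert (mf.n_cw, mf.n_ccw) == (1, 1)

    def test_empty_side_signalled(self):
        with pytest.raises(ValueError, match="one side"):
            model_free_bias([10.0, 20.0], [1.0, 2.0], 54.0)

    def test_permutation_null_and_strong_effect(self):
        rng = np.random.default_rng(17)
        d = rng.uniform(-54, 54, 300)
        assert model_free_permutation(d, np.zeros(300), 54.0, 200, seed=1) == 1.0
        p = params_from_amplitude_fwhm(4.0, 35.0)
        e = dvm_value(d, p) + rng.normal(0, 5, 300)
        assert model_free_permutation(d, e, 54.0, 500, seed=2) <= 0.01

    def test_model_free_type_i_error_near_alpha(self):
        rng = np.random.default_rng(18)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            d = rng.uniform(-54, 54, 200)
            e = rng.normal(0, 11, 200)
            p = model_free_permutation(
                d, e, 54.0, 100, seed=int(rng.integers(2**31))
            )
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.09


class TestInferenceBundleAndArea:
    def test_estimate_with_inference_populates_fields(self):
        p = params_from_amplitude_fwhm(3.0, 35.0)
        rng = np.random.default_rng(19)
        d = rng.uniform(-90, 90, 480)
        e = dvm_value(d, p) + rng.normal(0, 8, 480)
        fit = estimate_with_inference(
            d, e, level="group", n_perm=200, n_boot=100, seed=20
        )
        assert fit.p_perm is not None and fit.p_perm <= 0.05
        assert fit.boot_sd is not None and fit.boot_sd > 0

    def test_range_covering_area_monotone_and_bounded(self):
        p = params_from_amplitude_fwhm(2.0, 35.0)
        l_half = range_covering_area(p, 0.5)
        l_full = range_covering_area(p, 0.998)
        assert 0 < l_half < l_full <= 90.0
        with pytest.raises(ValueError):
            range_covering_area(DvMParams(a=0.0, kappa=1.0), 0.998)
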