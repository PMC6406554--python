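"""FRAP pipeline: correction, normalization, fits, D_app, mobile fraction."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from llpskit import synth
from llpskit.frap import (
    BleachProfile, FrapTrace, analyze_frap, apparent_diffusion,
    correct_photofading, fit_double_exponential, fit_effective_radius,
    fit_single_exponential, mobile_fraction, normalize_recovery,
)

LN2 = math.log(2.0)


def _manual_trace(ble, ref, bg, bleach_idx=1, rn=2.0):
    n = len(ble)
    return FrapTrace(time=np.arange(n, dtype=float),
                     intensity_bleach=np.asarray(ble, float),
                     intensity_ref=np.asarray(ref, float),
                     intensity_bg=np.asarray(bg, float),
                     bleach_frame_index=bleach_idx, nominal_radius_rn=rn)


class TestPhotofadingCorrection:
    def test_ratio_correction_arithmetic(self):
        # Ri=100 (pre-bleach), R(t)=80, I_bleached=40, background 0 -> 50
        tr = _manual_trace([100, 40, 40], [100, 80, 80], [0, 0, 0])
        corrected = correct_photofading(tr)
        assert corrected[1] == pytest.approx(50.0, abs=1e-12)

    def test_constant_reference_is_identity(self):
        ble = [90.0, 20.0, 40.0, 60.0]
        tr = _manual_trace(ble, [100] * 4, [0] * 4)
        np.testing.assert_allclose(correct_photofading(tr), ble, rtol=1e-14)

    def test_background_subtracted_before_ratio(self):
        # with background 10: Cf = (100-10)/(80-10), I = 40-10
        tr = _manual_trace([100, 40, 40], [100, 80, 80], [10, 10, 10])
        corrected = correct_photofading(tr)
        assert corrected[1] == pytest.approx(90.0 / 70.0 * 30.0, rel=1e-12)

    def test_correction_inverts_photofading(self):
        """Corrected faded trace equals the unfaded trace up to the constant
        pre-bleach gain (which downstream normalization removes)."""
        kw = dict(tau_a=10.0, mobile_fraction=0.7, noise_sd=0.0,
                  bleach_depth=0.8)
        faded = synth.generate_frap_trace(
            synth.FrapGroundTruth(photofade_rate=0.01, **kw), 300, seed=5)
        flat = synth.generate_frap_trace(
            synth.FrapGroundTruth(photofade_rate=0.0, **kw), 300, seed=5)
        c_faded = correct_photofading(faded)
        c_flat = correct_photofading(flat)
        pre = slice(0, faded.bleach_frame_index)
        np.testing.assert_allclose(c_faded / np.mean(c_faded[pre]),
                                   c_flat / np.mean(c_flat[pre]), atol=1e-9)

    def test_nonpositive_reference_names_frame(self):
        tr = _manual_trace([100, 40, 40], [100, 5, 80], [10, 10, 10])
        with pytest.raises(ValueError, match="frame 1"):
            correct_photofading(tr)


class TestNormalization:
    def test_shift_then_scale(self):
        corrected = np.array([10.0, 2.0, 4.0, 6.0])
        rec = normalize_recovery(corrected, np.arange(4.0), 1)
        np.testing.assert_allclose(rec.intensity_norm, [0.0, 0.5, 1.0])
        np.testing.assert_allclose(rec.time_post_bleach, [0.0, 1.0, 2.0])

    def test_idempotent_on_normalized_series(self):
        y = np.array([1.0, 0.0, 0.3, 0.8, 1.0])
        rec = normalize_recovery(y, np.arange(5.0), 1)
        np.testing.assert_allclose(rec.intensity_norm, y[1:], atol=1e-15)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            normalize_recovery(np.ones(6), np.arange(6.0), 2)

    def test_zero_pinned_to_immediate_post_bleach_within_noise(self):
        # minimum at frame 3 but within noise_tol of the post-bleach point
        corrected = np.array([1.0, 0.20, 0.21, 0.19, 0.5, 0.9])
        rec = normalize_recovery(corrected, np.arange(6.0), 1, noise_tol=0.02)
        assert rec.shift_value == pytest.approx(0.20)
        assert rec.intensity_norm[0] == 0.0

    @given(st.lists(st.floats(min_value=-100, max_value=100), min_size=4,
                    max_size=40))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_output_spans_unit_interval(self, values):
        corrected = np.asarray(values)
        if np.ptp(corrected[1:]) == 0:
            return
        rec = normalize_recovery(corrected, np.arange(len(values), dtype=float), 1)
        assert rec.intensity_norm.min() == pytest.approx(0.0, abs=1e-12)
        assert rec.intensity_norm.max() == pytest.approx(1.0, abs=1e-12)


class TestRecoveryFits:
    def test_single_exponential_exact(self):
        t = np.arange(0.0, 300.0)
        y = 1.0 - np.exp(-t / 10.0)
        rec = normalize_recovery(np.concatenate([[2.0], y]),
                                 np.arange(301.0), 1)
        fit = fit_single_exponential(rec)
        assert fit.tau_a == pytest.approx(10.0, rel=1e-6)
        assert fit.amp_a == pytest.approx(1.0, rel=1e-6)
        assert fit.tau_half == pytest.approx(10.0 * LN2, rel=1e-6)

    def test_single_exponential_amplitude_scaling(self):
        # amplitude < 1 arises when the curve is normalized by a transient max
        t = np.arange(0.0, 300.0)
        from llpskit.frap import NormalizedRecovery
        rec = NormalizedRecovery(time_post_bleach=t,
                                 intensity_norm=0.4 * (1 - np.exp(-t / 10.0)))
        fit = fit_single_exponential(rec)
        assert fit.amp_a == pytest.approx(0.4, rel=1e-6)
        assert fit.tau_a == pytest.approx(10.0, rel=1e-6)

    def test_double_exponential_recovers_parameters(self):
        from llpskit.frap import NormalizedRecovery
        t = np.arange(0.0, 200.0, 0.5)
        y = 0.5 * (1 - np.exp(-t / 2.0)) + 0.5 * (1 - np.exp(-t / 20.0))
        fit = fit_double_exponential(
            NormalizedRecovery(time_post_bleach=t, intensity_norm=y))
        assert fit.tau_a == pytest.approx(2.0, rel=1e-4)
        assert fit.tau_b == pytest.approx(20.0, rel=1e-4)
        assert fit.amp_a == pytest.approx(0.5, rel=1e-4)
        assert fit.amp_b == pytest.approx(0.5, rel=1e-4)

    def test_graphical_half_time_matches_bisection_oracle(self):
        # independent bisection on the *generating* curve
        def gen(t):
            return 0.5 * (1 - np.exp(-t / 2.0)) + 0.5 * (1 - np.exp(-t / 20.0))

        lo, hi = 0.0, 200.0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if gen(mid) < 0.5:
                lo = mid
            else:
                hi = mid
        oracle = 0.5 * (lo + hi)

        from llpskit.frap import NormalizedRecovery
        t = np.arange(0.0, 200.0, 0.5)
        fit = fit_double_exponential(
            NormalizedRecovery(time_post_bleach=t, intensity_norm=gen(t)))
        assert fit.tau_half == pytest.approx(oracle, rel=1e-6)

    def test_double_reduces_to_single_and_halftimes_agree(self):
        from llpskit.frap import NormalizedRecovery
        t = np.arange(0.0, 300.0)
        y = 1.0 - np.exp(-t / 10.0)
        rec = NormalizedRecovery(time_post_bleach=t, intensity_norm=y)
        fit2 = fit_double_exponential(rec)
        assert fit2.tau_half == pytest.approx(10.0 * LN2, rel=1e-6)


class TestEffectiveRadius:
    def test_exact_recovery(self):
        x = np.linspace(-6.0, 6.0, 201)
        prof = synth.generate_bleach_profile(
            synth.ProfileGroundTruth(depth_k=1.0, center_b=0.0,
                                     radius_re=1.2, x_grid=x), seed=0)
        fit = fit_effective_radius(prof)
        assert fit.depth_k == pytest.approx(1.0, rel=1e-6)
        assert fit.center_b == pytest.approx(0.0, abs=1e-8)
        assert fit.radius_re == pytest.approx(1.2, rel=1e-6)

    def test_translation_equivariance(self):
        x = np.linspace(-8.0, 8.0, 201)
        f0 = fit_effective_radius(synth.generate_bleach_profile(
            synth.ProfileGroundTruth(1.0, 0.0, 1.2, x), seed=0))
        f1 = fit_effective_radius(synth.generate_bleach_profile(
            synth.ProfileGroundTruth(1.0, 2.5, 1.2, x), seed=0))
        assert f1.center_b - f0.center_b == pytest.approx(2.5, abs=1e-8)
        assert f1.radius_re == pytest.approx(f0.radius_re, rel=1e-9)

    def test_no_dip_rejected(self):
        prof = BleachProfile(x_um=np.linspace(-5, 5, 50),
                             intensity=np.ones(50))
        with pytest.raises(ValueError, match="no detectable bleach"):
            fit_effective_radius(prof)


class TestApparentDiffusion:
    def test_closed_form(self):
        assert apparent_diffusion(1.0, 1.0, 2.0) == pytest.approx(0.125)

    def test_equal_radius_identity(self):
        r, th = 1.7, 3.3
        assert apparent_diffusion(r, r, th) == pytest.approx(
            r ** 2 / (4 * th), rel=1e-14)

    def test_homogeneity_degree_two(self):
        assert apparent_diffusion(2.0, 2.6, 1.3) == pytest.approx(
            4 * apparent_diffusion(1.0, 1.3, 1.3), rel=1e-14)

    @pytest.mark.parametrize("re,rn,th", [(0, 1, 1), (1, -1, 1), (1, 1, 0)])
    def test_nonpositive_rejected(self, re, rn, th):
        with pytest.raises(ValueError):
            apparent_diffusion(re, rn, th)


class TestMobileFraction:
    def test_full_recovery(self):
        assert mobile_fraction(1.0, 0.2, 1.0) == pytest.approx(1.0)

    def test_partial_recovery(self):
        assert mobile_fraction(1.0, 0.2, 0.52) == pytest.approx(0.4)

    def test_zero_bleach_depth_rejected(self):
        with pytest.raises(ValueError, match="zero bleach depth"):
            mobile_fraction(1.0, 1.0, 1.0)

    def test_generator_round_trip(self):
        gt = synth.FrapGroundTruth(tau_a=10.0, mobile_fraction=0.4,
                                   noise_sd=0.0)
        tr = synth.generate_frap_trace(gt, 310, seed=7)
        res = analyze_frap(tr, model="single")
        assert res.mobile_fraction == pytest.approx(0.4, abs=1e-6)


class TestAnalyzeFrap:
    def test_composed_d_app(self):
        gt = synth.FrapGroundTruth(tau_a=10.0, mobile_fraction=1.0,
                                   nominal_radius_rn=2.0)
        tr = synth.generate_frap_trace(gt, 310, seed=1)
        x = np.linspace(-8.0, 8.0, 201)
        prof = synth.generate_bleach_profile(
            synth.ProfileGroundTruth(1.0, 0.0, 2.0, x), seed=1)
        res = analyze_frap(tr, prof, model="single")
        assert res.d_app == pytest.approx(8.0 / (8 * 10 * LN2), rel=1e-6)

    def test_double_model_on_single_data_same_d_app(self):
        gt = synth.FrapGroundTruth(tau_a=10.0)
        tr = synth.generate_frap_trace(gt, 310, seed=1)
        d1 = analyze_frap(tr, model="single").d_app
        d2 = analyze_frap(tr, model="double").d_app
        assert d2 == pytest.approx(d1, rel=1e-4)

    def test_missing_profile_falls_back_to_rn(self):
        gt = synth.FrapGroundTruth(tau_a=10.0, nominal_radius_rn=2.0)
        tr = synth.generate_frap_trace(gt, 310, seed=1)
        res = analyze_frap(tr, model="single")
        assert res.radius_re == 2.0
        assert any("nominal" in w for w in res.warnings)

    def test_d_app_invariant_to_intensity_gain(self):
        gt = synth.FrapGroundTruth(tau_a=10.0, mobile_fraction=0.6,
                                   photofade_rate=0.005)
        tr = synth.generate_frap_trace(gt, 310, seed=3)
        gained = FrapTrace(time=tr.time,
                           intensity_bleach=7.3 * tr.intensity_bleach,
                           intensity_ref=7.3 * tr.intensity_ref,
                           intensity_bg=7.3 * tr.intensity_bg,
                           bleach_frame_index=tr.bleach_frame_index,
                           nominal_radius_rn=tr.nominal_radius_rn)
        r0 = analyze_frap(tr, model="single")
        r1 = analyze_frap(gained, model="single")
        assert r1.d_app == pytest.approx(r0.d_app, rel=1e-9)
        assert r1.mobile_fraction == pytest.approx(r0.mobile_fraction,
                                                   rel=1e-9)

    def test_monotone_trend_with_crowding_like_series(self):
        """Slower recovery + smaller mobile fraction across conditions must
        map to strictly decreasing D_app and mobile-fraction estimates."""
        taus = [5.0, 10.0, 20.0, 40.0]
        mfs = [1.0, 0.8, 0.6, 0.4]
        d_apps, mf_est = [], []
        for i, (tau, mf) in enumerate(zip(taus, mfs)):
            gt = synth.FrapGroundTruth(tau_a=tau, mobile_fraction=mf,
                                       noise_sd=0.0)
            tr = synth.generate_frap_trace(gt, 60 + int(30 * tau), seed=i)
            res = analyze_frap(tr, model="single")
            d_apps.append(res.d_app)
            mf_est.append(res.mobile_fraction)
        assert np.all(np.diff(d_apps) < 0)
        assert np.all(np.diff(mf_est) < 0)
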