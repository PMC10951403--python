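"""Widefield preprocessing, trial tensors, significance maps, ROIs and d'."""

import numpy as np
import pandas as pd
import pytest

from texgeom import widefield as wf
from texgeom.synth import WidefieldTruth, make_hemo_pair, make_trial_schedule, simulate_widefield_session


class TestChannelDff:
    def test_pure_linear_ramp_maps_to_zero(self):
        t = np.arange(100, dtype=float)
        F = (5.0 + 0.3 * t)[:, None]
        assert np.allclose(wf.channel_dff(F), 0.0, atol=1e-12)

    def test_constant_series_maps_to_zero(self):
        F = np.full((50, 2), 7.0)
        assert np.allclose(wf.channel_dff(F), 0.0, atol=1e-12)

    def test_ramp_plus_sinusoid_recovers_scaled_sinusoid(self):
        t = np.arange(200, dtype=float)
        b, a = 10.0, 0.05
        s = np.sin(2 * np.pi * t / 20)  # orthogonal-ish to the trend over full periods
        F = (b + a * t + s)[:, None]
        out = wf.channel_dff(F)[:, 0]
        # least-squares oracle computed directly in the test
        A = np.vstack([t, np.ones_like(t)]).T
        coef, *_ = np.linalg.lstsq(A, F[:, 0], rcond=None)
        expected = (F[:, 0] - A @ coef) / coef[1]
        assert np.allclose(out, expected, atol=1e-12)
        assert np.corrcoef(out, s)[0, 1] > 0.99

    def test_near_zero_intercept_pixels_masked(self):
        t = np.arange(64, dtype=float)
        F = np.stack([1e-12 + 0.0 * t, 5.0 + 0.1 * t], axis=1)
        with pytest.warns(UserWarning, match="masked"):
            out = wf.channel_dff(F)
        assert np.isnan(out[:, 0]).all() and np.isfinite(out[:, 1]).all()


class TestHemodynamicCorrect:
    def test_regression_oracle_recovers_c_and_d(self):
        blue, violet, truth = make_hemo_pair(rng_seed=0, c_true=0.8, d_true=0.1)
        corrected, fit = wf.hemodynamic_correct(
            blue[:, None], violet[:, None], truth["rate_hz"]
        )
        assert fit.c[0] == pytest.approx(0.8, abs=0.02)
        assert fit.d[0] == pytest.approx(0.1, abs=0.02)
        resid = corrected[:, 0]
        assert np.corrcoef(resid, truth["signal"])[0, 1] > 0.99

    def test_uncorrelated_violet_leaves_blue_untouched(self):
        rng = np.random.default_rng(1)
        blue = rng.standard_normal((4000, 1))
        violet = rng.standard_normal((4000, 1))
        corrected, fit = wf.hemodynamic_correct(blue, violet, 20.0)
        assert abs(fit.c[0]) < 0.05
        assert np.corrcoef(corrected[:, 0], blue[:, 0])[0, 1] > 0.99

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            wf.hemodynamic_correct(np.zeros((10, 1)), np.zeros((10, 1)), 8.0, cutoff_hz=5.0)


@pytest.fixture(scope="module")
def small_schedule():
    return make_trial_schedule("widefield", 9, n_exemplars=5, n_repeats=3, n_blanks=12)


class TestSplitTrials:
    def test_tensor_shape_and_blank_routing(self, small_schedule):
        rate = 20.0
        n = int(small_schedule.duration_s * rate) + 1
        movie = np.zeros((n, 4, 4))
        tens = wf.split_trials(movie, small_schedule, rate)
        assert tens.values.shape[:4] == (2, 4, 5, 3)
        assert tens.blanks.shape[0] == 12
        assert not np.isnan(tens.values).any()

    def test_frame_zero_is_the_onset_frame(self, small_schedule):
        rate = 20.0
        n = int(small_schedule.duration_s * rate) + 1
        movie = np.arange(n, dtype=float)[:, None, None] * np.ones((1, 2, 2))
        tens = wf.split_trials(movie, small_schedule, rate)
        onsets = small_schedule.onset_frames(rate)
        stim = small_schedule.trials[~small_schedule.trials.is_blank]
        row = stim.iloc[0]
        ci = tens.classes.index(row.stim_class)
        fi = tens.families.index(row.family)
        i0 = np.flatnonzero(tens.time_ms == 0.0)[0]
        # the movie value at frame zero equals the onset index for some repeat
        vals = tens.values[ci, fi, row.exemplar_id, :, 0, 0, i0]
        assert onsets[row.name] in vals

    def test_truncated_trials_dropped_with_warning(self, small_schedule):
        rate = 20.0
        movie = np.zeros((int(small_schedule.duration_s * rate) - 40, 2, 2))
        with pytest.warns(UserWarning, match="truncated"):
            tens = wf.split_trials(movie, small_schedule, rate)
        assert np.isnan(tens.values).any()


class TestMaps:
    def test_zero_tensor_gives_zero_peak_map(self, small_schedule):
        rate = 20.0
        movie = np.zeros((int(small_schedule.duration_s * rate) + 1, 3, 3))
        tens = wf.split_trials(movie, small_schedule, rate)
        assert np.array_equal(wf.peak_response_map(tens), np.zeros((3, 3)))

    def test_programmed_gain_map_recovered(self):
        sch = make_trial_schedule("widefield", 2, n_exemplars=4, n_repeats=2, n_blanks=8)
        truth = WidefieldTruth(shape=(16, 16), noise_sd_pct=0.05, artifact_amp_pct=0.0)
        ses = simulate_widefield_session(sch, truth, rng_seed=3)
        bd = wf.channel_dff(ses.blue)
        tens = wf.split_trials(bd * 100, ses.schedule, ses.rate_hz)
        pmap = wf.peak_response_map(tens)
        prog = ses.programmed["gain_map"] + 0.5 * ses.programmed["texmod_map"]
        assert np.corrcoef(pmap.ravel(), prog.ravel())[0, 1] > 0.95

    def test_identical_pre_post_yields_p_of_one(self, small_schedule):
        rate = 20.0
        movie = np.ones((int(small_schedule.duration_s * rate) + 1, 2, 2))
        tens = wf.split_trials(movie, small_schedule, rate)
        p, _ = wf.pixel_significance_map(tens, rng_seed=0)
        assert np.all(p == 1.0)

    def test_strong_modulation_detected_in_lm(self):
        sch = make_trial_schedule("widefield", 4, n_repeats=2, n_blanks=10)
        truth = WidefieldTruth(shape=(24, 24), tex_mod_lm=0.5, noise_sd_pct=0.1)
        ses = simulate_widefield_session(sch, truth, rng_seed=5)
        bd = wf.channel_dff(ses.blue)
        cor, _ = wf.hemodynamic_correct(bd, wf.channel_dff(ses.violet), ses.rate_hz)
        tens = wf.split_trials(cor * 100, ses.schedule, ses.rate_hz)
        p, _ = wf.pixel_significance_map(tens, rng_seed=0)
        assert (p[ses.area_masks["LM"]] < 0.01).mean() > 0.9


class TestROI:
    def test_rectangle_matches_analytic_bounds(self):
        az, el = np.meshgrid(np.linspace(-40, 40, 21), np.linspace(-40, 40, 21))
        roi = wf.roi_from_retinotopy(az, el, az_bounds=(-10, 30), el_bounds=(-30, 30))
        expected = (az >= -10) & (az <= 30) & (el >= -30) & (el <= 30)
        assert np.array_equal(roi.mask, expected)

    def test_full_bounds_reduce_to_area_mask(self):
        az, el = np.meshgrid(np.linspace(-40, 40, 11), np.linspace(-40, 40, 11))
        area = az > 0
        roi = wf.roi_from_retinotopy(az, el, (-50, 50), (-50, 50), area_mask=area)
        assert np.array_equal(roi.mask, area)

    def test_empty_intersection_raises(self):
        az, el = np.meshgrid(np.linspace(0, 10, 5), np.linspace(0, 10, 5))
        with pytest.raises(ValueError, match="empty"):
            wf.roi_from_retinotopy(az, el, az_bounds=(50, 60), el_bounds=(50, 60))

    def test_modulated_fraction_counts(self):
        p = np.array([[0.001, 0.5], [0.005, 0.9]])
        roi = wf.AreaROI(mask=np.ones((2, 2), bool), label="x", az_bounds=(0, 1), el_bounds=(0, 1))
        assert wf.area_modulated_fraction(p, roi, alpha=0.01) == 0.5
        assert wf.area_modulated_fraction(np.full((2, 2), 1e-4), roi) == 1.0
        assert wf.area_modulated_fraction(np.full((2, 2), 0.5), roi) == 0.0


class TestDprime:
    def test_equation_arithmetic(self):
        # mu 2 vs 1, both sd 1 -> d' = 1 exactly
        a = np.array([1.0, 3.0])  # mean 2, population sd 1
        b = np.array([0.0, 2.0])  # mean 1, population sd 1
        assert wf.dprime(a, b) == pytest.approx(1.0, abs=1e-15)

    def test_identical_distributions_give_zero(self):
        x = np.random.default_rng(0).standard_normal(50)
        assert wf.dprime(x, x.copy()) == 0.0

    def test_zero_variance_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wf.dprime(np.ones(5), np.ones(5))

    def test_matches_straight_formula_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a, b = rng.standard_normal(30), rng.standard_normal(30) + 0.4
            expect = (a.mean() - b.mean()) / np.sqrt((a.var() + b.var()) / 2)
            assert wf.dprime(a, b) == pytest.approx(expect, abs=1e-12)

    def test_area_dprime_affine_invariant(self, small_schedule):
        rate = 20.0
        rng = np.random.default_rng(2)
        n = int(small_schedule.duration_s * rate) + 1
        movie = rng.standard_normal((n, 3, 3))
        tens = wf.split_trials(movie, small_schedule, rate)
        roi = wf.AreaROI(np.ones((3, 3), bool), "all", (0, 0), (0, 0))
        res = wf.area_dprime(tens, roi, rng_seed=0)
        tens2 = wf.split_trials(3.0 * movie + 11.0, small_schedule, rate)
        res2 = wf.area_dprime(tens2, roi, rng_seed=0)
        assert res2["dprime"] == pytest.approx(res["dprime"], abs=1e-10)

    def test_null_band_covers_noise_dprime_most_of_the_time(self, small_schedule):
        """The 5th-95th percentile pre-stimulus band should contain the
        post-stimulus d' of pure-noise movies ~90% of the time."""
        rate = 20.0
        roi = wf.AreaROI(np.ones((3, 3), bool), "all", (0, 0), (0, 0))
        n = int(small_schedule.duration_s * rate) + 1
        inside = 0
        for seed in range(20):
            movie = np.random.default_rng(seed).standard_normal((n, 3, 3))
            tens = wf.split_trials(movie, small_schedule, rate)
            res = wf.area_dprime(tens, roi, rng_seed=seed, n_null=100)
            lo, hi = res["null_band"]
            inside += lo < res["dprime"] < hi
        assert inside >= 14  # binomial(20, 0.9) lower tail


class TestFieldGradient:
    def _maps(self, n=41):
        az, el = np.meshgrid(np.linspace(-40, 40, n), np.linspace(40, -40, n))
        return az, el

    def test_programmed_upper_bias_detected(self):
        az, el = self._maps()
        dmap = 0.5 + 0.01 * el + np.random.default_rng(3).normal(0, 0.05, el.shape)
        res = wf.field_gradient_dprime(dmap, az, el)
        assert res["upper_mean"] > res["lower_mean"]
        assert res["p_upper_lower"] < 0.01

    def test_symmetric_map_shows_no_gradient(self):
        az, el = self._maps()
        dmap = np.full(el.shape, 0.7)
        dmap += np.random.default_rng(4).normal(0, 0.01, el.shape)
        res = wf.field_gradient_dprime(dmap, az, el)
        assert abs(res["upper_mean"] - res["lower_mean"]) < 0.01

    def test_flipping_elevation_sign_swaps_comparison(self):
        az, el = self._maps()
        dmap = 0.5 + 0.01 * el
        a = wf.field_gradient_dprime(dmap, az, el)
        b = wf.field_gradient_dprime(dmap, az, -el)
        assert a["upper_mean"] == pytest.approx(b["lower_mean"])
        assert a["lower_mean"] == pytest.approx(b["upper_mean"])
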