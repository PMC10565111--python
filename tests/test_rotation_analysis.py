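"""Orientation-kinematics extraction and in-repo Wilcoxon machinery."""

import itertools

import numpy as np
import pytest
from scipy import stats
from scipy.spatial.transform import Rotation

from lanternjump import dynamics_sim as ds
from lanternjump import rotation_analysis as ra


def uniform_rotation_track(rate_rev_s=10.0, duration=200.0, dt=1.0):
    t = np.arange(0.0, duration + dt / 2, dt)
    ang = 2 * np.pi * rate_rev_s * t / 1000.0
    u = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
    return ra.OrientationTrack(times=t, u_cc=u)


class TestOmegaCcSeries:
    def test_uniform_planar_rotation(self):
        track = uniform_rotation_track(10.0)
        series = ra.omega_cc_series(track)
        assert np.allclose(series.omega_cc, 10.0, rtol=1e-9)
        assert series.omega_to == pytest.approx(10.0)

    def test_pure_roll_is_invisible(self):
        """Spin about the cranial-caudal axis leaves u_cc fixed."""
        t = np.arange(0.0, 50.0)
        u = np.tile([1.0, 0.0, 0.0], (len(t), 1))
        series = ra.omega_cc_series(ra.OrientationTrack(times=t, u_cc=u))
        assert np.allclose(series.omega_cc, 0.0, atol=1e-12)

    def test_matches_great_circle_oracle(self):
        """Per-step angles agree with an independent arccos great-circle
        computation on a simulated precessing track."""
        sch = ds.schedule_from_moments([2.0, 2.0, 3.0], [2.0, 2.0, 3.0],
                                       t_ext=1.0)
        res = ds.simulate_rotation([3.0, 0.0, 8.0], sch, duration=100.0,
                                   dt=0.02, sample_every=50)
        u = res.cranial_caudal_axis()
        series = ra.omega_cc_series(
            ra.OrientationTrack(times=res.times, u_cc=u))
        dots = np.clip(np.einsum("ij,ij->i", u[:-1], u[1:]), -1.0, 1.0)
        oracle = np.arccos(dots) / np.diff(res.times) * 1000 / (2 * np.pi)
        assert np.allclose(series.omega_cc, oracle, atol=1e-9)

    def test_invariant_under_global_rotation(self):
        track = uniform_rotation_track(7.0)
        rot = Rotation.from_rotvec([0.4, -1.1, 0.7])
        rotated = ra.OrientationTrack(times=track.times,
                                      u_cc=rot.apply(track.u_cc))
        a = ra.omega_cc_series(track)
        b = ra.omega_cc_series(rotated)
        assert np.allclose(a.omega_cc, b.omega_cc, atol=1e-9)

    def test_zero_length_frames_interpolated_and_flagged(self):
        t = np.arange(0.0, 10.0)
        ang = 0.1 * t
        u = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
        u[4] = 0.0
        track = ra.OrientationTrack(times=t, u_cc=u)
        assert 4 in track.flagged_frames
        series = ra.omega_cc_series(track)
        assert np.all(np.isfinite(series.omega_cc))

    def test_omega_ext_taken_near_extension_time(self):
        track = uniform_rotation_track(10.0)
        series = ra.omega_cc_series(track, t_ext=40.0)
        assert series.omega_ext == pytest.approx(10.0)
        assert series.ratio_ext_to == pytest.approx(1.0)


class TestInitialAngularVelocity:
    def test_identical_attitudes_zero(self):
        r = Rotation.from_euler("ZYX", [10, 20, 30], degrees=True)
        assert np.allclose(ra.initial_angular_velocity(r, r), 0.0)

    def test_18_degrees_in_5ms_is_10_rev_s(self):
        r0 = Rotation.identity()
        r5 = Rotation.from_euler("z", 18.0, degrees=True)
        omega = ra.initial_angular_velocity(r0, r5)
        assert np.allclose(omega, [0.0, 0.0, 10.0], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_round_trip_reintegration(self, seed):
        rng = np.random.default_rng(seed)
        r0 = Rotation.from_rotvec(rng.normal(0, 0.7, 3))
        r5 = Rotation.from_rotvec(rng.normal(0, 0.7, 3))
        omega = ra.initial_angular_velocity(r0, r5)  # rev/s, spatial frame
        rotvec = np.asarray(omega) * 2 * np.pi * 5.0 / 1000.0
        recomposed = Rotation.from_rotvec(rotvec) * r0
        assert np.allclose(recomposed.as_matrix(), r5.as_matrix(), atol=1e-9)

    def test_aliased_rotation_rejected(self):
        r0 = Rotation.identity()
        r5 = Rotation.from_euler("z", 180.0, degrees=True)
        with pytest.raises(ValueError, match="aliased"):
            ra.initial_angular_velocity(r0, r5)


class TestFitDragDecay:
    def test_noiseless_half_life_recovered(self):
        t = np.arange(0.0, 150.0)
        w = 20.0 * 2.0 ** (-t / 76.0)
        series = ra.OmegaCcSeries(times=t, omega_cc=w)
        fit = ra.fit_drag_decay(series, n_bootstrap=0)
        assert fit.t_char == pytest.approx(76.0, rel=1e-3)
        assert fit.omega_0 == pytest.approx(20.0, rel=1e-3)

    def test_constant_series_flagged_no_decay(self):
        series = ra.OmegaCcSeries(times=np.arange(50.0),
                                  omega_cc=np.full(50, 7.0))
        fit = ra.fit_drag_decay(series, n_bootstrap=0)
        assert fit.no_decay and np.isinf(fit.t_char)

    def test_posture_windows_fitted_separately(self):
        t = np.arange(0.0, 160.0)
        w = np.where(t < 60, 20.0 * 2.0 ** (-t / 155.0),
                     20.0 * 2.0 ** (-60.0 / 155.0) * 2.0 ** (-(t - 60) / 76.0))
        series = ra.OmegaCcSeries(times=t, omega_cc=w)
        fits = ra.fit_drag_decay(series, windows={"tucked": (0.0, 59.0),
                                                  "extended": (60.0, 159.0)},
                                 n_bootstrap=0)
        assert fits["tucked"].t_char == pytest.approx(155.0, rel=1e-3)
        assert fits["extended"].t_char == pytest.approx(76.0, rel=1e-3)

    def test_decay_with_precession_oscillation_recovered(self):
        """t_char recovered within 10% from a simulated precessing body
        when the oscillation period is much shorter than the window."""
        m = np.array([25.3, 133.9, 145.2])
        sch = ds.schedule_from_moments(m, m, t_ext=1.0)
        res = ds.simulate_rotation([3.0, 18.0, 5.0], sch,
                                   drag=ds.DragModel(155.0, 155.0),
                                   duration=300.0, dt=0.05, sample_every=20)
        u = res.cranial_caudal_axis()
        series = ra.omega_cc_series(
            ra.OrientationTrack(times=res.times, u_cc=u))
        fit = ra.fit_drag_decay(series, n_bootstrap=0)
        assert fit.t_char == pytest.approx(155.0, rel=0.10)

    def test_bootstrap_ci_brackets_estimate(self, rng):
        t = np.arange(0.0, 120.0)
        w = 15.0 * 2.0 ** (-t / 90.0) + rng.normal(0, 0.2, len(t))
        series = ra.OmegaCcSeries(times=t, omega_cc=w)
        fit = ra.fit_drag_decay(series, n_bootstrap=100, seed=0)
        lo, hi = fit.t_char_ci
        assert lo < fit.t_char < hi
        assert lo < 90.0 < hi

    def test_short_window_rejected(self):
        series = ra.OmegaCcSeries(times=np.arange(10.0),
                                  omega_cc=np.ones(10))
        with pytest.raises(ValueError, match="fewer than 5"):
            ra.fit_drag_decay(series, windows={"w": (0.0, 3.0)})


class TestOscillationPeriod:
    def test_pure_sinusoid_period_recovered(self):
        t = np.arange(0.0, 200.0)
        w = 10.0 + 2.0 * np.sin(2 * np.pi * t / 36.0)
        series = ra.OmegaCcSeries(times=t, omega_cc=w)
        t_osc = ra.oscillation_period(series)
        assert t_osc == pytest.approx(36.0, abs=1.0)

    def test_constant_series_undefined(self):
        series = ra.OmegaCcSeries(times=np.arange(100.0),
                                  omega_cc=np.full(100, 5.0))
        assert ra.oscillation_period(series) is None

    def test_symmetric_top_matches_closed_form(self):
        """Mean inter-peak interval equals the closed-form oscillation
        period pi / Omega_b of the body-frame precession, +-1 sample."""
        i_perp, i_s, w3, w_perp = 2.0, 3.0, 8.0, 3.0
        sch = ds.schedule_from_moments([i_perp, i_perp, i_s],
                                       [i_perp, i_perp, i_s], t_ext=1.0)
        res = ds.simulate_rotation([w_perp, 0.0, w3], sch, duration=400.0,
                                   dt=0.05, sample_every=20)
        u = res.cranial_caudal_axis()
        series = ra.omega_cc_series(
            ra.OrientationTrack(times=res.times, u_cc=u))
        t_osc = ra.oscillation_period(series)
        omega_b = w3 * (i_s - i_perp) / i_perp  # rev/s, body precession
        expected = 1000.0 / (2.0 * omega_b)  # ms: |omega x u| has period pi
        assert t_osc == pytest.approx(expected, abs=1.0)

    def test_decaying_oscillation_detrended(self):
        t = np.arange(0.0, 220.0)
        w = (12.0 + 2.5 * np.sin(2 * np.pi * t / 36.0)) * 2.0 ** (-t / 100.0)
        series = ra.OmegaCcSeries(times=t, omega_cc=w)
        t_osc = ra.oscillation_period(series)
        assert t_osc == pytest.approx(36.0, abs=1.5)


class TestWilcoxonSignedRank:
    def brute_force_p(self, d):
        """Exhaustive enumeration over all sign assignments."""
        d = np.asarray(d, float)
        d = d[d != 0]
        ranks = ra._rankdata_mid(np.abs(d))
        w_obs = ranks[d > 0].sum()
        ws = [np.sum(ranks[np.array(signs, bool)])
              for signs in itertools.product([0, 1], repeat=len(d))]
        ws = np.asarray(ws)
        p_le = np.mean(ws <= w_obs + 1e-12)
        p_ge = np.mean(ws >= w_obs - 1e-12)
        return min(1.0, 2 * min(p_le, p_ge))

    def test_spec_pairs_match_enumeration(self):
        x = [1, 3, 5, 7, 2]
        y = [2, 3, 4, 9, 1]
        out = ra.wilcoxon_signed_rank(x, y)
        assert out["exact"]
        assert out["p"] == pytest.approx(self.brute_force_p(
            np.array(x, float) - np.array(y, float)))

    @pytest.mark.parametrize("seed", range(6))
    def test_random_small_samples_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        d = rng.integers(-5, 6, size=9).astype(float)
        out = ra.wilcoxon_signed_rank(d)
        assert out["p"] == pytest.approx(self.brute_force_p(d))

    @pytest.mark.parametrize("seed", range(4))
    def test_tie_free_matches_scipy_exact(self, seed):
        rng = np.random.default_rng(100 + seed)
        d = rng.normal(0.3, 1.0, 12)  # continuous: no ties, no zeros
        ours = ra.wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, mode="exact")
        assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_all_zero_differences_degenerate(self):
        out = ra.wilcoxon_signed_rank([2.0, 2.0], [2.0, 2.0])
        assert out["degenerate"] and out["p"] == 1.0

    def test_large_sample_normal_approximation(self, rng):
        d = rng.normal(0.0, 1.0, 60)
        out = ra.wilcoxon_signed_rank(d)
        assert not out["exact"]
        ref = stats.wilcoxon(d, mode="approx", correction=False)
        assert out["p"] == pytest.approx(ref.pvalue, rel=1e-6)


class TestWilcoxonRankSum:
    def test_extreme_separation_exact_p(self):
        """{1,2,3} vs {4,5,6}: two-sided exact p = 2/20 = 0.1."""
        out = ra.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert out["w"] == 6.0
        assert out["p"] == pytest.approx(0.1)
        assert out["exact"]

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_combination_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 8, 5).astype(float)
        y = rng.integers(0, 8, 6).astype(float)
        out = ra.wilcoxon_rank_sum(x, y)
        pooled = np.concatenate([x, y])
        ranks = ra._rankdata_mid(pooled)
        w_obs = ranks[:5].sum()
        ws = [ranks[list(idx)].sum()
              for idx in itertools.combinations(range(11), 5)]
        ws = np.asarray(ws)
        p = min(1.0, 2 * min(np.mean(ws <= w_obs + 1e-12),
                             np.mean(ws >= w_obs - 1e-12)))
        assert out["p"] == pytest.approx(p)

    def test_tie_free_matches_scipy(self, rng):
        x = rng.normal(0, 1, 8)
        y = rng.normal(0.5, 1, 9)
        ours = ra.wilcoxon_rank_sum(x, y)
        ref = stats.mannwhitneyu(x, y, method="exact")
        assert ours["p"] == pytest.approx(ref.pvalue, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ra.wilcoxon_rank_sum([], [1.0])


class TestCompareTrackedVsSimulated:
    def test_identical_series_degenerate(self):
        t = np.arange(0.0, 150.0)
        w = 10.0 * 2.0 ** (-t / 100.0)
        a = ra.OmegaCcSeries(times=t, omega_cc=w)
        b = ra.OmegaCcSeries(times=t, omega_cc=w.copy())
        out = ra.compare_tracked_vs_simulated(a, b)
        assert out["degenerate"]
        assert np.allclose(out["differences"], 0.0)

    def test_offset_series_detected(self):
        t = np.arange(0.0, 200.0)
        a = ra.OmegaCcSeries(times=t, omega_cc=np.full(200, 10.0))
        b = ra.OmegaCcSeries(times=t, omega_cc=np.full(200, 12.0))
        out = ra.compare_tracked_vs_simulated(a, b)
        assert np.allclose(out["differences"], -2.0)
        assert out["signed_rank"]["p"] < 0.05

    def test_non_overlapping_rejected(self):
        a = ra.OmegaCcSeries(times=np.arange(0.0, 50.0),
                             omega_cc=np.ones(50))
        b = ra.OmegaCcSeries(times=np.arange(100.0, 150.0),
                             omega_cc=np.ones(50))
        with pytest.raises(ValueError, match="overlap"):
            ra.compare_tracked_vs_simulated(a, b)
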