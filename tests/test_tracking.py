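"""MSD estimation, diffusion fits, and the simple-diffusion filter."""

import numpy as np
import pytest

from nanodomain import (
    MSDCurve,
    TrackingConfig,
    Trajectory,
    classify_simple_diffusion,
    compute_msd,
    estimate_observations,
    fit_diffusion,
)

from conftest import make_brownian_track


def brute_force_msd(positions, max_lag):
    """Independent oracle: explicit double loop over ordered pairs."""
    n = len(positions)
    out = []
    for k in range(1, max_lag + 1):
        sq = [np.sum((positions[i + k] - positions[i]) ** 2)
              for i in range(n - k)]
        out.append(np.mean(sq))
    return np.array(out)


def line_curve(D, intercept=0.0, n=12, dt=0.1):
    lags = np.arange(1, n + 1) * dt
    return MSDCurve(lags=lags, msd=4 * D * lags + intercept,
                    n_pairs=np.arange(n, 0, -1) * 10)


class TestComputeMSD:
    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(11)
        for n in (10, 27, 50):
            pos = rng.normal(size=(n, 2))
            traj = Trajectory("t", np.arange(n) * 0.1, pos)
            curve = compute_msd(traj, max_lag_fraction=0.5)
            expected = brute_force_msd(pos, len(curve.lags))
            np.testing.assert_array_equal(curve.msd, expected)
            np.testing.assert_array_equal(
                curve.n_pairs, n - np.arange(1, len(curve.lags) + 1))

    def test_hand_worked_four_point_track(self):
        pos = np.array([[0, 0], [1, 0], [1, 1], [2, 1]], dtype=float)
        traj = Trajectory("hand", np.arange(4.0), pos)
        curve = compute_msd(traj, max_lag_fraction=0.5)
        assert curve.msd[0] == pytest.approx(1.0)
        assert curve.msd[1] == pytest.approx(2.0)  # mean of (2, 2)

    def test_stationary_track_is_zero(self):
        traj = Trajectory("s", np.arange(20.0), np.zeros((20, 2)))
        assert np.all(compute_msd(traj).msd == 0.0)

    def test_ballistic_track_is_quadratic(self):
        t = np.arange(40.0)
        pos = np.column_stack([t, np.zeros_like(t)])  # x = v·t, v = 1 μm/s
        curve = compute_msd(Trajectory("b", t, pos))
        np.testing.assert_allclose(curve.msd, curve.lags**2, rtol=1e-12)

    def test_too_short_track_raises(self):
        traj = Trajectory("short", np.arange(4.0), np.zeros((4, 2)))
        with pytest.raises(ValueError, match="lag"):
            compute_msd(traj, max_lag_fraction=0.25)


class TestTrajectoryValidation:
    def test_requires_uniform_interval(self):
        with pytest.raises(ValueError, match="uniform"):
            Trajectory("x", [0.0, 1.0, 2.5], np.zeros((3, 2)))

    def test_requires_increasing_times(self):
        with pytest.raises(ValueError):
            Trajectory("x", [0.0, 2.0, 1.0], np.zeros((3, 2)))

    def test_rejects_nonfinite(self):
        pos = np.zeros((3, 2))
        pos[1, 0] = np.nan
        with pytest.raises(ValueError):
            Trajectory("x", [0.0, 1.0, 2.0], pos)


class TestFitDiffusion:
    def test_exact_line(self):
        fit = fit_diffusion(line_curve(0.5))
        assert fit.D == pytest.approx(0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert not fit.negative_D

    def test_offset_identifiability(self):
        # the intercept absorbs static localization noise (b = 4σ_loc²)
        fit = fit_diffusion(line_curve(0.5, intercept=0.01))
        assert fit.D == pytest.approx(0.5, rel=1e-12)
        assert fit.intercept == pytest.approx(0.01, rel=1e-9)

    def test_single_brownian_track(self):
        traj = make_brownian_track(seed=42, D=1.0, dt=0.1, n_frames=10_000)
        curve = compute_msd(traj, max_lag_fraction=0.01)
        fit = fit_diffusion(curve, window=(1, 10))
        assert 0.95 <= fit.D <= 1.05

    def test_negative_slope_flagged_not_clipped(self):
        lags = np.arange(1, 11) * 0.1
        curve = MSDCurve(lags=lags, msd=np.linspace(1.0, 0.5, 10),
                         n_pairs=np.arange(10, 0, -1))
        fit = fit_diffusion(curve)
        assert fit.D < 0 and fit.negative_D

    def test_degenerate_window_raises(self):
        with pytest.raises(ValueError, match="window"):
            fit_diffusion(line_curve(0.5, n=3), window=(5, 10))

    def test_ensemble_unbiased(self):
        # time-averaged MSD + weighted fit must not bias D on ensembles
        D_hats = []
        for seed in range(200):
            traj = make_brownian_track(seed=500 + seed, D=1.0, dt=0.1,
                                       n_frames=500)
            D_hats.append(fit_diffusion(compute_msd(traj)).D)
        assert np.mean(D_hats) == pytest.approx(1.0, rel=0.02)


class TestClassifySimpleDiffusion:
    def test_linear_is_simple(self):
        verdict = classify_simple_diffusion(line_curve(0.5))
        assert verdict.is_simple
        assert verdict.alpha == pytest.approx(1.0, abs=1e-9)

    def test_ballistic_is_not_simple(self):
        lags = np.arange(1, 13) * 0.1
        curve = MSDCurve(lags=lags, msd=2.0 * lags**2,
                         n_pairs=np.arange(12, 0, -1))
        verdict = classify_simple_diffusion(curve)
        assert not verdict.is_simple
        assert verdict.alpha == pytest.approx(2.0, abs=1e-9)

    def test_confined_walk_is_not_simple(self):
        # reflecting disk of radius 0.5 μm saturates the MSD
        rng = np.random.default_rng(0)
        D, dt, n, radius = 1.0, 0.01, 5000, 0.5
        pos = np.zeros((n, 2))
        for i in range(1, n):
            p = pos[i - 1] + rng.normal(0, np.sqrt(2 * D * dt), 2)
            r = np.hypot(*p)
            if r > radius:
                p = p * (2 * radius - r) / r
            pos[i] = p
        traj = Trajectory("conf", np.arange(n) * dt, pos)
        verdict = classify_simple_diffusion(compute_msd(traj, 0.01))
        assert verdict.alpha < 0.8
        assert not verdict.is_simple

    def test_all_zero_msd_is_not_simple(self):
        lags = np.arange(1, 11) * 0.1
        curve = MSDCurve(lags=lags, msd=np.zeros(10),
                         n_pairs=np.arange(10, 0, -1))
        assert not classify_simple_diffusion(curve).is_simple

    def test_brownian_pass_rate(self):
        # ≥ 95% of pure Brownian tracks of ≥ 500 steps must pass
        passed = sum(
            classify_simple_diffusion(
                compute_msd(make_brownian_track(seed=100 + s))).is_simple
            for s in range(100))
        assert passed >= 95


class TestEstimateObservations:
    def _config(self):
        return TrackingConfig(n_boot=50, seed=3)

    def test_simple_tracks_all_survive(self):
        trajs = [make_brownian_track(seed=s, d_a=1.0 + s * 0.1, phase="LOD")
                 for s in range(10)]
        obs, exclusions = estimate_observations(trajs, self._config())
        assert len(obs) == 10
        assert sum(exclusions.values()) == 0
        assert all(o.sigma_D is not None and o.sigma_D > 0 for o in obs)

    def test_mixture_filters_ballistic(self):
        simple = [make_brownian_track(seed=s, d_a=1.0, phase="LOD")
                  for s in range(5)]
        t = np.arange(500.0) * 0.1
        ballistic = [
            Trajectory(f"bal{i}", t,
                       np.column_stack([(0.5 + 0.1 * i) * t, 0.2 * t]),
                       d_a=1.0, phase="LOD")
            for i in range(5)]
        obs, exclusions = estimate_observations(simple + ballistic,
                                                self._config())
        assert len(obs) == 5
        assert exclusions["not_simple"] == 5

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            estimate_observations([], self._config())

    def test_all_filtered_reports_summary(self):
        t = np.arange(500.0) * 0.1
        ballistic = Trajectory("bal", t, np.column_stack([t, t]), d_a=1.0)
        with pytest.raises(ValueError, match="not_simple"):
            estimate_observations([ballistic], self._config())
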