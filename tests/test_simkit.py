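"""Simulator statistics checked against closed forms and chain oracles."""

import numpy as np
import pytest

from ddrdyn import (
    RenderParams,
    SimulationConfig,
    render_movie,
    simulate_gel,
    simulate_recruitment_series,
    simulate_state_trajectories,
)
from ddrdyn.abundance import quantify_gel
from ddrdyn.recruitment import fit_one_phase, series_to_curve


def _unconfined(**kw):
    base = dict(dZ=1e9, nuclear_depth=np.inf, bleach_halflife=np.inf,
                field_size=(4000, 4000))
    base.update(kw)
    return SimulationConfig(**base)


class TestStateTrajectories:
    def test_msd_of_pure_bound_matches_4Ddt(self):
        cfg = _unconfined(n_particles=300, duration_frames=300, seed=1,
                          F_bound=1.0, D_bound=0.01, loc_error_sigma=0.0)
        tracks = simulate_state_trajectories(cfg)
        sq = np.concatenate([np.diff(t.x_um) ** 2 + np.diff(t.y_um) ** 2
                             for t in tracks])
        msd = sq.mean()
        expected = 4 * 0.01 * cfg.frame_interval
        assert msd == pytest.approx(expected, rel=0.02)

    def test_same_seed_bit_identical(self):
        cfg = SimulationConfig(n_particles=10, duration_frames=50, seed=42)
        a = simulate_state_trajectories(cfg)
        b = simulate_state_trajectories(cfg)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.x_obs, tb.x_obs)
            assert np.array_equal(ta.bound, tb.bound)
            assert ta.bleach_frame == tb.bleach_frame

    def test_adding_particles_preserves_existing_streams(self):
        small = simulate_state_trajectories(
            SimulationConfig(n_particles=5, duration_frames=50, seed=9))
        large = simulate_state_trajectories(
            SimulationConfig(n_particles=8, duration_frames=50, seed=9))
        for ta, tb in zip(small, large[:5]):
            assert np.array_equal(ta.x_um, tb.x_um)

    def test_stationary_bound_fraction_matches_chain_oracle(self):
        # independent oracle: direct discrete sampling of the two-state chain
        dt = 0.00724
        rng = np.random.default_rng(0)
        k = 1.0  # symmetric rates -> stationary fraction 1/2
        p_switch = 1 - np.exp(-k * dt)
        state = rng.random(2000) < 0.5
        frames = []
        for _ in range(100):
            frames.append(state.copy())
            state ^= rng.random(2000) < p_switch
        oracle = np.mean(frames)
        assert oracle == pytest.approx(0.5, abs=0.01)

        cfg = _unconfined(n_particles=1000, duration_frames=100, seed=5,
                          F_bound=0.5, k_unbind=1.0, k_bind=1.0)
        tracks = simulate_state_trajectories(cfg)
        frac = np.concatenate([t.bound for t in tracks]).mean()
        assert frac == pytest.approx(0.5, abs=0.01)

    def test_free_step_variance_includes_localization_error(self):
        cfg = _unconfined(n_particles=300, duration_frames=100, seed=2,
                          F_bound=0.0, D_free=2.0, loc_error_sigma=0.035)
        tracks = simulate_state_trajectories(cfg)
        dx = np.concatenate([np.diff(t.x_obs) for t in tracks])
        expected = 2 * 2.0 * cfg.frame_interval + 2 * 0.035 ** 2
        se = expected * np.sqrt(2 / dx.size)
        assert abs(dx.var() - expected) < 3 * se

    def test_observed_durations_exponential_with_bleach_halflife(self):
        from ddrdyn.residence import fit_exponential_decay, survival_curve

        cfg = SimulationConfig(n_particles=3000, duration_frames=2000, seed=8,
                               F_bound=1.0, D_bound=0.001, dZ=1e9,
                               nuclear_depth=np.inf, bleach_halflife=1.0,
                               z_init="slice")
        tracks = simulate_state_trajectories(cfg)
        durations = np.array([t.n_frames * cfg.frame_interval for t in tracks])
        curve = survival_curve(durations)
        est = fit_exponential_decay(curve.tau, curve.survival)
        assert est.half_life == pytest.approx(1.0, rel=0.05)

    @pytest.mark.parametrize("bad", [
        {"D_free": -1.0}, {"frame_interval": 0.0}, {"F_bound": 1.5},
        {"loc_error_sigma": np.nan}, {"dZ": -0.7},
        {"F_bound": 0.5, "k_bind": 3.0, "k_unbind": 1.0},  # inconsistent rates
    ])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


class TestRenderMovie:
    def test_static_spot_brightest_pixel(self):
        cfg = SimulationConfig(n_particles=1, duration_frames=10, seed=0,
                               field_size=(32, 32), F_bound=1.0, D_bound=0.0,
                               dZ=1e9, nuclear_depth=np.inf,
                               bleach_halflife=np.inf, loc_error_sigma=0.0)
        gt = simulate_state_trajectories(cfg)
        movie = render_movie(gt, cfg, RenderParams(photons=500, background=1,
                                                   noise="none"))
        px = int(round(gt[0].x_um[0] / cfg.pixel_size))
        py = int(round(gt[0].y_um[0] / cfg.pixel_size))
        for f in range(movie.n_frames):
            iy, ix = np.unravel_index(np.argmax(movie.frames[f]),
                                      movie.frames[f].shape)
            assert (abs(ix - px) <= 1) and (abs(iy - py) <= 1)

    def test_zero_particles_background_only(self):
        cfg = SimulationConfig(n_particles=0, duration_frames=5,
                               field_size=(16, 16))
        movie = render_movie([], cfg, RenderParams(background=7.0, noise="none"))
        assert np.all(movie.frames == 7.0)

    def test_spot_integrates_to_photon_count(self):
        cfg = SimulationConfig(n_particles=1, duration_frames=1, seed=1,
                               field_size=(64, 64), F_bound=1.0, D_bound=0.0,
                               dZ=1e9, nuclear_depth=np.inf,
                               bleach_halflife=np.inf)
        gt = simulate_state_trajectories(cfg)
        movie = render_movie(gt, cfg, RenderParams(photons=800, background=2,
                                                   noise="none"))
        above_bg = movie.frames[0].sum() - 2 * 64 * 64
        assert above_bg == pytest.approx(800, rel=1e-6)


class TestRecruitmentSeries:
    def test_half_time_and_asymptote(self):
        series = simulate_recruitment_series(t_half=10.0, plateau=2.0,
                                             noise_sd=0.0, n_frames=5000,
                                             frame_interval=1.0,
                                             baseline_frames=5)
        # t = t_half: 10 s after irradiation -> frame index 4 + 10
        assert series[4 + 10] == pytest.approx(1.0)       # plateau/2
        assert series[-1] == pytest.approx(2.0, abs=1e-3)  # asymptote

    def test_roundtrip_recovers_t_half_within_5pct(self):
        # single-cell round trip; peak normalization tolerates mild ROI noise
        series = simulate_recruitment_series(t_half=22.1, noise_sd=0.003,
                                             n_frames=300, frame_interval=1.0,
                                             baseline_frames=10, seed=4)
        fit = fit_one_phase(series_to_curve(series, 1.0, 10))
        assert fit.t_half == pytest.approx(22.1, rel=0.05)


class TestSimulateGel:
    def test_noiseless_roundtrip_recovers_truth_exactly(self):
        lanes = simulate_gel([0.5, 1.0, 2.0], [10000, 20000], 50000.0,
                             slope=100.0)
        result = quantify_gel(lanes)
        assert np.allclose(result["molecules_per_cell"], 50000.0)

    def test_zero_fmol_lane_zero_signal(self):
        lanes = simulate_gel([0.0, 1.0, 2.0], [], 0.0, slope=3.0)
        assert lanes.loc[lanes["amount"] == 0.0, "signal"].iloc[0] == 0.0

    def test_slope_cancels_in_calibration(self):
        a = quantify_gel(simulate_gel([0.5, 1, 2], [10000], 30000.0, slope=50.0))
        b = quantify_gel(simulate_gel([0.5, 1, 2], [10000], 30000.0, slope=100.0))
        assert a["molecules_per_cell"].iloc[0] == pytest.approx(
            b["molecules_per_cell"].iloc[0])
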