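"""Jump-length histograms, mixture density, defocus correction, and fits."""

import numpy as np
import pytest
from scipy.integrate import quad

from ddrdyn import SimulationConfig, ground_truth_to_trajectories, \
    simulate_state_trajectories
from ddrdyn.diffusion import (
    DEFAULT_BOUNDS_2STATE,
    compute_jump_histograms,
    defocus_fraction,
    fit_diffusion_model,
    model_density,
    per_cell_fit,
    slab_survival_sampled,
    split_by_mask,
)
from ddrdyn.tracking import Trajectory

DT = 0.00724


def _track(positions, track_id=0, frames=None):
    positions = np.asarray(positions, dtype=float)
    if frames is None:
        frames = np.arange(len(positions))
    return Trajectory(track_id=track_id, frames=frames, x=positions[:, 0],
                      y=positions[:, 1], intensity=np.ones(len(positions)))


class TestJumpHistograms:
    def test_hand_computed_jumps(self):
        tr = _track([(0, 0), (0.03, 0), (0.06, 0)])
        hist = compute_jump_histograms([tr], DT, n_lags=2, bin_width=0.01)
        # lag 1: jumps {0.03, 0.03}; lag 2: jump {0.06}
        assert hist.n_jumps[0] == 2
        assert hist.counts[0][2:4].sum() == 2  # 0.03 sits on a bin edge
        assert hist.n_jumps[1] == 1
        assert hist.counts[1][-1] == 1

    def test_static_track_all_mass_in_first_bin(self):
        tr = _track([(1.0, 1.0)] * 12)
        hist = compute_jump_histograms([tr], DT, n_lags=3)
        for lag in range(3):
            assert hist.counts[lag][0] == hist.counts[lag].sum() > 0

    def test_jumps_to_consider_caps_at_4(self):
        tr = _track([(0.01 * i, 0.0) for i in range(101)])
        hist = compute_jump_histograms([tr], DT, n_lags=1, jumps_to_consider=4)
        assert hist.n_jumps[0] == 4

    def test_uncapped_counts_every_gap_free_jump(self):
        tr = _track([(0.01 * i, 0.0) for i in range(101)])
        hist = compute_jump_histograms([tr], DT, n_lags=1, jumps_to_consider=None)
        assert hist.n_jumps[0] == 100

    def test_gap_excluded_from_jump_spans(self):
        tr = _track([(0, 0), (0.02, 0), (0.04, 0)], frames=[0, 1, 3])
        hist = compute_jump_histograms([tr], DT, n_lags=1)
        assert hist.n_jumps[0] == 1   # frames 1->3 span a gap and are skipped

    def test_error_names_empty_lag(self):
        tr = _track([(0, 0), (0.02, 0)])
        with pytest.raises(ValueError, match="lag 2"):
            compute_jump_histograms([tr], DT, n_lags=2)


class TestModelDensity:
    @pytest.mark.parametrize("defocus", ["sampled", "continuous"])
    def test_density_integrates_to_one(self, defocus):
        val, _ = quad(lambda r: model_density(r, 3, DT, [0.01, 2.0],
                                              [0.4, 0.6], defocus=defocus),
                      0, np.inf, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_peak_at_sqrt_2a(self):
        D, n, sigma = 1.5, 2, 0.03
        a = D * n * DT + sigma ** 2
        r = np.linspace(1e-4, 1.0, 20000)
        dens = model_density(r, n, DT, [D], [1.0], sigma=sigma)
        assert r[np.argmax(dens)] == pytest.approx(np.sqrt(2 * a), rel=1e-2)

    def test_zero_bound_fraction_equals_pure_free(self):
        r = np.linspace(0, 1, 200)
        mix = model_density(r, 2, DT, [0.01, 2.0], [0.0, 1.0])
        pure = model_density(r, 2, DT, [2.0], [1.0])
        assert np.allclose(mix, pure)


class TestDefocus:
    def test_immobile_always_in_slice(self):
        for n in range(1, 8):
            assert defocus_fraction(0.0, n, DT, 0.7) == 1.0

    def test_strictly_decreasing_in_lag_and_D(self):
        vals_n = [defocus_fraction(2.0, n, DT, 0.7) for n in range(1, 8)]
        assert np.all(np.diff(vals_n) < 0)
        vals_D = [defocus_fraction(D, 4, DT, 0.7) for D in (0.5, 2.0, 10.0)]
        assert np.all(np.diff(vals_D) < 0)

    def test_series_matches_small_monte_carlo(self):
        from ddrdyn.studies import monte_carlo_slab_survival

        mc = monte_carlo_slab_survival(2.0, 4, DT, 0.7, n_walkers=200_000, seed=1)
        series = np.array([defocus_fraction(2.0, n, DT, 0.7)
                           for n in range(1, 5)])
        assert np.max(np.abs(mc - series)) < 0.005

    def test_sampled_survival_exceeds_continuous(self):
        # between-frame excursions are forgiven when only frames are scored
        sampled = slab_survival_sampled(2.0, DT, 0.7, 7)
        continuous = np.array([defocus_fraction(2.0, n, DT, 0.7)
                               for n in range(1, 8)])
        assert np.all(sampled >= continuous)


def _simulated_hist(F_bound, D_free, seed=3, n_particles=3000):
    cfg = SimulationConfig(n_particles=n_particles, duration_frames=100,
                           seed=seed, D_free=D_free, F_bound=F_bound,
                           bleach_halflife=0.05)
    gt = simulate_state_trajectories(cfg)
    tracks = ground_truth_to_trajectories(gt)
    return compute_jump_histograms(tracks, cfg.frame_interval,
                                   jumps_to_consider=None)


class TestFit:
    def test_estimates_stay_within_bounds(self):
        hist = _simulated_hist(0.5, 2.0)
        fit = fit_diffusion_model(hist)
        lo, hi = DEFAULT_BOUNDS_2STATE["D_free"]
        assert lo <= fit.D_free <= hi
        lo, hi = DEFAULT_BOUNDS_2STATE["D_bound"]
        assert lo <= fit.D_bound <= hi
        assert 0.0 <= fit.F_bound <= 1.0

    def test_all_static_data_yields_high_bound_fraction(self):
        # static molecules observed with 35 nm localization jitter
        rng = np.random.default_rng(0)
        tracks = []
        for i in range(200):
            jitter = rng.normal(0, 0.035, (15, 2))
            pos = np.array([1.0 + 0.3 * i, 1.0]) + jitter
            tracks.append(_track(pos, track_id=i))
        hist = compute_jump_histograms(tracks, DT, jumps_to_consider=None)
        fit = fit_diffusion_model(hist)
        assert fit.F_bound >= 0.95

    def test_ignoring_defocus_biases_bound_fraction_up(self):
        hist = _simulated_hist(0.5, 2.0, seed=6, n_particles=6000)
        corrected = fit_diffusion_model(hist, dZ=0.700)
        uncorrected = fit_diffusion_model(hist, dZ=np.inf)  # Z == 1
        assert uncorrected.F_bound > corrected.F_bound

    def test_three_state_residual_not_worse_than_two_state(self):
        hist = _simulated_hist(0.5, 2.0, seed=9)
        two = fit_diffusion_model(hist, n_states=2)
        three = fit_diffusion_model(hist, n_states=3)
        assert three.rss <= two.rss * 1.001
        assert abs(sum(three.fractions) - 1.0) < 1e-9


class TestSplitByMask:
    def _tracks(self):
        inside = _track([(0.5, 0.5)] * 3, track_id=0)
        outside = _track([(2.5, 2.5)] * 3, track_id=1)
        return [inside, outside]

    def test_empty_and_full_masks(self):
        tracks = self._tracks()
        mask = np.zeros((20, 20), dtype=bool)
        ov, non = split_by_mask(tracks, mask, 0.16)
        assert ov == [] and len(non) == 2
        ov, non = split_by_mask(tracks, ~mask, 0.16)
        assert len(ov) == 2 and non == []

    def test_single_in_mask_localization_counts_as_overlap(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[3, 3] = True
        tr = _track([(2.5, 2.5), (3 * 0.16, 3 * 0.16), (2.5, 2.5)])
        ov, non = split_by_mask([tr], mask, 0.16)
        assert len(ov) == 1 and non == []

    def test_mismatched_grid_raises(self):
        tr = _track([(10.0, 10.0)] * 3)
        with pytest.raises(ValueError):
            split_by_mask([tr], np.zeros((8, 8), dtype=bool), 0.16)


class TestPerCell:
    def test_single_cell_equals_pooled(self):
        cfg = SimulationConfig(n_particles=2000, duration_frames=80, seed=4,
                               bleach_halflife=0.05)
        tracks = ground_truth_to_trajectories(simulate_state_trajectories(cfg))
        per_cell, pooled = per_cell_fit({"cellA": tracks}, cfg.frame_interval,
                                        jumps_to_consider=None)
        fit = per_cell["cellA"]
        assert fit.F_bound == pytest.approx(pooled.F_bound, abs=1e-9)
        assert fit.D_free == pytest.approx(pooled.D_free, rel=1e-9)

    def test_identical_cells_close_to_pooled(self):
        cells = {}
        for c in range(3):
            cfg = SimulationConfig(n_particles=3000, duration_frames=80,
                                   seed=20 + c, bleach_halflife=0.05)
            cells[f"c{c}"] = ground_truth_to_trajectories(
                simulate_state_trajectories(cfg))
        per_cell, pooled = per_cell_fit(cells, 0.00724, jumps_to_consider=None)
        med = np.median([f.F_bound for f in per_cell.values()])
        assert med == pytest.approx(pooled.F_bound, abs=0.05)

    def test_cell_without_jumps_skipped_with_warning(self):
        good_cfg = SimulationConfig(n_particles=2000, duration_frames=80,
                                    seed=4, bleach_halflife=0.05)
        good = ground_truth_to_trajectories(
            simulate_state_trajectories(good_cfg))
        bad = [_track([(0, 0), (0.02, 0)])]  # too short for lag 7
        with pytest.warns(UserWarning, match="skipped"):
            per_cell, _ = per_cell_fit({"good": good, "bad": bad}, 0.00724,
                                       jumps_to_consider=None)
        assert set(per_cell) == {"good"}
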