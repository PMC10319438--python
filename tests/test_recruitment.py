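"""Drift correction, ROI curves, normalization, one-phase association fits."""

import numpy as np
import pytest
from scipy.ndimage import shift as nd_shift

from ddrdyn import Movie, simulate_recruitment_series
from ddrdyn.recruitment import (
    RecruitmentCurve,
    average_curves,
    extract_normalized_curve,
    fit_one_phase,
    normalize_series,
    register_movie,
    series_to_curve,
)

LN2 = np.log(2.0)


def _textured_frame(rng, shape=(64, 64)):
    img = rng.random(shape) * 10
    img[20:28, 20:28] += 100
    img[40:44, 10:14] += 60
    return img


class TestRegister:
    def test_known_shift_recovered(self, rng):
        base = _textured_frame(rng)
        shifted = nd_shift(base, (2, -3), order=1, mode="nearest")
        movie = Movie(np.stack([base, shifted]), 1.0, 0.16)
        registered, shifts = register_movie(movie)
        # the applied correction undoes the (2, -3) drift
        assert shifts[1][0] == pytest.approx(-2, abs=0.2)
        assert shifts[1][1] == pytest.approx(3, abs=0.2)

    def test_static_movie_zero_shifts(self, rng):
        frame = _textured_frame(rng)
        movie = Movie(np.stack([frame] * 4), 1.0, 0.16)
        _, shifts = register_movie(movie)
        assert np.allclose(shifts, 0.0)

    def test_registration_restores_correlation(self, rng):
        base = _textured_frame(rng)
        shifted = nd_shift(base, (4, 5), order=1, mode="nearest")
        movie = Movie(np.stack([base, shifted]), 1.0, 0.16)
        registered, _ = register_movie(movie)
        inner = slice(8, -8)
        def corr(a, b):
            return np.corrcoef(a[inner, inner].ravel(), b[inner, inner].ravel())[0, 1]
        assert corr(base, registered.frames[1]) > corr(base, shifted) + 0.05

    def test_featureless_frames_warn(self):
        movie = Movie(np.zeros((3, 16, 16)), 1.0, 0.16)
        with pytest.warns(UserWarning):
            register_movie(movie)


class TestExtract:
    def _recruitment_movie(self, scale=1.0):
        series = simulate_recruitment_series(t_half=5.0, plateau=50.0,
                                             baseline_frames=5, n_frames=60,
                                             frame_interval=1.0, baseline=20.0)
        frames = np.ones((60, 16, 16)) * 2.0
        frames[:, 4:8, 4:8] = series[:, None, None]
        return Movie(frames * scale, 1.0, 0.16)

    def test_noiseless_curve_matches_one_phase_form(self):
        curve = extract_normalized_curve(self._recruitment_movie(),
                                         (4, 4, 7, 7), baseline_frames=5)
        t = curve.time[curve.time > 0]
        plateau_frac = 1 - np.exp2(-curve.time[-1] / 5.0)
        expected = (1 - np.exp2(-t / 5.0)) / plateau_frac
        assert np.allclose(curve.intensity[curve.time > 0], expected, atol=1e-9)

    def test_constant_movie_no_signal_error(self):
        movie = Movie(np.ones((20, 8, 8)), 1.0, 0.16)
        with pytest.raises(ValueError, match="signal"):
            extract_normalized_curve(movie, (0, 0, 7, 7), baseline_frames=5)

    def test_scale_invariance(self):
        a = extract_normalized_curve(self._recruitment_movie(1.0),
                                     (4, 4, 7, 7), baseline_frames=5)
        b = extract_normalized_curve(self._recruitment_movie(2.0),
                                     (4, 4, 7, 7), baseline_frames=5)
        assert np.allclose(a.intensity, b.intensity)

    def test_normalization_idempotent(self):
        series = simulate_recruitment_series(t_half=5.0, baseline_frames=5,
                                             n_frames=40, frame_interval=1.0)
        once = normalize_series(series, 5)
        twice = normalize_series(once, 5)
        assert np.allclose(once, twice)

    def test_roi_outside_field_rejected(self):
        movie = Movie(np.ones((10, 8, 8)), 1.0, 0.16)
        with pytest.raises(ValueError):
            extract_normalized_curve(movie, (0, 0, 9, 9), baseline_frames=2)


class TestAverage:
    def _cell(self, seed, n=50):
        series = simulate_recruitment_series(t_half=8.0, noise_sd=0.02,
                                             n_frames=n, frame_interval=1.0,
                                             baseline_frames=5, seed=seed)
        return series_to_curve(series, 1.0, 5)

    def test_identical_cells_average_to_same_curve(self):
        c = self._cell(1)
        avg = average_curves([c, c, c])
        assert np.allclose(avg.intensity, c.intensity / c.intensity.max())
        assert avg.n_cells == 3

    def test_mismatched_grids_rejected(self):
        a = self._cell(1)
        b = RecruitmentCurve(time=a.time * 2.0, intensity=a.intensity)
        with pytest.raises(ValueError, match="grid"):
            average_curves([a, b])

    def test_averaging_shrinks_noise_variance(self, rng):
        t = np.arange(1.0, 101.0)
        clean = 1 - np.exp2(-t / 10.0)
        def noisy_curve(seed):
            r = np.random.default_rng(seed)
            return RecruitmentCurve(time=t, intensity=clean + 0.05 * r.standard_normal(t.size))
        n = 16
        avg = average_curves([noisy_curve(s) for s in range(n)])
        resid_avg = np.var(avg.intensity - clean / clean.max())
        resid_one = np.var(noisy_curve(99).intensity - clean)
        assert resid_avg < 3 * resid_one / n


class TestOnePhaseFit:
    def test_noiseless_22p1s_roundtrip(self):
        t = np.arange(1.0, 301.0)
        curve = RecruitmentCurve(time=t, intensity=1 - np.exp2(-t / 22.1))
        fit = fit_one_phase(curve)
        assert fit.t_half == pytest.approx(22.1, rel=1e-3)

    def test_t_half_is_ln2_over_K(self):
        t = np.arange(1.0, 100.0)
        fit = fit_one_phase(RecruitmentCurve(time=t, intensity=1 - np.exp(-0.05 * t)))
        assert fit.t_half == pytest.approx(LN2 / fit.K, rel=1e-12)

    def test_noisy_recovery_within_5pct(self, rng):
        t = np.arange(1.0, 301.0)
        y = 1 - np.exp2(-t / 22.1) + 0.05 * rng.standard_normal(t.size)
        fit = fit_one_phase(RecruitmentCurve(time=t, intensity=y))
        assert fit.t_half == pytest.approx(22.1, rel=0.05)

    def test_too_few_points_rejected(self):
        curve = RecruitmentCurve(time=np.array([-1.0, 1.0, 2.0]),
                                 intensity=np.array([0.0, 0.3, 0.5]))
        with pytest.raises(ValueError):
            fit_one_phase(curve)
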