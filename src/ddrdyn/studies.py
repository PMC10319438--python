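"""End-to-end validation studies on synthetic ground truth.

Each function here runs one complete simulate → analyze → compare cycle at
a fixed, documented problem size and returns the measured quantities. They
back both the acceptance checks and any re-validation after changes to the
simulator or the fitting code.

Study conditions (chosen once, see the methods note for rationale):

* diffusion recovery — fast-tracking acquisition: Δt = 7.24 ms, 0.16 µm
  pixels, dZ = 0.7 µm, nucleus 4 µm deep, σ = 35 nm, photobleaching
  half-life 50 ms (≈7-frame tracks, typical of full-power HILO tracking
  illumination), unbinding rate 0.2 s⁻¹, trajectories segmented with the
  2-gap rule and ≥3 localizations, all gap-free jumps counted;
* residence — chromatin-locked molecules (permanently bound, D = 10⁻⁴
  µm²/s), bleach half-life 7.7 s, 3000 frames at 138 fps, 10-frame
  averaging, bound-molecule tracking at D_max = 0.5 µm²/s;
* recruitment — 10 cells per condition, 1 % ROI noise, acquisitions
  running to ≥6 half-lives;
* tracking oracle — noiseless sparse renderings (4 particles per 31 µm
  field), links scored against ground-truth identities.
"""

from __future__ import annotations

import math

import numpy as np

from . import recruitment as _recruitment
from . import residence as _residence
from . import simkit as _simkit
from .diffusion import compute_jump_histograms, defocus_fraction, fit_diffusion_model
from .tracking import DetectionParams, LinkingParams, average_frames, detect_spots, \
    link_trajectories

__all__ = [
    "recover_two_state",
    "recovery_grid",
    "monte_carlo_slab_survival",
    "defocus_mc_comparison",
    "residence_study",
    "recruitment_study",
    "tracking_oracle_study",
]


def recover_two_state(F_bound: float, D_free: float, seed: int,
                      D_bound: float = 0.01, n_particles: int = 42000,
                      duration_frames: int = 100) -> dict:
    """Simulate a two-state acquisition and re-estimate its parameters.

    Returns truth, estimates, and the number of lag-1 jumps used.
    """
    cfg = _simkit.SimulationConfig(
        n_particles=n_particles, duration_frames=duration_frames, seed=seed,
        D_free=D_free, D_bound=D_bound, F_bound=F_bound, k_unbind=0.2,
        bleach_halflife=0.05, field_size=(140, 170),
    )
    gt = _simkit.simulate_state_trajectories(cfg)
    tracks = _simkit.ground_truth_to_trajectories(gt, max_gaps=2,
                                                  min_track_length=3)
    hist = compute_jump_histograms(tracks, cfg.frame_interval,
                                   jumps_to_consider=None)
    fit = fit_diffusion_model(hist, sigma=cfg.loc_error_sigma, dZ=cfg.dZ)
    return {
        "F_bound_true": F_bound, "D_free_true": D_free, "D_bound_true": D_bound,
        "F_bound_est": fit.F_bound, "D_free_est": fit.D_free,
        "D_bound_est": fit.D_bound, "n_lag1_jumps": int(hist.n_jumps[0]),
    }


def recovery_grid(seed: int, F_values=(0.2, 0.5, 0.66),
                  D_values=(1.0, 2.0, 4.0)) -> list:
    """Two-state parameter recovery across a grid of ground truths."""
    return [recover_two_state(F, D, seed=seed + 7 * i)
            for i, (F, D) in enumerate(
                (F, D) for F in F_values for D in D_values)]


def monte_carlo_slab_survival(D: float, n_lags: int, dt: float, dZ: float,
                              n_walkers: int = 10 ** 6, substeps: int = 20,
                              seed: int = 0) -> np.ndarray:
    """Monte-Carlo oracle for the continuous absorbing-slab survival.

    Walkers start uniform in the slab; each frame interval is split into
    ``substeps`` increments, and between-increment boundary touches are
    resolved with the Brownian-bridge crossing probability, so the
    discretization error is far below the walker noise.
    """
    rng = np.random.default_rng(seed)
    z = rng.uniform(-dZ / 2, dZ / 2, n_walkers)
    alive = np.ones(n_walkers, dtype=bool)
    sub_dt = dt / substeps
    sig = math.sqrt(2.0 * D * sub_dt)
    out = np.empty(n_lags)
    for step in range(n_lags * substeps):
        z_next = z + rng.standard_normal(n_walkers) * sig
        crossed = np.abs(z_next) >= dZ / 2
        up = np.exp(-2.0 * np.clip(dZ / 2 - z, 0, None)
                    * np.clip(dZ / 2 - z_next, 0, None) / (2.0 * D * sub_dt))
        down = np.exp(-2.0 * np.clip(z + dZ / 2, 0, None)
                      * np.clip(z_next + dZ / 2, 0, None) / (2.0 * D * sub_dt))
        bridged = rng.random(n_walkers) < (up + down)
        alive &= ~(crossed | bridged)
        z = z_next
        if (step + 1) % substeps == 0:
            out[(step + 1) // substeps - 1] = alive.mean()
    return out


def defocus_mc_comparison(seed: int, D_values=(0.5, 2.0, 10.0),
                          n_lags: int = 7, dt: float = 0.00724,
                          dZ: float = 0.700, n_walkers: int = 10 ** 6) -> dict:
    """Max |series − Monte Carlo| of the slab survival over D and lag."""
    worst = 0.0
    per_D = {}
    for i, D in enumerate(D_values):
        mc = monte_carlo_slab_survival(D, n_lags, dt, dZ,
                                       n_walkers=n_walkers, seed=seed + i)
        series = np.array([defocus_fraction(D, n, dt, dZ)
                           for n in range(1, n_lags + 1)])
        diff = float(np.max(np.abs(mc - series)))
        per_D[D] = diff
        worst = max(worst, diff)
    return {"max_abs_diff": worst, "per_D": per_D}


def residence_study(seed: int, n_movies: int = 96, n_particles: int = 15,
                    bleach_halflife: float = 7.7,
                    duration_frames: int = 3000) -> dict:
    """Full movie-based residence pipeline on a chromatin-locked control.

    Renders movies of permanently bound, immobile molecules (the control
    regime in which dissociation and focal-plane drift contribute nothing,
    so signal loss is photobleaching alone), block-averages 10 frames,
    tracks low-mobility molecules, and fits the survival curve. With true
    residence ≫ observation window the recovered slow half-life measures
    the photobleaching half-life.
    """
    durations = []
    eff_dt = None
    min_sep_um = 8 * 0.16  # emitters closer than the PSF merge; not measured here
    for rep in range(n_movies):
        for attempt in range(50):
            cfg = _simkit.SimulationConfig(
                n_particles=n_particles, duration_frames=duration_frames,
                seed=seed + rep + 100_000 * attempt, field_size=(128, 128),
                F_bound=1.0, D_bound=0.0, z_init="slice",
                bleach_halflife=bleach_halflife,
            )
            gt = _simkit.simulate_state_trajectories(cfg)
            starts = np.array([[t.x_um[0], t.y_um[0]] for t in gt])
            dists = np.sqrt(((starts[:, None] - starts[None, :]) ** 2).sum(-1))
            np.fill_diagonal(dists, np.inf)
            if dists.min() >= min_sep_um:
                break
        movie = _simkit.render_movie(
            gt, cfg, _simkit.RenderParams(photons=500, background=10,
                                          seed=seed + rep))
        averaged = average_frames(movie, 10)
        eff_dt = averaged.frame_interval_s
        tracks = _residence.track_bound(averaged, D_max_bound=0.5)
        durations.extend(tr.duration_seconds(eff_dt) for tr in tracks)
    durations = np.asarray(durations)
    window = duration_frames * 0.00724
    curve = _residence.survival_curve(durations)
    fit = _residence.fit_biexponential(curve, tau_max=window - 0.1)
    return {
        "t_half_slow": fit.t_half_slow, "t_half_fast": fit.t_half_fast,
        "fraction_slow": fit.fraction_slow, "r_squared": fit.r_squared,
        "n_tracks": int(curve.n_tracks),
        "fraction_exceeding_window":
            _residence.fraction_exceeding(durations, window - 0.1),
        "bleach_halflife_true": bleach_halflife,
    }


def recruitment_study(seed: int,
                      conditions=((22.1, 1.0, 300), (90.8, 2.0, 410),
                                  (669.0, 10.0, 460)),
                      n_cells: int = 10, noise_sd: float = 0.01,
                      baseline_frames: int = 10) -> list:
    """Recruitment pipeline recovery over (t_half, frame interval, frames)."""
    out = []
    for j, (t_half, dt, n_frames) in enumerate(conditions):
        curves = []
        for c in range(n_cells):
            series = _simkit.simulate_recruitment_series(
                t_half, noise_sd=noise_sd, n_frames=n_frames,
                frame_interval=dt, baseline_frames=baseline_frames,
                seed=seed + 1000 * j + c)
            curves.append(_recruitment.series_to_curve(series, dt,
                                                       baseline_frames))
        fit = _recruitment.fit_one_phase(_recruitment.average_curves(curves))
        out.append({"t_half_true": t_half, "t_half_est": fit.t_half,
                    "frame_interval": dt})
    return out


def tracking_oracle_study(seed: int, n_movies: int = 6, n_particles: int = 4,
                          duration_frames: int = 150) -> dict:
    """Detection + linking round trip scored against ground-truth identities.

    Renders sparse noiseless movies, runs the full detect/link pipeline, and
    scores each consecutive localization pair in the output against the
    identity of the nearest ground-truth particle (within half a pixel).
    Emitters are required to start well separated (≥25 px), as in a sparse
    single-molecule labeling benchmark; unresolvable same-pixel starts are
    not what this round trip measures.
    """
    px = 0.16
    total_gt_links = 0
    correct = 0
    total_out_links = 0
    min_sep_um = 25 * px
    for rep in range(n_movies):
        for attempt in range(50):
            cfg = _simkit.SimulationConfig(
                n_particles=n_particles, duration_frames=duration_frames,
                seed=seed + rep + 1000 * attempt, field_size=(192, 192),
                F_bound=0.5, D_free=1.0, D_bound=0.01, dZ=1e9,
                nuclear_depth=np.inf, bleach_halflife=np.inf,
                loc_error_sigma=0.0,
            )
            gt = _simkit.simulate_state_trajectories(cfg)
            starts = np.array([[t.x_um[0], t.y_um[0]] for t in gt])
            dists = np.sqrt(((starts[:, None] - starts[None, :]) ** 2).sum(-1))
            np.fill_diagonal(dists, np.inf)
            if dists.min() >= min_sep_um:
                break
        movie = _simkit.render_movie(
            gt, cfg, _simkit.RenderParams(photons=1000, background=5,
                                          noise="none"))
        locs = []
        for f in range(movie.n_frames):
            locs.extend(detect_spots(movie.frames[f],
                                     DetectionParams(threshold=10),
                                     movie.pixel_size_um, frame=f))
        tracks = link_trajectories(locs, LinkingParams(D_max=5.0),
                                   movie.frame_interval_s)
        by_frame: dict = {}
        for t in gt:
            for i in range(t.n_frames):
                by_frame.setdefault(int(t.frames[i]), []).append(
                    (t.particle_id, t.x_um[i], t.y_um[i]))

        def identify(frame, x, y):
            best = None
            for pid, gx, gy in by_frame.get(frame, []):
                d2 = (gx - x) ** 2 + (gy - y) ** 2
                if best is None or d2 < best[1]:
                    best = (pid, d2)
            if best is not None and best[1] < (0.5 * px) ** 2:
                return best[0]
            return None

        for tr in tracks:
            ids = [identify(int(tr.frames[i]), tr.x[i], tr.y[i])
                   for i in range(tr.n_locs)]
            for a, b in zip(ids, ids[1:]):
                total_out_links += 1
                if a is not None and a == b:
                    correct += 1
        total_gt_links += sum(t.n_frames - 1 for t in gt)
    return {
        "link_recovery": correct / total_gt_links,
        "link_purity": correct / max(total_out_links, 1),
        "n_gt_links": total_gt_links,
    }
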