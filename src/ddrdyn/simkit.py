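"""Synthetic single-molecule data generator.

Emulates the statistical structure of HILO single-molecule acquisitions of
HaloTag-labeled nuclear factors so that every analysis stage in this package
can be tested against known ground truth:

* 2D Brownian particles switching between a chromatin-**bound** state
  (D_bound, slow) and a **free** state (D_free, fast) via a continuous-time
  two-state Markov chain, with static localization error, exponential
  photobleaching, and an axial detection slice of depth dZ within which a
  particle must reside to be visible;
* rendered movies (Gaussian spots + Poisson shot noise + Gaussian read
  noise, the standard EMCCD approximation);
* recruitment time series following a one-phase association after a
  pre-irradiation baseline;
* linear in-gel fluorescence datasets (standard lanes + sample lanes).

Defaults mirror a fast-acquisition live-cell experiment: 7.24 ms frame
interval (138 fps), 0.16 µm pixels, a 0.700 µm detection slice, and 3000
frames per movie.

State switching is simulated as an exact continuous-time chain; each frame
interval is assigned the state occupying the majority of that interval, and
the planar/axial displacement over the interval is drawn with that state's
diffusion coefficient. Axial motion is 1D Brownian motion; a particle
outside the slice is invisible for that frame but may re-enter, so
gap-closing in the tracker is exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.constants import Avogadro

from .movie import Movie
from .tracking import Trajectory

__all__ = [
    "SimulationConfig",
    "GroundTruthTrack",
    "RenderParams",
    "simulate_state_trajectories",
    "ground_truth_to_trajectories",
    "render_movie",
    "simulate_recruitment_series",
    "simulate_gel",
]

_LN2 = math.log(2.0)


@dataclass
class SimulationConfig:
    """Parameters of the two-state diffusion simulation.

    ``F_bound`` (stationary bound occupancy) and the switching rates are
    linked by ``F_bound = k_bind / (k_bind + k_unbind)``; supply either
    ``F_bound`` (with ``k_unbind`` setting the timescale) or both rates, and
    the missing quantity is derived. Diffusion coefficients are in µm²/s,
    lengths in µm, times in seconds.
    """

    n_particles: int = 50
    duration_frames: int = 3000
    frame_interval: float = 0.00724
    pixel_size: float = 0.16
    field_size: tuple = (140, 170)  # (height, width) pixels
    D_free: float = 2.0
    D_bound: float = 0.01
    F_bound: float | None = 0.5
    k_unbind: float | None = 0.2   # residence-scale unbinding (half-life ~3.5 s)
    k_bind: float | None = None
    loc_error_sigma: float = 0.035
    dZ: float = 0.700
    nuclear_depth: float = 4.0   # axial extent of the nucleus, µm (reflecting)
    z_init: str = "nucleus"      # start z uniform over the nucleus or the slice
    bleach_halflife: float = 7.7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.z_init not in ("nucleus", "slice"):
            raise ValueError("z_init must be 'nucleus' or 'slice'")
        if np.isfinite(self.dZ) and np.isfinite(self.nuclear_depth) \
                and self.nuclear_depth < self.dZ:
            raise ValueError("nuclear_depth must be >= dZ")
        for name in ("frame_interval", "pixel_size", "dZ", "bleach_halflife"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be positive, got {v}")
        for name in ("D_free", "D_bound", "loc_error_sigma"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.n_particles < 0 or self.duration_frames < 1:
            raise ValueError("n_particles must be >= 0 and duration_frames >= 1")
        self._resolve_rates()

    def _resolve_rates(self) -> None:
        f, kb, ku = self.F_bound, self.k_bind, self.k_unbind
        if f is not None and not (0.0 <= f <= 1.0):
            raise ValueError(f"F_bound must lie in [0, 1], got {f}")
        for name, v in (("k_bind", kb), ("k_unbind", ku)):
            if v is not None and not (np.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if kb is not None and ku is not None:
            total = kb + ku
            derived = kb / total if total > 0 else None
            if f is None:
                if derived is None:
                    raise ValueError(
                        "F_bound cannot be derived from k_bind = k_unbind = 0"
                    )
                self.F_bound = derived
            elif derived is not None and abs(derived - f) > 1e-9:
                raise ValueError(
                    f"inconsistent rates: k_bind/(k_bind+k_unbind)={derived:.6g} "
                    f"but F_bound={f:.6g}"
                )
        elif f is not None:
            if ku is None:
                raise ValueError("need k_unbind (timescale) when deriving k_bind")
            if f >= 1.0:
                # permanently bound: unbinding never happens
                self.k_unbind, self.k_bind = 0.0, 1.0 if ku == 0 else ku
            else:
                self.k_bind = f * ku / (1.0 - f)
        else:
            raise ValueError("supply F_bound or both switching rates")

    @property
    def field_um(self) -> tuple:
        return (self.field_size[0] * self.pixel_size,
                self.field_size[1] * self.pixel_size)

    def with_(self, **kwargs) -> "SimulationConfig":
        """Return a copy with fields replaced (rates re-resolved)."""
        if ("F_bound" in kwargs) and not {"k_bind", "k_unbind"} & kwargs.keys():
            kwargs.setdefault("k_bind", None)
        return replace(self, **kwargs)


@dataclass
class GroundTruthTrack:
    """One simulated particle: true path, state sequence, and visibility."""

    particle_id: int
    frames: np.ndarray       # 0-based frame indices, contiguous from 0
    x_um: np.ndarray         # true positions
    y_um: np.ndarray
    z_um: np.ndarray
    x_obs: np.ndarray        # true + localization noise
    y_obs: np.ndarray
    bound: np.ndarray        # bool, state at each frame time
    in_slice: np.ndarray     # bool, |z| <= dZ/2
    bleach_frame: int | None  # first frame at which the dye is dark, or None

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def _particle_rng(seed: int, particle_id: int) -> np.random.Generator:
    # per-particle stream: adding particles never reshuffles existing ones
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence(entropy=seed, spawn_key=(particle_id,)))
    )


def _state_path(rng: np.random.Generator, cfg: SimulationConfig,
                n_frames: int) -> tuple:
    """Realize the two-state chain over ``n_frames`` frame intervals.

    Returns (bound_at_frame[n_frames], dominant_bound[n_frames-1]) where the
    dominant flag marks intervals mostly spent in the bound state.
    """
    dt = cfg.frame_interval
    total = n_frames * dt
    bound0 = bool(rng.random() < cfg.F_bound)
    switch_times = []
    t, state = 0.0, bound0
    while True:
        rate = cfg.k_unbind if state else cfg.k_bind
        if rate <= 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= total:
            break
        switch_times.append(t)
        state = not state
    knots = np.concatenate([[0.0], switch_times, [total]])
    seg_bound = (np.arange(len(knots) - 1) % 2 == 0) == bound0
    # cumulative time spent bound, piecewise linear between knots
    seg_dur = np.diff(knots)
    cum_bound = np.concatenate([[0.0], np.cumsum(seg_dur * seg_bound)])
    frame_times = np.arange(n_frames + 1) * dt
    cum_at_frames = np.interp(frame_times, knots, cum_bound)
    bound_frac = np.diff(cum_at_frames) / dt
    dominant = bound_frac > 0.5
    # state at each frame time
    seg_idx = np.clip(np.searchsorted(knots, frame_times[:n_frames], side="right") - 1,
                      0, len(seg_bound) - 1)
    bound_at_frame = seg_bound[seg_idx]
    return bound_at_frame, dominant[: n_frames - 1] if n_frames > 1 else dominant[:0]


def _reflect(path: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold an unconstrained Brownian path into [lo, hi] by reflection."""
    span = hi - lo
    r = np.mod(path - lo, 2.0 * span)
    return lo + np.minimum(r, 2.0 * span - r)


def simulate_state_trajectories(config: SimulationConfig) -> list:
    """Simulate ground-truth particle tracks under the two-state model.

    Each particle starts uniformly in the field (laterally) and uniformly
    over the nuclear depth (axially; ``z_init='slice'`` restricts the start
    to the detection slice), switches states by exponential waiting times,
    displaces with per-axis variance 2·D(state)·Δt, bleaches after an
    exponential lifetime (half-life ``bleach_halflife``), and is flagged
    out-of-slice whenever its axial position leaves [−dZ/2, dZ/2]. Axial
    motion reflects at the nuclear envelope (±nuclear_depth/2), so both
    states share the equilibrium in-slice occupancy dZ/nuclear_depth.
    Observed positions carry Gaussian error of s.d. ``loc_error_sigma``.
    Equal seeds give bit-identical output.
    """
    cfg = config
    dt = cfg.frame_interval
    fy, fx = cfg.field_um
    tracks: list = []
    for pid in range(cfg.n_particles):
        rng = _particle_rng(cfg.seed, pid)
        # bleaching first: it sets how many frames exist at all
        if np.isfinite(cfg.bleach_halflife):
            t_bleach = rng.exponential(cfg.bleach_halflife / _LN2)
            bleach_frame = int(t_bleach / dt) + 1
        else:
            t_bleach, bleach_frame = np.inf, None
        if bleach_frame is not None and bleach_frame >= cfg.duration_frames:
            bleach_frame = None
        n_frames = cfg.duration_frames if bleach_frame is None else bleach_frame

        bound_at_frame, dominant_bound = _state_path(rng, cfg, n_frames)
        D_step = np.where(dominant_bound, cfg.D_bound, cfg.D_free)
        step_sd = np.sqrt(2.0 * D_step * dt)

        x0 = rng.uniform(0.0, fx)
        y0 = rng.uniform(0.0, fy)
        z_half = (cfg.dZ if cfg.z_init == "slice" else cfg.nuclear_depth) / 2.0
        if not np.isfinite(z_half):
            z_half = cfg.dZ / 2.0 if np.isfinite(cfg.dZ) else 0.0
        z0 = rng.uniform(-z_half, z_half) if z_half > 0 else 0.0
        steps = rng.standard_normal((3, n_frames - 1)) * step_sd
        x = _reflect(x0 + np.concatenate([[0.0], np.cumsum(steps[0])]), 0.0, fx)
        y = _reflect(y0 + np.concatenate([[0.0], np.cumsum(steps[1])]), 0.0, fy)
        z = z0 + np.concatenate([[0.0], np.cumsum(steps[2])])
        if np.isfinite(cfg.nuclear_depth):
            z = _reflect(z, -cfg.nuclear_depth / 2.0, cfg.nuclear_depth / 2.0)

        noise = rng.standard_normal((2, n_frames)) * cfg.loc_error_sigma
        tracks.append(GroundTruthTrack(
            particle_id=pid,
            frames=np.arange(n_frames),
            x_um=x, y_um=y, z_um=z,
            x_obs=x + noise[0], y_obs=y + noise[1],
            bound=bound_at_frame,
            in_slice=np.abs(z) <= cfg.dZ / 2.0,
            bleach_frame=bleach_frame,
        ))
    return tracks


def ground_truth_to_trajectories(tracks: list, max_gaps: int = 2,
                                 min_track_length: int = 3) -> list:
    """Idealized tracker output: observed positions segmented by visibility.

    A particle's visible frames are split into separate trajectories wherever
    it stays out of the detection slice for more than ``max_gaps`` consecutive
    frames, mirroring the gap-closing rule of the real linker. Useful for
    parameter-recovery studies where rendering and re-detecting movies would
    only add localization noise already modeled by ``loc_error_sigma``.
    """
    out: list = []
    next_id = 0
    for tr in tracks:
        vis = np.flatnonzero(tr.in_slice)
        if vis.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(vis) > max_gaps + 1)
        for seg in np.split(vis, breaks + 1):
            if len(seg) < min_track_length:
                continue
            out.append(Trajectory(
                track_id=next_id,
                frames=tr.frames[seg],
                x=tr.x_obs[seg],
                y=tr.y_obs[seg],
                intensity=np.ones(len(seg)),
            ))
            next_id += 1
    return out


@dataclass
class RenderParams:
    """Camera model for rendering ground-truth tracks into a movie."""

    photons: float = 500.0       # integrated photons per in-focus spot
    psf_sigma_px: float = 1.0
    background: float = 10.0     # photons per pixel per frame
    noise: str = "poisson"       # "poisson" (+ optional read noise) or "none"
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise not in ("poisson", "none"):
            raise ValueError("noise must be 'poisson' or 'none'")
        if self.photons < 0 or self.background < 0 or self.psf_sigma_px <= 0:
            raise ValueError("photons/background must be >= 0 and psf_sigma_px > 0")


def render_movie(tracks: list, config: SimulationConfig,
                 params: RenderParams | None = None) -> Movie:
    """Render ground-truth tracks into a calibrated movie.

    Each in-slice, unbleached particle appears as a 2D Gaussian spot whose
    pixel sum equals ``params.photons``; an empty track list yields a
    background-only movie. Spots are rendered at the *true* positions —
    localization error is what the detector incurs, not a camera property.
    """
    params = params or RenderParams()
    cfg = config
    H, W = cfg.field_size
    T = cfg.duration_frames
    frames = np.full((T, H, W), float(params.background))
    halfwin = max(3, int(math.ceil(4.0 * params.psf_sigma_px)))

    for tr in tracks:
        visible = tr.in_slice
        cx = tr.x_um / cfg.pixel_size
        cy = tr.y_um / cfg.pixel_size
        for i in np.flatnonzero(visible):
            f = int(tr.frames[i])
            if f >= T:
                continue
            x0, y0 = cx[i], cy[i]
            ix, iy = int(round(x0)), int(round(y0))
            xs = np.arange(max(0, ix - halfwin), min(W, ix + halfwin + 1))
            ys = np.arange(max(0, iy - halfwin), min(H, iy + halfwin + 1))
            if xs.size == 0 or ys.size == 0:
                continue
            gx = np.exp(-0.5 * ((xs - x0) / params.psf_sigma_px) ** 2)
            gy = np.exp(-0.5 * ((ys - y0) / params.psf_sigma_px) ** 2)
            patch = np.outer(gy, gx)
            s = patch.sum()
            if s > 0:
                frames[f, ys[0]: ys[-1] + 1, xs[0]: xs[-1] + 1] += (
                    patch * (params.photons / s)
                )

    if params.noise == "poisson":
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence(entropy=params.seed,
                                                   spawn_key=(0x6D07,)))
        )
        frames = rng.poisson(frames).astype(float)
        if params.read_noise_sd > 0:
            frames += rng.standard_normal(frames.shape) * params.read_noise_sd
    return Movie(frames, cfg.frame_interval, cfg.pixel_size,
                 meta={"source": "ddrdyn.simkit"})


def simulate_recruitment_series(t_half: float, plateau: float = 1.0,
                                noise_sd: float = 0.0, n_frames: int = 300,
                                frame_interval: float = 1.0,
                                baseline_frames: int = 10,
                                baseline: float = 0.0,
                                seed: int | None = None) -> np.ndarray:
    """Intensity time series of one-phase association recruitment.

    Frames before ``baseline_frames`` sit at ``baseline``; irradiation occurs
    at the time of the last baseline frame, and subsequent frames follow
    ``baseline + plateau · (1 − 2^(−t/t_half))`` with Gaussian noise of s.d.
    ``noise_sd``, where t is time since irradiation.
    """
    if not (t_half > 0):
        raise ValueError(f"t_half must be positive, got {t_half}")
    if baseline_frames < 1 or baseline_frames >= n_frames:
        raise ValueError("need 1 <= baseline_frames < n_frames")
    if frame_interval <= 0 or noise_sd < 0:
        raise ValueError("frame_interval must be > 0 and noise_sd >= 0")
    idx = np.arange(n_frames)
    t = (idx - (baseline_frames - 1)) * frame_interval  # s since irradiation
    values = np.where(t <= 0, baseline,
                      baseline + plateau * (1.0 - np.exp2(-t / t_half)))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.standard_normal(n_frames) * noise_sd
    return values


def simulate_gel(standard_fmol, cells_per_lane, true_molecules_per_cell: float,
                 slope: float, noise_sd: float = 0.0, intercept: float = 0.0,
                 seed: int | None = None) -> pd.DataFrame:
    """Synthetic in-gel fluorescence lane table.

    Standard lanes carry ``slope·fmol + intercept`` signal; sample lanes carry
    the signal of ``cells · true_molecules_per_cell`` molecules expressed in
    fmol (molecules / N_A × 10¹⁵). Gaussian lane noise of s.d. ``noise_sd``.
    Columns: lane_id, role ∈ {standard, sample}, amount, signal,
    loading_signal.
    """
    standard_fmol = np.asarray(standard_fmol, dtype=float)
    cells_per_lane = np.asarray(cells_per_lane, dtype=float)
    if np.any(standard_fmol < 0) or np.any(cells_per_lane < 0):
        raise ValueError("amounts must be non-negative")
    if true_molecules_per_cell < 0 or slope <= 0:
        raise ValueError("true_molecules_per_cell >= 0 and slope > 0 required")
    rng = np.random.default_rng(seed)
    rows = []
    for i, fmol in enumerate(standard_fmol):
        signal = slope * fmol + intercept
        if noise_sd > 0:
            signal += rng.standard_normal() * noise_sd
        rows.append((f"std{i}", "standard", fmol, signal, 1.0))
    for i, cells in enumerate(cells_per_lane):
        fmol = cells * true_molecules_per_cell / Avogadro * 1e15
        signal = slope * fmol + intercept
        if noise_sd > 0:
            signal += rng.standard_normal() * noise_sd
        rows.append((f"smp{i}", "sample", cells, signal, 1.0))
    return pd.DataFrame(rows, columns=["lane_id", "role", "amount",
                                       "signal", "loading_signal"])
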