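"""Configuration, trajectory I/O, logging, and pipeline drivers.

Conventions enforced here and assumed package-wide: frames are 0-based,
physical coordinates in µm, times in seconds. Trajectories interchange as
delimited text with header ``track_id,frame,x_um,y_um,intensity``; configs
are flat ``key=value`` text files with dotted stage prefixes; every
pipeline run logs the parameters actually used and is deterministic given
its seed.

Four pipelines are wired: ``diffusion`` (simulate or load trajectories →
jump-length histograms → two/three-state fit, per cell and pooled),
``residence`` (movie → 10-frame averaging → bound-molecule tracking →
survival curve → biexponential fit), ``recruitment`` (per-cell series →
normalization → averaging → one-phase association fit) and ``abundance``
(lane table → standard curves → molecules per cell). ``demo`` chains small
synthetic versions of all four.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import abundance as _abundance
from . import diffusion as _diffusion
from . import recruitment as _recruitment
from . import residence as _residence
from . import simkit as _simkit
from .movie import read_movie
from .tracking import Trajectory, average_frames

__all__ = [
    "PipelineConfig",
    "read_trajectories",
    "write_trajectories",
    "read_config",
    "run_pipeline",
    "PIPELINES",
]

logger = logging.getLogger("ddrdyn")


# ---------------------------------------------------------------------------
# trajectory interchange format

_TRAJ_COLUMNS = ["track_id", "frame", "x_um", "y_um", "intensity"]


def write_trajectories(tracks, path: str) -> None:
    """Write trajectories as delimited text (the package interchange format)."""
    rows = []
    for tr in tracks:
        for i in range(tr.n_locs):
            rows.append((tr.track_id, int(tr.frames[i]), tr.x[i], tr.y[i],
                         tr.intensity[i]))
    df = pd.DataFrame(rows, columns=_TRAJ_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9g")


def read_trajectories(path: str) -> list:
    """Read trajectories written by :func:`write_trajectories`.

    Enforces strictly increasing frames within each track and reports the
    1-based line number of any malformed row.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty file (missing header)")
    missing = [c for c in _TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in _TRAJ_COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}:{line}: malformed value in column {col!r}")
        if df[col].isna().any():
            line = int(df[col].isna().idxmax()) + 2
            raise ValueError(f"{path}:{line}: missing value in column {col!r}")
    tracks = []
    for tid, grp in df.groupby("track_id", sort=True):
        frames = grp["frame"].to_numpy(dtype=int)
        if np.any(np.diff(frames) <= 0):
            j = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 1
            line = int(grp.index[j]) + 2
            raise ValueError(
                f"{path}:{line}: frames not strictly increasing in track {tid}"
            )
        tracks.append(Trajectory(
            track_id=int(tid), frames=frames,
            x=grp["x_um"].to_numpy(dtype=float),
            y=grp["y_um"].to_numpy(dtype=float),
            intensity=grp["intensity"].to_numpy(dtype=float),
        ))
    return tracks


# ---------------------------------------------------------------------------
# configuration

_GLOBAL_KEYS = {
    "frame_interval_s": float,
    "pixel_size_um": float,
    "dZ_um": float,
    "seed": int,
    "output_dir": str,
}
_STAGE_KEYS = {
    "sim.n_particles": int,
    "sim.duration_frames": int,
    "sim.D_free": float,
    "sim.D_bound": float,
    "sim.F_bound": float,
    "sim.k_unbind": float,
    "sim.loc_error_sigma_um": float,
    "sim.bleach_halflife_s": float,
    "diffusion.n_cells": int,
    "diffusion.n_states": int,
    "diffusion.sigma_um": float,
    "diffusion.trajectories": str,   # glob of per-cell trajectory files
    "residence.movie": str,          # TIFF path; simulated when absent
    "residence.window": int,
    "residence.D_max_bound": float,
    "residence.observation_window_s": float,
    "recruitment.t_half_s": float,
    "recruitment.n_cells": int,
    "recruitment.n_frames": int,
    "recruitment.frame_interval_s": float,
    "recruitment.baseline_frames": int,
    "recruitment.noise_sd": float,
    "abundance.lanes": str,          # lane-table CSV; simulated when absent
    "abundance.tev_factor": float,
    "abundance.molecules_per_cell": float,
}
_DEFAULTS = {
    "frame_interval_s": 0.00724,
    "pixel_size_um": 0.16,
    "dZ_um": 0.700,
    "seed": 0,
    "output_dir": "ddrdyn_out",
    "sim.n_particles": 200,
    "sim.duration_frames": 300,
    "sim.D_free": 2.0,
    "sim.D_bound": 0.01,
    "sim.F_bound": 0.5,
    "sim.k_unbind": 0.2,
    "sim.loc_error_sigma_um": 0.035,
    "sim.bleach_halflife_s": 7.7,
    "diffusion.n_cells": 3,
    "diffusion.n_states": 2,
    "diffusion.sigma_um": 0.035,
    "residence.window": 10,
    "residence.D_max_bound": 0.5,
    "residence.observation_window_s": 22.0,
    "recruitment.t_half_s": 22.1,
    "recruitment.n_cells": 8,
    "recruitment.n_frames": 300,
    "recruitment.frame_interval_s": 1.0,
    "recruitment.baseline_frames": 10,
    "recruitment.noise_sd": 0.01,
    "abundance.tev_factor": 1.5,
    "abundance.molecules_per_cell": 50000.0,
}


@dataclass
class PipelineConfig:
    """Validated flat configuration; unknown keys are rejected."""

    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = {**_GLOBAL_KEYS, **_STAGE_KEYS}
        merged = dict(_DEFAULTS)
        for key, raw in self.values.items():
            if key not in known:
                raise ValueError(f"unknown config key {key!r}")
            merged[key] = known[key](raw)
        for key in ("frame_interval_s", "pixel_size_um", "dZ_um"):
            if merged[key] <= 0:
                raise ValueError(f"{key} must be positive")
        self.values = merged

    def __getitem__(self, key: str):
        return self.values[key]

    def get(self, key: str, default=None):
        return self.values.get(key, default)


def read_config(path: str) -> PipelineConfig:
    """Parse a flat key=value config file (# comments, blank lines ignored)."""
    values: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, value = line.split("=", 1)
            values[key.strip()] = value.strip()
    return PipelineConfig(values)


# ---------------------------------------------------------------------------
# pipelines

def _write_keyvalues(path: str, items: dict) -> None:
    with open(path, "w") as fh:
        for key, value in items.items():
            if isinstance(value, float):
                fh.write(f"{key}={value:.9g}\n")
            else:
                fh.write(f"{key}={value}\n")


def _log_params(config: PipelineConfig, prefix: tuple) -> None:
    for key, value in sorted(config.values.items()):
        if key.split(".")[0] in prefix or "." not in key:
            logger.info("param %s=%r", key, value)


def _sim_config(config: PipelineConfig, seed_offset: int = 0,
                **overrides) -> "_simkit.SimulationConfig":
    kwargs = dict(
        n_particles=config["sim.n_particles"],
        duration_frames=config["sim.duration_frames"],
        frame_interval=config["frame_interval_s"],
        pixel_size=config["pixel_size_um"],
        D_free=config["sim.D_free"],
        D_bound=config["sim.D_bound"],
        F_bound=config["sim.F_bound"],
        k_unbind=config["sim.k_unbind"],
        loc_error_sigma=config["sim.loc_error_sigma_um"],
        dZ=config["dZ_um"],
        bleach_halflife=config["sim.bleach_halflife_s"],
        seed=config["seed"] + seed_offset,
    )
    kwargs.update(overrides)
    return _simkit.SimulationConfig(**kwargs)


def _run_diffusion(config: PipelineConfig, outdir: str) -> dict:
    dt = config["frame_interval_s"]
    traj_glob = config.get("diffusion.trajectories")
    tracks_by_cell: dict = {}
    if traj_glob:
        import glob as _glob

        files = sorted(_glob.glob(traj_glob))
        if not files:
            raise FileNotFoundError(f"no trajectory files match {traj_glob!r}")
        for f in files:
            tracks_by_cell[os.path.basename(f)] = read_trajectories(f)
    else:
        for cell in range(config["diffusion.n_cells"]):
            sim = _sim_config(config, seed_offset=cell)
            gt = _simkit.simulate_state_trajectories(sim)
            tracks = _simkit.ground_truth_to_trajectories(gt)
            tracks_by_cell[f"cell{cell}"] = tracks
            write_trajectories(tracks, os.path.join(outdir, f"cell{cell}_tracks.csv"))
    per_cell, pooled = _diffusion.per_cell_fit(
        tracks_by_cell, dt, n_states=config["diffusion.n_states"],
        sigma=config["diffusion.sigma_um"], dZ=config["dZ_um"],
        jumps_to_consider=None)
    _diffusion.fits_table(per_cell).to_csv(
        os.path.join(outdir, "per_cell_fits.csv"), index=False,
        float_format="%.9g")
    result = {"D_free": pooled.D_free, "D_bound": pooled.D_bound,
              "F_bound": pooled.F_bound, "rss": pooled.rss,
              "n_jumps": pooled.n_jumps, "n_cells": len(per_cell)}
    _write_keyvalues(os.path.join(outdir, "pooled_fit.txt"), result)
    return result


def _run_residence(config: PipelineConfig, outdir: str) -> dict:
    movie_path = config.get("residence.movie")
    if movie_path:
        if not os.path.exists(movie_path):
            raise FileNotFoundError(f"residence movie not found: {movie_path}")
        movie = read_movie(movie_path)
    else:
        # chromatin-locked control species: permanently bound, in-slice start
        sim = _sim_config(config, seed_offset=101, F_bound=1.0, D_bound=1e-4,
                          z_init="slice", n_particles=30, field_size=(96, 96),
                          duration_frames=max(1500, config["sim.duration_frames"]),
                          bleach_halflife=min(config["sim.bleach_halflife_s"],
                                              1500 * config["frame_interval_s"] / 3))
        gt = _simkit.simulate_state_trajectories(sim)
        movie = _simkit.render_movie(
            gt, sim, _simkit.RenderParams(photons=500, background=10,
                                          noise="poisson", seed=config["seed"]))
    averaged = average_frames(movie, config["residence.window"])
    tracks = _residence.track_bound(averaged,
                                    D_max_bound=config["residence.D_max_bound"])
    if not tracks:
        raise RuntimeError("residence: no bound tracks found")
    durations = np.array([tr.duration_seconds(averaged.frame_interval_s)
                          for tr in tracks])
    curve = _residence.survival_curve(durations)
    pd.DataFrame({"tau_s": curve.tau, "survival": curve.survival}).to_csv(
        os.path.join(outdir, "survival.csv"), index=False, float_format="%.9g")
    movie_span = movie.n_frames * movie.frame_interval_s
    fit = _residence.fit_biexponential(curve, tau_max=movie_span - 0.01)
    window = config["residence.observation_window_s"]
    result = {"t_half_fast_s": fit.t_half_fast, "t_half_slow_s": fit.t_half_slow,
              "fraction_slow": fit.fraction_slow, "r_squared": fit.r_squared,
              "n_tracks": curve.n_tracks,
              "fraction_exceeding_window":
                  _residence.fraction_exceeding(durations, window)}
    _write_keyvalues(os.path.join(outdir, "residence_fit.txt"), result)
    return result


def _run_recruitment(config: PipelineConfig, outdir: str) -> dict:
    curves = []
    for cell in range(config["recruitment.n_cells"]):
        series = _simkit.simulate_recruitment_series(
            t_half=config["recruitment.t_half_s"],
            noise_sd=config["recruitment.noise_sd"],
            n_frames=config["recruitment.n_frames"],
            frame_interval=config["recruitment.frame_interval_s"],
            baseline_frames=config["recruitment.baseline_frames"],
            seed=config["seed"] * 1000 + cell,
        )
        curves.append(_recruitment.series_to_curve(
            series, config["recruitment.frame_interval_s"],
            config["recruitment.baseline_frames"]))
    mean_curve = _recruitment.average_curves(curves)
    pd.DataFrame({"t_s": mean_curve.time, "intensity_norm": mean_curve.intensity}
                 ).to_csv(os.path.join(outdir, "recruitment_curve.csv"),
                          index=False, float_format="%.9g")
    fit = _recruitment.fit_one_phase(mean_curve)
    result = {"K_per_s": fit.K, "t_half_s": fit.t_half,
              "residual": fit.residual, "n_cells": mean_curve.n_cells}
    _write_keyvalues(os.path.join(outdir, "recruitment_fit.txt"), result)
    return result


def _run_abundance(config: PipelineConfig, outdir: str) -> dict:
    lanes_path = config.get("abundance.lanes")
    if lanes_path:
        if not os.path.exists(lanes_path):
            raise FileNotFoundError(f"lane table not found: {lanes_path}")
        lanes = pd.read_csv(lanes_path)
    else:
        lanes = _simkit.simulate_gel(
            standard_fmol=[0.25, 0.5, 1.0, 2.0, 4.0],
            cells_per_lane=[20000.0, 40000.0],
            true_molecules_per_cell=config["abundance.molecules_per_cell"],
            slope=1000.0, seed=config["seed"])
        # fusion protein runs dimmer than the free tag standard; the TEV
        # factor applied downstream undoes exactly this
        sample = lanes["role"] == "sample"
        lanes.loc[sample, "signal"] /= config["abundance.tev_factor"]
        lanes.to_csv(os.path.join(outdir, "lanes.csv"), index=False,
                     float_format="%.9g")
    table = _abundance.quantify_gel(lanes, tev_factor=config["abundance.tev_factor"])
    table.to_csv(os.path.join(outdir, "abundance.csv"), index=False,
                 float_format="%.9g")
    return {"mean_molecules_per_cell": float(table["molecules_per_cell"].mean()),
            "n_lanes": len(table)}


PIPELINES = {
    "diffusion": (_run_diffusion, ("sim", "diffusion")),
    "residence": (_run_residence, ("sim", "residence")),
    "recruitment": (_run_recruitment, ("recruitment",)),
    "abundance": (_run_abundance, ("abundance",)),
}


def run_pipeline(config: PipelineConfig, pipeline: str) -> dict:
    """Run one named pipeline; outputs land in ``<output_dir>/<pipeline>/``.

    Deterministic given the config seed. Every parameter used is logged to
    stderr and to ``run.log`` in the output directory; stage failures abort
    with the stage name in the error.
    """
    if pipeline == "demo":
        return {name: run_pipeline(config, name) for name in PIPELINES}
    if pipeline not in PIPELINES:
        raise ValueError(f"unknown pipeline {pipeline!r}; "
                         f"choose from {sorted(PIPELINES)} or 'demo'")
    func, prefixes = PIPELINES[pipeline]
    outdir = os.path.join(config["output_dir"], pipeline)
    os.makedirs(outdir, exist_ok=True)
    handler = logging.FileHandler(os.path.join(outdir, "run.log"), mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        logger.info("pipeline %s starting", pipeline)
        _log_params(config, prefixes)
        try:
            result = func(config, outdir)
        except Exception as exc:
            raise type(exc)(f"[{pipeline}] {exc}") from exc
        logger.info("pipeline %s finished: %r", pipeline, result)
        return result
    finally:
        logger.removeHandler(handler)
        handler.close()
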