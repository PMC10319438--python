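"""Calibrated image-stack container and TIFF I/O.

A :class:`Movie` is the raw substrate of every imaging analysis in this
package: a time-ordered stack of 2D intensity frames together with the two
pieces of physical calibration that all downstream arithmetic depends on,
the frame interval (seconds) and the pixel size (µm).

Coordinate conventions (used package-wide): frames are 0-based; the origin
of the continuous coordinate system is the *center* of the top-left pixel,
x increases rightward (columns), y downward (rows); all physical distances
are in µm and times in seconds.
"""

from __future__ import annotations

import glob as _glob
import os
from dataclasses import dataclass, field

import numpy as np
import tifffile

__all__ = ["Movie", "read_movie", "write_movie"]


@dataclass
class Movie:
    """Time × y × x intensity stack with physical calibration."""

    frames: np.ndarray  # shape (T, H, W)
    frame_interval_s: float
    pixel_size_um: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError(
                f"movie frames must be a (T, H, W) array, got shape {self.frames.shape}"
            )
        if not (self.frame_interval_s > 0 and np.isfinite(self.frame_interval_s)):
            raise ValueError("frame_interval_s must be positive and finite")
        if not (self.pixel_size_um > 0 and np.isfinite(self.pixel_size_um)):
            raise ValueError("pixel_size_um must be positive and finite")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple:
        return self.frames.shape

    @property
    def frame_rate_fps(self) -> float:
        return 1.0 / self.frame_interval_s

    @property
    def duration_s(self) -> float:
        """Total time spanned by the acquisition (n_frames × interval)."""
        return self.n_frames * self.frame_interval_s


def _sidecar_path(path: str) -> str:
    return path + ".meta.txt"


def write_movie(movie: Movie, path: str) -> None:
    """Write a movie as a multi-page TIFF plus a plain-text metadata sidecar.

    The sidecar (``<path>.meta.txt``) holds ``key=value`` lines with at least
    ``frame_interval_s`` and ``pixel_size_um``.
    """
    tifffile.imwrite(path, movie.frames.astype(np.float32),
                     photometric="minisblack")
    with open(_sidecar_path(path), "w") as fh:
        fh.write(f"frame_interval_s={movie.frame_interval_s!r}\n")
        fh.write(f"pixel_size_um={movie.pixel_size_um!r}\n")
        for key, value in movie.meta.items():
            fh.write(f"{key}={value}\n")


def read_movie(path: str, frame_interval_s: float | None = None,
               pixel_size_um: float | None = None) -> Movie:
    """Read a movie from a multi-page TIFF or a per-frame file series.

    ``path`` may be a single TIFF or a glob pattern matching one file per
    frame (sorted lexicographically). Calibration is taken from the sidecar
    written by :func:`write_movie` unless overridden by the keyword
    arguments.
    """
    if os.path.exists(path):
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
        sidecar = _sidecar_path(path)
    else:
        files = sorted(_glob.glob(path))
        if not files:
            raise FileNotFoundError(f"no movie found at {path!r}")
        stack = np.stack([tifffile.imread(f) for f in files])
        sidecar = _sidecar_path(files[0])

    meta: dict = {}
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            for line in fh:
                line = line.strip()
                if not line or "=" not in line:
                    continue
                key, value = line.split("=", 1)
                meta[key.strip()] = value.strip()
    if frame_interval_s is None:
        if "frame_interval_s" not in meta:
            raise ValueError(f"frame_interval_s not given and no sidecar for {path!r}")
        frame_interval_s = float(meta.pop("frame_interval_s"))
    else:
        meta.pop("frame_interval_s", None)
    if pixel_size_um is None:
        if "pixel_size_um" not in meta:
            raise ValueError(f"pixel_size_um not given and no sidecar for {path!r}")
        pixel_size_um = float(meta.pop("pixel_size_um"))
    else:
        meta.pop("pixel_size_um", None)
    return Movie(np.asarray(stack, dtype=float), frame_interval_s, pixel_size_um, meta)
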