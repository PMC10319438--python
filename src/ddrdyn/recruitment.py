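"""Recruitment kinetics at laser-microirradiation sites.

The measurement chain: drift-correct the movie (translation registration to
the first frame), average the intensity inside a user-drawn ROI per frame,
subtract the pre-irradiation baseline, normalize each cell's curve to its
own brightest frame, average cells, renormalize the mean curve so its
brightest frame equals one, and fit the one-phase association

    Y(t) = 1 − exp(−K·t),    t_1/2 = ln2 / K,

with Y0 fixed at 0 and the plateau fixed at 1 (both are enforced by the
normalization). Cells imaged at different frame rates are fit separately,
never resampled onto a common grid.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import shift as nd_shift
from scipy.optimize import curve_fit
from skimage.registration import phase_cross_correlation

from .movie import Movie

__all__ = [
    "RecruitmentCurve",
    "OnePhaseFit",
    "register_movie",
    "extract_normalized_curve",
    "normalize_series",
    "series_to_curve",
    "average_curves",
    "fit_one_phase",
]

_LN2 = math.log(2.0)


@dataclass
class RecruitmentCurve:
    """Normalized recruitment intensity vs. time since irradiation."""

    time: np.ndarray       # s, strictly increasing; t <= 0 is pre-irradiation
    intensity: np.ndarray  # normalized so the brightest frame is 1
    n_cells: int = 1

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")


@dataclass
class OnePhaseFit:
    K: float        # s^-1
    t_half: float   # ln2 / K, s
    residual: float


def register_movie(movie: Movie, upsample_factor: int = 20):
    """Drift-correct a movie by translation to its first frame.

    Per-frame shifts are estimated by cross-correlation (sub-pixel via
    ``upsample_factor``) and applied with linear interpolation. Featureless
    frames get identity shifts with a warning. Returns ``(movie, shifts)``
    with shifts in (row, col) pixels.
    """
    if movie.n_frames < 2:
        raise ValueError("registration needs at least 2 frames")
    ref = movie.frames[0]
    out = np.empty_like(movie.frames)
    out[0] = ref
    shifts = np.zeros((movie.n_frames, 2))
    for f in range(1, movie.n_frames):
        frame = movie.frames[f]
        if frame.std() == 0 or ref.std() == 0:
            warnings.warn(f"featureless frame {f}: identity shift applied",
                          stacklevel=2)
            out[f] = frame
            continue
        shift, _, _ = phase_cross_correlation(ref, frame,
                                              upsample_factor=upsample_factor)
        shifts[f] = shift
        out[f] = nd_shift(frame, shift, order=1, mode="nearest")
    registered = Movie(out, movie.frame_interval_s, movie.pixel_size_um,
                       meta=dict(movie.meta, registered=True))
    return registered, shifts


def normalize_series(values, baseline_frames: int) -> np.ndarray:
    """Baseline-subtract and peak-normalize one cell's intensity series.

    The mean of the first ``baseline_frames`` frames is subtracted and the
    series divided by its maximum; the operation is idempotent and
    invariant to rescaling the input. Raises if no signal remains above
    baseline.
    """
    values = np.asarray(values, dtype=float)
    if baseline_frames < 1 or baseline_frames >= values.size:
        raise ValueError("need 1 <= baseline_frames < series length")
    sub = values - values[:baseline_frames].mean()
    peak = sub.max()
    if peak <= 0:
        raise ValueError("no recruitment signal: maximum not above baseline")
    return sub / peak


def series_to_curve(values, frame_interval: float,
                    baseline_frames: int) -> RecruitmentCurve:
    """Normalize a raw intensity series and attach its time axis.

    Irradiation is placed at the time of the last baseline frame, so the
    first post-irradiation frame sits at t = frame_interval.
    """
    norm = normalize_series(values, baseline_frames)
    idx = np.arange(norm.size)
    time = (idx - (baseline_frames - 1)) * frame_interval
    return RecruitmentCurve(time=time, intensity=norm, n_cells=1)


def extract_normalized_curve(movie: Movie, roi, baseline_frames: int) -> RecruitmentCurve:
    """Per-cell normalized recruitment curve from a movie and an ROI.

    ``roi`` is either a boolean mask on the movie's pixel grid or a
    rectangle ``(x0, y0, x1, y1)`` in pixels (inclusive corners). The mean
    ROI intensity per frame is baseline-subtracted and peak-normalized.
    """
    H, W = movie.frames.shape[1:]
    if isinstance(roi, np.ndarray) and roi.dtype == bool:
        if roi.shape != (H, W):
            raise ValueError("ROI mask shape does not match the movie")
        mask = roi
    else:
        x0, y0, x1, y1 = (int(v) for v in roi)
        if not (0 <= x0 <= x1 < W and 0 <= y0 <= y1 < H):
            raise ValueError(f"ROI {roi} not inside the {H}x{W} field")
        mask = np.zeros((H, W), dtype=bool)
        mask[y0:y1 + 1, x0:x1 + 1] = True
    series = movie.frames[:, mask].mean(axis=1)
    return series_to_curve(series, movie.frame_interval_s, baseline_frames)


def average_curves(curves) -> RecruitmentCurve:
    """Average per-cell curves and renormalize the brightest mean frame to 1.

    All curves must share one frame grid (same rate and baseline length);
    curves of unequal length are truncated to the shortest.
    """
    curves = list(curves)
    if not curves:
        raise ValueError("no curves to average")
    n = min(c.time.size for c in curves)
    t0 = curves[0].time[:n]
    for c in curves[1:]:
        if not np.allclose(c.time[:n], t0):
            raise ValueError("curves are not on a common time grid")
    mean = np.mean([c.intensity[:n] for c in curves], axis=0)
    peak = mean.max()
    if peak <= 0:
        raise ValueError("averaged curve has no signal above baseline")
    return RecruitmentCurve(time=t0, intensity=mean / peak,
                            n_cells=sum(c.n_cells for c in curves))


def fit_one_phase(curve: RecruitmentCurve) -> OnePhaseFit:
    """Fit Y = 1 − exp(−K·t) to the post-irradiation part of a curve."""
    post = curve.time > 0
    t = curve.time[post]
    y = curve.intensity[post]
    if t.size < 5:
        raise ValueError("need at least 5 post-irradiation points")
    # initialize K from the first crossing of half-maximum
    above = np.flatnonzero(y >= 0.5)
    t_half0 = t[above[0]] if above.size else t[-1] / 2.0
    k0 = _LN2 / max(t_half0, t[0])
    try:
        popt, _ = curve_fit(lambda tt, k: 1.0 - np.exp(-k * tt), t, y,
                            p0=(k0,), bounds=(1e-12, np.inf), maxfev=10000)
    except RuntimeError as exc:
        raise RuntimeError(f"one-phase association fit did not converge: {exc}")
    k = float(popt[0])
    rss = float(np.sum((1.0 - np.exp(-k * t) - y) ** 2))
    return OnePhaseFit(K=k, t_half=_LN2 / k, residual=rss)
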