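"""Absolute protein abundance from in-gel fluorescence.

Molecules per cell are computed by calibrating a sample lane's fluorescence
against two standard curves — known femtomole amounts of purified labeled
tag protein, and lysate from known cell numbers — then applying two
multiplicative corrections: a TEV factor (the cleaved tag runs brighter
than the fusion protein on SDS-PAGE; observed range ~1.04–3.04×) and a
western factor translating tagged-line abundance into the untagged
wild-type equivalent. Uncertainties combine relative variances in
quadrature for products and quotients.

Gel-derived relative abundances can be cross-checked against flow-cytometry
mean fluorescence via Pearson correlation after normalizing both to a
common reference line.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.constants import Avogadro
from scipy.stats import linregress, pearsonr

__all__ = [
    "StandardCurve",
    "AbundanceResult",
    "NonQuantifiableError",
    "fit_standard_curve",
    "tev_correction_factor",
    "molecules_per_cell",
    "western_correction",
    "method_correlation",
    "quantify_gel",
]


class NonQuantifiableError(ValueError):
    """Sample signal indistinguishable from (or below) the blank."""


@dataclass
class StandardCurve:
    """Ordinary least-squares calibration line (signal vs. amount)."""

    slope: float
    intercept: float
    r_squared: float

    def amount(self, signal: float) -> float:
        """Invert the calibration: signal → amount."""
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive to invert")
        return (signal - self.intercept) / self.slope


@dataclass
class AbundanceResult:
    """Molecules per cell with propagated uncertainty."""

    molecules_per_cell: float
    sd: float
    tev_factor: float = 1.0
    western_factor: float = 1.0


def fit_standard_curve(x, y) -> StandardCurve:
    """Fit a calibration line through measured points (≥3, OLS).

    The intercept is fit, not forced through the origin: gel backgrounds
    are nonzero. Degenerate x (no spread) raises; constant y yields slope 0
    and R² = 0, rejected later at inversion time.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("need >= 3 paired calibration points")
    if np.ptp(x) == 0:
        raise ValueError("degenerate calibration: all amounts equal")
    if np.ptp(y) == 0:
        return StandardCurve(slope=0.0, intercept=float(y[0]), r_squared=0.0)
    res = linregress(x, y)
    return StandardCurve(slope=float(res.slope), intercept=float(res.intercept),
                         r_squared=float(res.rvalue ** 2))


def tev_correction_factor(signal_cleaved: float, signal_uncleaved: float,
                          loading_cleaved: float = 1.0,
                          loading_uncleaved: float = 1.0) -> float:
    """Loading-normalized cleaved/uncleaved fluorescence ratio.

    Applied multiplicatively to fusion-protein signal to compensate for the
    migration-dependent dimming of the intact fusion relative to free tag.
    """
    if loading_cleaved <= 0 or loading_uncleaved <= 0:
        raise ValueError("loading signals must be positive")
    if signal_cleaved <= 0 or signal_uncleaved <= 0:
        raise ValueError("fluorescence signals must be positive")
    return (signal_cleaved / loading_cleaved) / (signal_uncleaved / loading_uncleaved)


def molecules_per_cell(sample_signal: float, std_curve: StandardCurve,
                       cells: float | None = None,
                       cell_curve: StandardCurve | None = None,
                       cell_signal: float | None = None,
                       tev_factor: float = 1.0,
                       signal_sd: float = 0.0, tev_sd: float = 0.0,
                       blank: float = 0.0) -> AbundanceResult:
    """Convert a sample lane signal into molecules per cell.

    The TEV-corrected signal is inverted through the protein standard curve
    to femtomoles, and the cell number either given directly (``cells``) or
    read off a cell-number standard curve (``cell_curve`` + ``cell_signal``,
    the loading-normalization variant). molecules = fmol × 10⁻¹⁵ × N_A /
    cells. Relative s.d.s of the signal and the TEV factor propagate in
    quadrature.
    """
    if tev_factor <= 0:
        raise ValueError("tev_factor must be positive")
    if sample_signal <= blank:
        raise NonQuantifiableError(
            f"sample signal {sample_signal} not above blank {blank}"
        )
    if cells is None:
        if cell_curve is None or cell_signal is None:
            raise ValueError("give cells directly or cell_curve + cell_signal")
        cells = cell_curve.amount(cell_signal)
    if cells <= 0:
        raise ValueError("cell number must be positive")
    fmol = std_curve.amount(sample_signal * tev_factor)
    if fmol <= 0:
        raise NonQuantifiableError("corrected signal below calibration blank")
    molecules = fmol * 1e-15 * Avogadro / cells
    rel_var = 0.0
    if signal_sd > 0:
        rel_var += (signal_sd / sample_signal) ** 2
    if tev_sd > 0:
        rel_var += (tev_sd / tev_factor) ** 2
    return AbundanceResult(molecules_per_cell=float(molecules),
                           sd=float(molecules * math.sqrt(rel_var)),
                           tev_factor=float(tev_factor))


def western_correction(result: AbundanceResult, untagged_to_tagged_ratio: float,
                       ratio_sd: float = 0.0) -> AbundanceResult:
    """Rescale a tagged-line abundance to the untagged wild-type level.

    ``untagged_to_tagged_ratio`` is untagged/tagged expression (western
    blot); molecules are multiplied by it and uncertainties propagate in
    quadrature.
    """
    r = untagged_to_tagged_ratio
    if r <= 0:
        raise ValueError("expression ratio must be positive")
    molecules = result.molecules_per_cell * r
    rel_var = 0.0
    if result.molecules_per_cell > 0 and result.sd > 0:
        rel_var += (result.sd / result.molecules_per_cell) ** 2
    if ratio_sd > 0:
        rel_var += (ratio_sd / r) ** 2
    return replace(result, molecules_per_cell=float(molecules),
                   sd=float(molecules * math.sqrt(rel_var)),
                   western_factor=float(r))


def method_correlation(gel_values, flow_values) -> float:
    """Pearson r between gel- and flow-derived relative abundances.

    Both vectors should be normalized to the same reference line before the
    comparison. Requires n ≥ 3 paired values with nonzero variance.
    """
    gel_values = np.asarray(gel_values, dtype=float)
    flow_values = np.asarray(flow_values, dtype=float)
    if gel_values.size < 3 or gel_values.size != flow_values.size:
        raise ValueError("need >= 3 paired values")
    if np.ptp(gel_values) == 0 or np.ptp(flow_values) == 0:
        raise ValueError("zero variance: correlation undefined")
    return float(pearsonr(gel_values, flow_values).statistic)


def quantify_gel(lanes: pd.DataFrame, tev_factor: float = 1.0,
                 tev_sd: float = 0.0) -> pd.DataFrame:
    """Run the full abundance pipeline on a lane table.

    Expects the columns written by the gel simulator / lane-table format:
    ``lane_id, role, amount, signal`` with roles ``standard`` (amount in
    fmol) and ``sample`` (amount = cells loaded). Returns one row per
    sample lane with molecules_per_cell and sd.
    """
    std = lanes[lanes["role"] == "standard"]
    if len(std) < 3:
        raise ValueError("need >= 3 standard lanes")
    curve = fit_standard_curve(std["amount"].to_numpy(), std["signal"].to_numpy())
    rows = []
    for _, lane in lanes[lanes["role"] == "sample"].iterrows():
        res = molecules_per_cell(float(lane["signal"]), curve,
                                 cells=float(lane["amount"]),
                                 tev_factor=tev_factor, tev_sd=tev_sd)
        rows.append({"lane_id": lane["lane_id"],
                     "molecules_per_cell": res.molecules_per_cell,
                     "sd": res.sd})
    return pd.DataFrame(rows)
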