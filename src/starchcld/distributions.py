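"""Chromatogram -> chain-length distribution transforms and normalisations.

The DRI detector responds to mass concentration, so a calibrated trace gives
a weight distribution per logarithmic size interval,

    w(logVh) = S_DRI(V_el) * |dV_el / dlogVh|,

with the Jacobian taken from the calibration polynomial. In DP coordinates
the number distribution follows from w(logX) = X^2 * Nde(X). All ``log``
coordinates are base 10; the choice only affects constant factors that
cancel after area or SNV normalisation.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np

from .calibration import (
    CalibrationCurve,
    MarkHouwinkParams,
    jacobian_dvel_dlogrh,
    molecular_weight_from_radius,
    radius_at,
)
from .io_config import Chromatogram

logger = logging.getLogger("starchcld")

COORD_LOG10_RH = "log10_rh"
COORD_LOG10_DP = "log10_dp"


@dataclass
class WeightDistribution:
    """Weight distribution w per unit log10(size).

    ``coord`` is ``"log10_rh"`` (size = hydrodynamic radius in nm) or
    ``"log10_dp"`` (size = degree of polymerisation). ``extrapolated`` marks
    grid points mapped through the calibration outside the standards' range.
    ``normalization`` is one of ``raw``, ``area``, ``snv``; SNV-normalised
    values may be negative, raw/area values may not.
    """

    coord: str
    grid: np.ndarray
    w: np.ndarray
    extrapolated: np.ndarray = None
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        if self.extrapolated is None:
            self.extrapolated = np.zeros(self.grid.shape, dtype=bool)
        self.extrapolated = np.asarray(self.extrapolated, dtype=bool)
        if self.coord not in (COORD_LOG10_RH, COORD_LOG10_DP):
            raise ValueError(f"unknown coordinate kind: {self.coord!r}")
        if not (self.grid.shape == self.w.shape == self.extrapolated.shape):
            raise ValueError("grid, w and extrapolated must have equal shapes")
        if self.grid.size and not np.all(np.diff(self.grid) > 0):
            raise ValueError("coordinate grid must be strictly increasing")
        # Raw curves may carry small negative detector-noise residuals after
        # baseline correction; only an area-normalised curve must be >= 0.
        if self.normalization == "area" and self.grid.size and np.any(self.w < 0):
            raise ValueError("area-normalised weights must be non-negative")

    @property
    def dp(self) -> np.ndarray:
        if self.coord != COORD_LOG10_DP:
            raise ValueError("distribution is not in DP coordinates")
        return 10.0 ** self.grid

    def replace(self, **kwargs) -> "WeightDistribution":
        return dataclasses.replace(self, **kwargs)


@dataclass
class NumberDistribution:
    """Number distribution Nde(X): relative number of chains of length X (DP)."""

    x: np.ndarray
    n: np.ndarray
    normalization: str = "raw"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.x.shape != self.n.shape:
            raise ValueError("x and n must have equal shapes")
        if self.x.size and not np.all(np.diff(self.x) > 0):
            raise ValueError("x must be strictly increasing")
        if np.any(self.x < 1):
            raise ValueError("degree of polymerisation must be >= 1")


def baseline_correct(chrom: Chromatogram, anchor_fraction: float = 0.05) -> Chromatogram:
    """Subtract a linear baseline anchored in the leading/trailing margins.

    The line passes through (median V, median S) of the first and last
    ``anchor_fraction`` of points. After subtraction, small negative
    residuals (within 3x the anchor-region noise sd) are clipped to zero;
    larger negative excursions are retained and logged as a warning since
    they indicate a genuinely mis-set baseline.
    """
    if not 0 < anchor_fraction < 0.25:
        raise ValueError("anchor_fraction must be in (0, 0.25)")
    n = len(chrom)
    k = max(2, int(round(anchor_fraction * n)))
    if 2 * k >= n:
        raise ValueError("anchor regions overlap; shrink anchor_fraction")
    v, s = chrom.elution_volume, chrom.signal
    v0, s0 = np.median(v[:k]), np.median(s[:k])
    v1, s1 = np.median(v[-k:]), np.median(s[-k:])
    slope = (s1 - s0) / (v1 - v0)
    corrected = s - (s0 + slope * (v - v0))
    noise_sd = max(np.std(corrected[:k]), np.std(corrected[-k:]))
    small_negative = (corrected < 0) & (np.abs(corrected) < 3 * noise_sd)
    # ~0.13% of points fall below -3 sd for pure Gaussian noise; noticeably
    # more indicates a genuinely mis-set baseline.
    if np.mean(corrected < -3 * noise_sd) > 0.01:
        logger.warning(
            "baseline correction of %r left >1%% of points below -3 sigma; "
            "negative signal retained", chrom.sample_id,
        )
    corrected = np.where(small_negative, 0.0, corrected)
    return chrom.replace(signal=corrected)


def weight_distribution_from_trace(
    chrom: Chromatogram, cal: CalibrationCurve
) -> WeightDistribution:
    """Convert a baseline-corrected trace to w(log10 Rh) via the calibration.

    Each sample point maps to coordinate log10(Rh(V_el)) with weight
    S_DRI(V_el) * |dV_el/dlog10Rh|; the output is re-ordered so the size
    grid increases (SEC elutes large species first, so the raw order is
    reversed). Points outside the standards' elution range carry the
    extrapolated flag.
    """
    rh, extrapolated = radius_at(cal, chrom.elution_volume)
    jac = jacobian_dvel_dlogrh(cal, chrom.elution_volume)
    w = chrom.signal * np.abs(jac)
    grid = np.log10(rh)
    order = np.argsort(grid)
    return WeightDistribution(
        coord=COORD_LOG10_RH,
        grid=grid[order],
        w=w[order],
        extrapolated=np.asarray(extrapolated)[order],
    )


def to_dp_coordinate(
    dist: WeightDistribution,
    mh: MarkHouwinkParams,
    monomer_mass: float,
) -> WeightDistribution:
    """Re-express w(log10 Rh) as w(log10 X), X = M(Rh) / monomer_mass.

    log10(X) is affine in log10(Rh) with slope 3/(1+alpha), so the
    transformation only relabels the grid and rescales w by the constant
    Jacobian dlog10Rh/dlog10X = (1+alpha)/3 — feature ordering and relative
    heights are preserved exactly.
    """
    if dist.coord != COORD_LOG10_RH:
        raise ValueError("input must be in log10_rh coordinates")
    rh = 10.0 ** dist.grid
    x = molecular_weight_from_radius(rh, mh) / monomer_mass
    jac = (1.0 + mh.alpha) / 3.0  # dlog10Rh / dlog10X, constant
    return WeightDistribution(
        coord=COORD_LOG10_DP,
        grid=np.log10(x),
        w=dist.w * jac,
        extrapolated=dist.extrapolated.copy(),
        normalization=dist.normalization,
    )


def weight_to_number(dist: WeightDistribution) -> NumberDistribution:
    """Nde(X) = w(log10 X) / X**2 — exact inverse of :func:`number_to_weight`."""
    if dist.coord != COORD_LOG10_DP:
        raise ValueError("input must be in log10_dp coordinates")
    x = 10.0 ** dist.grid
    return NumberDistribution(x=x, n=dist.w / x ** 2, normalization=dist.normalization)


def number_to_weight(dist: NumberDistribution) -> WeightDistribution:
    """w(log10 X) = X**2 * Nde(X)."""
    return WeightDistribution(
        coord=COORD_LOG10_DP,
        grid=np.log10(dist.x),
        w=dist.x ** 2 * dist.n,
        normalization=dist.normalization,
    )


def snv_normalize(values: np.ndarray) -> np.ndarray:
    """Standard normal variate: (x - mean) / sd with the sample (n-1) sd.

    Removes intensity-scale differences between runs (e.g. different
    injection concentrations) so curve shapes can be overlaid; invariant to
    positive affine transforms of the input.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SNV needs at least 2 points")
    sd = np.std(values, ddof=1)
    if sd == 0:
        raise ValueError("SNV undefined for constant input (sd = 0)")
    return (values - np.mean(values)) / sd


def snv_normalize_distribution(dist: WeightDistribution) -> WeightDistribution:
    return dist.replace(w=snv_normalize(dist.w), normalization="snv")


def area_normalize(dist: WeightDistribution) -> WeightDistribution:
    """Scale so the trapezoidal integral of w over the log10 grid is 1."""
    area = np.trapezoid(dist.w, dist.grid)
    if area <= 0:
        raise ValueError("cannot area-normalise a zero-area distribution")
    return dist.replace(w=dist.w / area, normalization="area")


def resample_uniform(
    dist: WeightDistribution,
    n: int = 1000,
    min_dp: float | None = 6.0,
) -> WeightDistribution:
    """Linearly interpolate onto a uniform log10 grid of ``n`` points.

    For DP coordinates the grid is clipped to X >= ``min_dp`` (the reported
    CLD coverage starts at DP 6). The extrapolated flag is carried over
    conservatively: a resampled point is flagged if either bracketing
    native point was.
    """
    lo = dist.grid[0]
    if dist.coord == COORD_LOG10_DP and min_dp is not None:
        lo = max(lo, np.log10(min_dp))
    hi = dist.grid[-1]
    if not hi > lo:
        raise ValueError("empty coordinate range after clipping")
    grid = np.linspace(lo, hi, n)
    w = np.interp(grid, dist.grid, dist.w)
    extr = np.interp(grid, dist.grid, dist.extrapolated.astype(float)) > 0
    return WeightDistribution(
        coord=dist.coord, grid=grid, w=w, extrapolated=extr,
        normalization=dist.normalization,
    )
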