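"""Structural descriptors of a chain-length distribution.

Peaks and shoulders of the weight CLD, the amylopectin/amylose area split,
and cluster-model chain-class number fractions (A+B1 < 25 DP, B2 25-50 DP,
B3 > 50 DP). Peak detection runs on a Savitzky-Golay smoothed curve with a
prominence threshold relative to the global maximum; a shoulder is
operationalised as a derivative plateau — a local extremum of the smoothed
first derivative that does not change sign, i.e. a flattening of a flank
that never becomes a separate maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_coeffs, savgol_filter

from .distributions import (
    COORD_LOG10_DP,
    NumberDistribution,
    WeightDistribution,
)


@dataclass
class Peak:
    dp: float
    height: float
    prominence: float


@dataclass
class CLDFeatures:
    """Flat feature report for one sample's CLD."""

    global_max_dp: float
    peaks: list[Peak]
    shoulders: list[float]
    amylopectin_fraction: float
    amylose_fraction: float
    chain_class_fractions: dict[str, float]  # short (<25), intermediate (25-50), long (>50)

    def as_dict(self) -> dict:
        return {
            "global_max_dp": self.global_max_dp,
            "peaks": [vars(p) for p in self.peaks],
            "shoulders": list(self.shoulders),
            "amylopectin_fraction": self.amylopectin_fraction,
            "amylose_fraction": self.amylose_fraction,
            "chain_class_fractions": dict(self.chain_class_fractions),
        }

    def summary_line(self, sample_id: str = "") -> str:
        peaks = ", ".join(f"{p.dp:.0f}" for p in self.peaks)
        shoulders = ", ".join(f"{s:.0f}" for s in self.shoulders) or "-"
        return (
            f"{sample_id or 'sample'}: peaks DP [{peaks}] shoulders DP [{shoulders}] "
            f"amylose {self.amylose_fraction:.2f}"
        )


def _require_uniform(dist: WeightDistribution) -> float:
    if dist.coord != COORD_LOG10_DP:
        raise ValueError("feature extraction requires log10_dp coordinates")
    steps = np.diff(dist.grid)
    if dist.grid.size < 8 or not np.allclose(steps, steps[0], rtol=1e-6):
        raise ValueError("feature extraction requires a uniform log10_dp grid")
    return float(steps[0])


def _smooth(values: np.ndarray, window: int, order: int, deriv: int = 0, delta: float = 1.0) -> np.ndarray:
    window = min(window, values.size if values.size % 2 else values.size - 1)
    if window <= order:
        return values if deriv == 0 else np.gradient(values, delta)
    return savgol_filter(values, window, order, deriv=deriv, delta=delta)


def detect_peaks(
    dist: WeightDistribution,
    prominence_fraction: float = 0.02,
    smooth_window: int = 21,
    smooth_order: int = 3,
) -> list[Peak]:
    """Local maxima of the smoothed CLD with relative-prominence filtering.

    A maximum is reported when its prominence is at least
    ``prominence_fraction`` times the global maximum of the smoothed curve.
    Positions are invariant to positive rescaling and to SNV normalisation
    (both are affine in w). Returns peaks sorted by increasing DP.
    """
    if not 0 < prominence_fraction < 1:
        raise ValueError("prominence_fraction must be in (0, 1)")
    _require_uniform(dist)
    smoothed = _smooth(dist.w, smooth_window, smooth_order)
    # The span (not the raw maximum) keeps the threshold affine-invariant,
    # so SNV curves give identical peak positions.
    span = smoothed.max() - smoothed.min()
    if span <= 1e-9 * max(1.0, np.abs(smoothed).max()):
        return []
    idx, props = find_peaks(smoothed, prominence=prominence_fraction * span)
    peaks = [
        Peak(dp=float(10.0 ** dist.grid[i]), height=float(smoothed[i]), prominence=float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    return sorted(peaks, key=lambda p: p.dp)


def detect_shoulders(
    dist: WeightDistribution,
    smooth_window: int = 21,
    smooth_order: int = 3,
    min_prominence_fraction: float = 0.05,
    prominence_fraction: float = 0.02,
) -> list[float]:
    """Shoulder positions (DP): concavity maxima that are not resolved peaks.

    A shoulder is an unresolved component that flattens a flank without
    forming its own maximum. Its location is estimated as a local minimum
    of the smoothed second derivative (the point of maximum concavity):
    this estimator is unaffected by any linear background and tracks the
    underlying component mode far better than the slope-plateau midpoint,
    which the neighbouring peak's flank drags sideways. Every resolved peak
    apex is itself a concavity minimum, so candidates within one smoothing
    window of a detected peak are excluded; the rest must exceed a
    concavity prominence of ``min_prominence_fraction`` times the largest
    concavity magnitude, which suppresses noise-induced wiggles.
    """
    step = _require_uniform(dist)
    # Differentiation amplifies high-frequency noise, so the second
    # derivative uses a doubled window relative to the curve smoothing.
    d_window = min(2 * smooth_window - 1, dist.w.size - (dist.w.size + 1) % 2)
    d2 = _smooth(dist.w, d_window, smooth_order, deriv=2, delta=step)
    scale = np.abs(d2).max()
    if scale <= 0:
        return []
    threshold = min_prominence_fraction * scale
    if d_window > smooth_order:
        resid = dist.w - savgol_filter(dist.w, d_window, smooth_order)
        noise_sd = 1.4826 * np.median(np.abs(resid - np.median(resid)))
        d2_noise = noise_sd * np.linalg.norm(
            savgol_coeffs(d_window, smooth_order, deriv=2, delta=step)
        )
        threshold = max(threshold, 5.0 * d2_noise)
    idx, _ = find_peaks(-d2, prominence=threshold)
    idx = idx[d2[idx] < 0]
    peaks = detect_peaks(dist, prominence_fraction, smooth_window, smooth_order)
    peak_pos = np.array([np.log10(p.dp) for p in peaks])
    exclusion = d_window * step
    shoulders = [
        float(10.0 ** dist.grid[i])
        for i in idx
        if peak_pos.size == 0 or np.abs(peak_pos - dist.grid[i]).min() > exclusion
    ]
    return sorted(shoulders)


def split_regions(
    dist: WeightDistribution, boundary_dp: float = 100.0
) -> tuple[float, float]:
    """Trapezoidal area fractions below/above the amylopectin/amylose boundary.

    Returns ``(amylopectin_fraction, amylose_fraction)``; the two share one
    trapezoid partition (the boundary is inserted by interpolation) so they
    sum to 1 exactly.
    """
    if dist.coord != COORD_LOG10_DP:
        raise ValueError("split_regions requires log10_dp coordinates")
    b = np.log10(boundary_dp)
    if not dist.grid[0] <= b <= dist.grid[-1]:
        raise ValueError(
            f"boundary DP {boundary_dp} outside grid range "
            f"[{10**dist.grid[0]:.1f}, {10**dist.grid[-1]:.1f}]"
        )
    grid = np.union1d(dist.grid, [b])
    w = np.interp(grid, dist.grid, dist.w)
    total = np.trapezoid(w, grid)
    if total <= 0:
        raise ValueError("zero-area distribution")
    below_mask = grid <= b
    below = np.trapezoid(w[below_mask], grid[below_mask])
    return below / total, 1.0 - below / total


_CLASS_BOUNDS = {"short": (None, 25.0), "intermediate": (25.0, 50.0), "long": (50.0, None)}


def chain_class_fractions(dist: NumberDistribution) -> dict[str, float]:
    """Number fractions of chains per cluster-model length class.

    Classes: short (A+B1, DP < 25), intermediate (B2, 25 <= DP < 50) and
    long (B3, DP >= 50); integration of N(X) dX by trapezoid with boundary
    points inserted, normalised to sum to 1.
    """
    if dist.x[-1] < 50:
        raise ValueError("DP grid must reach the DP-50 class boundary")
    interior = [b for b in (25.0, 50.0) if dist.x[0] < b < dist.x[-1]]
    x = np.union1d(dist.x, interior)
    n = np.interp(x, dist.x, dist.n)
    total = np.trapezoid(n, x)
    if total <= 0:
        raise ValueError("zero-area number distribution")

    def band(lo, hi):
        mask = np.ones_like(x, dtype=bool)
        if lo is not None:
            mask &= x >= lo
        if hi is not None:
            mask &= x <= hi
        if mask.sum() < 2:
            return 0.0
        return float(np.trapezoid(n[mask], x[mask]))

    raw = {name: band(lo, hi) for name, (lo, hi) in _CLASS_BOUNDS.items()}
    s = sum(raw.values())
    return {name: v / s for name, v in raw.items()}


def extract_features(
    wdist: WeightDistribution,
    ndist: NumberDistribution | None = None,
    prominence_fraction: float = 0.02,
    smooth_window: int = 21,
    smooth_order: int = 3,
    boundary_dp: float = 100.0,
) -> CLDFeatures:
    """Assemble the full feature report from a uniform-grid weight CLD."""
    from .distributions import weight_to_number

    peaks = detect_peaks(wdist, prominence_fraction, smooth_window, smooth_order)
    shoulders = detect_shoulders(wdist, smooth_window, smooth_order)
    if not peaks:
        raise ValueError("no peaks detected; cannot build a feature report")
    global_max = max(peaks, key=lambda p: p.height)
    amylopectin, amylose = split_regions(wdist, boundary_dp)
    if ndist is None:
        ndist = weight_to_number(wdist)
    classes = chain_class_fractions(ndist)
    return CLDFeatures(
        global_max_dp=global_max.dp,
        peaks=peaks,
        shoulders=shoulders,
        amylopectin_fraction=amylopectin,
        amylose_fraction=amylose,
        chain_class_fractions=classes,
    )
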