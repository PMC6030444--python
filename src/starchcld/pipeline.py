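"""End-to-end reduction: calibrated trace -> CLDs -> feature report."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calibration import CalibrationCurve
from .distributions import (
    NumberDistribution,
    WeightDistribution,
    area_normalize,
    baseline_correct,
    resample_uniform,
    to_dp_coordinate,
    weight_distribution_from_trace,
    weight_to_number,
)
from .features import CLDFeatures, extract_features
from .io_config import Chromatogram, PipelineConfig


@dataclass
class ReductionResult:
    """Everything the reduction of one sample produces."""

    weight_dp: WeightDistribution     # area-normalised w(log10 DP), uniform grid
    number: NumberDistribution        # Nde(X) on the same DP grid
    features: CLDFeatures


def reduce_trace(
    chrom: Chromatogram,
    cal: CalibrationCurve,
    config: PipelineConfig | None = None,
) -> ReductionResult:
    """Run the full data reduction for one chromatogram.

    Steps: optional linear baseline correction; trace -> w(log10 Rh) via the
    calibration Jacobian; relabel to DP coordinates; resample to a uniform
    log10 DP grid clipped to DP >= config.min_dp; area-normalise; extract
    peaks/shoulders/region fractions; derive the number distribution.
    """
    config = config or PipelineConfig()
    if config.baseline_correction:
        chrom = baseline_correct(chrom, config.baseline_anchor_fraction)
    wdist = weight_distribution_from_trace(chrom, cal)
    wdist = to_dp_coordinate(wdist, cal.mh, config.monomer_mass)
    wdist = resample_uniform(wdist, n=config.grid_size, min_dp=config.min_dp)
    wdist = area_normalize(wdist.replace(w=np.clip(wdist.w, 0.0, None)))
    ndist = weight_to_number(wdist)
    features = extract_features(
        wdist,
        ndist,
        prominence_fraction=config.prominence_fraction,
        smooth_window=config.smooth_window,
        smooth_order=config.smooth_order,
        boundary_dp=config.boundary_dp,
    )
    return ReductionResult(weight_dp=wdist, number=ndist, features=features)
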