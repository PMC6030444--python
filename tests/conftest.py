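"""Shared fixtures: a fitted calibration and reduced reference samples.

Everything is generated programmatically by the forward simulator; no data
files. Session scope keeps the full-pipeline runs to one per fixture.
"""

from __future__ import annotations

import numpy as np
import pytest

import starchcld as sc


@pytest.fixture(scope="session")
def mh() -> sc.MarkHouwinkParams:
    return sc.PULLULAN_DMSO_90C


@pytest.fixture(scope="session")
def fixtures():
    return sc.reference_fixtures(seed=11)


@pytest.fixture(scope="session")
def instrument(fixtures):
    # All reference fixtures share one instrument model.
    return fixtures["pea_cameor"][1]


@pytest.fixture(scope="session")
def standards(instrument):
    """Simulated pullulan standard chromatograms plus exact truth table."""
    return sc.simulate_standard_set(instrument, seed=101)


@pytest.fixture(scope="session")
def calibration(standards, mh) -> sc.CalibrationCurve:
    chroms, _ = standards
    peaks = sc.locate_standard_peaks(chroms, sc.DEFAULT_STANDARD_MP)
    return sc.fit_calibration(peaks, mh, order=1)


@pytest.fixture(scope="session")
def reduced(fixtures, calibration):
    """Full-pipeline reduction of every reference fixture at default noise."""
    out = {}
    for name, (cld, instrument) in fixtures.items():
        trace = sc.simulate_trace(cld, instrument, seed=202)
        out[name] = sc.reduce_trace(trace, calibration)
    return out


def analytic_features(cld: sc.GroundTruthCLD, n: int = 20001,
                      min_shoulder_strength: float = 0.10):
    """Dense-evaluation oracle: maxima and concavity shoulders of the truth.

    Evaluates the analytic mixture on a fine log10(DP) grid and reads off
    local maxima of w, and concavity shoulders as local minima of w''
    (negative, away from maxima) whose concavity prominence is at least
    ``min_shoulder_strength`` of the curve's largest |w''| — weaker
    concavity wrinkles are below what band broadening preserves, so they
    are not identifiable features of the measured curve. Independent of the
    pipeline's smoothing-based detectors.
    """
    from scipy.signal import find_peaks

    grid = np.linspace(np.log10(6), 4.0, n)
    w = cld.weight_density(grid)
    d = np.gradient(w, grid)
    sign = np.sign(d)
    maxima = grid[1:][(sign[:-1] > 0) & (sign[1:] <= 0)]
    d2 = np.gradient(d, grid)
    idx, props = find_peaks(-d2, prominence=min_shoulder_strength * np.abs(d2).max())
    shoulders = [
        grid[i] for i in idx
        if d2[i] < 0 and np.min(np.abs(maxima - grid[i])) > 0.05
    ]
    return 10.0 ** maxima, 10.0 ** np.asarray(shoulders)
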