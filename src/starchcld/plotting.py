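"""Matplotlib helpers for CLDs and calibration curves."""

from __future__ import annotations

import numpy as np

from .calibration import CalibrationCurve
from .distributions import WeightDistribution
from .features import CLDFeatures


def plot_weight_cld(dist: WeightDistribution, features: CLDFeatures | None = None,
                    ax=None, **kwargs):
    """Plot w against DP on a log axis; mark peaks/shoulders if given.

    The extrapolated (semi-quantitative) region is drawn dashed.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = 10.0 ** dist.grid
    core = ~dist.extrapolated
    ax.plot(x[core], np.where(core, dist.w, np.nan)[core], **kwargs)
    if dist.extrapolated.any():
        ax.plot(x, np.where(dist.extrapolated, dist.w, np.nan), ls="--",
                color=ax.lines[-1].get_color())
    if features is not None:
        for p in features.peaks:
            ax.axvline(p.dp, color="0.6", lw=0.5)
        for s in features.shoulders:
            ax.axvline(s, color="0.6", lw=0.5, ls=":")
    ax.set_xscale("log")
    ax.set_xlabel("degree of polymerization X")
    ax.set_ylabel(r"$w(\log_{10} X)$")
    return ax


def plot_calibration(cal: CalibrationCurve, ax=None):
    """Fitted calibration with the standards overlaid."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    if cal.standards:
        vel = [v for _, v, _ in cal.standards]
        rh = [r for _, _, r in cal.standards]
        ax.plot(vel, np.log10(rh), "o", label="standards")
    v = np.linspace(cal.vel_range[0], cal.vel_range[1], 200)
    ax.plot(v, np.polyval(cal.coefficients, v), label=f"order-{cal.order} fit")
    ax.set_xlabel("elution volume (mL)")
    ax.set_ylabel(r"$\log_{10}(R_h/\mathrm{nm})$")
    ax.legend()
    return ax
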