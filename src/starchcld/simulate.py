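"""Forward simulation of SEC-DRI chromatograms from known ground truth.

A ground-truth CLD is a mixture of log-normal components in DP (Gaussian in
log10 X — the minimal shape matching real debranched-starch CLDs plotted on
a log axis). The instrument model maps size to elution volume through a
known "true" calibration polynomial, applies Gaussian band broadening in
elution volume, and adds linear baseline drift and white detector noise.
Because every stage of the forward model is analytic, the reduction
pipeline can be validated end to end by parameter recovery: simulate,
reduce, and check that the recovered CLD reproduces the generating modes,
areas and fractions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from math import erf, sqrt

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .calibration import (
    MarkHouwinkParams,
    PULLULAN_DMSO_90C,
    hydrodynamic_radius,
    molecular_weight_from_radius,
)
from .io_config import ANHYDROGLUCOSE_MASS, Chromatogram


@dataclass(frozen=True)
class CLDComponent:
    mode_dp: float        # DP at the component mode
    width_log10: float    # sd of the Gaussian in log10(DP)
    weight: float         # mass fraction of the component


@dataclass
class GroundTruthCLD:
    """Analytic weight CLD: mixture of Gaussians in log10(DP)."""

    components: list[CLDComponent]
    name: str = ""

    def __post_init__(self) -> None:
        self.components = [
            c if isinstance(c, CLDComponent) else CLDComponent(*c)
            for c in self.components
        ]
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"component weights must sum to 1, got {total}")
        for c in self.components:
            if c.mode_dp < 6:
                raise ValueError(f"component mode DP {c.mode_dp} below 6")
            if c.width_log10 <= 0:
                raise ValueError("component width must be positive")

    def weight_density(self, log10_x: np.ndarray) -> np.ndarray:
        """w(log10 X): unit total area over log10 X."""
        log10_x = np.asarray(log10_x, dtype=float)
        out = np.zeros_like(log10_x)
        for c in self.components:
            mu = np.log10(c.mode_dp)
            out += (
                c.weight
                / (c.width_log10 * np.sqrt(2 * np.pi))
                * np.exp(-0.5 * ((log10_x - mu) / c.width_log10) ** 2)
            )
        return out

    def mass_within(self, log10_lo: float, log10_hi: float) -> float:
        """Mass fraction inside [log10_lo, log10_hi] (analytic normal CDFs)."""
        total = 0.0
        for c in self.components:
            mu = np.log10(c.mode_dp)
            z_hi = (log10_hi - mu) / (c.width_log10 * sqrt(2))
            z_lo = (log10_lo - mu) / (c.width_log10 * sqrt(2))
            total += c.weight * 0.5 * (erf(z_hi) - erf(z_lo))
        return total


@dataclass
class InstrumentModel:
    """Virtual UPLC-SEC instrument: true calibration plus imperfections.

    ``cal_coefficients`` define the true log10(Rh/nm) as a polynomial in
    elution volume (mL), numpy polyval order. Band broadening is a Gaussian
    of sd ``broadening_sigma`` mL applied in elution volume; detector noise
    is white Gaussian of sd ``noise_sigma`` signal units; the baseline
    drifts linearly at ``drift_slope`` signal units per mL.
    """

    cal_coefficients: np.ndarray
    grid: np.ndarray                 # elution volumes sampled, mL
    broadening_sigma: float = 0.03   # mL
    noise_sigma: float = 0.0025      # signal units (~0.2% of a unit-mass peak)
    drift_slope: float = 0.01        # signal units per mL
    seed: int = 0

    def __post_init__(self) -> None:
        self.cal_coefficients = np.asarray(self.cal_coefficients, dtype=float)
        self.grid = np.asarray(self.grid, dtype=float)
        if self.broadening_sigma < 0 or self.noise_sigma < 0:
            raise ValueError("broadening and noise sigmas must be >= 0")
        dydv = np.polyval(np.polyder(self.cal_coefficients), self.grid)
        if not np.all(dydv < 0):
            raise ValueError("true calibration must be monotone decreasing")

    def log10_rh(self, v: np.ndarray) -> np.ndarray:
        return np.polyval(self.cal_coefficients, v)

    def vel_of_log10_rh(self, log10_rh: float) -> float:
        """Invert the true calibration inside the sampling window."""
        shifted = self.cal_coefficients.copy()
        shifted[-1] -= log10_rh
        roots = np.roots(shifted)
        real = roots[np.isclose(roots.imag, 0)].real
        inside = real[(real >= self.grid[0]) & (real <= self.grid[-1])]
        if inside.size == 0:
            raise ValueError(
                f"log10Rh = {log10_rh:.3f} maps outside the sampling window"
            )
        return float(inside[0])

    def replace(self, **kwargs) -> "InstrumentModel":
        return dataclasses.replace(self, **kwargs)

    def quiet(self) -> "InstrumentModel":
        """Noise-free, drift-free copy (band broadening retained)."""
        return self.replace(noise_sigma=0.0, drift_slope=0.0)


def default_instrument(
    mh: MarkHouwinkParams = PULLULAN_DMSO_90C,
    monomer_mass: float = ANHYDROGLUCOSE_MASS,
    seed: int = 0,
) -> InstrumentModel:
    """Linear true calibration spanning DP 6-10,000 across ~3.5 mL.

    Anchored so DP 10,000 elutes at 4.5 mL and DP 6 at 8.0 mL — mimicking a
    separation finishing in under 8 min at 0.3 mL/min. Sampled every
    0.001 mL over 3.9-8.6 mL (4701 points).
    """
    lo = np.log10(hydrodynamic_radius(6 * monomer_mass, mh))
    hi = np.log10(hydrodynamic_radius(10_000 * monomer_mass, mh))
    v_hi, v_lo = 4.5, 8.0  # large species elute first
    slope = (lo - hi) / (v_lo - v_hi)
    intercept = hi - slope * v_hi
    return InstrumentModel(
        cal_coefficients=np.array([slope, intercept]),
        grid=np.arange(3.9, 8.601, 0.001),
        seed=seed,
    )


#: Peak molecular weights (Da) of the default simulated pullulan standard
#: kit: the stated 342 and 708,000 Da endpoints plus 8 log-spaced
#: intermediates (intermediates are a fixture choice, not vendor data).
DEFAULT_STANDARD_MP = tuple(np.logspace(np.log10(342.0), np.log10(708_000.0), 10))

#: Dispersity of simulated standards expressed as the sd of log10(M); 0.1
#: corresponds to a narrow calibrant (Mw/Mn ~ 1.05).
STANDARD_SIGMA_LOG10M = 0.10


def simulate_standard_set(
    instrument: InstrumentModel,
    mp_list=DEFAULT_STANDARD_MP,
    mh: MarkHouwinkParams = PULLULAN_DMSO_90C,
    seed: int | None = None,
) -> tuple[list[Chromatogram], pd.DataFrame]:
    """One chromatogram per pullulan standard, plus an exact truth table.

    Each standard is a narrow log-normal in M; through the (locally linear)
    calibration this is a Gaussian in elution volume which convolves
    analytically with the broadening kernel, so the noiseless apex sits
    exactly at the truth-table elution volume.
    """
    rng = np.random.default_rng(instrument.seed if seed is None else seed)
    slope = np.polyval(np.polyder(instrument.cal_coefficients), np.mean(instrument.grid))
    chroms, rows = [], []
    for i, mp in enumerate(mp_list):
        rh = hydrodynamic_radius(mp, mh)
        v0 = instrument.vel_of_log10_rh(np.log10(rh))
        sigma_v = STANDARD_SIGMA_LOG10M * (1 + mh.alpha) / 3.0 / abs(slope)
        sigma_tot = np.hypot(sigma_v, instrument.broadening_sigma)
        v = instrument.grid
        signal = np.exp(-0.5 * ((v - v0) / sigma_tot) ** 2) / (sigma_tot * np.sqrt(2 * np.pi))
        signal = signal + instrument.drift_slope * (v - v[0])
        if instrument.noise_sigma > 0:
            signal = signal + rng.normal(0.0, instrument.noise_sigma, v.size)
        chroms.append(
            Chromatogram(elution_volume=v.copy(), signal=signal,
                         sample_id=f"standard_{i:02d}_mp{mp:.0f}")
        )
        rows.append({"mp": mp, "rh_nm": rh, "v_apex": v0})
    return chroms, pd.DataFrame(rows)


def simulate_trace(
    cld: GroundTruthCLD,
    instrument: InstrumentModel,
    mh: MarkHouwinkParams = PULLULAN_DMSO_90C,
    monomer_mass: float = ANHYDROGLUCOSE_MASS,
    injected_mass: float = 1.0,
    seed: int | None = None,
) -> Chromatogram:
    """Forward-simulate the DRI trace of a debranched-starch sample.

    The noiseless signal is mass-proportional:
    ``injected_mass * w_truth(log10 X(V)) * |dlog10X/dV|`` through the true
    calibration (so its elution-volume integral equals the injected mass),
    then Gaussian band broadening, baseline drift and seeded white noise
    are applied. Identical seeds give identical traces.

    Raises if more than 1% of the ground-truth mass falls outside the
    sampling window.
    """
    v = instrument.grid
    log10_rh = instrument.log10_rh(v)
    m = molecular_weight_from_radius(10.0 ** log10_rh, mh)
    log10_x = np.log10(m / monomer_mass)
    covered = cld.mass_within(min(log10_x[0], log10_x[-1]), max(log10_x[0], log10_x[-1]))
    if covered < 0.99:
        raise ValueError(
            f"{100 * (1 - covered):.1f}% of CLD mass outside sampling window"
        )
    dlog10rh_dv = np.polyval(np.polyder(instrument.cal_coefficients), v)
    dlog10x_dv = dlog10rh_dv * 3.0 / (1.0 + mh.alpha)
    signal = injected_mass * cld.weight_density(log10_x) * np.abs(dlog10x_dv)
    if instrument.broadening_sigma > 0:
        step = v[1] - v[0]
        signal = gaussian_filter1d(signal, instrument.broadening_sigma / step, mode="constant")
    signal = signal + instrument.drift_slope * (v - v[0])
    rng = np.random.default_rng(instrument.seed if seed is None else seed)
    if instrument.noise_sigma > 0:
        signal = signal + rng.normal(0.0, instrument.noise_sigma, v.size)
    return Chromatogram(
        elution_volume=v.copy(), signal=signal, sample_id=cld.name or "sample",
        concentration=injected_mass,
    )


def reference_fixtures(
    mh: MarkHouwinkParams = PULLULAN_DMSO_90C,
    monomer_mass: float = ANHYDROGLUCOSE_MASS,
    seed: int = 0,
) -> dict[str, tuple[GroundTruthCLD, InstrumentModel]]:
    """Named synthetic analogues of pea and barley debranched starches.

    Mode positions reproduce the CLD features reported for smooth pea
    (cv. Cameor, cv. BC1/19RR) and barley (cv. Tipple) starches: amylopectin
    peaks near DP 13-16 and 44, the barley-specific DP-21 shoulder, and
    amylose peaks near DP 300 and (barley only) DP 1300. Component widths
    and weight fractions are synthetic choices made so each feature is
    recoverable; they are not measurements of the real cultivars.
    """
    instrument = default_instrument(mh, monomer_mass, seed=seed)
    fixtures = {
        "pea_cameor": GroundTruthCLD(
            name="pea_cameor",
            components=[(16, 0.12, 0.40), (44, 0.15, 0.25), (300, 0.25, 0.35)],
        ),
        "pea_bc1": GroundTruthCLD(
            name="pea_bc1",
            components=[(16, 0.12, 0.40), (44, 0.15, 0.25), (150, 0.30, 0.27),
                        (300, 0.12, 0.08)],
        ),
        "barley_tipple": GroundTruthCLD(
            name="barley_tipple",
            components=[(13, 0.10, 0.28), (21, 0.08, 0.12), (44, 0.15, 0.20),
                        (300, 0.20, 0.22), (1300, 0.20, 0.18)],
        ),
    }
    return {name: (cld, instrument) for name, cld in fixtures.items()}
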