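"""Size calibration for SEC of linear glucans.

Pullulan calibrants of known peak molecular weight Mp are converted to
hydrodynamic radii through the Mark-Houwink relation [eta] = K * M**alpha
and the Einstein viscosity relation for the hydrodynamic volume of an
equivalent sphere,

    Vh = 2 [eta] M / (5 N_A),        Rh = (3 Vh / 4 pi)**(1/3),

and a polynomial mapping elution volume (mL) -> log10(Rh/nm) is fitted by
least squares. Because SEC separates by size, the mapping must be strictly
decreasing (larger species elute first); the fit refuses calibrations that
are not. The analytic derivative of the fitted polynomial supplies the
dV_el/dlogRh Jacobian used when converting detector traces into weight
distributions.

Units: K in dL/g, M in Da (g/mol), Rh in nm. Internally the intrinsic
viscosity is converted dL -> mL (x100) and the hydrodynamic volume
cm^3 -> nm^3 (x1e21).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml
from scipy.signal import find_peaks, savgol_filter

AVOGADRO = 6.02214076e23  # 1/mol, exact (SI definition)

_DL_TO_ML = 100.0
_CM3_TO_NM3 = 1e21


class CalibrationError(ValueError):
    """Raised for invalid calibration inputs or degenerate fits."""


@dataclass(frozen=True)
class MarkHouwinkParams:
    """Mark-Houwink constants for one polymer/solvent/temperature system.

    Attributes
    ----------
    K : float
        Prefactor in dL/g.
    alpha : float
        Exponent, dimensionless; 0 < alpha < 1.2 for flexible chains.
    """

    K: float
    alpha: float

    def __post_init__(self) -> None:
        if not self.K > 0:
            raise CalibrationError(f"K must be positive, got {self.K}")
        if not 0 < self.alpha < 1.2:
            raise CalibrationError(f"alpha must be in (0, 1.2), got {self.alpha}")


#: Pullulan in DMSO/LiBr at 90 degC — the calibrant system this pipeline
#: defaults to.
PULLULAN_DMSO_90C = MarkHouwinkParams(K=0.0002427, alpha=0.6804)


def intrinsic_viscosity(m: float | np.ndarray, mh: MarkHouwinkParams) -> float | np.ndarray:
    """Intrinsic viscosity [eta] = K * M**alpha in dL/g for molecular weight M (Da)."""
    m = np.asarray(m, dtype=float)
    if np.any(m <= 0):
        raise CalibrationError("molecular weight must be positive")
    out = mh.K * m ** mh.alpha
    return out.item() if out.ndim == 0 else out


def hydrodynamic_radius(m: float | np.ndarray, mh: MarkHouwinkParams) -> float | np.ndarray:
    """Hydrodynamic radius Rh (nm) of a chain of molecular weight M (Da).

    Combines the Mark-Houwink viscosity with the Einstein relation
    Vh = 2 [eta] M / (5 N_A); strictly increasing in M with log-log slope
    (1 + alpha) / 3.
    """
    m = np.asarray(m, dtype=float)
    eta_ml_per_g = intrinsic_viscosity(m, mh) * _DL_TO_ML
    vh_cm3 = 2.0 * eta_ml_per_g * m / (5.0 * AVOGADRO)
    vh_nm3 = vh_cm3 * _CM3_TO_NM3
    out = (3.0 * vh_nm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return out.item() if np.ndim(out) == 0 else out


def molecular_weight_from_radius(rh: float | np.ndarray, mh: MarkHouwinkParams) -> float | np.ndarray:
    """Closed-form inverse of :func:`hydrodynamic_radius`: Rh (nm) -> M (Da)."""
    rh = np.asarray(rh, dtype=float)
    if np.any(rh <= 0):
        raise CalibrationError("hydrodynamic radius must be positive")
    vh_cm3 = (4.0 * np.pi / 3.0) * rh ** 3 / _CM3_TO_NM3
    out = (5.0 * AVOGADRO * vh_cm3 / (2.0 * mh.K * _DL_TO_ML)) ** (1.0 / (1.0 + mh.alpha))
    return out.item() if np.ndim(out) == 0 else out


@dataclass
class CalibrationCurve:
    """Fitted polynomial mapping elution volume (mL) -> log10(Rh/nm).

    ``coefficients`` are in numpy ``polyval`` order (highest power first).
    The validity ranges record the elution-volume and Rh span of the fitted
    standards; evaluation outside the V_el span is permitted but flagged as
    extrapolated.
    """

    coefficients: np.ndarray
    order: int
    vel_range: tuple[float, float]       # mL, [min, max] of fitted standards
    rh_range: tuple[float, float]        # nm, [min, max] Rh of fitted standards
    residual_rms: float                  # rms residual in log10(Rh)
    mh: MarkHouwinkParams
    standards: list[tuple[float, float, float]] = field(default_factory=list)  # (Mp, V_el, Rh)

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        v = np.linspace(self.vel_range[0], self.vel_range[1], 512)
        dydv = np.polyval(np.polyder(self.coefficients), v)
        if not np.all(dydv < 0):
            raise CalibrationError(
                "calibration must be strictly decreasing in elution volume "
                "over its validity range"
            )

    # -- persistence ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "coefficients": [float(c) for c in self.coefficients],
            "order": int(self.order),
            "vel_range": [float(x) for x in self.vel_range],
            "rh_range": [float(x) for x in self.rh_range],
            "residual_rms": float(self.residual_rms),
            "mark_houwink": {"K": self.mh.K, "alpha": self.mh.alpha},
            "standards": [
                {"mp": float(mp), "v_el": float(vel), "rh": float(rh)}
                for mp, vel, rh in self.standards
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CalibrationCurve":
        doc = yaml.safe_load(Path(path).read_text())
        return cls(
            coefficients=np.asarray(doc["coefficients"], dtype=float),
            order=int(doc["order"]),
            vel_range=tuple(doc["vel_range"]),
            rh_range=tuple(doc["rh_range"]),
            residual_rms=float(doc["residual_rms"]),
            mh=MarkHouwinkParams(**doc["mark_houwink"]),
            standards=[(s["mp"], s["v_el"], s["rh"]) for s in doc.get("standards", [])],
        )


def locate_standard_peaks(
    standards_chroms: Sequence,
    mp_list: Sequence[float],
    smooth_window: int = 11,
    smooth_order: int = 3,
) -> list[tuple[float, float]]:
    """Locate the apex elution volume of each single-standard chromatogram.

    One chromatogram per standard. Each trace is Savitzky-Golay smoothed and
    its most prominent local maximum taken as the apex. Apexes are assigned
    to peak molecular weights in decreasing-M = increasing-V_el order (SEC
    elution physics); the assignment never relies on input file order.
    Returns (Mp, V_el) sorted by increasing V_el.
    """
    if len(standards_chroms) != len(mp_list):
        raise CalibrationError(
            f"{len(standards_chroms)} chromatograms for {len(mp_list)} standards"
        )
    apexes = [_single_apex(ch, smooth_window, smooth_order) for ch in standards_chroms]
    apexes.sort()
    mps = sorted(mp_list, reverse=True)
    return list(zip(mps, apexes))


def _single_apex(chrom, window: int, order: int) -> float:
    sig = chrom.signal
    if sig.size > window:
        sig = savgol_filter(sig, window, order)
    span = sig.max() - sig.min()
    if span <= 1e-9 * max(1.0, np.abs(sig).max()):
        raise CalibrationError(f"no peak in chromatogram {chrom.sample_id!r}")
    idx, props = find_peaks(sig, prominence=0.1 * span)
    if idx.size == 0:
        raise CalibrationError(f"no peak in chromatogram {chrom.sample_id!r}")
    best = idx[np.argmax(props["prominences"])]
    return _refine_apex(chrom.elution_volume, sig, best)


def _refine_apex(v: np.ndarray, sig: np.ndarray, apex: int) -> float:
    """Sub-sample apex localisation: quadratic vertex fitted to the peak top.

    Averages over every point above 75% of the apex height around the
    maximum, which beats the raw argmax by far when detector noise jitters
    single samples.
    """
    height = sig[apex]
    lo = apex
    while lo > 0 and sig[lo - 1] >= 0.75 * height:
        lo -= 1
    hi = apex
    while hi < sig.size - 1 and sig[hi + 1] >= 0.75 * height:
        hi += 1
    if hi - lo < 4:
        return float(v[apex])
    coeffs = np.polyfit(v[lo:hi + 1], sig[lo:hi + 1], 2)
    if coeffs[0] >= 0:
        return float(v[apex])
    vertex = -coeffs[1] / (2 * coeffs[0])
    if not v[lo] <= vertex <= v[hi]:
        return float(v[apex])
    return float(vertex)


def fit_calibration(
    peaks: Sequence[tuple[float, float]],
    mh: MarkHouwinkParams,
    order: int = 1,
) -> CalibrationCurve:
    """Least-squares polynomial fit of log10(Rh(Mp)) on apex elution volume.

    ``peaks`` are (Mp in Da, V_el in mL) pairs. Requires at least
    ``order + 2`` points so the fit is over-determined, and verifies that
    elution volume decreases with molecular weight before fitting.
    """
    peaks = list(peaks)
    if len(peaks) < order + 2:
        raise CalibrationError(
            f"need >= {order + 2} standards for an order-{order} fit, got {len(peaks)}"
        )
    mp = np.array([p[0] for p in peaks], dtype=float)
    vel = np.array([p[1] for p in peaks], dtype=float)
    srt = np.argsort(vel)
    mp, vel = mp[srt], vel[srt]
    if not np.all(np.diff(mp) < 0):
        raise CalibrationError("elution volume must decrease strictly with Mp")
    rh = hydrodynamic_radius(mp, mh)
    log_rh = np.log10(rh)
    coeffs = np.polyfit(vel, log_rh, order)
    residuals = log_rh - np.polyval(coeffs, vel)
    return CalibrationCurve(
        coefficients=coeffs,
        order=order,
        vel_range=(float(vel.min()), float(vel.max())),
        rh_range=(float(rh.min()), float(rh.max())),
        residual_rms=float(np.sqrt(np.mean(residuals ** 2))),
        mh=mh,
        standards=[(float(m), float(v), float(r)) for m, v, r in zip(mp, vel, rh)],
    )


def radius_at(cal: CalibrationCurve, v_el: float | np.ndarray) -> tuple[np.ndarray | float, np.ndarray | bool]:
    """Evaluate the calibration at elution volume(s) v_el.

    Returns ``(rh_nm, extrapolated)``. Evaluation outside the standards'
    elution-volume span is still returned but flagged: DP assignment there
    is semi-quantitative.
    """
    v = np.asarray(v_el, dtype=float)
    if not np.isfinite(v).all():
        raise CalibrationError("elution volume must be finite")
    rh = 10.0 ** np.polyval(cal.coefficients, v)
    extrapolated = (v < cal.vel_range[0]) | (v > cal.vel_range[1])
    if np.ndim(v_el) == 0:
        return float(rh), bool(extrapolated)
    return rh, extrapolated


def jacobian_dvel_dlogrh(cal: CalibrationCurve, v_el: float | np.ndarray) -> float | np.ndarray:
    """dV_el / dlog10(Rh) in mL per log10-unit, from the fitted polynomial.

    Computed analytically as the reciprocal of the polynomial derivative.
    Negative by the monotonicity invariant; consumers needing a density take
    the absolute value.
    """
    v = np.asarray(v_el, dtype=float)
    dlogrh_dv = np.polyval(np.polyder(cal.coefficients), v)
    if np.any(np.abs(dlogrh_dv) < 1e-12):
        raise CalibrationError("degenerate calibration: |dlog10Rh/dV_el| < 1e-12")
    out = 1.0 / dlogrh_dv
    return out.item() if np.ndim(v_el) == 0 else out
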