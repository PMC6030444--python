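"""Chromatogram and CLD-table I/O plus pipeline configuration.

All tabular artefacts are plain delimited text (comma or tab, auto-detected
on read) with a single optional header line, so a complete reduction run is
reproducible from files written by this module alone. The canonical abscissa
unit is elution volume in mL; time-indexed exports are converted on read
using an explicit flow rate.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("starchcld")

MIN_CHROMATOGRAM_POINTS = 16

#: Mass of one anhydroglucose unit in g/mol. The water terminus (+18) is
#: ignored; it is negligible for chains above DP ~6.
ANHYDROGLUCOSE_MASS = 162.2


class ChromatogramError(ValueError):
    """Raised for malformed chromatogram data or files."""


@dataclass
class Chromatogram:
    """A sampled detector trace: DRI signal versus elution volume.

    Parameters
    ----------
    elution_volume
        Strictly increasing elution volumes in mL.
    signal
        Detector response in arbitrary units, same length.
    sample_id
        Free-text identifier.
    flow_rate
        Pump flow rate in mL/min, if known.
    concentration
        Injection concentration in mg/mL, if known.
    """

    elution_volume: np.ndarray
    signal: np.ndarray
    sample_id: str = ""
    flow_rate: Optional[float] = None
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        self.elution_volume = np.asarray(self.elution_volume, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.elution_volume.ndim != 1 or self.signal.ndim != 1:
            raise ChromatogramError("elution_volume and signal must be 1-D")
        if self.elution_volume.size != self.signal.size:
            raise ChromatogramError("elution_volume and signal lengths differ")
        if self.elution_volume.size < MIN_CHROMATOGRAM_POINTS:
            raise ChromatogramError(
                f"chromatogram needs >= {MIN_CHROMATOGRAM_POINTS} samples, "
                f"got {self.elution_volume.size}"
            )
        if not (np.isfinite(self.elution_volume).all() and np.isfinite(self.signal).all()):
            raise ChromatogramError("non-finite values in chromatogram")
        if not np.all(np.diff(self.elution_volume) > 0):
            raise ChromatogramError("non-monotone elution volume axis")

    def __len__(self) -> int:
        return int(self.elution_volume.size)

    def replace(self, **kwargs) -> "Chromatogram":
        return dataclasses.replace(self, **kwargs)


@dataclass
class StandardSet:
    """Pullulan calibrant definitions: peak molecular weights in Da.

    ``entries`` maps each standard's peak molecular weight (Mp, Da) to an
    optional known apex elution volume (mL); the volume may be absent when
    it is to be located from a measured trace.
    """

    entries: list[tuple[float, Optional[float]]]
    solvent_tag: str = ""

    def __post_init__(self) -> None:
        if len(self.entries) < 3:
            raise ValueError("a standard set needs at least 3 entries")
        for mp, _ in self.entries:
            if not mp > 0:
                raise ValueError(f"non-positive standard molecular weight: {mp}")

    @property
    def molecular_weights(self) -> np.ndarray:
        return np.array([mp for mp, _ in self.entries], dtype=float)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StandardSet":
        doc = yaml.safe_load(Path(path).read_text())
        entries = []
        for row in doc["standards"]:
            if isinstance(row, dict):
                entries.append((float(row["mp"]), _maybe_float(row.get("v_el"))))
            else:
                entries.append((float(row), None))
        return cls(entries=entries, solvent_tag=str(doc.get("solvent", "")))

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "solvent": self.solvent_tag,
            "standards": [
                {"mp": mp} if vel is None else {"mp": mp, "v_el": vel}
                for mp, vel in self.entries
            ],
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _maybe_float(x) -> Optional[float]:
    return None if x is None else float(x)


@dataclass
class PipelineConfig:
    """Tunable parameters of the reduction pipeline.

    Defaults follow the conventions documented in docs/methods.md; every
    value can be overridden from a YAML file or CLI flag.
    """

    monomer_mass: float = ANHYDROGLUCOSE_MASS  # g/mol per DP unit
    calibration_order: int = 1
    smooth_window: int = 21      # points, Savitzky-Golay
    smooth_order: int = 3
    prominence_fraction: float = 0.02
    boundary_dp: float = 100.0   # amylose/amylopectin split
    grid_size: int = 1000        # uniform log10(DP) grid for comparison
    min_dp: float = 6.0          # reported coverage starts here
    baseline_anchor_fraction: float = 0.05
    baseline_correction: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "monomer_mass": self.monomer_mass,
            "calibration_order": self.calibration_order,
            "smooth_window": self.smooth_window,
            "smooth_order": self.smooth_order,
            "prominence_fraction": self.prominence_fraction,
            "boundary_dp": self.boundary_dp,
            "grid_size": self.grid_size,
            "min_dp": self.min_dp,
            "baseline_anchor_fraction": self.baseline_anchor_fraction,
        }
        for name, value in positive.items():
            if not value > 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.boundary_dp < 1:
            raise ValueError("boundary_dp must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=False))

    def replace(self, **kwargs) -> "PipelineConfig":
        return dataclasses.replace(self, **kwargs)


def read_chromatogram(
    path: str | Path,
    time_mode: bool = False,
    flow_rate: Optional[float] = None,
    sample_id: Optional[str] = None,
) -> Chromatogram:
    """Read a two-column delimited text chromatogram.

    The first column is elution volume in mL, or retention time in minutes
    when ``time_mode`` is set (then ``flow_rate`` in mL/min is required and
    volumes are ``time * flow_rate``). Delimiter (comma/tab/whitespace) is
    auto-detected; one leading non-numeric header line is allowed.
    """
    path = Path(path)
    if time_mode and flow_rate is None:
        raise ChromatogramError("time_mode requires an explicit flow_rate (mL/min)")
    table = _read_two_columns(path)
    abscissa = table[:, 0]
    if time_mode:
        abscissa = abscissa * flow_rate
    return Chromatogram(
        elution_volume=abscissa,
        signal=table[:, 1],
        sample_id=sample_id if sample_id is not None else path.stem,
        flow_rate=flow_rate,
    )


def _read_two_columns(path: Path) -> np.ndarray:
    try:
        frame = pd.read_csv(path, sep=None, engine="python", header=None, comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ChromatogramError(f"cannot parse {path}: {exc}") from exc
    # Drop a single header line if the first row is not numeric.
    first = pd.to_numeric(frame.iloc[0], errors="coerce")
    if first.isna().any():
        frame = frame.iloc[1:]
    if frame.shape[1] < 2:
        raise ChromatogramError(f"{path}: expected two delimited columns")
    values = frame.iloc[:, :2].apply(pd.to_numeric, errors="raise").to_numpy(dtype=float)
    if values.shape[0] < MIN_CHROMATOGRAM_POINTS:
        raise ChromatogramError(
            f"{path}: fewer than {MIN_CHROMATOGRAM_POINTS} data rows"
        )
    return values


def write_chromatogram(chrom: Chromatogram, path: str | Path) -> None:
    """Write a chromatogram as CSV with an ``elution_volume_ml,signal`` header."""
    _write_table(
        Path(path),
        header=["elution_volume_ml", "signal"],
        columns=[chrom.elution_volume, chrom.signal],
    )


def write_cld_table(dist, path: str | Path) -> None:
    """Write a weight or number distribution as delimited text.

    Weight distributions in DP coordinates get columns
    ``DP,w_log10DP,extrapolated``; in Rh coordinates ``Rh_nm,w_log10Rh,
    extrapolated``; number distributions get ``DP,Nde``. Values are written
    with 17 significant digits so a read-back round trip is lossless well
    beyond 12 significant digits.
    """
    from .distributions import NumberDistribution, WeightDistribution

    path = Path(path)
    if isinstance(dist, WeightDistribution):
        if dist.grid.size == 0:
            raise ValueError("refusing to write an empty distribution")
        if not np.isfinite(dist.w).all():
            raise ValueError("distribution contains non-finite values")
        axis = 10.0 ** dist.grid
        name = "DP" if dist.coord == "log10_dp" else "Rh_nm"
        _write_table(
            path,
            header=[name, f"w_log10{'DP' if dist.coord == 'log10_dp' else 'Rh'}",
                    "extrapolated"],
            columns=[axis, dist.w, dist.extrapolated.astype(int)],
        )
    elif isinstance(dist, NumberDistribution):
        if dist.x.size == 0:
            raise ValueError("refusing to write an empty distribution")
        _write_table(path, header=["DP", "Nde"], columns=[dist.x, dist.n])
    else:
        raise TypeError(f"unsupported distribution type: {type(dist)!r}")


def read_cld_table(path: str | Path) -> pd.DataFrame:
    """Read back a CLD table written by :func:`write_cld_table`."""
    return pd.read_csv(path)


def _write_table(path: Path, header: Sequence[str], columns: Sequence[np.ndarray]) -> None:
    frame = pd.DataFrame({name: np.asarray(col) for name, col in zip(header, columns)})
    frame.to_csv(path, index=False, float_format="%.17g")
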