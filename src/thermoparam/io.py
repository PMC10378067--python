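"""Thermogram and clinical-table I/O plus curve post-processing.

A plasma DSC thermogram is the excess specific heat capacity of a plasma
sample (cal/°C·g) recorded against temperature.  All downstream analysis in
this package operates on a canonical temperature mesh of 45.0–90.0 °C at
0.1 °C steps (451 points); this module provides the container types, the
wide-CSV readers/writers, and the standard post-processing steps that bring
raw per-temperature heat-capacity tables onto that mesh:

* linear interpolation to a target mesh,
* buffer-reference subtraction,
* normalization by total protein mass,
* linear baseline correction anchored in flat pre-/post-transition windows,
* replicate averaging.

Instrument-native files (raw power vs. time) are out of scope; the entry
point is a per-temperature heat-capacity table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TemperatureMesh",
    "ThermogramCurve",
    "ThermogramFormatError",
    "CANONICAL_START",
    "CANONICAL_STOP",
    "CANONICAL_STEP",
    "read_thermogram_matrix",
    "write_thermogram_matrix",
    "read_clinical_table",
    "write_clinical_table",
    "curves_to_matrix",
    "interpolate_to_mesh",
    "subtract_reference",
    "normalize_by_concentration",
    "linear_baseline_correct",
    "average_replicates",
]

CANONICAL_START = 45.0
CANONICAL_STOP = 90.0
CANONICAL_STEP = 0.1

#: Tolerance for declaring two temperature values "the same mesh point".
MESH_ATOL = 1e-6

STATUS_LEVELS = ("control", "NED", "active")
SEX_LEVELS = ("female", "male")


class ThermogramFormatError(ValueError):
    """Raised for malformed thermogram or clinical input files."""


@dataclass(frozen=True)
class TemperatureMesh:
    """Uniform, strictly increasing temperature grid (°C)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        if vals.ndim != 1 or vals.size < 2:
            raise ThermogramFormatError("temperature mesh needs >= 2 points")
        diffs = np.diff(vals)
        if np.any(diffs <= 0):
            raise ThermogramFormatError("temperatures must be strictly increasing")
        if np.ptp(diffs) > 1e-9 + 1e-9 * abs(diffs[0]):
            raise ThermogramFormatError("temperature mesh spacing is not uniform")
        object.__setattr__(self, "values", vals)

    @property
    def start(self) -> float:
        return float(self.values[0])

    @property
    def stop(self) -> float:
        return float(self.values[-1])

    @property
    def step(self) -> float:
        return float(self.values[1] - self.values[0])

    def __len__(self) -> int:
        return self.values.size

    @classmethod
    def canonical(cls) -> "TemperatureMesh":
        """The 45–90 °C, 0.1 °C analysis mesh (exactly 451 points)."""
        n = int(round((CANONICAL_STOP - CANONICAL_START) / CANONICAL_STEP)) + 1
        return cls(np.round(CANONICAL_START + CANONICAL_STEP * np.arange(n), 6))

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "TemperatureMesh":
        n = int(round((stop - start) / step)) + 1
        return cls(start + step * np.arange(n))

    def is_canonical(self) -> bool:
        canon = TemperatureMesh.canonical()
        return len(self) == len(canon) and np.allclose(
            self.values, canon.values, atol=MESH_ATOL, rtol=0.0
        )

    def matches(self, other: "TemperatureMesh") -> bool:
        return len(self) == len(other) and np.allclose(
            self.values, other.values, atol=MESH_ATOL, rtol=0.0
        )

    def index_of(self, temperature: float) -> int:
        """Index of the mesh point equal to ``temperature`` (within tolerance)."""
        idx = int(np.argmin(np.abs(self.values - temperature)))
        if abs(self.values[idx] - temperature) > MESH_ATOL:
            raise ValueError(f"{temperature} is not a mesh point")
        return idx


@dataclass
class ThermogramCurve:
    """One sample's excess specific heat capacity on a temperature mesh."""

    sample_id: str
    mesh: TemperatureMesh
    cp: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        cp = np.asarray(self.cp, dtype=float)
        if cp.shape != (len(self.mesh),):
            raise ThermogramFormatError(
                f"sample {self.sample_id!r}: cp length {cp.size} != mesh length {len(self.mesh)}"
            )
        if not np.all(np.isfinite(cp)):
            raise ThermogramFormatError(
                f"sample {self.sample_id!r}: non-finite heat-capacity values"
            )
        self.cp = cp

    @property
    def temperatures(self) -> np.ndarray:
        return self.mesh.values

    def require_canonical(self) -> None:
        if not self.mesh.is_canonical():
            raise ValueError(
                f"sample {self.sample_id!r} is not on the canonical 45–90 °C / 0.1 °C mesh"
            )

    def with_cp(self, cp: np.ndarray, suffix: str = "") -> "ThermogramCurve":
        return ThermogramCurve(self.sample_id + suffix, self.mesh, np.asarray(cp, float))


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def read_thermogram_matrix(path: str | Path) -> list[ThermogramCurve]:
    """Read a wide thermogram CSV: column 1 = Temperature, one column per sample.

    All curves share the temperature column's mesh; temperatures are rounded
    to 0.1 °C before mesh construction (tolerance 1e-6).
    """
    df = pd.read_csv(path, header=0)
    if df.shape[1] < 2:
        raise ThermogramFormatError(f"{path}: need a temperature column plus >=1 sample")
    temp_col = df.columns[0]
    try:
        temps = pd.to_numeric(df[temp_col], errors="raise").to_numpy(float)
    except (ValueError, TypeError) as exc:
        raise ThermogramFormatError(f"{path}: non-numeric temperature value ({exc})") from exc
    mesh = TemperatureMesh(np.round(temps, 6))
    curves: list[ThermogramCurve] = []
    for col in df.columns[1:]:
        series = df[col]
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise ThermogramFormatError(
                f"{path}: missing value for sample {col!r} at row {row + 2}"
            )
        try:
            cp = pd.to_numeric(series, errors="raise").to_numpy(float)
        except (ValueError, TypeError) as exc:
            raise ThermogramFormatError(
                f"{path}: non-numeric heat capacity for sample {col!r} ({exc})"
            ) from exc
        curves.append(ThermogramCurve(str(col), mesh, cp))
    return curves


def curves_to_matrix(curves: Sequence[ThermogramCurve]) -> pd.DataFrame:
    """Stack curves on one mesh into the wide-CSV DataFrame layout."""
    if not curves:
        raise ValueError("no curves given")
    mesh = curves[0].mesh
    for c in curves[1:]:
        if not c.mesh.matches(mesh):
            raise ValueError(f"sample {c.sample_id!r} is on a different mesh")
    data = {"Temperature": mesh.values}
    for c in curves:
        data[c.sample_id] = c.cp
    return pd.DataFrame(data)


def write_thermogram_matrix(curves: Sequence[ThermogramCurve], path: str | Path) -> None:
    curves_to_matrix(curves).to_csv(path, index=False, float_format="%.6g")


CLINICAL_COLUMNS = [
    "sample_id", "status", "sex", "age", "stage", "n_affected", "location",
    "os_time", "os_event", "pfs_time", "pfs_event",
]


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read and validate the per-sample clinical table.

    Required columns: sample_id, status, sex, age, os_time, os_event.
    stage / n_affected / location / pfs_time / pfs_event may be blank.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("sample_id", "status", "sex", "age") if c not in df.columns]
    if missing:
        raise ThermogramFormatError(f"{path}: missing clinical columns {missing}")
    bad_status = set(df["status"].dropna()) - set(STATUS_LEVELS)
    if bad_status:
        raise ThermogramFormatError(f"{path}: unknown status labels {sorted(bad_status)}")
    bad_sex = set(df["sex"].dropna()) - set(SEX_LEVELS)
    if bad_sex:
        raise ThermogramFormatError(f"{path}: unknown sex labels {sorted(bad_sex)}")
    if "os_time" in df.columns:
        ok = df["os_time"].dropna() > 0
        if not ok.all():
            raise ThermogramFormatError(f"{path}: os_time must be > 0")
    for col in ("os_event", "pfs_event"):
        if col in df.columns:
            df[col] = df[col].map(
                lambda v: v if pd.isna(v) else bool(int(v))
            )
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("os_event", "pfs_event"):
        if col in out.columns:
            out[col] = out[col].map(lambda v: "" if pd.isna(v) else int(bool(v)))
    out.to_csv(path, index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# Post-processing operations
# ---------------------------------------------------------------------------

def interpolate_to_mesh(curve: ThermogramCurve, target: TemperatureMesh) -> ThermogramCurve:
    """Linearly interpolate a curve onto ``target``.

    Exact at coincident temperatures; refuses to extrapolate beyond the
    source temperature support.
    """
    src = curve.mesh.values
    if target.values[0] < src[0] - MESH_ATOL or target.values[-1] > src[-1] + MESH_ATOL:
        raise ValueError(
            f"target mesh [{target.start}, {target.stop}] extends beyond source "
            f"support [{src[0]}, {src[-1]}]"
        )
    cp = np.interp(np.clip(target.values, src[0], src[-1]), src, curve.cp)
    return ThermogramCurve(curve.sample_id, target, cp)


def _require_same_mesh(a: ThermogramCurve, b: ThermogramCurve) -> None:
    if not a.mesh.matches(b.mesh):
        raise ValueError(
            f"mesh mismatch between samples {a.sample_id!r} and {b.sample_id!r}"
        )


def subtract_reference(sample: ThermogramCurve, reference: ThermogramCurve) -> ThermogramCurve:
    """Pointwise buffer-reference subtraction (same mesh required)."""
    _require_same_mesh(sample, reference)
    return sample.with_cp(sample.cp - reference.cp)


def normalize_by_concentration(
    curve: ThermogramCurve, protein_conc: float, cell_volume: float
) -> ThermogramCurve:
    """Divide by total protein mass (concentration [g/L] × cell volume [L])."""
    if protein_conc <= 0:
        raise ValueError("protein concentration must be positive")
    if cell_volume <= 0:
        raise ValueError("cell volume must be positive")
    return curve.with_cp(curve.cp / (protein_conc * cell_volume))


def linear_baseline_correct(
    curve: ThermogramCurve,
    pre_window: tuple[float, float] = (45.0, 50.0),
    post_window: tuple[float, float] = (85.0, 90.0),
) -> ThermogramCurve:
    """Fit a least-squares line to the two anchor windows and subtract it.

    The windows default to the flat pre-/post-transition regions 45–50 °C and
    85–90 °C.
    """
    t = curve.temperatures
    lo1, hi1 = pre_window
    lo2, hi2 = post_window
    if hi1 > lo2:
        raise ValueError("baseline windows must not overlap")
    mask = ((t >= lo1 - MESH_ATOL) & (t <= hi1 + MESH_ATOL)) | (
        (t >= lo2 - MESH_ATOL) & (t <= hi2 + MESH_ATOL)
    )
    if mask.sum() < 2:
        raise ValueError("baseline windows contain fewer than two mesh points")
    slope, intercept = np.polyfit(t[mask], curve.cp[mask], 1)
    return curve.with_cp(curve.cp - (slope * t + intercept))


def average_replicates(curves: Iterable[ThermogramCurve]) -> ThermogramCurve:
    """Pointwise mean of replicate scans (n >= 1) on one mesh."""
    curves = list(curves)
    if not curves:
        raise ValueError("no replicate curves given")
    mesh = curves[0].mesh
    for c in curves[1:]:
        _require_same_mesh(curves[0], c)
    cp = np.mean([c.cp for c in curves], axis=0)
    return ThermogramCurve(curves[0].sample_id, mesh, cp)
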