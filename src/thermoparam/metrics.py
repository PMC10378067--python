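"""Thermogram summary metrics.

Twenty scalar features are extracted from each thermogram: global shape
descriptors (Width at half height, Area, Max, Median, TMax, first-moment
temperature TFM), the heights and positions of the three denaturation peaks
(Peak 1: 60–66.9 °C, Peak 2: 67–72.9 °C, Peak 3: 73–78 °C, loosely tracking
the albumin and globulin transitions), the inter-peak valley V1.2 with its
position, and six peak/valley height ratios.  TPeak3 is computed but is
conventionally excluded from the statistical parameter set because the
windowed estimate is pinned for most samples.

Two peak identification methods are provided and cross-checked:

* ``find_peaks_monotonic`` — local maxima preceded by >= 3 strictly
  increasing mesh steps and followed by >= 3 strictly decreasing steps;
* ``find_peaks_windowed`` — the maximum of each pre-defined temperature
  window (ties to the lowest temperature).

``compute_metric_set`` records, per peak, whether the two methods agree
(Peak 3 frequently presents as a shoulder, where the monotonic method finds
nothing — that disagreement is expected and flagged, not an error).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ThermogramCurve

__all__ = [
    "PeakWindows",
    "MetricSet",
    "METRIC_COLUMNS",
    "STATISTICAL_METRICS",
    "find_peaks_monotonic",
    "find_peaks_windowed",
    "find_valley",
    "width_at_half_height",
    "total_area",
    "max_and_tmax",
    "median_cp",
    "first_moment_temperature",
    "compute_metric_set",
    "metrics_table",
]


@dataclass(frozen=True)
class PeakWindows:
    """Closed temperature windows assigning the three thermogram peaks."""

    peak1: tuple[float, float] = (60.0, 66.9)
    peak2: tuple[float, float] = (67.0, 72.9)
    peak3: tuple[float, float] = (73.0, 78.0)

    def __post_init__(self) -> None:
        lo1, hi1 = self.peak1
        lo2, hi2 = self.peak2
        lo3, hi3 = self.peak3
        if not (lo1 < hi1 < lo2 < hi2 < lo3 < hi3):
            raise ValueError("peak windows must be ordered and non-overlapping")

    def as_tuple(self) -> tuple[tuple[float, float], ...]:
        return (self.peak1, self.peak2, self.peak3)


#: Output column order for the per-sample metric table.
METRIC_COLUMNS = [
    "Width", "Area", "Max", "Median", "TMax",
    "Peak1", "Peak2", "Peak3", "V1.2",
    "TPeak1", "TPeak2", "TPeak3", "TV1.2",
    "Peak1.2", "Peak1.3", "Peak2.3",
    "V1.2.Peak1", "V1.2.Peak2", "V1.2.Peak3",
    "TFM",
]

#: The 19 metrics entering the statistical analyses (TPeak3 excluded).
STATISTICAL_METRICS = [c for c in METRIC_COLUMNS if c != "TPeak3"]


@dataclass
class MetricSet:
    """The 20 summary metrics for one thermogram, plus method-agreement flags."""

    sample_id: str
    values: dict[str, float]
    agreement: dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def as_row(self) -> dict[str, float | bool | str]:
        row: dict[str, float | bool | str] = {"sample_id": self.sample_id}
        row.update({k: self.values[k] for k in METRIC_COLUMNS})
        row.update(
            {f"agree_peak{i}": self.agreement.get(f"peak{i}", False) for i in (1, 2, 3)}
        )
        return row


# ---------------------------------------------------------------------------
# Peak / valley identification
# ---------------------------------------------------------------------------

def find_peaks_monotonic(
    curve: ThermogramCurve, min_up: int = 3, min_down: int = 3
) -> list[tuple[float, float]]:
    """Local maxima with >= ``min_up`` strictly rising steps before and
    >= ``min_down`` strictly falling steps after.

    Plateaus break a run (strict inequalities).  Returns (temperature,
    height) pairs sorted by temperature; may be empty.
    """
    cp = curve.cp
    t = curve.temperatures
    n = cp.size
    up = np.zeros(n, dtype=int)     # strictly increasing run ending at i
    down = np.zeros(n, dtype=int)   # strictly decreasing run starting at i
    for i in range(1, n):
        up[i] = up[i - 1] + 1 if cp[i] > cp[i - 1] else 0
    for i in range(n - 2, -1, -1):
        down[i] = down[i + 1] + 1 if cp[i] > cp[i + 1] else 0
    peaks = [
        (float(t[i]), float(cp[i]))
        for i in range(n)
        if up[i] >= min_up and down[i] >= min_down
    ]
    return peaks


def _window_mask(t: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (t >= lo - 1e-9) & (t <= hi + 1e-9)


def find_peaks_windowed(
    curve: ThermogramCurve, windows: PeakWindows | None = None
) -> list[tuple[float, float]]:
    """Maximum mesh point of each closed peak window; ties to lowest T."""
    windows = windows or PeakWindows()
    t = curve.temperatures
    out = []
    for window in windows.as_tuple():
        mask = _window_mask(t, window)
        if not mask.any():
            raise ValueError(f"peak window {window} contains no mesh points")
        idx = np.flatnonzero(mask)
        # np.argmax returns the first (lowest-temperature) maximum
        best = idx[int(np.argmax(curve.cp[idx]))]
        out.append((float(t[best]), float(curve.cp[best])))
    return out


def find_valley(
    curve: ThermogramCurve, t_left: float, t_right: float
) -> tuple[float, float]:
    """Minimum mesh point strictly between two temperatures; ties to lowest T."""
    if not t_left < t_right:
        raise ValueError("t_left must be below t_right")
    t = curve.temperatures
    mask = (t > t_left + 1e-9) & (t < t_right - 1e-9)
    if mask.sum() < 1:
        raise ValueError(
            f"no interior mesh points between {t_left} and {t_right} °C"
        )
    idx = np.flatnonzero(mask)
    best = idx[int(np.argmin(curve.cp[idx]))]
    return float(t[best]), float(curve.cp[best])


# ---------------------------------------------------------------------------
# Global curve descriptors
# ---------------------------------------------------------------------------

def max_and_tmax(curve: ThermogramCurve) -> tuple[float, float]:
    """Global maximum height and its temperature (ties to lowest T)."""
    i = int(np.argmax(curve.cp))
    return float(curve.cp[i]), float(curve.temperatures[i])


def width_at_half_height(curve: ThermogramCurve) -> float:
    """Distance between the outermost crossings of half the global maximum.

    Crossings are located by linear interpolation between bracketing mesh
    points.  The half level refers to the global envelope maximum over the
    whole 45–90 °C range.
    """
    cp = curve.cp
    t = curve.temperatures
    cmax = float(cp.max())
    if cmax <= 0:
        raise ValueError("curve maximum must be positive to define Width")
    half = cmax / 2.0
    above = cp >= half
    if not above.any():
        raise ValueError("curve never reaches half height")
    first = int(np.argmax(above))
    last = int(len(cp) - 1 - np.argmax(above[::-1]))
    if first == 0 and last == len(cp) - 1 and above[0] and above[-1]:
        raise ValueError("curve never falls below half height: Width undefined")
    if first > 0:
        t0, t1, y0, y1 = t[first - 1], t[first], cp[first - 1], cp[first]
        t_first = t0 + (half - y0) / (y1 - y0) * (t1 - t0)
    else:
        t_first = float(t[0])
    if last < len(cp) - 1:
        t0, t1, y0, y1 = t[last], t[last + 1], cp[last], cp[last + 1]
        t_last = t0 + (half - y0) / (y1 - y0) * (t1 - t0)
    else:
        t_last = float(t[-1])
    return float(t_last - t_first)


def total_area(curve: ThermogramCurve) -> float:
    """Trapezoid integral of cp over the mesh (cal/g)."""
    return float(np.trapezoid(curve.cp, curve.temperatures))


def median_cp(curve: ThermogramCurve) -> float:
    return float(np.median(curve.cp))


def first_moment_temperature(curve: ThermogramCurve) -> float:
    """Heat-capacity-weighted mean temperature Σ(T·cp)/Σ(cp)."""
    total = float(curve.cp.sum())
    if total <= 0:
        raise ValueError("total heat capacity must be positive for TFM")
    return float((curve.temperatures * curve.cp).sum() / total)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        raise ZeroDivisionError(f"zero denominator in metric {name}")
    return num / den


def compute_metric_set(
    curve: ThermogramCurve, windows: PeakWindows | None = None
) -> MetricSet:
    """Assemble all 20 summary metrics for one canonical-mesh curve.

    Peaks come from the windowed method; V1.2 is the minimum strictly
    between TPeak1 and TPeak2.  ``agreement`` records, per peak, whether the
    monotonic method found the identical (temperature, height) point.
    """
    curve.require_canonical()
    windows = windows or PeakWindows()
    try:
        peaks = find_peaks_windowed(curve, windows)
        (tp1, p1), (tp2, p2), (tp3, p3) = peaks
        tv12, v12 = find_valley(curve, tp1, tp2)
        cmax, tmax = max_and_tmax(curve)
        values = {
            "Width": width_at_half_height(curve),
            "Area": total_area(curve),
            "Max": cmax,
            "Median": median_cp(curve),
            "TMax": tmax,
            "Peak1": p1,
            "Peak2": p2,
            "Peak3": p3,
            "V1.2": v12,
            "TPeak1": tp1,
            "TPeak2": tp2,
            "TPeak3": tp3,
            "TV1.2": tv12,
            "Peak1.2": _ratio(p1, p2, "Peak1.2"),
            "Peak1.3": _ratio(p1, p3, "Peak1.3"),
            "Peak2.3": _ratio(p2, p3, "Peak2.3"),
            "V1.2.Peak1": _ratio(v12, p1, "V1.2.Peak1"),
            "V1.2.Peak2": _ratio(v12, p2, "V1.2.Peak2"),
            "V1.2.Peak3": _ratio(v12, p3, "V1.2.Peak3"),
            "TFM": first_moment_temperature(curve),
        }
    except (ValueError, ZeroDivisionError) as exc:
        raise ValueError(f"sample {curve.sample_id!r}: {exc}") from exc
    mono = find_peaks_monotonic(curve)
    agreement = {}
    for i, (tw, hw) in enumerate(peaks, start=1):
        agreement[f"peak{i}"] = any(
            abs(tm - tw) < 1e-9 and abs(hm - hw) < 1e-12 for tm, hm in mono
        )
    return MetricSet(curve.sample_id, values, agreement)


def metrics_table(
    curves: Sequence[ThermogramCurve], windows: PeakWindows | None = None
) -> pd.DataFrame:
    """Per-sample metric table (one row per curve, standard column names)."""
    rows = [compute_metric_set(c, windows).as_row() for c in curves]
    return pd.DataFrame(rows).set_index("sample_id")
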