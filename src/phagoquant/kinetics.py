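"""Per-well kinetic curves and summary metrics.

Frame-level measurements are aggregated into one time series per well
(mean over the well's replicate images at each timepoint); wells are the
unit of replication for group statistics.  Summaries follow the
conventions of plate-based uptake assays:

* ``slope_metric`` — ordinary-least-squares slope of the max-normalized
  signal over its rising window (start to first sample reaching 90% of
  the maximum), in fraction-of-max per minute.  This is a transparent
  replacement for the proprietary per-curve "slope" index of vendor
  software, whose exact formula and units are not public.
* ``auc`` — trapezoidal area under the curve, metric-units x minutes.
* ``percent_of_control`` / ``fold_change`` — endpoint normalization
  against vehicle wells; a vehicle group against itself is 100% by
  construction.
* ``detect_phases`` — peak and plateau detection distinguishing
  biphasic uptake (e.g. E. coli meals peaking around 4 h and 24 h) from
  saturating uptake that plateaus (e.g. S. aureus meals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.ndimage import uniform_filter1d
from scipy.signal import find_peaks

__all__ = [
    "METRICS",
    "FrameMetrics",
    "WellTimeSeries",
    "KineticSummary",
    "build_timeseries",
    "slope_metric",
    "auc",
    "endpoint",
    "percent_of_control",
    "fold_change",
    "detect_phases",
    "kinetic_summary",
]

#: metric name -> FrameMetrics attribute
METRICS: Mapping[str, str] = {
    "object_count": "object_count",
    "total_area": "total_area_um2",
    "total_intensity": "total_integrated_intensity",
}


@dataclass(frozen=True)
class FrameMetrics:
    """Scalar metrics of one analyzed frame."""

    well_id: str
    time_min: float
    object_count: int
    total_area_um2: float
    total_integrated_intensity: float
    confluence_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.object_count < 0:
            raise ValueError("object_count must be >= 0")
        if self.object_count == 0 and (
            self.total_area_um2 != 0 or self.total_integrated_intensity != 0
        ):
            raise ValueError("zero objects must have zero area and intensity")
        if self.confluence_fraction is not None and not (
            0 <= self.confluence_fraction <= 1
        ):
            raise ValueError("confluence_fraction must lie in [0, 1]")


@dataclass
class WellTimeSeries:
    """One kinetic curve: a metric over time for one well."""

    well_id: str
    metric_name: str
    times: np.ndarray
    values: np.ndarray
    n_images_per_point: int = 1

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D and equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if len(self.values) and np.min(self.values) < 0:
            raise ValueError("values must be non-negative")
        if self.metric_name not in METRICS:
            raise ValueError(f"unknown metric {self.metric_name!r}")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class KineticSummary:
    """Kinetic descriptors for one well or treatment group."""

    slope: float
    auc: float
    value_at: dict[float, float] = field(default_factory=dict)
    fold_change_vs_vehicle: float | None = None
    percent_of_control: float | None = None
    plateau_time_min: float | None = None
    peak_times_min: list[float] = field(default_factory=list)


class EmptySeriesError(ValueError):
    """A well has no frames to build a series from."""


def build_timeseries(
    frame_metrics: Iterable[FrameMetrics], metric_name: str
) -> dict[str, WellTimeSeries]:
    """Aggregate frame metrics into one series per well.

    At each (well, timepoint) the value is the arithmetic mean over that
    well's replicate images; series are sorted by time.  The per-point
    image count is recorded as the minimum across timepoints when it is
    not constant.
    """
    attr = METRICS.get(metric_name)
    if attr is None:
        raise ValueError(f"unknown metric {metric_name!r}; valid: {sorted(METRICS)}")
    by_well: dict[str, dict[float, list[float]]] = {}
    for fm in frame_metrics:
        by_well.setdefault(fm.well_id, {}).setdefault(fm.time_min, []).append(
            float(getattr(fm, attr))
        )
    if not by_well:
        raise EmptySeriesError("no frame metrics supplied")
    out: dict[str, WellTimeSeries] = {}
    for well in sorted(by_well):
        points = by_well[well]
        times = np.array(sorted(points))
        values = np.array([np.mean(points[t]) for t in times])
        n_images = min(len(points[t]) for t in times)
        out[well] = WellTimeSeries(well, metric_name, times, values, n_images)
    return out


def slope_metric(series: WellTimeSeries) -> float:
    """OLS slope of the max-normalized signal over its rising window.

    The series is divided by its maximum; the window runs from the first
    timepoint to the first sample reaching 90% of the maximum.  Units are
    fraction-of-max per minute.  A series with zero maximum, or whose
    window degenerates to a single point, has slope 0 by convention.
    """
    if len(series) < 3:
        raise ValueError("slope_metric needs a series of length >= 3")
    vmax = series.values.max()
    if vmax <= 0:
        return 0.0
    norm = series.values / vmax
    stop = int(np.argmax(norm >= 0.9))
    if stop == 0:
        return 0.0
    t, v = series.times[: stop + 1], norm[: stop + 1]
    return float(np.polyfit(t, v, 1)[0])


def auc(series: WellTimeSeries) -> float:
    """Trapezoidal integral of the full series (metric units x minutes)."""
    if len(series) < 2:
        raise ValueError("auc needs a series of length >= 2")
    return float(np.trapezoid(series.values, series.times))


def endpoint(series: WellTimeSeries) -> float:
    """Value at the final timepoint (default endpoint for normalization)."""
    if len(series) == 0:
        raise ValueError("empty series has no endpoint")
    return float(series.values[-1])


def percent_of_control(
    treated: Sequence[float] | float, vehicle: Sequence[float] | float
) -> float:
    """``100 x mean(treated) / mean(vehicle)``; scale-invariant.

    Reductions are conventionally reported as ``100 - result``.
    """
    v = float(np.mean(np.atleast_1d(np.asarray(vehicle, dtype=float))))
    t = float(np.mean(np.atleast_1d(np.asarray(treated, dtype=float))))
    if v <= 0:
        raise ValueError("vehicle mean must be positive (undefined control)")
    return 100.0 * t / v


def fold_change(treated: float, vehicle: float) -> float:
    """Ratio of treated to vehicle endpoint values."""
    if vehicle <= 0:
        raise ValueError("vehicle value must be positive")
    return float(treated) / float(vehicle)


def detect_phases(
    series: WellTimeSeries,
    min_prominence_frac: float = 0.2,
    plateau_eps_frac: float = 0.02,
    plateau_len: int = 3,
) -> tuple[list[float], float | None]:
    """Locate interior peaks and the onset of a plateau, if any.

    The series is smoothed by a 3-point moving average.  Peaks are local
    maxima with prominence at least ``min_prominence_frac`` of the
    smoothed maximum.  The plateau time is the first timepoint after
    which the absolute discrete derivative stays below
    ``plateau_eps_frac x max / interval`` for at least ``plateau_len``
    consecutive intervals, or ``None`` if never satisfied.
    """
    if len(series) < 5:
        raise ValueError("detect_phases needs a series of length >= 5")
    smoothed = uniform_filter1d(series.values, size=3, mode="nearest")
    vmax = float(smoothed.max())
    if vmax <= 0:
        return [], None
    peak_idx, _ = find_peaks(smoothed, prominence=min_prominence_frac * vmax)
    peak_times = [float(series.times[i]) for i in peak_idx]

    # |dv/dt| < eps*max/dt  <=>  |delta v| < eps*max per interval
    flat = np.abs(np.diff(smoothed)) < plateau_eps_frac * vmax
    plateau_time: float | None = None
    for i in range(len(flat) - plateau_len + 1):
        if flat[i : i + plateau_len].all():
            plateau_time = float(series.times[i])
            break
    return peak_times, plateau_time


def kinetic_summary(
    series: WellTimeSeries,
    vehicle_endpoint: float | None = None,
    value_at: Sequence[float] = (),
    **phase_kwargs,
) -> KineticSummary:
    """Assemble the standard descriptors for one series."""
    ep = endpoint(series)
    summary = KineticSummary(
        slope=slope_metric(series),
        auc=auc(series),
        value_at={float(t): float(np.interp(t, series.times, series.values)) for t in value_at},
    )
    if vehicle_endpoint is not None:
        summary.fold_change_vs_vehicle = fold_change(ep, vehicle_endpoint)
        summary.percent_of_control = percent_of_control([ep], [vehicle_endpoint])
    if len(series) >= 5:
        peaks, plateau = detect_phases(series, **phase_kwargs)
        summary.peak_times_min = peaks
        summary.plateau_time_min = plateau
    return summary
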