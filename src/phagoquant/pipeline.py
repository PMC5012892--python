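"""Plate-level orchestration: frames -> object tables -> kinetics -> CSV.

This is the glue the command-line interface and batch analyses use.  It
walks a directory of frames named under the package convention, runs the
per-frame segmentation chain on the fluorescence channel of interest,
computes the confluence fraction from phase frames when present, and
assembles the three standard output tables (``objects``, ``timeseries``,
``summary``).
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from phagoquant import kinetics as kin
from phagoquant.plate_model import (
    AnalysisParams,
    Channel,
    Frame,
    PlateLayout,
    WellRole,
    iter_frame_paths,
    read_frame,
)
from phagoquant.segmentation import analyze_frame, confluence_mask

__all__ = [
    "frame_metrics",
    "analyze_frames",
    "analyze_directory",
    "build_tables",
    "group_summary",
]


def frame_metrics(frame: Frame, params: AnalysisParams) -> tuple[kin.FrameMetrics, pd.DataFrame]:
    """Run the fluorescence chain on one frame; return metrics and objects."""
    _corrected, _labels, objects = analyze_frame(frame, params)
    fm = kin.FrameMetrics(
        well_id=frame.well_id,
        time_min=frame.time_min,
        object_count=len(objects),
        total_area_um2=float(objects["area_um2"].sum()) if len(objects) else 0.0,
        total_integrated_intensity=float(objects["integrated"].sum()) if len(objects) else 0.0,
    )
    annotated = objects.copy()
    annotated.insert(0, "well", frame.well_id)
    annotated.insert(1, "time_min", frame.time_min)
    annotated.insert(2, "image", frame.image_index)
    annotated.insert(3, "channel", frame.channel.value)
    return fm, annotated


def analyze_frames(
    frames: Sequence[Frame], params: AnalysisParams
) -> tuple[list[kin.FrameMetrics], pd.DataFrame]:
    """Per-frame metrics and a concatenated object table for many frames."""
    metrics: list[kin.FrameMetrics] = []
    tables: list[pd.DataFrame] = []
    confluence: dict[tuple[str, float, int], float] = {}
    for frame in frames:
        if frame.channel is Channel.PHASE:
            _mask, frac = confluence_mask(frame.pixels, params, frame.pixel_size_um)
            confluence[(frame.well_id, frame.time_min, frame.image_index)] = frac
            continue
        if frame.channel is not params.channel_of_interest:
            continue
        fm, objects = frame_metrics(frame, params)
        metrics.append(fm)
        tables.append(objects)
    if confluence:
        metrics = [_attach_confluence(fm, confluence) for fm in metrics]
    non_empty = [t for t in tables if not t.empty]
    if non_empty:
        objects_df = pd.concat(non_empty, ignore_index=True)
    elif tables:
        objects_df = tables[0].iloc[0:0]
    else:
        objects_df = pd.DataFrame()
    return metrics, objects_df


def _attach_confluence(
    fm: kin.FrameMetrics, confluence: Mapping[tuple[str, float, int], float]
) -> kin.FrameMetrics:
    """Mean phase-derived confluence over images at the frame's (well, time)."""
    fracs = [v for (w, t, _i), v in confluence.items() if w == fm.well_id and t == fm.time_min]
    if not fracs:
        return fm
    return kin.FrameMetrics(
        fm.well_id, fm.time_min, fm.object_count, fm.total_area_um2,
        fm.total_integrated_intensity, float(np.mean(fracs)),
    )


def analyze_directory(
    images_dir: str | Path,
    params: AnalysisParams,
    pixel_size_um: float = 1.0,
) -> tuple[list[kin.FrameMetrics], pd.DataFrame]:
    """Load and analyze every parseable frame in a directory."""
    frames = [
        read_frame(path, pixel_size_um)
        for path, meta in iter_frame_paths(images_dir)
        if meta.channel in (params.channel_of_interest, Channel.PHASE)
    ]
    if not any(f.channel is params.channel_of_interest for f in frames):
        raise FileNotFoundError(
            f"no frames found for channel {params.channel_of_interest.value!r} in {images_dir}"
        )
    return analyze_frames(frames, params)


def _sem(values: np.ndarray) -> float:
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def _series_descriptors(series: kin.WellTimeSeries) -> dict[str, object]:
    slope = kin.slope_metric(series) if len(series) >= 3 else math.nan
    area = kin.auc(series) if len(series) >= 2 else math.nan
    peaks: list[float] = []
    plateau: float | None = None
    if len(series) >= 5:
        peaks, plateau = kin.detect_phases(series)
    return {
        "slope": slope,
        "auc": area,
        "peaks": ";".join(f"{t:g}" for t in peaks),
        "plateau_time_min": plateau if plateau is not None else math.nan,
    }


def build_tables(
    metrics: Sequence[kin.FrameMetrics],
    objects_df: pd.DataFrame,
    layout: PlateLayout | None = None,
    normalize: bool = False,
    metric: str = "object_count",
) -> dict[str, pd.DataFrame]:
    """Assemble the objects / timeseries / summary tables for one plate.

    With ``normalize`` set (requires a layout with at least one vehicle
    well), each well's endpoint is expressed as percent of the vehicle
    group's mean endpoint and as a fold change against it.
    """
    series = kin.build_timeseries(metrics, metric)
    ts_rows = [
        {
            "well": s.well_id,
            "time_min": t,
            "metric": metric,
            "value": v,
            "n_images": s.n_images_per_point,
        }
        for s in series.values()
        for t, v in zip(s.times, s.values)
    ]
    timeseries_df = pd.DataFrame(ts_rows)

    vehicle_mean: float | None = None
    if normalize:
        if layout is None or not layout.vehicle_wells:
            raise ValueError("normalization requested but the layout has no vehicle well")
        vehicle_eps = [
            kin.endpoint(series[w.well_id])
            for w in layout.vehicle_wells
            if w.well_id in series
        ]
        if not vehicle_eps:
            raise ValueError("no analyzed frames for any vehicle well")
        vehicle_mean = float(np.mean(vehicle_eps))

    rows = []
    for well_id, s in series.items():
        ep = kin.endpoint(s)
        row: dict[str, object] = {
            "group": well_id,
            "n_wells": 1,
            "endpoint_mean": ep,
            "endpoint_sem": math.nan,
            **_series_descriptors(s),
        }
        if vehicle_mean is not None:
            row["pct_of_control"] = kin.percent_of_control([ep], [vehicle_mean])
            row["fold_change"] = kin.fold_change(ep, vehicle_mean)
        else:
            row["pct_of_control"] = math.nan
            row["fold_change"] = math.nan
        rows.append(row)
    summary_df = pd.DataFrame(rows)
    return {"objects": objects_df, "timeseries": timeseries_df, "summary": summary_df}


def group_summary(
    timeseries_df: pd.DataFrame,
    layout: PlateLayout,
    group_by: str = "treatment",
) -> pd.DataFrame:
    """Treatment-group summary: mean +- SEM of endpoints across wells.

    Wells are the unit of replication.  Percent of control and fold
    change are computed against the mean endpoint of vehicle wells when
    the layout defines any.
    """
    layout_df = layout.to_frame()
    if group_by not in layout_df.columns:
        raise KeyError(
            f"unknown grouping column {group_by!r}; valid: {list(layout_df.columns)}"
        )
    metric = timeseries_df["metric"].iloc[0]
    per_well: dict[str, kin.WellTimeSeries] = {}
    for well_id, sub in timeseries_df.groupby("well"):
        sub = sub.sort_values("time_min")
        per_well[str(well_id)] = kin.WellTimeSeries(
            str(well_id), metric, sub["time_min"].to_numpy(), sub["value"].to_numpy(),
            int(sub["n_images"].iloc[0]),
        )
    vehicle_ids = {w.well_id for w in layout.vehicle_wells}
    vehicle_eps = [kin.endpoint(s) for w, s in per_well.items() if w in vehicle_ids]
    vehicle_mean = float(np.mean(vehicle_eps)) if vehicle_eps else None

    rows = []
    for group, sub in layout_df.groupby(group_by, sort=True):
        wells = [w for w in sub["well"] if w in per_well]
        if not wells:
            continue
        eps = np.array([kin.endpoint(per_well[w]) for w in wells])
        slopes = [kin.slope_metric(per_well[w]) for w in wells if len(per_well[w]) >= 3]
        aucs = [kin.auc(per_well[w]) for w in wells if len(per_well[w]) >= 2]
        row: dict[str, object] = {
            "group": group,
            "n_wells": len(wells),
            "endpoint_mean": float(eps.mean()),
            "endpoint_sem": _sem(eps),
            "slope": float(np.mean(slopes)) if slopes else math.nan,
            "auc": float(np.mean(aucs)) if aucs else math.nan,
            "peaks": "",
            "plateau_time_min": math.nan,
        }
        if vehicle_mean is not None and vehicle_mean > 0:
            row["pct_of_control"] = kin.percent_of_control(eps, [vehicle_mean])
            row["fold_change"] = kin.fold_change(float(eps.mean()), vehicle_mean)
        else:
            row["pct_of_control"] = math.nan
            row["fold_change"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
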