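"""Core data types, file naming, plate layout, parameters and CSV output.

Conventions fixed here and relied on by every other module:

* frame files are named ``{well}_{image_index}_{channel}_t{minutes}.tif``,
  e.g. ``B07_1_green_t010.tif`` — deterministic, sortable and parseable
  without a sidecar database;
* times are minutes since assay start, stored as reals (no fixed cadence
  is assumed; timestamps come from filenames);
* pixel coordinates are 0-based ``(row, col)``; areas are converted to
  square micrometres via ``pixel_size_um ** 2``;
* all tabular output is UTF-8 CSV with a header row and ``.`` decimals,
  written with a deterministic column order so identical inputs give
  byte-identical files.
"""

from __future__ import annotations

import enum
import re
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

if sys.version_info >= (3, 11):
    import tomllib
else:  # pragma: no cover
    import tomli as tomllib

__all__ = [
    "Channel",
    "WellRole",
    "Frame",
    "FrameMeta",
    "WellInfo",
    "PlateLayout",
    "AnalysisParams",
    "FramePathError",
    "LayoutError",
    "parse_frame_path",
    "format_frame_path",
    "read_frame",
    "write_frame",
    "load_layout",
    "load_params",
    "write_results",
]


class Channel(str, enum.Enum):
    """Acquisition channel; decides the downstream analysis path.

    ``phase`` frames feed the confluence mask; ``green``/``red`` frames
    feed fluorescent-object detection.
    """

    PHASE = "phase"
    GREEN = "green"
    RED = "red"


class WellRole(str, enum.Enum):
    VEHICLE = "vehicle"
    TREATED = "treated"
    BLANK = "blank"


class FramePathError(ValueError):
    """A frame filename does not follow the documented convention."""


class LayoutError(ValueError):
    """A plate-layout table failed validation."""


_WELL_RE = r"[A-Za-z]{1,2}\d{1,3}"
_FRAME_RE = re.compile(
    rf"(?P<well>{_WELL_RE})_(?P<index>\d+)_(?P<channel>[a-z]+)_t(?P<time>\d+(?:\.\d+)?)\.tiff?$"
)


@dataclass(frozen=True)
class FrameMeta:
    """Identifying metadata of one acquired image plane."""

    well_id: str
    image_index: int
    channel: Channel
    time_min: float

    def __post_init__(self) -> None:
        if self.image_index < 1:
            raise ValueError(f"image_index must be >= 1, got {self.image_index}")
        if self.time_min < 0:
            raise ValueError(f"time_min must be >= 0, got {self.time_min}")


@dataclass
class Frame:
    """One acquired image plane with its metadata.

    ``pixels`` holds raw (or corrected) intensities in acquisition units;
    vendor exposure times are metadata of the acquisition and never
    rescale intensities here.
    """

    pixels: np.ndarray
    channel: Channel
    time_min: float
    well_id: str
    image_index: int = 1
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2 or self.pixels.size == 0:
            raise ValueError("pixels must be a non-empty 2-D grid")
        if np.min(self.pixels) < 0:
            raise ValueError("pixel intensities must be non-negative")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        self.channel = Channel(self.channel)
        if self.time_min < 0:
            raise ValueError("time_min must be >= 0")
        if self.image_index < 1:
            raise ValueError("image_index must be >= 1")

    @property
    def meta(self) -> FrameMeta:
        return FrameMeta(self.well_id, self.image_index, self.channel, self.time_min)


def parse_frame_path(path: str | Path) -> FrameMeta:
    """Parse well, image index, channel and time from a frame filename.

    Raises :class:`FramePathError` naming the offending component when the
    name does not follow ``{well}_{image_index}_{channel}_t{minutes}.tif``.
    """
    name = Path(path).name
    m = _FRAME_RE.fullmatch(name)
    if m is None:
        parts = Path(name).stem.split("_")
        if len(parts) != 4:
            raise FramePathError(
                f"{name!r}: expected 4 underscore-separated components "
                f"(well, image index, channel, t<minutes>), got {len(parts)}"
            )
        if not re.fullmatch(_WELL_RE, parts[0]):
            raise FramePathError(f"{name!r}: bad well component {parts[0]!r}")
        if not parts[1].isdigit():
            raise FramePathError(f"{name!r}: bad image-index component {parts[1]!r}")
        if not re.fullmatch(r"t\d+(?:\.\d+)?", parts[3]):
            raise FramePathError(f"{name!r}: bad time component {parts[3]!r}")
        raise FramePathError(f"{name!r}: bad channel component {parts[2]!r}")
    try:
        channel = Channel(m.group("channel"))
    except ValueError as exc:
        valid = ", ".join(c.value for c in Channel)
        raise FramePathError(
            f"{name!r}: unknown channel {m.group('channel')!r} (valid: {valid})"
        ) from exc
    return FrameMeta(
        well_id=m.group("well"),
        image_index=int(m.group("index")),
        channel=channel,
        time_min=float(m.group("time")),
    )


def format_frame_path(meta: FrameMeta) -> str:
    """Inverse of :func:`parse_frame_path` for valid metadata."""
    t = meta.time_min
    t_str = f"{int(round(t)):03d}" if float(t).is_integer() else f"{t:g}"
    return f"{meta.well_id}_{meta.image_index}_{Channel(meta.channel).value}_t{t_str}.tif"


def read_frame(path: str | Path, pixel_size_um: float = 1.0) -> Frame:
    """Load a single-plane grayscale TIFF and its filename metadata.

    8/16-bit unsigned and 32-bit float planes are accepted; values are
    treated as real intensities without rescaling.
    """
    meta = parse_frame_path(path)
    pixels = tifffile.imread(path)
    if pixels.ndim != 2:
        raise ValueError(f"{path}: expected a single 2-D plane, got shape {pixels.shape}")
    return Frame(
        pixels=pixels.astype(np.float64, copy=False),
        channel=meta.channel,
        time_min=meta.time_min,
        well_id=meta.well_id,
        image_index=meta.image_index,
        pixel_size_um=pixel_size_um,
    )


def write_frame(frame: Frame, out_dir: str | Path) -> Path:
    """Write a frame as a 32-bit float TIFF under the naming convention."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / format_frame_path(frame.meta)
    tifffile.imwrite(path, frame.pixels.astype(np.float32))
    return path


@dataclass(frozen=True)
class WellInfo:
    well_id: str
    treatment: str
    concentration: float
    unit: str
    role: WellRole
    seeded_cells: int
    meal: str


@dataclass
class PlateLayout:
    """Per-well experimental design: treatments, roles and cell numbers."""

    wells: list[WellInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for w in self.wells:
            if w.well_id in seen:
                raise LayoutError(f"duplicate well_id {w.well_id!r}")
            seen.add(w.well_id)
            if w.concentration < 0:
                raise LayoutError(f"{w.well_id}: concentration must be >= 0")
            if w.seeded_cells < 0:
                raise LayoutError(f"{w.well_id}: seeded_cells must be >= 0")
            if w.role is WellRole.BLANK and w.seeded_cells != 0:
                raise LayoutError(f"{w.well_id}: blank wells must have 0 seeded cells")

    def __len__(self) -> int:
        return len(self.wells)

    def __getitem__(self, well_id: str) -> WellInfo:
        for w in self.wells:
            if w.well_id == well_id:
                return w
        raise KeyError(well_id)

    def wells_with_role(self, role: WellRole) -> list[WellInfo]:
        return [w for w in self.wells if w.role is role]

    @property
    def vehicle_wells(self) -> list[WellInfo]:
        return self.wells_with_role(WellRole.VEHICLE)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "well": [w.well_id for w in self.wells],
                "treatment": [w.treatment for w in self.wells],
                "concentration": [w.concentration for w in self.wells],
                "unit": [w.unit for w in self.wells],
                "role": [w.role.value for w in self.wells],
                "cells": [w.seeded_cells for w in self.wells],
                "meal": [w.meal for w in self.wells],
            }
        )


_LAYOUT_COLUMNS = ["well", "treatment", "concentration", "unit", "role", "cells", "meal"]


def load_layout(path: str | Path) -> PlateLayout:
    """Read and validate a plate-layout CSV.

    The table must carry the header columns
    ``well,treatment,concentration,unit,role,cells,meal``.  Row order is
    irrelevant: wells are compared by id, never by position.
    """
    df = pd.read_csv(path, dtype={"well": str, "treatment": str, "unit": str, "meal": str})
    missing = [c for c in _LAYOUT_COLUMNS if c not in df.columns]
    if missing:
        raise LayoutError(f"{path}: missing layout columns {missing}")
    wells: list[WellInfo] = []
    valid_roles = ", ".join(r.value for r in WellRole)
    for rec in df.to_dict("records"):
        role_str = str(rec["role"]).strip().lower()
        try:
            role = WellRole(role_str)
        except ValueError as exc:
            raise LayoutError(
                f"{path}: unknown role {rec['role']!r} for well {rec['well']!r} "
                f"(valid: {valid_roles})"
            ) from exc
        try:
            conc = float(rec["concentration"])
        except (TypeError, ValueError) as exc:
            raise LayoutError(
                f"{path}: non-numeric concentration {rec['concentration']!r} "
                f"for well {rec['well']!r}"
            ) from exc
        wells.append(
            WellInfo(
                well_id=str(rec["well"]),
                treatment=str(rec["treatment"]),
                concentration=conc,
                unit=str(rec["unit"]),
                role=role,
                seeded_cells=int(rec["cells"]),
                meal=str(rec["meal"]),
            )
        )
    return PlateLayout(wells)


@dataclass
class AnalysisParams:
    """Image-analysis settings.

    Defaults are the vendor-software settings of the original assay:
    top-hat background correction with a 20 um radius, a fixed threshold
    of 2 corrected units on the fluorescence channels, a 50 um^2 minimum
    object area, and edge-split declumping enabled.
    """

    tophat_radius_um: float = 20.0
    threshold_corrected_units: float = 2.0
    min_object_area_um2: float = 50.0
    edge_split: bool = True
    apply_area_filter_to_fluorescence: bool = True
    channel_of_interest: Channel = Channel.GREEN
    smoothing_sigma_px: float = 1.0

    def __post_init__(self) -> None:
        if self.tophat_radius_um <= 0:
            raise ValueError("tophat_radius_um must be > 0")
        if self.threshold_corrected_units <= 0:
            raise ValueError("threshold_corrected_units must be > 0")
        if self.min_object_area_um2 < 0:
            raise ValueError("min_object_area_um2 must be >= 0")
        if self.smoothing_sigma_px < 0:
            raise ValueError("smoothing_sigma_px must be >= 0")
        self.channel_of_interest = Channel(self.channel_of_interest)
        if self.channel_of_interest is Channel.PHASE:
            raise ValueError("channel_of_interest must be a fluorescence channel")

    def replace(self, **changes) -> "AnalysisParams":
        return replace(self, **changes)


def load_params(path: str | Path) -> AnalysisParams:
    """Load :class:`AnalysisParams` from a TOML file.

    Keys may live at top level or under an ``[analysis]`` table; unknown
    keys are rejected so typos do not silently fall back to defaults.
    """
    with open(path, "rb") as fh:
        data = tomllib.load(fh)
    section = data.get("analysis", data)
    known = set(AnalysisParams.__dataclass_fields__)
    unknown = set(section) - known
    if unknown:
        raise ValueError(f"{path}: unknown analysis parameter(s) {sorted(unknown)}")
    return AnalysisParams(**section)


_TABLE_COLUMNS: Mapping[str, list[str]] = {
    "objects": [
        "well", "time_min", "image", "channel", "label", "row", "col",
        "pixel_count", "area_um2", "integrated", "mean",
        "bbox0", "bbox1", "bbox2", "bbox3",
    ],
    "timeseries": ["well", "time_min", "metric", "value", "n_images"],
    "summary": [
        "group", "n_wells", "endpoint_mean", "endpoint_sem", "slope", "auc",
        "pct_of_control", "fold_change", "peaks", "plateau_time_min",
    ],
    "groups": [
        "group", "n_wells", "endpoint_mean", "endpoint_sem", "slope", "auc",
        "pct_of_control", "fold_change", "peaks", "plateau_time_min",
    ],
}


def write_results(tables: Mapping[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write result tables as ``<name>.csv`` with a deterministic column order.

    ``tables`` maps a table name (``objects``, ``timeseries``, ``summary``,
    or any custom name) to a DataFrame.  Known tables are reordered to
    their canonical column list; an empty table still gets its header row.
    Re-running on identical input produces byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name in sorted(tables):
        df = tables[name]
        cols = _TABLE_COLUMNS.get(name)
        if cols is not None:
            if df.empty and df.columns.empty:
                df = pd.DataFrame(columns=cols)
            else:
                ordered = [c for c in cols if c in df.columns]
                ordered += [c for c in df.columns if c not in ordered]
                df = df[ordered]
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")
        written.append(path)
    return written


def iter_frame_paths(images_dir: str | Path) -> Iterable[tuple[Path, FrameMeta]]:
    """Yield ``(path, metadata)`` for every parseable frame file, sorted by name."""
    for path in sorted(Path(images_dir).glob("*.tif*")):
        try:
            meta = parse_frame_path(path)
        except FramePathError:
            continue
        yield path, meta
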