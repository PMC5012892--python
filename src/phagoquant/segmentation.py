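"""Per-frame image processing.

The fluorescence path is: white top-hat background correction (disk
radius given in micrometres), fixed thresholding in corrected units
(inclusive, ``>=``), 8-connected component labeling in deterministic
raster order, optional edge-split declumping by marker-controlled
watershed, object measurement, and an area filter that removes objects
strictly below the minimum area ("below 50 um^2" is read literally, so
an exactly-50 um^2 object is retained).

The phase-contrast path produces a confluence mask from a local-variance
texture map.  It feeds reporting only and never enters the fluorescence
metrics.
"""

from __future__ import annotations

import warnings
from math import pi, sqrt

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import label as _sk_label
from skimage.measure import regionprops_table
from skimage.morphology import closing, disk, remove_small_objects, white_tophat
from skimage.segmentation import watershed

from phagoquant.plate_model import AnalysisParams, Channel, Frame

__all__ = [
    "tophat_correct",
    "threshold_mask",
    "label_connected",
    "edge_split",
    "area_filter",
    "measure_objects",
    "confluence_mask",
    "analyze_frame",
    "OBJECT_COLUMNS",
]

OBJECT_COLUMNS = [
    "label", "row", "col", "pixel_count", "area_um2", "integrated", "mean",
    "bbox0", "bbox1", "bbox2", "bbox3",
]


def _radius_px(radius_um: float, pixel_size_um: float) -> int:
    r = int(round(radius_um / pixel_size_um))
    if r < 1:
        warnings.warn(
            f"structuring-element radius {radius_um} um is below one pixel "
            f"({pixel_size_um} um/px); clamping to 1 px",
            stacklevel=3,
        )
        r = 1
    return r


def tophat_correct(
    pixels: np.ndarray, radius_um: float, pixel_size_um: float
) -> np.ndarray:
    """White top-hat transform: image minus its grayscale opening by a disk.

    Removes smooth background non-uniformity while preserving structures
    smaller than the structuring element.  The disk radius is
    ``round(radius_um / pixel_size_um)`` pixels, at least 1.  The output
    is pointwise in ``[0, input]``.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("pixels must be a non-empty 2-D grid")
    if radius_um <= 0 or pixel_size_um <= 0:
        raise ValueError("radius_um and pixel_size_um must be positive")
    r = _radius_px(radius_um, pixel_size_um)
    return white_tophat(pixels, footprint=disk(r))


def threshold_mask(corrected: np.ndarray, threshold: float) -> np.ndarray:
    """Foreground where the corrected intensity is >= ``threshold``."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    return np.asarray(corrected) >= threshold


def _relabel_raster(labels: np.ndarray) -> np.ndarray:
    """Renumber labels 1..K by raster order of each label's first pixel."""
    flat = labels.ravel()
    uniq, first = np.unique(flat, return_index=True)
    nz = uniq != 0
    uniq, first = uniq[nz], first[nz]
    order = np.argsort(first, kind="stable")
    mapping = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    mapping[uniq[order]] = np.arange(1, len(uniq) + 1)
    return mapping[labels]


def label_connected(mask: np.ndarray) -> np.ndarray:
    """8-connected component labeling with deterministic raster ordering.

    Labels form the contiguous set ``{0..K}``; label k's first pixel in
    raster (row-major) order precedes label k+1's.
    """
    labels = _sk_label(np.asarray(mask, dtype=bool), connectivity=2)
    return _relabel_raster(labels.astype(np.int32))


def edge_split(
    labels: np.ndarray,
    corrected: np.ndarray,
    params: AnalysisParams,
    pixel_size_um: float,
) -> np.ndarray:
    """Split labeled regions containing multiple closely-spaced objects.

    Within each region, seeds are local maxima of the Gaussian-smoothed
    corrected image separated by at least the equivalent diameter of
    ``params.min_object_area_um2``.  Regions with two or more seeds are
    re-partitioned by marker-controlled watershed on the inverted
    smoothed intensity; the union of the children equals the parent
    exactly.  Regions with at most one seed pass through unchanged.
    With ``params.edge_split`` false this is the identity.
    """
    labels = np.asarray(labels)
    if not params.edge_split:
        return labels.copy()
    corrected = np.asarray(corrected, dtype=np.float64)
    if corrected.shape != labels.shape:
        raise ValueError("labels and corrected must share shape")
    if labels.max() == 0:
        return labels.copy()

    sigma = params.smoothing_sigma_px
    smoothed = ndimage.gaussian_filter(corrected, sigma) if sigma > 0 else corrected
    equiv_diam_px = 2.0 * sqrt(params.min_object_area_um2 / pi) / pixel_size_um
    min_dist = max(1, int(round(equiv_diam_px)))
    seeds = peak_local_max(
        smoothed, min_distance=min_dist, labels=labels, exclude_border=False
    )
    seed_parent = labels[tuple(seeds.T)] if len(seeds) else np.empty(0, dtype=labels.dtype)

    out = labels.copy().astype(np.int32)
    next_label = int(labels.max())
    for parent in np.unique(seed_parent):
        idx = np.nonzero(seed_parent == parent)[0]
        if len(idx) < 2:
            continue
        region = labels == parent
        markers = np.zeros(labels.shape, dtype=np.int32)
        for k, s in enumerate(idx, start=1):
            markers[tuple(seeds[s])] = k
        children = watershed(-smoothed, markers=markers, mask=region)
        out[region] = children[region] + next_label
        next_label += len(idx)
    return _relabel_raster(out)


def measure_objects(
    labels: np.ndarray, corrected: np.ndarray, pixel_size_um: float
) -> pd.DataFrame:
    """One row per nonzero label: centroid, pixel count, area in um^2,
    integrated and mean corrected intensity, and half-open bounding box.
    The table is sorted by label id."""
    labels = np.asarray(labels)
    corrected = np.asarray(corrected, dtype=np.float64)
    if labels.shape != corrected.shape:
        raise ValueError("labels and corrected must share shape")
    if labels.max() == 0:
        return pd.DataFrame(columns=OBJECT_COLUMNS)
    props = regionprops_table(
        labels,
        intensity_image=corrected,
        properties=("label", "centroid", "area", "intensity_mean", "bbox"),
    )
    n_px = props["area"].astype(np.int64)
    df = pd.DataFrame(
        {
            "label": props["label"],
            "row": props["centroid-0"],
            "col": props["centroid-1"],
            "pixel_count": n_px,
            "area_um2": n_px * pixel_size_um**2,
            "integrated": props["intensity_mean"] * n_px,
            "mean": props["intensity_mean"],
            "bbox0": props["bbox-0"],
            "bbox1": props["bbox-1"],
            "bbox2": props["bbox-2"],
            "bbox3": props["bbox-3"],
        }
    )
    return df.sort_values("label", ignore_index=True)


def area_filter(objects: pd.DataFrame, min_area_um2: float) -> pd.DataFrame:
    """Retain objects with ``area_um2 >= min_area_um2`` (strict 'below' removed)."""
    if min_area_um2 < 0:
        raise ValueError("min_area_um2 must be >= 0")
    if objects.empty:
        return objects.copy()
    return objects[objects["area_um2"] >= min_area_um2].reset_index(drop=True)


def confluence_mask(
    phase: np.ndarray, params: AnalysisParams, pixel_size_um: float
) -> tuple[np.ndarray, float]:
    """Cell-coverage mask from a phase-contrast frame.

    A local-variance texture map (square window of twice the top-hat
    radius) is Otsu-thresholded, morphologically closed (disk 2 px), and
    components below ``min_object_area_um2`` are removed.  Returns the
    binary mask and the foreground fraction in ``[0, 1]``.

    Two degenerate cases yield an empty mask with a warning: a constant
    image (no texture at all), and a texture map without contrast
    between the Otsu classes (e.g. pure sensor noise with no cells),
    detected as a foreground-class mean variance below three times the
    background-class mean.
    """
    phase = np.asarray(phase, dtype=np.float64)
    size = max(3, int(round(2.0 * params.tophat_radius_um / pixel_size_um)))
    mean = ndimage.uniform_filter(phase, size=size)
    mean_sq = ndimage.uniform_filter(phase**2, size=size)
    var = np.clip(mean_sq - mean**2, 0.0, None)
    if var.max() <= 0:
        warnings.warn("constant phase image: degenerate texture threshold", stacklevel=2)
        return np.zeros_like(phase, dtype=bool), 0.0
    thr = threshold_otsu(var)
    fg = var > thr
    if not fg.any() or fg.all():
        warnings.warn("degenerate texture threshold on phase image", stacklevel=2)
        return np.zeros_like(phase, dtype=bool), 0.0
    if var[fg].mean() < 3.0 * var[~fg].mean():
        warnings.warn(
            "no texture contrast between Otsu classes; treating frame as cell-free",
            stacklevel=2,
        )
        return np.zeros_like(phase, dtype=bool), 0.0
    fg = closing(fg, footprint=disk(2))
    min_px = int(np.ceil(params.min_object_area_um2 / pixel_size_um**2))
    if min_px > 1:
        # retain components of >= min_px pixels ("below" removed)
        fg = remove_small_objects(fg, max_size=min_px - 1)
    return fg, float(fg.mean())


def analyze_frame(
    frame: Frame, params: AnalysisParams
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Full fluorescence chain for one frame.

    Correction -> threshold -> label -> edge split -> measurement ->
    area filter (when ``apply_area_filter_to_fluorescence``).  Returns
    ``(corrected, labels, objects)``; the label grid is the pre-filter
    segmentation, the object table is post-filter.
    """
    if frame.channel is Channel.PHASE:
        raise ValueError("analyze_frame expects a fluorescence frame")
    corrected = tophat_correct(frame.pixels, params.tophat_radius_um, frame.pixel_size_um)
    mask = threshold_mask(corrected, params.threshold_corrected_units)
    labels = label_connected(mask)
    labels = edge_split(labels, corrected, params, frame.pixel_size_um)
    objects = measure_objects(labels, corrected, frame.pixel_size_um)
    if params.apply_area_filter_to_fluorescence:
        objects = area_filter(objects, params.min_object_area_um2)
    return corrected, labels, objects
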