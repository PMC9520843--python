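"""Vesicle detection: background subtraction, thresholding, particle analysis.

The pipeline mirrors the classic ImageJ workflow for punctate structures:
subtract a smooth background estimate (white top-hat with a disk), apply an
automatic threshold to the subtracted raster, label connected components,
and keep components that pass area and circularity filters. Circularity
uses the 4·pi·area / perimeter² convention (1 for a perfect disk).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation
from skimage.feature import peak_local_max

from .field import FieldOfView, LabeledMask
from .params import DetectionParams

logger = logging.getLogger(__name__)

#: columns of a freshly detected (unclassified) vesicle table
TABLE_COLUMNS = ["label", "row", "col", "area", "perimeter", "circularity"]


def _as_float(raster: np.ndarray) -> np.ndarray:
    """Integer (8/16-bit) input is promoted to float; floats pass through."""
    return np.asarray(raster, dtype=float)


def subtract_background(raster: np.ndarray, background_radius: float) -> np.ndarray:
    """White top-hat background subtraction with a disk structuring element.

    Equivalent in spirit to rolling-ball subtraction: a grayscale opening
    with a disk of the given radius estimates the smooth background, and the
    result is the raster minus that estimate. Features smaller than the disk
    are preserved; the output is non-negative everywhere.
    """
    raster = _as_float(raster)
    if background_radius <= 0:
        raise ValueError("background_radius must be > 0")
    if background_radius >= min(raster.shape):
        raise ValueError(
            f"background_radius {background_radius} exceeds image extent "
            f"{raster.shape}"
        )
    footprint = morphology.disk(int(round(background_radius)),
                                decomposition="sequence")
    # the decomposed disk is a fast approximation; clip the (tiny) negative
    # residuals it can introduce so the non-negativity contract holds
    return np.maximum(morphology.white_tophat(raster, footprint=footprint), 0.0)


def _threshold(subtracted: np.ndarray, params: DetectionParams) -> float:
    method = params.threshold_method
    if not isinstance(method, str):
        return float(method)
    if subtracted.max() == subtracted.min():
        # constant raster: no automatic threshold exists; put it above the
        # constant so nothing is detected
        return float(subtracted.max()) + 1.0
    if method == "otsu":
        thr = float(filters.threshold_otsu(subtracted))
    elif method == "triangle":
        thr = float(filters.threshold_triangle(subtracted))
    elif method == "mean_sd":
        thr = float(subtracted.mean() + params.threshold_k * subtracted.std())
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    if params.noise_floor_k > 0:
        # automatic thresholds split even a pure-noise histogram; the robust
        # floor (signal pixels are sparse, so median/MAD estimate the noise)
        # keeps a signal-free image detection-free
        med = float(np.median(subtracted))
        mad = float(np.median(np.abs(subtracted - med)))
        thr = max(thr, med + params.noise_floor_k * 1.4826 * mad)
    return thr


def _split_touching(binary: np.ndarray, connectivity: int) -> np.ndarray:
    """Distance-transform watershed to separate touching blobs (optional)."""
    distance = ndimage.distance_transform_edt(binary)
    coords = peak_local_max(distance, labels=binary, min_distance=2,
                            exclude_border=False)
    markers = np.zeros(binary.shape, dtype=int)
    markers[tuple(coords.T)] = np.arange(1, len(coords) + 1)
    if markers.max() == 0:
        return measure.label(binary, connectivity=connectivity)
    return segmentation.watershed(-distance, markers, mask=binary,
                                  connectivity=connectivity)


def circularity(area: float, perimeter: float) -> float:
    """ImageJ-convention circularity, 4*pi*area / perimeter**2, capped at 1."""
    if perimeter <= 0:
        return 1.0
    return min(1.0, 4.0 * np.pi * area / (perimeter * perimeter))


def detect_vesicles(
    field: FieldOfView,
    detection_channel: str,
    params: DetectionParams | None = None,
) -> tuple[LabeledMask, pd.DataFrame]:
    """Detect vesicles in one channel and tabulate per-object geometry.

    Returns the consecutive-labeled mask and a table with one row per kept
    vesicle: ``label``, intensity-weighted centroid ``row``/``col`` (0-based,
    weighted on the background-subtracted raster), ``area`` (px²),
    ``perimeter`` and ``circularity``. Area and circularity bounds are
    inclusive. A blank or degenerate image yields an empty table, not an
    error.
    """
    if params is None:
        params = DetectionParams()
    raster = _as_float(field.channel(detection_channel))

    if raster.size and raster.max() == raster.min() and raster.max() > 0:
        logger.warning("channel %r is constant (possibly saturated); "
                       "no vesicles will be detected", detection_channel)

    smoothed = raster
    if params.smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(raster, params.smooth_sigma)
    subtracted = subtract_background(smoothed, params.background_radius)
    thr = _threshold(subtracted, params)
    binary = subtracted > thr
    if params.fill_holes:
        binary = ndimage.binary_fill_holes(binary)

    skimage_conn = 1 if params.connectivity == 4 else 2
    if params.split_touching:
        labels = _split_touching(binary, skimage_conn)
    else:
        labels = measure.label(binary, connectivity=skimage_conn)

    props = measure.regionprops(labels, intensity_image=subtracted)
    kept = []
    for p in props:
        if not (params.min_area <= p.area <= params.max_area):
            continue
        if circularity(p.area, p.perimeter) < params.min_circularity:
            continue
        kept.append(p)

    relabeled = np.zeros_like(labels)
    records = []
    for new_label, p in enumerate(kept, start=1):
        relabeled[labels == p.label] = new_label
        r, c = p.centroid_weighted if p.intensity_max > 0 else p.centroid
        records.append({
            "label": new_label,
            "row": float(r),
            "col": float(c),
            "area": float(p.area),
            "perimeter": float(p.perimeter),
            "circularity": circularity(p.area, p.perimeter),
        })
    table = pd.DataFrame.from_records(records, columns=TABLE_COLUMNS)
    mask = LabeledMask(labels=relabeled, detection_channel=detection_channel,
                       params=params)
    return mask, table
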