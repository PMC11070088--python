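"""2D spheroid adhesion/migration assay: spread area at 24 h normalized to
the spheroid area at 0 h.

The segmentation is a deterministic automatic pipeline (global Otsu
threshold, largest connected component, optional hole filling) defined on
any frame where the spheroid plus its migration halo is the dominant
intensity object. The normalized metric includes the original spheroid
body, so identical frames score exactly 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label


class SegmentationError(ValueError):
    """Segmentation produced no foreground object."""


@dataclass
class MigrationMeasurement:
    """Areas (px) at 0 h and 24 h and their ratio."""

    area_0h_px: int
    area_24h_px: int
    pixel_size_um: float
    normalized_migration: float
    method: dict


def segment_spread_area(
    frame: np.ndarray,
    threshold_method: str = "otsu",
    min_object_px: int = 16,
    fill_holes: bool = True,
) -> int:
    """Segment the spheroid + halo and return its area in pixels."""
    frame = np.asarray(frame, dtype=float)
    if frame.size == 0:
        raise SegmentationError("empty frame")
    if threshold_method == "otsu":
        if np.ptp(frame) == 0:
            raise SegmentationError("flat frame: no foreground to segment")
        thr = float(threshold_otsu(frame))
    else:
        thr = float(threshold_method)
    mask = frame > thr
    if not mask.any():
        raise SegmentationError("empty foreground after thresholding")
    labels = cc_label(mask)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    biggest = int(sizes.argmax())
    obj = labels == biggest
    if obj.sum() < min_object_px:
        raise SegmentationError(
            f"largest object has {int(obj.sum())} px < min_object_px"
        )
    if fill_holes:
        obj = ndimage.binary_fill_holes(obj)
    return int(obj.sum())


def migration_metric(
    frame_0h: np.ndarray,
    frame_24h: np.ndarray,
    pixel_size_um: float = 1.0,
    threshold_method: str = "otsu",
    min_object_px: int = 16,
    fill_holes: bool = True,
) -> MigrationMeasurement:
    """Spread area at 24 h / spheroid area at 0 h."""
    if np.shape(frame_0h) != np.shape(frame_24h):
        raise ValueError("frames must share shape and pixel size")
    areas = {}
    for name, frame in (("0h", frame_0h), ("24h", frame_24h)):
        try:
            areas[name] = segment_spread_area(
                frame, threshold_method, min_object_px, fill_holes
            )
        except SegmentationError as exc:
            raise SegmentationError(f"{name} frame: {exc}") from exc
    return MigrationMeasurement(
        area_0h_px=areas["0h"],
        area_24h_px=areas["24h"],
        pixel_size_um=pixel_size_um,
        normalized_migration=areas["24h"] / areas["0h"],
        method={
            "threshold_method": threshold_method,
            "min_object_px": min_object_px,
            "fill_holes": fill_holes,
        },
    )
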