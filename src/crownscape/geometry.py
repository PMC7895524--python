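"""Axis-aligned box arithmetic: areas, intersection-over-union, clipping.

Boxes are ``(xmin, ymin, xmax, ymax)`` sequences or the four columns of a
crown table. Everything here is exact float arithmetic on rectangles; no
general polygon machinery is needed for bounding-box crowns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .types import Extent


def box_area(xmin, ymin, xmax, ymax):
    """Width x height of one or many boxes; raises on degenerate boxes."""
    xmin, ymin = np.asarray(xmin, float), np.asarray(ymin, float)
    xmax, ymax = np.asarray(xmax, float), np.asarray(ymax, float)
    if np.any(xmax <= xmin) or np.any(ymax <= ymin):
        raise ValueError("degenerate box: xmax <= xmin or ymax <= ymin")
    return (xmax - xmin) * (ymax - ymin)


def iou(a, b) -> float:
    """Intersection area over union area of two boxes; 0 when disjoint."""
    axmin, aymin, axmax, aymax = map(float, a)
    bxmin, bymin, bxmax, bymax = map(float, b)
    area_a = box_area(axmin, aymin, axmax, aymax)
    area_b = box_area(bxmin, bymin, bxmax, bymax)
    iw = min(axmax, bxmax) - max(axmin, bxmin)
    ih = min(aymax, bymax) - max(aymin, bymin)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def iou_matrix(a: pd.DataFrame | np.ndarray, b: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise IoU between two box sets, shape ``(len(a), len(b))``.

    Accepts crown tables (uses the xmin/ymin/xmax/ymax columns) or
    ``(n, 4)`` arrays.
    """
    A = _as_box_array(a)
    B = _as_box_array(b)
    if A.shape[0] == 0 or B.shape[0] == 0:
        return np.zeros((A.shape[0], B.shape[0]))
    area_a = box_area(A[:, 0], A[:, 1], A[:, 2], A[:, 3])[:, None]
    area_b = box_area(B[:, 0], B[:, 1], B[:, 2], B[:, 3])[None, :]
    iw = np.minimum(A[:, 2, None], B[None, :, 2]) - np.maximum(A[:, 0, None], B[None, :, 0])
    ih = np.minimum(A[:, 3, None], B[None, :, 3]) - np.maximum(A[:, 1, None], B[None, :, 1])
    inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
    return inter / (area_a + area_b - inter)


def clip_box(xmin, ymin, xmax, ymax, extent: Extent):
    """Clip a box to an extent. Returns None if nothing remains."""
    xmin, ymin = max(xmin, extent.xmin), max(ymin, extent.ymin)
    xmax, ymax = min(xmax, extent.xmax), min(ymax, extent.ymax)
    if xmax <= xmin or ymax <= ymin:
        return None
    return xmin, ymin, xmax, ymax


def centroids(crowns: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Box centroids of a crown table."""
    cx = (crowns["xmin"].to_numpy(float) + crowns["xmax"].to_numpy(float)) / 2.0
    cy = (crowns["ymin"].to_numpy(float) + crowns["ymax"].to_numpy(float)) / 2.0
    return cx, cy


def boundary_gap(a, b) -> float:
    """Smallest separation between two boxes' boundaries (0 if they touch
    or overlap)."""
    axmin, aymin, axmax, aymax = map(float, a)
    bxmin, bymin, bxmax, bymax = map(float, b)
    dx = max(max(axmin, bxmin) - min(axmax, bxmax), 0.0)
    dy = max(max(aymin, bymin) - min(aymax, bymax), 0.0)
    return float(np.hypot(dx, dy))


def _as_box_array(x) -> np.ndarray:
    if isinstance(x, pd.DataFrame):
        return x[["xmin", "ymin", "xmax", "ymax"]].to_numpy(dtype=float)
    arr = np.asarray(x, dtype=float)
    if arr.ndim == 1:
        arr = arr.reshape(1, 4)
    return arr
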