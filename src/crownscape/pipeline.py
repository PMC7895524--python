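"""Post-detection crown workflow: score filter, LiDAR height attribution,
the 3 m canopy-height filter, and crown-area computation.

The stages mirror how operational crown datasets are assembled from raw
detector output: low-confidence boxes are dropped (score >= 0.15 kept),
each surviving box is assigned the 99th quantile of the LiDAR return
heights inside it as its tree height, boxes shorter than 3 m — shrubs,
ground clutter, low vegetation the detector mistook for trees — are
removed, and the bounding-box area is recorded as a crown-area proxy.

Both thresholds are boundary-inclusive on the keep side (score >= 0.15,
height >= 3 m): records *below* the floor are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import box_area
from .types import ChmRaster, LidarPoints, validate_crown_table

DEFAULT_MIN_SCORE = 0.15
DEFAULT_MIN_HEIGHT_M = 3.0
DEFAULT_HEIGHT_QUANTILE = 0.99


def filter_by_score(crowns: pd.DataFrame, min_score: float = DEFAULT_MIN_SCORE) -> pd.DataFrame:
    """Retain boxes with confidence score >= ``min_score``, order preserved."""
    return crowns[crowns["score"] >= min_score].copy()


def attribute_height(
    crowns: pd.DataFrame | tuple,
    points: LidarPoints,
    quantile: float = DEFAULT_HEIGHT_QUANTILE,
) -> pd.Series | float:
    """Per-box tree height: a quantile of in-box LiDAR return heights.

    For each box, takes the ``quantile`` (linear interpolation between
    order statistics) of ``z_agl`` over returns with
    ``xmin <= x <= xmax and ymin <= y <= ymax`` — boundary-inclusive on all
    four edges. Boxes containing no returns get NaN (the absence flag);
    downstream they are dropped and reported, never silently kept.

    Accepts a crown table (returns a Series aligned to its index) or a
    single ``(xmin, ymin, xmax, ymax)`` box (returns a float).
    """
    if not 0 < quantile <= 1:
        raise ValueError("quantile must be in (0, 1]")
    single = not isinstance(crowns, pd.DataFrame)
    if single:
        xmin, ymin, xmax, ymax = map(float, crowns)
        boxes = pd.DataFrame({"xmin": [xmin], "ymin": [ymin], "xmax": [xmax], "ymax": [ymax]})
    else:
        boxes = crowns

    heights = np.full(len(boxes), np.nan)
    if len(points) and len(boxes):
        order = np.argsort(points.x, kind="stable")
        xs = points.x[order]
        ys = points.y[order]
        zs = points.z_agl[order]
        lo = np.searchsorted(xs, boxes["xmin"].to_numpy(), side="left")
        hi = np.searchsorted(xs, boxes["xmax"].to_numpy(), side="right")
        ymin_arr = boxes["ymin"].to_numpy()
        ymax_arr = boxes["ymax"].to_numpy()
        for i in range(len(boxes)):
            sel = slice(lo[i], hi[i])
            inside = (ys[sel] >= ymin_arr[i]) & (ys[sel] <= ymax_arr[i])
            z = zs[sel][inside]
            if z.size:
                heights[i] = np.quantile(z, quantile, method="linear")
    if single:
        return float(heights[0])
    return pd.Series(heights, index=boxes.index, name="height_m")


@dataclass
class HeightFilterReport:
    n_in: int = 0
    n_kept: int = 0
    n_below_threshold: int = 0
    n_no_height: int = 0


def filter_by_height(
    crowns: pd.DataFrame,
    threshold_m: float = DEFAULT_MIN_HEIGHT_M,
) -> tuple[pd.DataFrame, HeightFilterReport]:
    """Retain boxes with attributed height >= ``threshold_m``.

    Boxes whose height is absent (no LiDAR coverage) are dropped and
    counted separately in the report — they model the recall loss a sparse
    point cloud imposes on a height-based filter.
    """
    h = crowns["height_m"]
    no_height = h.isna()
    kept = crowns[~no_height & (h >= threshold_m)].copy()
    report = HeightFilterReport(
        n_in=len(crowns),
        n_kept=len(kept),
        n_below_threshold=int((~no_height & (h < threshold_m)).sum()),
        n_no_height=int(no_height.sum()),
    )
    return kept, report


def compute_area(box) -> float | pd.Series:
    """Bounding-box area, width x height — the dataset's crown-area proxy."""
    if isinstance(box, pd.DataFrame):
        return pd.Series(
            box_area(box["xmin"], box["ymin"], box["xmax"], box["ymax"]),
            index=box.index,
            name="area_m2",
        )
    xmin, ymin, xmax, ymax = map(float, box)
    return float(box_area(xmin, ymin, xmax, ymax))


@dataclass
class PipelineConfig:
    min_score: float = DEFAULT_MIN_SCORE
    min_height_m: float = DEFAULT_MIN_HEIGHT_M
    quantile: float = DEFAULT_HEIGHT_QUANTILE


@dataclass
class PipelineReport:
    """Stage-by-stage record counts of one pipeline run."""

    n_input: int = 0
    n_after_score: int = 0
    n_no_height: int = 0
    n_below_height: int = 0
    n_released: int = 0
    height_source: str = ""
    log: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_after_score": self.n_after_score,
            "n_no_height": self.n_no_height,
            "n_below_height": self.n_below_height,
            "n_released": self.n_released,
            "height_source": self.height_source,
        }


def run_pipeline(
    crowns: pd.DataFrame,
    points: LidarPoints | None = None,
    chm: ChmRaster | None = None,
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, PipelineReport]:
    """Score filter -> height attribution -> height filter -> area.

    Heights come from the point quantile when ``points`` is supplied;
    with only a ``chm``, each box gets the maximum valid CHM value among
    cells whose center falls inside it. All inputs must share one planar
    metric coordinate frame; a spatially disjoint frame (no box sees any
    return and none sits on the CHM) raises, since that is the observable
    symptom of mismatched coordinate systems.
    """
    config = config or PipelineConfig()
    if points is None and chm is None:
        raise ValueError("run_pipeline needs LiDAR points and/or a CHM")
    validate_crown_table(crowns)
    report = PipelineReport(n_input=len(crowns))

    kept = filter_by_score(crowns, config.min_score)
    report.n_after_score = len(kept)
    report.log.append(f"score filter (>= {config.min_score}): {len(crowns)} -> {len(kept)}")

    if points is not None:
        heights = attribute_height(kept, points, config.quantile)
        report.height_source = f"point quantile {config.quantile}"
    else:
        heights = pd.Series(
            [chm.max_in_box(b.xmin, b.ymin, b.xmax, b.ymax) for b in kept.itertuples(index=False)],
            index=kept.index,
            dtype=float,
        )
        report.height_source = "CHM cell maximum"
    has_height_data = (points is not None and len(points) > 0) or (
        chm is not None and np.isfinite(chm.values).any()
    )
    if len(kept) and has_height_data and heights.isna().all():
        raise ValueError(
            "no crown box contains any LiDAR return / CHM cell: "
            "inputs appear to be in different coordinate frames or units"
        )
    kept = kept.assign(height_m=heights)

    released, hrep = filter_by_height(kept, config.min_height_m)
    report.n_no_height = hrep.n_no_height
    report.n_below_height = hrep.n_below_threshold
    report.log.append(
        f"height filter (>= {config.min_height_m} m): {hrep.n_in} -> {hrep.n_kept} "
        f"({hrep.n_below_threshold} below, {hrep.n_no_height} without coverage)"
    )

    released = released.assign(area_m2=compute_area(released))
    report.n_released = len(released)
    validate_crown_table(released)
    return released.reset_index(drop=True), report
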