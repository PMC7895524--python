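"""Core containers for synthetic forest scenes, crown tables, and rasters.

Conventions used throughout the package:

* coordinates are planar map units in meters, y increasing northwards;
* boxes are axis-aligned ``(xmin, ymin, xmax, ymax)`` tuples or table columns;
* rasters are row-major grids whose origin is the upper-left corner, with
  half-open cells: cell ``(row, col)`` covers ``x in [xmin + col*res,
  xmin + (col+1)*res)`` and ``y in (ymax - (row+1)*res, ymax - row*res]``;
* crown tables are :class:`pandas.DataFrame` objects with the release
  schema columns :data:`CROWN_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, NamedTuple

import numpy as np
import pandas as pd

#: Column order of the released crown table (also the on-disk CSV order).
CROWN_COLUMNS = [
    "crown_id",
    "site",
    "year",
    "xmin",
    "ymin",
    "xmax",
    "ymax",
    "score",
    "height_m",
    "area_m2",
]

#: Columns of a field-stem table (internal names; see io.STEM_COLUMN_MAP
#: for the NEON-style aliases).
STEM_COLUMNS = [
    "stem_id",
    "x",
    "y",
    "dbh_cm",
    "height_m",
    "status",
    "plot_id",
    "site",
    "year",
]

#: Columns of the ground-truth tree table inside a SceneTruth.
TREE_COLUMNS = [
    "tree_id",
    "x",
    "y",
    "height_m",
    "crown_radius_m",
    "canopy_position",
    "status",
]


class Extent(NamedTuple):
    """A rectangular map region ``[xmin, xmax] x [ymin, ymax]`` in meters."""

    xmin: float
    ymin: float
    xmax: float
    ymax: float

    @property
    def width(self) -> float:
        return self.xmax - self.xmin

    @property
    def height(self) -> float:
        return self.ymax - self.ymin

    @property
    def area_m2(self) -> float:
        return self.width * self.height

    @property
    def area_ha(self) -> float:
        return self.area_m2 / 1e4

    def contains(self, x, y):
        """Boundary-inclusive point-in-extent test (vectorised)."""
        return (
            (np.asarray(x) >= self.xmin)
            & (np.asarray(x) <= self.xmax)
            & (np.asarray(y) >= self.ymin)
            & (np.asarray(y) <= self.ymax)
        )

    def validate(self) -> "Extent":
        if not (self.xmax > self.xmin and self.ymax > self.ymin):
            raise ValueError(f"empty extent: {self}")
        return self


@dataclass
class LidarPoints:
    """Height-normalized LiDAR returns: x, y (m) and height above ground."""

    x: np.ndarray
    y: np.ndarray
    z_agl: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.z_agl = np.asarray(self.z_agl, dtype=float)
        if not (self.x.shape == self.y.shape == self.z_agl.shape):
            raise ValueError("x, y, z_agl must have identical shapes")
        if self.z_agl.size and np.nanmin(self.z_agl) < 0:
            raise ValueError("z_agl must be >= 0 after ground normalization")

    def __len__(self) -> int:
        return self.x.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"x": self.x, "y": self.y, "z_agl": self.z_agl})


@dataclass
class Raster:
    """A single-band grid with upper-left origin and half-open square cells.

    ``values`` is indexed ``[row, col]`` with row 0 at the top (largest y).
    No-data cells hold NaN in memory regardless of the on-disk tag.
    """

    xmin: float
    ymax: float
    resolution_m: float
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.resolution_m <= 0:
            raise ValueError("resolution_m must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> Extent:
        return Extent(
            self.xmin,
            self.ymax - self.nrows * self.resolution_m,
            self.xmin + self.ncols * self.resolution_m,
            self.ymax,
        )

    def cell_index(self, x, y):
        """Map coordinates to (row, col); points on the top/left closed edges
        fall in the first row/column they bound."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.xmin) / self.resolution_m).astype(int)
        row = np.ceil((self.ymax - y) / self.resolution_m).astype(int) - 1
        row = np.where(np.asarray(y) == self.ymax, 0, row)
        return row, col

    def in_grid(self, row, col):
        return (row >= 0) & (row < self.nrows) & (col >= 0) & (col < self.ncols)

    def cell_centers(self):
        """(x, y) arrays of all cell centers, same shape as ``values``."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        cx = self.xmin + (cols + 0.5) * self.resolution_m
        cy = self.ymax - (rows + 0.5) * self.resolution_m
        return np.meshgrid(cx, cy)

    def max_in_radius(self, x: float, y: float, radius_m: float) -> float:
        """Max valid value among cells whose center lies within ``radius_m``
        of (x, y); NaN if none."""
        cx, cy = self.cell_centers()
        sel = (cx - x) ** 2 + (cy - y) ** 2 <= radius_m**2
        vals = self.values[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")

    def max_in_box(self, xmin: float, ymin: float, xmax: float, ymax: float) -> float:
        """Max valid value among cells whose center lies in the closed box;
        NaN if none."""
        cx, cy = self.cell_centers()
        sel = (cx >= xmin) & (cx <= xmax) & (cy >= ymin) & (cy <= ymax)
        vals = self.values[sel]
        vals = vals[np.isfinite(vals)]
        return float(vals.max()) if vals.size else float("nan")


# A CHM and a crown-density raster share the grid container; the aliases
# keep call sites readable.
ChmRaster = Raster
DensityRaster = Raster


@dataclass
class SceneTruth:
    """Ground truth for one synthetic forest scene.

    ``trees`` has columns :data:`TREE_COLUMNS`; ``params`` records every
    generating parameter so that the scene can be regenerated bit-exactly
    from ``(params, seed)``.
    """

    extent: Extent
    trees: pd.DataFrame
    seed: int
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in TREE_COLUMNS if c not in self.trees.columns]
        if missing:
            raise ValueError(f"trees table missing columns: {missing}")
        if len(self.trees):
            if (self.trees["height_m"] <= 0).any():
                raise ValueError("tree heights must be > 0")
            if (self.trees["crown_radius_m"] <= 0).any():
                raise ValueError("crown radii must be > 0")
            inside = self.extent.contains(self.trees["x"], self.trees["y"])
            if not inside.all():
                raise ValueError("all trees must lie inside the extent")

    @property
    def site(self) -> str:
        return self.params.get("site", "SYNT")

    @property
    def year(self) -> int:
        return int(self.params.get("year", 2019))

    def overstory(self) -> pd.DataFrame:
        return self.trees[self.trees["canopy_position"] == "overstory"]


@dataclass
class DetectorErrorModel:
    """Error model of a simulated crown detector.

    The model mimics the documented behaviour of CNN crown detectors on
    airborne RGB imagery: missed crowns, undersegmentation (two adjacent
    crowns emitted as one box), box-edge jitter, spurious boxes, and a
    confidence score whose distribution differs between real and spurious
    detections (Beta laws truncated below at ``score_floor``).
    """

    miss_prob: float = 0.2
    merge_prob: float = 0.1
    false_pos_rate_per_ha: float = 20.0
    jitter_sd_m: float = 0.5
    merge_gap_m: float = 1.0
    true_score_ab: tuple[float, float] = (6.0, 2.0)
    false_score_ab: tuple[float, float] = (2.0, 4.0)
    score_floor: float = 0.05

    def __post_init__(self) -> None:
        for name in ("miss_prob", "merge_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        for name in ("false_pos_rate_per_ha", "jitter_sd_m", "merge_gap_m"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if not 0.0 <= self.score_floor <= 1.0:
            raise ValueError("score_floor must be in [0, 1]")

    @classmethod
    def perfect(cls) -> "DetectorErrorModel":
        """An all-zero error model: output boxes equal truth, scores only."""
        return cls(miss_prob=0.0, merge_prob=0.0, false_pos_rate_per_ha=0.0, jitter_sd_m=0.0)


@dataclass
class MatchResult:
    """One-to-one assignment between predicted and reference crowns.

    ``pairs`` has columns ``pred_id``, ``ref_id``, ``iou``; every pair's IoU
    strictly exceeds ``iou_threshold`` and no id appears in two pairs.
    """

    pairs: pd.DataFrame
    unmatched_predictions: list
    unmatched_references: list
    iou_threshold: float

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)


def empty_crown_table() -> pd.DataFrame:
    """A zero-row crown table with the release schema and dtypes."""
    df = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        CROWN_COLUMNS,
        [str, str, int, float, float, float, float, float, float, float],
    )})
    return df[CROWN_COLUMNS]


def validate_crown_table(crowns: pd.DataFrame, release: bool = False) -> None:
    """Raise ValueError on schema violations.

    With ``release=True`` additionally enforces the release invariants
    (score >= 0.15, height >= 3 m, stored area exactly width*height).
    """
    missing = [c for c in CROWN_COLUMNS if c not in crowns.columns]
    if missing:
        raise ValueError(f"crown table missing columns: {missing}")
    if not len(crowns):
        return
    if not ((crowns["xmax"] > crowns["xmin"]) & (crowns["ymax"] > crowns["ymin"])).all():
        raise ValueError("degenerate boxes: xmax <= xmin or ymax <= ymin")
    score = crowns["score"].to_numpy(dtype=float)
    ok = np.isnan(score) | ((score >= 0) & (score <= 1))
    if not ok.all():
        raise ValueError("scores must lie in [0, 1]")
    if release:
        if crowns["score"].isna().any() or (crowns["score"] < 0.15).any():
            raise ValueError("release records must have score >= 0.15")
        if crowns["height_m"].isna().any() or (crowns["height_m"] < 3.0).any():
            raise ValueError("release records must have height_m >= 3")
        w = crowns["xmax"].to_numpy() - crowns["xmin"].to_numpy()
        h = crowns["ymax"].to_numpy() - crowns["ymin"].to_numpy()
        if not np.array_equal(crowns["area_m2"].to_numpy(), w * h):
            raise ValueError("area_m2 must equal (xmax-xmin)*(ymax-ymin) exactly")
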