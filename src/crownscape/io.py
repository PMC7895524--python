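"""Readers and writers for the interchange formats, and the release
validator.

Supported formats are the plain-text dialects of the geospatial stack:

* crowns — CSV (fixed column order) and GeoJSON (boxes as Polygon rings);
* field stems — CSV, with a configurable column-name map covering the
  NEON-style vegetation-structure headers;
* LiDAR points — XYZ CSV (``x,y,z_agl``);
* rasters (CHM, density, masks) — ESRI ASCII grid (``.asc``).

All writers emit byte-stable output for identical records: fixed column
order and fixed float formatting (3 decimals for coordinates, heights and
areas; 4 for confidence scores).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import CROWN_COLUMNS, STEM_COLUMNS, LidarPoints, Raster

COORD_DECIMALS = 3
SCORE_DECIMALS = 4
ASC_NODATA = -9999.0

#: Default mapping from NEON-style vegetation-structure column names to
#: the internal stem schema. Override entries via the ``column_map``
#: argument of :func:`read_stems`.
STEM_COLUMN_MAP = {
    "individualID": "stem_id",
    "itcEasting": "x",
    "itcNorthing": "y",
    "stemDiameter": "dbh_cm",
    "height": "height_m",
    "plantStatus": "status",
    "plotID": "plot_id",
    "siteID": "site",
    "eventID": "year",
}


def _detect_format(path: Path, fmt: str) -> str:
    if fmt != "auto":
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".csv":
        return "csv"
    if suffix in (".geojson", ".json"):
        return "geojson"
    raise ValueError(f"cannot infer crown format from suffix {suffix!r}")


def _row_error(row: dict) -> str | None:
    """Release-independent row validity; returns a reason or None."""
    try:
        xmin, ymin = float(row["xmin"]), float(row["ymin"])
        xmax, ymax = float(row["xmax"]), float(row["ymax"])
        score = float(row["score"])
    except (TypeError, ValueError, KeyError) as exc:
        return f"unparseable numeric field: {exc}"
    if not (xmax > xmin and ymax > ymin):
        return "degenerate box"
    if not (np.isnan(score) or 0.0 <= score <= 1.0):
        return "score outside [0, 1]"
    return None


def write_crowns(crowns: pd.DataFrame, path, fmt: str = "auto") -> None:
    """Write a crown table as CSV or GeoJSON (byte-stable)."""
    path = Path(path)
    fmt = _detect_format(path, fmt)
    df = crowns[CROWN_COLUMNS].copy()
    if fmt == "csv":
        for c in ("xmin", "ymin", "xmax", "ymax", "height_m", "area_m2"):
            df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.{COORD_DECIMALS}f}")
        df["score"] = df["score"].map(lambda v: "" if pd.isna(v) else f"{v:.{SCORE_DECIMALS}f}")
        df.to_csv(path, index=False, lineterminator="\n")
    elif fmt == "geojson":
        features = []
        for r in df.itertuples(index=False):
            xmin, ymin = round(r.xmin, COORD_DECIMALS), round(r.ymin, COORD_DECIMALS)
            xmax, ymax = round(r.xmax, COORD_DECIMALS), round(r.ymax, COORD_DECIMALS)
            features.append(
                {
                    "type": "Feature",
                    "geometry": {
                        "type": "Polygon",
                        "coordinates": [
                            [[xmin, ymin], [xmax, ymin], [xmax, ymax], [xmin, ymax], [xmin, ymin]]
                        ],
                    },
                    "properties": {
                        "crown_id": r.crown_id,
                        "site": r.site,
                        "year": int(r.year),
                        "score": None if pd.isna(r.score) else round(r.score, SCORE_DECIMALS),
                        "height_m": None if pd.isna(r.height_m) else round(r.height_m, COORD_DECIMALS),
                        "area_m2": None if pd.isna(r.area_m2) else round(r.area_m2, COORD_DECIMALS),
                    },
                }
            )
        doc = {"type": "FeatureCollection", "features": features}
        Path(path).write_text(json.dumps(doc, indent=1) + "\n")
    else:
        raise ValueError(f"unsupported crown format: {fmt!r}")


def read_crowns(path, fmt: str = "auto") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a crown table; returns ``(crowns, rejected)``.

    Malformed rows (degenerate boxes, out-of-range scores, unparseable
    numbers) are collected into the ``rejected`` table with a ``reason``
    column rather than silently dropped or fatally raised.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    if fmt == "csv":
        raw = pd.read_csv(path, dtype={"crown_id": str, "site": str})
        missing = [c for c in CROWN_COLUMNS if c not in raw.columns]
        if missing:
            raise ValueError(f"crown CSV missing required columns: {missing}")
        records = raw.to_dict("records")
    elif fmt == "geojson":
        doc = json.loads(Path(path).read_text())
        records = []
        for feat in doc.get("features", []):
            ring = feat["geometry"]["coordinates"][0]
            xs = [p[0] for p in ring]
            ys = [p[1] for p in ring]
            rec = dict(feat["properties"])
            rec.update(xmin=min(xs), ymin=min(ys), xmax=max(xs), ymax=max(ys))
            records.append(rec)
    else:
        raise ValueError(f"unsupported crown format: {fmt!r}")

    good, bad = [], []
    for rec in records:
        reason = _row_error(rec)
        if reason is None:
            good.append(rec)
        else:
            bad.append({**rec, "reason": reason})
    crowns = pd.DataFrame(good, columns=CROWN_COLUMNS)
    if len(crowns):
        crowns = crowns.astype(
            {c: float for c in ("xmin", "ymin", "xmax", "ymax", "score", "height_m", "area_m2")}
        ).astype({"year": int})
    rejected = pd.DataFrame(bad, columns=CROWN_COLUMNS + ["reason"])
    return crowns, rejected


def write_stems(stems: pd.DataFrame, path) -> None:
    df = stems[STEM_COLUMNS].copy()
    for c in ("x", "y", "height_m"):
        df[c] = df[c].map(lambda v: "" if pd.isna(v) else f"{v:.{COORD_DECIMALS}f}")
    df["dbh_cm"] = df["dbh_cm"].map(lambda v: "" if pd.isna(v) else f"{v:.{COORD_DECIMALS}f}")
    df.to_csv(path, index=False, lineterminator="\n")


def read_stems(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a field-stem CSV, renaming NEON-style columns to the internal
    schema via ``column_map`` (merged over :data:`STEM_COLUMN_MAP`)."""
    mapping = {**STEM_COLUMN_MAP, **(column_map or {})}
    raw = pd.read_csv(path)
    raw = raw.rename(columns={k: v for k, v in mapping.items() if k in raw.columns})
    missing = [c for c in ("stem_id", "plot_id") if c not in raw.columns]
    if missing:
        raise ValueError(f"stem table missing required columns: {missing}")
    for c in STEM_COLUMNS:
        if c not in raw.columns:
            raw[c] = np.nan
    return raw[STEM_COLUMNS]


def write_points_xyz(points: LidarPoints, path) -> None:
    df = pd.DataFrame(
        {
            "x": [f"{v:.{COORD_DECIMALS}f}" for v in points.x],
            "y": [f"{v:.{COORD_DECIMALS}f}" for v in points.y],
            "z_agl": [f"{v:.{COORD_DECIMALS}f}" for v in points.z_agl],
        }
    )
    df.to_csv(path, index=False, lineterminator="\n")


def read_points_xyz(path) -> LidarPoints:
    df = pd.read_csv(path)
    return LidarPoints(df["x"].to_numpy(), df["y"].to_numpy(), df["z_agl"].to_numpy())


def write_raster_asc(raster: Raster, path) -> None:
    """Write a grid as an ESRI ASCII raster (NaN becomes the no-data tag)."""
    lines = [
        f"ncols {raster.ncols}",
        f"nrows {raster.nrows}",
        f"xllcorner {raster.xmin:.{COORD_DECIMALS}f}",
        f"yllcorner {raster.extent.ymin:.{COORD_DECIMALS}f}",
        f"cellsize {raster.resolution_m:.{COORD_DECIMALS}f}",
        f"NODATA_value {ASC_NODATA:g}",
    ]
    vals = np.where(np.isfinite(raster.values), raster.values, ASC_NODATA)
    for row in vals:
        lines.append(" ".join(f"{v:.{COORD_DECIMALS}f}" for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_raster_asc(path) -> Raster:
    text = Path(path).read_text().strip().splitlines()
    header = {}
    for line in text[:6]:
        key, val = line.split()
        header[key.lower()] = float(val)
    nrows = int(header["nrows"])
    values = np.array([[float(v) for v in line.split()] for line in text[6:]])
    if values.shape != (nrows, int(header["ncols"])):
        raise ValueError("ASCII raster data does not match its header")
    nodata = header.get("nodata_value", ASC_NODATA)
    values = np.where(values == nodata, np.nan, values)
    res = header["cellsize"]
    return Raster(header["xllcorner"], header["yllcorner"] + nrows * res, res, values)


# ---------------------------------------------------------------------------
# release validation
# ---------------------------------------------------------------------------

RELEASE_RULES = (
    "degenerate_box",
    "score_out_of_range",
    "score_below_floor",
    "height_missing",
    "height_below_minimum",
    "area_mismatch",
)


def validate_release(
    crowns: pd.DataFrame | str | Path,
    min_score: float = 0.15,
    min_height_m: float = 3.0,
) -> dict:
    """Check every release invariant; violations are report content.

    Rules: box validity, score in range and >= the release floor, height
    present and >= the tree threshold, and stored area equal to the
    recomputed width x height. The area check is exact for in-memory
    tables; for records read back from disk it allows the error the
    documented 3-decimal coordinate formatting can introduce
    (``(w + h + 1) * 5e-4`` per box).
    """
    area_atol = 0.0
    if not isinstance(crowns, pd.DataFrame):
        crowns, _ = read_crowns(crowns)
        area_atol = 5.0 * 10.0**-COORD_DECIMALS
    report = {rule: 0 for rule in RELEASE_RULES}
    for r in crowns.itertuples(index=False):
        if not (r.xmax > r.xmin and r.ymax > r.ymin):
            report["degenerate_box"] += 1
            continue
        if pd.isna(r.score) or not 0 <= r.score <= 1:
            report["score_out_of_range"] += 1
        elif r.score < min_score:
            report["score_below_floor"] += 1
        if pd.isna(r.height_m):
            report["height_missing"] += 1
        elif r.height_m < min_height_m:
            report["height_below_minimum"] += 1
        w, h = r.xmax - r.xmin, r.ymax - r.ymin
        tol = area_atol * (w + h + 1.0)
        if pd.isna(r.area_m2) or abs(r.area_m2 - w * h) > tol:
            report["area_mismatch"] += 1
    report["n_records"] = len(crowns)
    report["n_violations"] = sum(report[rule] for rule in RELEASE_RULES)
    return report


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    min_score: float = 0.15
    min_height_m: float = 3.0
    iou_threshold: float = 0.5
    quantile: float = 0.99
    seed: int = 0
    scene: dict = field(default_factory=dict)
    detector: dict = field(default_factory=dict)
    survey: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)
    output_dir: str = "results"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if not 0 <= self.min_score <= 1:
            raise ValueError("min_score must be in [0, 1]")
        if not 0 < self.quantile <= 1:
            raise ValueError("quantile must be in (0, 1]")
        if not 0 <= self.iou_threshold < 1:
            raise ValueError("iou_threshold must be in [0, 1)")
        if self.min_height_m < 0:
            raise ValueError("min_height_m must be >= 0")
        self.seed = int(self.seed)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
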