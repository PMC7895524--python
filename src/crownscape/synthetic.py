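"""Synthetic forest scenes: stem maps, crowns, sparse LiDAR, an imperfect
detector, and imperfect field surveys.

The generator reproduces the statistical structure an airborne crown-mapping
workflow has to cope with, so that every downstream stage (score filter,
height attribution, 3 m filter, crown/stem evaluation, landscape summaries)
can be exercised without any remote-sensing download:

* stems from a homogeneous Poisson or Thomas cluster process;
* tree heights from a lognormal law and crown radii from a power-law
  allometry ``r = a * h**b`` with lognormal noise;
* an overstory/understory label: a tree is understory iff its stem lies in
  the crown disk of a tree taller by more than ``overtop_margin_m``;
* sparse LiDAR (default 6 pts/m^2, typical of operational surveys) sampling
  a crown surface model, rasterised to a canopy height model by cell-max;
* detector output with misses, undersegmentation merges, edge jitter,
  uniform false positives and Beta-distributed confidence scores;
* field surveys with geolocation error, height measurement error and a
  growth lag between field campaign and overflight.

Every function is deterministic given its ``seed``: each draws from a
single ``numpy.random.default_rng(seed)`` stream in a fixed, documented
order, so seeds are portable across runs and platforms.
"""

from __future__ import annotations

from typing import Any

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import boundary_gap, box_area, clip_box
from .types import (
    CROWN_COLUMNS,
    STEM_COLUMNS,
    TREE_COLUMNS,
    DetectorErrorModel,
    Extent,
    LidarPoints,
    Raster,
    SceneTruth,
    empty_crown_table,
)

DEFAULT_HEIGHT_DISTRIBUTION = {"kind": "lognormal", "median_m": 12.0, "sigma_log": 0.45}
#: Crown-radius allometry r = a * h**b * exp(N(0, sd_log)).
DEFAULT_ALLOMETRY = {"a": 0.5, "b": 0.6, "sd_log": 0.15}
#: DBH allometry dbh_cm = a * h**b * exp(N(0, sd_log)).
DEFAULT_DBH_MODEL = {"a": 1.0, "b": 1.15, "sd_log": 0.1}

MIN_TREE_HEIGHT_M = 0.5
MIN_CROWN_RADIUS_M = 0.25
#: Crown base height as a fraction of total tree height.
CROWN_BASE_FRACTION = 0.6


# ---------------------------------------------------------------------------
# stem maps
# ---------------------------------------------------------------------------

def generate_stem_map(
    extent: Extent | tuple,
    stem_density: float,
    clustering: dict[str, float] | None = None,
    height_distribution: dict[str, Any] | None = None,
    allometry: dict[str, float] | None = None,
    overtop_margin_m: float = 2.0,
    dead_fraction: float = 0.03,
    site: str = "SYNT",
    year: int = 2019,
    seed: int = 0,
) -> SceneTruth:
    """Generate a ground-truth stem map.

    Parameters
    ----------
    extent
        Scene rectangle in meters.
    stem_density
        Expected stems per m^2 (>= 0).
    clustering
        ``None`` for a homogeneous Poisson process, or Thomas-process
        parameters ``{"parent_density": per m^2, "cluster_sd_m": float}``;
        the mean offspring per parent is ``stem_density / parent_density``
        so the overall intensity stays ``stem_density``.
    height_distribution
        ``{"kind": "lognormal", "median_m", "sigma_log"}`` or
        ``{"kind": "uniform", "low_m", "high_m"}``.
    allometry
        ``{"a", "b", "sd_log"}`` of the crown-radius law ``r = a*h**b``.
    overtop_margin_m
        Height deficit beyond which an overtopped stem is understory.
    dead_fraction
        Probability a tree is standing dead.

    RNG order: stem positions (+ cluster assignment), heights, crown-radius
    noise, status draws.
    """
    extent = Extent(*extent).validate()
    if stem_density < 0:
        raise ValueError("stem_density must be >= 0")
    height_distribution = dict(height_distribution or DEFAULT_HEIGHT_DISTRIBUTION)
    allometry = dict(allometry or DEFAULT_ALLOMETRY)
    if allometry["a"] <= 0:
        raise ValueError("allometry coefficient a must be > 0")
    if not 0 <= dead_fraction <= 1:
        raise ValueError("dead_fraction must be in [0, 1]")

    rng = np.random.default_rng(seed)

    if clustering is None:
        n = rng.poisson(stem_density * extent.area_m2)
        x = rng.uniform(extent.xmin, extent.xmax, n)
        y = rng.uniform(extent.ymin, extent.ymax, n)
    else:
        x, y = _thomas_process(rng, extent, stem_density, clustering)
        n = x.size

    h = _draw_heights(rng, height_distribution, n)
    radius_noise = rng.normal(0.0, allometry.get("sd_log", 0.0), n)
    r = allometry["a"] * h ** allometry["b"] * np.exp(radius_noise)
    r = np.maximum(r, MIN_CROWN_RADIUS_M)
    status = np.where(rng.random(n) < dead_fraction, "dead", "live")

    position = classify_canopy_position(x, y, h, r, overtop_margin_m)

    trees = pd.DataFrame(
        {
            "tree_id": [f"T{i:06d}" for i in range(n)],
            "x": x,
            "y": y,
            "height_m": h,
            "crown_radius_m": r,
            "canopy_position": position,
            "status": status,
        }
    )[TREE_COLUMNS]

    params = {
        "stem_density": stem_density,
        "clustering": clustering,
        "height_distribution": height_distribution,
        "allometry": allometry,
        "overtop_margin_m": overtop_margin_m,
        "dead_fraction": dead_fraction,
        "site": site,
        "year": year,
        "extent": tuple(extent),
    }
    return SceneTruth(extent=extent, trees=trees, seed=seed, params=params)


def classify_canopy_position(x, y, h, r, overtop_margin_m: float) -> np.ndarray:
    """Overstory/understory labels under the overtopping rule.

    A tree is understory iff some other tree's crown disk contains its stem
    and that tree is taller by more than ``overtop_margin_m``.
    """
    n = len(x)
    position = np.full(n, "overstory", dtype=object)
    if n < 2:
        return position
    pts = np.column_stack([x, y])
    tree = cKDTree(pts)
    for j in range(n):  # j: candidate overtopping tree
        for i in tree.query_ball_point(pts[j], r[j]):
            if i != j and h[j] - h[i] > overtop_margin_m:
                position[i] = "understory"
    return position


def _thomas_process(rng, extent, stem_density, clustering):
    parent_density = clustering["parent_density"]
    sd = clustering["cluster_sd_m"]
    if parent_density <= 0:
        raise ValueError("parent_density must be > 0")
    # parents on a 3-sigma dilated region so edge clusters contribute
    pad = 3.0 * sd
    pxmin, pxmax = extent.xmin - pad, extent.xmax + pad
    pymin, pymax = extent.ymin - pad, extent.ymax + pad
    area = (pxmax - pxmin) * (pymax - pymin)
    n_parents = rng.poisson(parent_density * area)
    px = rng.uniform(pxmin, pxmax, n_parents)
    py = rng.uniform(pymin, pymax, n_parents)
    mean_offspring = stem_density / parent_density
    counts = rng.poisson(mean_offspring, n_parents)
    cx = np.repeat(px, counts) + rng.normal(0.0, sd, counts.sum())
    cy = np.repeat(py, counts) + rng.normal(0.0, sd, counts.sum())
    keep = extent.contains(cx, cy)
    return cx[keep], cy[keep]


def _draw_heights(rng, dist, n):
    kind = dist.get("kind", "lognormal")
    if kind == "lognormal":
        h = rng.lognormal(np.log(dist["median_m"]), dist["sigma_log"], n)
    elif kind == "uniform":
        h = rng.uniform(dist["low_m"], dist["high_m"], n)
    else:
        raise ValueError(f"unknown height distribution kind: {kind!r}")
    return np.maximum(h, MIN_TREE_HEIGHT_M)


# ---------------------------------------------------------------------------
# true crown boxes
# ---------------------------------------------------------------------------

def true_crown_boxes(scene: SceneTruth) -> pd.DataFrame:
    """Ground-truth crown boxes: one per overstory tree.

    Each box is the axis-aligned square circumscribing the crown disk
    (side ``2 * crown_radius_m``, centred on the stem), clipped to the
    scene extent. Understory trees emit no box. ``height_m`` carries the
    true tree height; ``score`` is 1.
    """
    rows = []
    for t in scene.overstory().itertuples(index=False):
        box = clip_box(
            t.x - t.crown_radius_m,
            t.y - t.crown_radius_m,
            t.x + t.crown_radius_m,
            t.y + t.crown_radius_m,
            scene.extent,
        )
        if box is None:
            continue
        xmin, ymin, xmax, ymax = box
        rows.append(
            {
                "crown_id": t.tree_id,
                "site": scene.site,
                "year": scene.year,
                "xmin": xmin,
                "ymin": ymin,
                "xmax": xmax,
                "ymax": ymax,
                "score": 1.0,
                "height_m": t.height_m,
                "area_m2": box_area(xmin, ymin, xmax, ymax),
            }
        )
    if not rows:
        return empty_crown_table()
    return pd.DataFrame(rows)[CROWN_COLUMNS]


# ---------------------------------------------------------------------------
# LiDAR
# ---------------------------------------------------------------------------

def crown_surface_height(scene: SceneTruth, x, y, crown_shape: str = "ellipsoid") -> np.ndarray:
    """Canopy surface height above ground at (x, y).

    The crown of a tree of height ``h`` and radius ``r`` occupies the
    vertical band from ``0.6 h`` (crown base) to ``h`` (apex). At planar
    distance ``d <= r`` from the stem the surface is:

    * ``ellipsoid`` (default): ``0.6 h + 0.4 h * sqrt(1 - (d/r)^2)`` — a
      half-ellipsoid cap, the flat-topped profile typical of mature crowns;
    * ``paraboloid``: ``h * (1 - 0.4 (d/r)^2)``;
    * ``cone``: ``h * (1 - 0.4 d/r)``.

    Outside every crown disk the surface is ground (0). Overlapping crowns
    take the pointwise maximum, i.e. the first (highest) return surface.
    """
    if crown_shape not in ("ellipsoid", "paraboloid", "cone"):
        raise ValueError(f"unknown crown_shape: {crown_shape!r}")
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.zeros_like(x)
    trees = scene.trees
    if not len(trees) or not x.size:
        return z
    pt_tree = cKDTree(np.column_stack([x.ravel(), y.ravel()]))
    tx = trees["x"].to_numpy()
    ty = trees["y"].to_numpy()
    th = trees["height_m"].to_numpy()
    tr = trees["crown_radius_m"].to_numpy()
    flat = z.ravel()
    for j in range(len(trees)):
        idx = pt_tree.query_ball_point((tx[j], ty[j]), tr[j])
        if not idx:
            continue
        idx = np.asarray(idx)
        d = np.hypot(x.ravel()[idx] - tx[j], y.ravel()[idx] - ty[j])
        frac = d / tr[j]
        if crown_shape == "ellipsoid":
            s = CROWN_BASE_FRACTION * th[j] + (1 - CROWN_BASE_FRACTION) * th[j] * np.sqrt(
                np.clip(1 - frac**2, 0, None)
            )
        elif crown_shape == "paraboloid":
            s = th[j] * (1 - (1 - CROWN_BASE_FRACTION) * frac**2)
        else:
            s = th[j] * (1 - (1 - CROWN_BASE_FRACTION) * frac)
        np.maximum.at(flat, idx, s)
    return flat.reshape(z.shape)


def simulate_point_cloud(
    scene: SceneTruth,
    pulse_density: float = 6.0,
    crown_shape: str = "ellipsoid",
    noise_sd_m: float = 0.0,
    seed: int = 0,
) -> LidarPoints:
    """Sparse LiDAR returns over the scene.

    The total return count is Poisson(``pulse_density`` x area) with
    positions uniform over the extent — equivalently, each 1 m^2 column
    receives a Poisson(``pulse_density``) count. Each return's height above
    ground is the crown surface at its position (0 over gaps) plus Gaussian
    noise truncated at 0.

    RNG order: total count, x, y, noise.
    """
    if pulse_density < 0:
        raise ValueError("pulse_density must be >= 0")
    rng = np.random.default_rng(seed)
    n = rng.poisson(pulse_density * scene.extent.area_m2)
    x = rng.uniform(scene.extent.xmin, scene.extent.xmax, n)
    y = rng.uniform(scene.extent.ymin, scene.extent.ymax, n)
    z = crown_surface_height(scene, x, y, crown_shape)
    if noise_sd_m > 0:
        z = z + rng.normal(0.0, noise_sd_m, n)
    return LidarPoints(x=x, y=y, z_agl=np.clip(z, 0.0, None))


def rasterize_chm(
    points: LidarPoints,
    resolution_m: float = 0.5,
    extent: Extent | tuple | None = None,
) -> Raster:
    """Grid the point cloud into a canopy height model by per-cell maximum.

    Cells are half-open (see :class:`~crownscape.types.Raster`); cells that
    receive no return hold NaN (no-data). With no ``extent`` the grid is
    fitted to the point bounding box.
    """
    if resolution_m <= 0:
        raise ValueError("resolution_m must be > 0")
    if extent is None:
        if not len(points):
            return Raster(0.0, resolution_m, resolution_m, np.full((1, 1), np.nan))
        extent = Extent(points.x.min(), points.y.min(), points.x.max(), points.y.max())
    extent = Extent(*extent)
    ncols = max(int(np.ceil((extent.xmax - extent.xmin) / resolution_m)), 1)
    nrows = max(int(np.ceil((extent.ymax - extent.ymin) / resolution_m)), 1)
    ymax = extent.ymin + nrows * resolution_m
    grid = Raster(extent.xmin, ymax, resolution_m, np.full((nrows, ncols), np.nan))
    if len(points):
        row, col = grid.cell_index(points.x, points.y)
        ok = grid.in_grid(row, col)
        vals = np.full((nrows, ncols), -np.inf)
        np.maximum.at(vals, (row[ok], col[ok]), points.z_agl[ok])
        grid.values = np.where(np.isfinite(vals), vals, np.nan)
    return grid


# ---------------------------------------------------------------------------
# detector simulation
# ---------------------------------------------------------------------------

def simulate_detections(
    scene: SceneTruth,
    error_model: DetectorErrorModel | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Imperfect detector output over the scene's true overstory boxes.

    In order: (1) each true box is independently dropped with ``miss_prob``;
    (2) each survivor draws a confidence score from the true-box Beta law;
    (3) surviving pairs whose boundary gap is at most ``merge_gap_m`` are
    visited in lexicographic id order and, with ``merge_prob``, replaced by
    their union envelope carrying the larger of the two scores (a box takes
    part in at most one merge — undersegmentation of dense stands);
    (4) every box edge is jittered by N(0, ``jitter_sd_m``) and the box is
    clipped to the extent (a box collapsing below 0.1 m width is restored
    around its centroid); (5) Poisson(``false_pos_rate_per_ha`` x area)
    false boxes are placed uniformly with lognormal half-sizes and draw
    scores from the false-box Beta law. Scores below ``score_floor`` are
    raised to the floor.

    RNG order: miss draws, survivor scores, merge draws, jitter normals
    (4 per box), FP count, FP centers, FP half-sizes, FP scores.
    """
    error_model = error_model or DetectorErrorModel()
    rng = np.random.default_rng(seed)
    truth = true_crown_boxes(scene)

    n = len(truth)
    keep = rng.random(n) >= error_model.miss_prob if n else np.zeros(0, bool)
    boxes = [
        {
            "crown_id": t.crown_id,
            "xmin": t.xmin,
            "ymin": t.ymin,
            "xmax": t.xmax,
            "ymax": t.ymax,
        }
        for t, k in zip(truth.itertuples(index=False), keep)
        if k
    ]
    a, b = error_model.true_score_ab
    scores = rng.beta(a, b, len(boxes))
    for box, s in zip(boxes, scores):
        box["score"] = max(float(s), error_model.score_floor)

    if error_model.merge_prob > 0 and len(boxes) > 1:
        boxes = _merge_adjacent(rng, boxes, error_model)

    for box in boxes:
        jit = rng.normal(0.0, error_model.jitter_sd_m, 4) if error_model.jitter_sd_m > 0 else np.zeros(4)
        _apply_jitter(box, jit, scene.extent)

    area_ha = scene.extent.area_ha
    n_fp = rng.poisson(error_model.false_pos_rate_per_ha * area_ha)
    fx = rng.uniform(scene.extent.xmin, scene.extent.xmax, n_fp)
    fy = rng.uniform(scene.extent.ymin, scene.extent.ymax, n_fp)
    half = rng.lognormal(np.log(2.0), 0.3, n_fp)
    fscores = rng.beta(*error_model.false_score_ab, n_fp)
    for i in range(n_fp):
        box = clip_box(fx[i] - half[i], fy[i] - half[i], fx[i] + half[i], fy[i] + half[i], scene.extent)
        if box is None:
            continue
        boxes.append(
            {
                "crown_id": f"FP{i:05d}",
                "xmin": box[0],
                "ymin": box[1],
                "xmax": box[2],
                "ymax": box[3],
                "score": max(float(fscores[i]), error_model.score_floor),
            }
        )

    if not boxes:
        return empty_crown_table()
    out = pd.DataFrame(boxes)
    out["site"] = scene.site
    out["year"] = scene.year
    out["height_m"] = np.nan
    out["area_m2"] = box_area(out["xmin"], out["ymin"], out["xmax"], out["ymax"])
    return out[CROWN_COLUMNS].reset_index(drop=True)


def _merge_adjacent(rng, boxes, error_model):
    coords = lambda b: (b["xmin"], b["ymin"], b["xmax"], b["ymax"])
    pairs = []
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if boundary_gap(coords(boxes[i]), coords(boxes[j])) <= error_model.merge_gap_m:
                pairs.append((boxes[i]["crown_id"], boxes[j]["crown_id"], i, j))
    pairs.sort(key=lambda p: (p[0], p[1]))
    consumed: set[int] = set()
    merged_out = {}
    for _, _, i, j in pairs:
        if i in consumed or j in consumed:
            continue
        if rng.random() < error_model.merge_prob:
            consumed.update((i, j))
            bi, bj = boxes[i], boxes[j]
            merged_out[i] = {
                "crown_id": f"{bi['crown_id']}+{bj['crown_id']}",
                "xmin": min(bi["xmin"], bj["xmin"]),
                "ymin": min(bi["ymin"], bj["ymin"]),
                "xmax": max(bi["xmax"], bj["xmax"]),
                "ymax": max(bi["ymax"], bj["ymax"]),
                "score": max(bi["score"], bj["score"]),
            }
    out = []
    for i, box in enumerate(boxes):
        if i in merged_out:
            out.append(merged_out[i])
        elif i not in consumed:
            out.append(box)
    return out


def _apply_jitter(box, jit, extent):
    xmin = box["xmin"] + jit[0]
    ymin = box["ymin"] + jit[1]
    xmax = box["xmax"] + jit[2]
    ymax = box["ymax"] + jit[3]
    cx, cy = (xmin + xmax) / 2, (ymin + ymax) / 2
    if xmax - xmin < 0.1:
        xmin, xmax = cx - 0.05, cx + 0.05
    if ymax - ymin < 0.1:
        ymin, ymax = cy - 0.05, cy + 0.05
    clipped = clip_box(xmin, ymin, xmax, ymax, extent)
    if clipped is None:  # fully jittered out: pin a minimal box at the edge
        clipped = clip_box(
            min(max(xmin, extent.xmin), extent.xmax - 0.1),
            min(max(ymin, extent.ymin), extent.ymax - 0.1),
            min(max(xmax, extent.xmin + 0.1), extent.xmax),
            min(max(ymax, extent.ymin + 0.1), extent.ymax),
            extent,
        )
    box["xmin"], box["ymin"], box["xmax"], box["ymax"] = clipped


# ---------------------------------------------------------------------------
# field surveys
# ---------------------------------------------------------------------------

def simulate_field_survey(
    scene: SceneTruth,
    plot_layout: str = "tower",
    n_plots: int = 5,
    geolocation_sd_m: float = 1.0,
    height_error_sd_m: float = 0.5,
    growth_rate_m_per_yr: float = 0.25,
    lag_years: float = 3.0,
    dbh_model: dict[str, float] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a stem-mapped field campaign over the scene.

    Plot designs follow operational forest-inventory networks: ``tower``
    plots are 40 m x 40 m with two of their four 20 m x 20 m quadrants
    sampled (chosen at random per plot); ``distributed`` plots are a single
    fully-sampled 20 m x 20 m square. Plots are placed uniformly without
    overlap. Every tree whose true stem lies in a sampled quadrant yields a
    record with

    * coordinates perturbed by N(0, ``geolocation_sd_m``) per axis,
    * recorded height = true height - ``growth_rate_m_per_yr * lag_years``
      + N(0, ``height_error_sd_m``) (the field campaign predates the
      overflight by the lag), floored at 0.1 m,
    * DBH from ``dbh_model`` applied to the recorded epoch's height.

    RNG order: plot centers (rejection sampling), sampled-quadrant choices,
    then per-stem coordinate noise, height noise, DBH noise.
    """
    if n_plots < 0:
        raise ValueError("n_plots must be >= 0")
    if plot_layout not in ("tower", "distributed"):
        raise ValueError(f"unknown plot_layout: {plot_layout!r}")
    dbh_model = dict(dbh_model or DEFAULT_DBH_MODEL)
    plot_size = 40.0 if plot_layout == "tower" else 20.0
    ext = scene.extent
    if plot_size > ext.width or plot_size > ext.height:
        raise ValueError(f"{plot_layout} plot ({plot_size} m) larger than extent")

    rng = np.random.default_rng(seed)
    centers = _place_plots(rng, ext, plot_size, n_plots)

    sampled_rects = []  # (plot_id, rect) in plot order
    for p, (cx, cy) in enumerate(centers):
        plot_id = f"PLOT{p:03d}"
        x0, y0 = cx - plot_size / 2, cy - plot_size / 2
        if plot_layout == "tower":
            quadrants = [
                (x0, y0, x0 + 20, y0 + 20),
                (x0 + 20, y0, x0 + 40, y0 + 20),
                (x0, y0 + 20, x0 + 20, y0 + 40),
                (x0 + 20, y0 + 20, x0 + 40, y0 + 40),
            ]
            chosen = rng.choice(4, size=2, replace=False)
            for q in sorted(chosen):
                sampled_rects.append((plot_id, quadrants[q]))
        else:
            sampled_rects.append((plot_id, (x0, y0, x0 + plot_size, y0 + plot_size)))

    trees = scene.trees
    tx = trees["x"].to_numpy()
    ty = trees["y"].to_numpy()
    rows = []
    for plot_id, (x0, y0, x1, y1) in sampled_rects:
        inplot = (tx >= x0) & (tx < x1) & (ty >= y0) & (ty < y1)
        for t in trees[inplot].itertuples(index=False):
            gx, gy = rng.normal(0.0, geolocation_sd_m, 2) if geolocation_sd_m > 0 else (0.0, 0.0)
            herr = rng.normal(0.0, height_error_sd_m) if height_error_sd_m > 0 else 0.0
            h_rec = max(t.height_m - growth_rate_m_per_yr * lag_years + herr, 0.1)
            dnoise = rng.normal(0.0, dbh_model.get("sd_log", 0.0)) if dbh_model.get("sd_log", 0.0) > 0 else 0.0
            dbh = dbh_model["a"] * h_rec ** dbh_model["b"] * np.exp(dnoise)
            rows.append(
                {
                    "stem_id": t.tree_id,
                    "x": t.x + gx,
                    "y": t.y + gy,
                    "dbh_cm": dbh,
                    "height_m": h_rec,
                    "status": t.status,
                    "plot_id": plot_id,
                    "site": scene.site,
                    "year": scene.year - lag_years,
                }
            )
    if not rows:
        return pd.DataFrame(columns=STEM_COLUMNS)
    return pd.DataFrame(rows)[STEM_COLUMNS]


def _place_plots(rng, extent, plot_size, n_plots, max_tries_per_plot=1000):
    half = plot_size / 2
    centers: list[tuple[float, float]] = []
    for _ in range(n_plots):
        for _try in range(max_tries_per_plot):
            cx = rng.uniform(extent.xmin + half, extent.xmax - half)
            cy = rng.uniform(extent.ymin + half, extent.ymax - half)
            if all(abs(cx - ox) >= plot_size or abs(cy - oy) >= plot_size for ox, oy in centers):
                centers.append((cx, cy))
                break
        else:
            raise ValueError(
                f"could not place {n_plots} non-overlapping {plot_size} m plots in the extent"
            )
    return centers
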