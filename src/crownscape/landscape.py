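"""Landscape-scale summaries of crown tables: density rasters, simulated
inventory-plot densities, field-plot densities, and per-site allometry.

Crowns are assigned to cells and plots by their box centroid, which gives
every crown exactly one assignment and makes counts conserve exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import centroids
from .types import DensityRaster, Extent, Raster


def density_raster(
    crowns: pd.DataFrame,
    extent: Extent | tuple,
    cell_size_m: float = 10.0,
) -> DensityRaster:
    """Count crowns per grid cell (default 10 m cells, i.e. 100 m^2).

    Each crown falls in exactly one half-open cell by its box centroid;
    the cell counts sum to the number of in-extent crowns.
    """
    extent = Extent(*extent).validate()
    ncols = int(np.ceil(extent.width / cell_size_m))
    nrows = int(np.ceil(extent.height / cell_size_m))
    grid = Raster(extent.xmin, extent.ymin + nrows * cell_size_m, cell_size_m, np.zeros((nrows, ncols)))
    if len(crowns):
        cx, cy = centroids(crowns)
        row, col = grid.cell_index(cx, cy)
        ok = grid.in_grid(row, col) & extent.contains(cx, cy)
        np.add.at(grid.values, (row[ok], col[ok]), 1.0)
    return grid


@dataclass
class PlotDensitySample:
    """One simulated inventory plot: two sampled 20 m quadrants of a
    40 m x 40 m plot (mimicking tower-plot sampling)."""

    center_x: float
    center_y: float
    quadrants: tuple[int, ...]
    crown_count: int
    area_sampled_m2: float


def simulate_plot_densities(
    crowns: pd.DataFrame,
    extent: Extent | tuple,
    n_plots: int = 10_000,
    plot_size_m: float = 40.0,
    quadrants_per_plot: int = 2,
    mask: Raster | None = None,
    seed: int = 0,
) -> list[PlotDensitySample]:
    """Crown counts in randomly placed simulated inventory plots.

    ``n_plots`` square plots are centred uniformly wherever the plot fits
    inside the extent (and, when a binary ``mask`` is given, where the
    center cell is allowed, i.e. mask value > 0 — used to exclude water,
    bare ground or herbaceous cover). Each plot is split into four
    ``plot_size_m/2`` quadrants of which ``quadrants_per_plot`` are drawn
    without replacement; the sample's count is the number of crown
    centroids inside the chosen quadrants.

    RNG order: plot centers (rejection-sampled against the mask), then the
    quadrant choice per plot.
    """
    extent = Extent(*extent).validate()
    half = plot_size_m / 2.0
    if plot_size_m > extent.width or plot_size_m > extent.height:
        raise ValueError("plot does not fit in the extent")
    rng = np.random.default_rng(seed)

    cx_lo, cx_hi = extent.xmin + half, extent.xmax - half
    cy_lo, cy_hi = extent.ymin + half, extent.ymax - half
    if mask is not None and not (mask.values > 0).any():
        raise ValueError("mask excludes every plot position")

    centers_x = np.empty(n_plots)
    centers_y = np.empty(n_plots)
    n_placed = 0
    max_batches = 1000
    for _ in range(max_batches):
        if n_placed >= n_plots:
            break
        need = n_plots - n_placed
        px = rng.uniform(cx_lo, cx_hi, need) if cx_hi > cx_lo else np.full(need, cx_lo)
        py = rng.uniform(cy_lo, cy_hi, need) if cy_hi > cy_lo else np.full(need, cy_lo)
        if mask is not None:
            row, col = mask.cell_index(px, py)
            ok = mask.in_grid(row, col)
            ok[ok] = mask.values[row[ok], col[ok]] > 0
            px, py = px[ok], py[ok]
        centers_x[n_placed : n_placed + px.size] = px
        centers_y[n_placed : n_placed + px.size] = py
        n_placed += px.size
    if n_placed < n_plots:
        raise ValueError("mask admits too few plot positions")

    quad_choices = [tuple(sorted(rng.choice(4, size=quadrants_per_plot, replace=False)))
                    for _ in range(n_plots)]

    if len(crowns):
        ccx, ccy = centroids(crowns)
        order = np.argsort(ccx, kind="stable")
        sx, sy = ccx[order], ccy[order]
    else:
        sx = sy = np.array([])

    q = plot_size_m / 2.0  # quadrant side
    samples = []
    for p in range(n_plots):
        x0, y0 = centers_x[p] - half, centers_y[p] - half
        count = 0
        for qi in quad_choices[p]:
            qx0 = x0 + (qi % 2) * q
            qy0 = y0 + (qi // 2) * q
            if sx.size:
                lo = np.searchsorted(sx, qx0, side="left")
                hi = np.searchsorted(sx, qx0 + q, side="left")
                ys = sy[lo:hi]
                count += int(((ys >= qy0) & (ys < qy0 + q)).sum())
        samples.append(
            PlotDensitySample(
                center_x=float(centers_x[p]),
                center_y=float(centers_y[p]),
                quadrants=quad_choices[p],
                crown_count=count,
                area_sampled_m2=quadrants_per_plot * q * q,
            )
        )
    return samples


def plot_density_frame(samples: list[PlotDensitySample]) -> pd.DataFrame:
    """Plot samples as a flat table (one row per simulated plot)."""
    return pd.DataFrame(
        {
            "center_x": [s.center_x for s in samples],
            "center_y": [s.center_y for s in samples],
            "quadrants": ["+".join(map(str, s.quadrants)) for s in samples],
            "crown_count": [s.crown_count for s in samples],
            "area_sampled_m2": [s.area_sampled_m2 for s in samples],
        }
    )


def field_plot_density(
    stems: pd.DataFrame,
    min_height_m: float = 3.0,
    fallback_min_dbh_cm: float = 15.0,
) -> tuple[pd.DataFrame, dict]:
    """Tree counts per field plot under the inventory inclusion rule.

    A stem is counted when it has valid coordinates and either a recorded
    height >= ``min_height_m``, or no height but DBH >=
    ``fallback_min_dbh_cm`` (the fallback covers legacy campaigns that
    recorded no heights). Returns per-plot counts and exclusion tallies.
    """
    has_coords = stems["x"].notna() & stems["y"].notna()
    has_height = stems["height_m"].notna()
    tall = has_height & (stems["height_m"] >= min_height_m)
    fallback = ~has_height & stems["dbh_cm"].notna() & (stems["dbh_cm"] >= fallback_min_dbh_cm)
    include = has_coords & (tall | fallback)
    report = {
        "n_in": len(stems),
        "n_included": int(include.sum()),
        "n_no_coordinates": int((~has_coords).sum()),
        "n_below_min_height": int((has_coords & has_height & ~tall).sum()),
        "n_below_fallback_dbh": int((has_coords & ~has_height & ~fallback).sum()),
    }
    counts = (
        stems[include]
        .groupby("plot_id")
        .size()
        .rename("stem_count")
        .reset_index()
    )
    # plots whose stems were all excluded still appear, with count 0
    all_plots = stems["plot_id"].drop_duplicates()
    counts = (
        pd.DataFrame({"plot_id": all_plots})
        .merge(counts, on="plot_id", how="left")
        .fillna({"stem_count": 0})
        .astype({"stem_count": int})
    )
    return counts, report


def allometry_summary(
    crowns: pd.DataFrame,
    group_by: str = "site",
    footprint_ha: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Per-group crown structure summary.

    For each group (default: site): crown count, mean/median attributed
    height, mean/median bounding-box area, crown density per hectare
    (needs the group's footprint area), and the mean per-crown
    height-to-area ratio (m / m^2) — a coarse shape descriptor separating
    tall-narrow from short-broad canopies. Groups with no crowns yield NaN
    statistics.
    """
    footprint_ha = footprint_ha or {}
    rows = []
    for group, sub in crowns.groupby(group_by, sort=True):
        n = len(sub)
        fp = footprint_ha.get(group, np.nan)
        rows.append(
            {
                group_by: group,
                "n": n,
                "mean_height_m": sub["height_m"].mean() if n else np.nan,
                "median_height_m": sub["height_m"].median() if n else np.nan,
                "mean_area_m2": sub["area_m2"].mean() if n else np.nan,
                "median_area_m2": sub["area_m2"].median() if n else np.nan,
                "density_per_ha": n / fp if fp and np.isfinite(fp) else np.nan,
                "height_area_ratio": (sub["height_m"] / sub["area_m2"]).mean() if n else np.nan,
            }
        )
    return pd.DataFrame(rows)
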