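"""A multi-site synthetic survey campaign: the end-to-end study design.

One campaign emulates a small airborne observation network: several sites
with contrasting stand structure, each with a stem map, sparse LiDAR, a
canopy height model, imperfect detector output, and a lagged field survey.
The downstream functions then measure everything the workflow is built to
report: crown precision/recall, the precision/recall change contributed by
the 3 m LiDAR filter, exclusive stem recall, the mixed-model height
validation, and landscape density/allometry summaries.

The default site roster spans the structural extremes the workflow has to
handle: an open savanna-like stand, two mid-density mixed stands, and a
dense conifer-like stand with tall narrow crowns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from . import evaluation, landscape, pipeline, synthetic
from .types import DetectorErrorModel, Extent

#: Per-site generating parameters: density (/m^2), height median (m),
#: crown-allometry scale. Chosen to span open to closed canopies.
DEFAULT_SITES: dict[str, dict[str, float]] = {
    "OPEN": {"stem_density": 0.004, "height_median_m": 9.0, "allometry_a": 0.7},
    "MIXA": {"stem_density": 0.008, "height_median_m": 12.0, "allometry_a": 0.5},
    "MIXB": {"stem_density": 0.010, "height_median_m": 15.0, "allometry_a": 0.5},
    "CONI": {"stem_density": 0.014, "height_median_m": 22.0, "allometry_a": 0.35},
}


@dataclass
class SiteRun:
    """Everything simulated and derived for one site."""

    site: str
    scene: synthetic.SceneTruth
    truth_boxes: pd.DataFrame
    points: synthetic.LidarPoints
    chm: synthetic.Raster
    detections: pd.DataFrame
    released: pd.DataFrame
    unfiltered: pd.DataFrame  # score-filtered + height-attributed, no 3 m filter
    report: pipeline.PipelineReport
    stems: pd.DataFrame


@dataclass
class CampaignConfig:
    sites: dict[str, dict[str, float]] = field(default_factory=lambda: dict(DEFAULT_SITES))
    extent_m: float = 300.0
    pulse_density: float = 6.0
    chm_resolution_m: float = 0.5
    error_model: DetectorErrorModel = field(default_factory=DetectorErrorModel)
    n_plots_per_site: int = 3
    lag_years: float = 3.0
    growth_rate_m_per_yr: float = 0.25
    geolocation_sd_m: float = 0.5
    height_error_sd_m: float = 0.5


def run_site(site: str, params: dict[str, float], config: CampaignConfig, seed: int) -> SiteRun:
    """Simulate one site and push it through the crown pipeline.

    Seeds for the stochastic stages are derived deterministically from
    ``seed`` so a campaign is reproducible from a single integer.
    """
    extent = Extent(0.0, 0.0, config.extent_m, config.extent_m)
    scene = synthetic.generate_stem_map(
        extent,
        stem_density=params["stem_density"],
        height_distribution={"kind": "lognormal", "median_m": params["height_median_m"],
                             "sigma_log": 0.35},
        allometry={"a": params["allometry_a"], "b": 0.6, "sd_log": 0.15},
        site=site,
        seed=seed,
    )
    truth_boxes = synthetic.true_crown_boxes(scene)
    points = synthetic.simulate_point_cloud(
        scene, config.pulse_density, noise_sd_m=0.15, seed=seed + 1
    )
    chm = synthetic.rasterize_chm(points, config.chm_resolution_m, extent)
    detections = synthetic.simulate_detections(scene, config.error_model, seed=seed + 2)
    released, report = pipeline.run_pipeline(detections, points)

    # the same table without the 3 m LiDAR filter, to measure its effect
    unfiltered = pipeline.filter_by_score(detections)
    unfiltered = unfiltered.assign(height_m=pipeline.attribute_height(unfiltered, points))

    stems = synthetic.simulate_field_survey(
        scene,
        plot_layout="tower",
        n_plots=config.n_plots_per_site,
        geolocation_sd_m=config.geolocation_sd_m,
        height_error_sd_m=config.height_error_sd_m,
        growth_rate_m_per_yr=config.growth_rate_m_per_yr,
        lag_years=config.lag_years,
        seed=seed + 3,
    )
    return SiteRun(site, scene, truth_boxes, points, chm, detections, released,
                   unfiltered, report, stems)


def run_campaign(seed: int, config: CampaignConfig | None = None) -> list[SiteRun]:
    config = config or CampaignConfig()
    runs = []
    for i, (site, params) in enumerate(sorted(config.sites.items())):
        runs.append(run_site(site, params, config, seed=seed + 100 * i))
    return runs


def crown_metrics(runs: list[SiteRun], iou_threshold: float = 0.5) -> dict[str, Any]:
    """Pooled crown precision/recall, with and without the 3 m filter."""
    tallies = {"with": [0, 0, 0], "without": [0, 0, 0]}  # tp, n_pred, n_ref
    for run in runs:
        for key, preds in (("with", run.released), ("without", run.unfiltered)):
            match = evaluation.match_crowns(preds, run.truth_boxes, iou_threshold)
            tallies[key][0] += match.n_pairs
            tallies[key][1] += len(preds)
            tallies[key][2] += len(run.truth_boxes)
    out = {}
    for key, (tp, n_pred, n_ref) in tallies.items():
        out[f"precision_{key}_filter"] = tp / n_pred if n_pred else None
        out[f"recall_{key}_filter"] = tp / n_ref if n_ref else None
    out["precision"] = out["precision_with_filter"]
    out["recall"] = out["recall_with_filter"]
    out["filter_precision_gain"] = out["precision_with_filter"] - out["precision_without_filter"]
    out["filter_recall_change"] = out["recall_with_filter"] - out["recall_without_filter"]
    out["n_predictions"] = tallies["with"][1]
    out["n_references"] = tallies["with"][2]
    return out


def stem_metrics(runs: list[SiteRun]) -> dict[str, Any]:
    """Pooled exclusive stem recall over overstory-selected field stems."""
    n_matched = n_stems = 0
    for run in runs:
        overstory, _ = evaluation.select_overstory_stems(run.stems, run.chm)
        result = evaluation.stem_recall(run.released, overstory)
        n_matched += result.n_matched
        n_stems += result.n_stems
    return {
        "stem_recall": n_matched / n_stems if n_stems else None,
        "n_overstory_stems": n_stems,
        "n_matched": n_matched,
    }


def height_metrics(runs: list[SiteRun]) -> evaluation.HeightValidationReport:
    """Mixed-model height validation pooled across sites."""
    all_pairs = []
    for run in runs:
        overstory, _ = evaluation.select_overstory_stems(run.stems, run.chm)
        all_pairs.append(evaluation.pair_stems_to_crowns(overstory, run.released))
    pairs = pd.concat(all_pairs, ignore_index=True)
    return evaluation.height_validation(pairs)


def landscape_metrics(runs: list[SiteRun], n_plots: int = 10_000, seed: int = 0) -> dict[str, Any]:
    """Density rasters, simulated-plot densities, and allometry per site."""
    per_site = []
    footprints = {}
    for i, run in enumerate(runs):
        extent = run.scene.extent
        footprints[run.site] = extent.area_ha
        grid = landscape.density_raster(run.released, extent)
        samples = landscape.simulate_plot_densities(
            run.released, extent, n_plots=n_plots, seed=seed + i
        )
        counts = np.array([s.crown_count for s in samples])
        field_counts, _ = landscape.field_plot_density(run.stems)
        per_site.append(
            {
                "site": run.site,
                "n_released": len(run.released),
                "raster_total": int(grid.values.sum()),
                "mean_plot_count": float(counts.mean()),
                "plot_density_per_ha": float(counts.mean() / 800.0 * 1e4),
                "released_density_per_ha": len(run.released) / extent.area_ha,
                "mean_field_plot_count": float(field_counts["stem_count"].mean())
                if len(field_counts) else np.nan,
            }
        )
    crowns = pd.concat([r.released for r in runs], ignore_index=True)
    summary = landscape.allometry_summary(crowns, footprint_ha=footprints)
    return {"per_site": pd.DataFrame(per_site), "allometry": summary}
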