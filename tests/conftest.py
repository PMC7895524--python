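import numpy as np
import pandas as pd
import pytest

from crownscape.types import Extent, SceneTruth, TREE_COLUMNS


def make_single_tree_scene(height_m: float, radius_m: float | None = None,
                           extent=(0.0, 0.0, 60.0, 60.0), x=30.0, y=30.0) -> SceneTruth:
    """One overstory tree centred in a square scene."""
    if radius_m is None:
        radius_m = 0.5 * height_m**0.6
    trees = pd.DataFrame(
        {
            "tree_id": ["T000000"],
            "x": [x],
            "y": [y],
            "height_m": [height_m],
            "crown_radius_m": [radius_m],
            "canopy_position": ["overstory"],
            "status": ["live"],
        }
    )[TREE_COLUMNS]
    return SceneTruth(extent=Extent(*extent), trees=trees, seed=0, params={})


def make_scene_from_rows(rows, extent=(0.0, 0.0, 100.0, 100.0)) -> SceneTruth:
    """Scene from explicit (x, y, height, radius, position) tuples."""
    trees = pd.DataFrame(
        [
            {
                "tree_id": f"T{i:06d}",
                "x": r[0],
                "y": r[1],
                "height_m": r[2],
                "crown_radius_m": r[3],
                "canopy_position": r[4] if len(r) > 4 else "overstory",
                "status": "live",
            }
            for i, r in enumerate(rows)
        ]
    )[TREE_COLUMNS]
    return SceneTruth(extent=Extent(*extent), trees=trees, seed=0, params={})


def random_boxes(rng: np.random.Generator, n: int, extent=100.0, min_side=1.0, max_side=8.0) -> pd.DataFrame:
    """Random valid boxes as a crown table."""
    cx = rng.uniform(0, extent, n)
    cy = rng.uniform(0, extent, n)
    w = rng.uniform(min_side, max_side, n)
    h = rng.uniform(min_side, max_side, n)
    return pd.DataFrame(
        {
            "crown_id": [f"B{i:04d}" for i in range(n)],
            "site": "SYNT",
            "year": 2019,
            "xmin": cx - w / 2,
            "ymin": cy - h / 2,
            "xmax": cx + w / 2,
            "ymax": cy + h / 2,
            "score": rng.uniform(0, 1, n),
            "height_m": rng.uniform(3, 40, n),
            "area_m2": w * h,
        }
    )


@pytest.fixture
def box_factory():
    return random_boxes
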