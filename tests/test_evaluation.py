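"""Tests of crown matching, stem recall, overstory selection, and the
mixed-model height validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crownscape import evaluation, synthetic
from crownscape.geometry import iou
from crownscape.types import DetectorErrorModel

from conftest import random_boxes


# --- independent oracles -----------------------------------------------------

def iou_ref(a, b):
    """Reference rectangle IoU, written out longhand."""
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    return inter / (area_a + area_b - inter) if inter else 0.0


def greedy_match_ref(preds, refs, threshold):
    """Brute-force trace of the greedy rule over an explicit candidate list."""
    cands = []
    for i, p in preds.iterrows():
        for j, r in refs.iterrows():
            v = iou_ref((p.xmin, p.ymin, p.xmax, p.ymax), (r.xmin, r.ymin, r.xmax, r.ymax))
            if v > threshold:
                cands.append((-v, str(p.crown_id), str(r.crown_id)))
    cands.sort()
    used_p, used_r, pairs = set(), set(), []
    for nv, pid, rid in cands:
        if pid in used_p or rid in used_r:
            continue
        used_p.add(pid)
        used_r.add(rid)
        pairs.append((pid, rid, -nv))
    return pairs


def max_matching_ref(adj, n_left):
    """Exhaustive maximum bipartite matching size by recursive search."""

    def best(i, used):
        if i == n_left:
            return 0
        score = best(i + 1, used)  # leave stem i unmatched
        for j in adj[i]:
            if j not in used:
                score = max(score, 1 + best(i + 1, used | {j}))
        return score

    return best(0, frozenset())


# --- IoU ---------------------------------------------------------------------

class TestIou:
    def test_identical_boxes(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_disjoint_boxes(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_known_overlap(self):
        # intersection 1, union 7
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_degenerate_box_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 2), (0, 0, 1, 1))

    @settings(deadline=None, max_examples=50)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry_and_range(self, seed):
        rng = np.random.default_rng(seed)
        a = np.sort(rng.uniform(0, 10, 2)).tolist() + [0]
        b = np.sort(rng.uniform(0, 10, 2)).tolist() + [0]
        box_a = (a[0], a[0], a[1] + 0.1, a[1] + 0.1)
        box_b = (b[0], b[0], b[1] + 0.1, b[1] + 0.1)
        v = iou(box_a, box_b)
        assert v == iou(box_b, box_a)
        assert 0.0 <= v <= 1.0


# --- crown matching ----------------------------------------------------------

class TestMatchCrowns:
    def test_identical_sets_fully_matched(self):
        boxes = random_boxes(np.random.default_rng(2), 10)
        m = evaluation.match_crowns(boxes, boxes)
        assert m.n_pairs == 10
        assert np.all(m.pairs["iou"] == 1.0)
        p, r = evaluation.precision_recall(m, 10, 10)
        assert p == r == 1.0

    def test_prediction_takes_highest_overlap_reference(self):
        pred = pd.DataFrame(
            [{"crown_id": "P0", "xmin": 0.0, "ymin": 0.0, "xmax": 10.0, "ymax": 10.0}]
        )
        # references at IoU 0.6 and ~0.55 with the prediction
        refs = pd.DataFrame(
            [
                {"crown_id": "R0", "xmin": 0.0, "ymin": 0.0, "xmax": 10.0, "ymax": 6.0},
                {"crown_id": "R1", "xmin": 0.0, "ymin": 0.0, "xmax": 10.0, "ymax": 5.5},
            ]
        )
        assert iou_ref((0, 0, 10, 10), (0, 0, 10, 6)) == pytest.approx(0.6)
        m = evaluation.match_crowns(pred, refs)
        assert m.pairs.iloc[0]["ref_id"] == "R0"
        assert m.unmatched_references == ["R1"]

    def test_threshold_is_strict(self):
        pred = pd.DataFrame([{"crown_id": "P0", "xmin": 0, "ymin": 0, "xmax": 2, "ymax": 2}])
        refs = pd.DataFrame([{"crown_id": "R0", "xmin": 0, "ymin": 0, "xmax": 2, "ymax": 4}])
        assert iou_ref((0, 0, 2, 2), (0, 0, 2, 4)) == 0.5
        assert evaluation.match_crowns(pred, refs, iou_threshold=0.5).n_pairs == 0

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(7)
        preds = random_boxes(rng, 30, extent=40.0)
        refs = random_boxes(rng, 30, extent=40.0)
        m1 = evaluation.match_crowns(preds, refs)
        m2 = evaluation.match_crowns(
            preds.sample(frac=1, random_state=1), refs.sample(frac=1, random_state=2)
        )
        p1 = sorted(map(tuple, m1.pairs[["pred_id", "ref_id"]].to_numpy()))
        p2 = sorted(map(tuple, m2.pairs[["pred_id", "ref_id"]].to_numpy()))
        assert p1 == p2

    def test_matches_bruteforce_greedy_oracle(self):
        for seed in range(100):
            rng = np.random.default_rng(seed)
            preds = random_boxes(rng, rng.integers(0, 8), extent=12.0, max_side=6.0)
            refs = random_boxes(rng, rng.integers(0, 8), extent=12.0, max_side=6.0)
            refs["crown_id"] = [f"R{i}" for i in range(len(refs))]
            m = evaluation.match_crowns(preds, refs)
            expected = greedy_match_ref(preds, refs, 0.5)
            got = list(map(tuple, m.pairs[["pred_id", "ref_id", "iou"]].to_numpy()))
            assert [(p, r) for p, r, _ in got] == [(p, r) for p, r, _ in expected]

    def test_empty_inputs_allowed(self):
        empty = random_boxes(np.random.default_rng(0), 0)
        some = random_boxes(np.random.default_rng(1), 3)
        m = evaluation.match_crowns(empty, some)
        assert m.n_pairs == 0
        p, r = evaluation.precision_recall(m, 0, 3)
        assert p is None and r == 0.0


class TestPrecisionRecall:
    def test_arithmetic(self):
        m = evaluation.MatchResult(
            pairs=pd.DataFrame({"pred_id": [f"P{i}" for i in range(9)],
                                "ref_id": [f"R{i}" for i in range(9)],
                                "iou": [0.8] * 9}),
            unmatched_predictions=[], unmatched_references=[], iou_threshold=0.5,
        )
        p, r = evaluation.precision_recall(m, 12, 10)
        assert p == 0.75 and r == 0.9

    def test_extra_nonmatching_prediction_lowers_precision_keeps_recall(self):
        rng = np.random.default_rng(4)
        refs = random_boxes(rng, 10, extent=50.0)
        preds = refs.copy()
        m0 = evaluation.match_crowns(preds, refs)
        p0, r0 = evaluation.precision_recall(m0, len(preds), len(refs))
        fp = preds.iloc[[0]].assign(crown_id="FPX", xmin=200.0, xmax=203.0)
        preds2 = pd.concat([preds, fp], ignore_index=True)
        m1 = evaluation.match_crowns(preds2, refs)
        p1, r1 = evaluation.precision_recall(m1, len(preds2), len(refs))
        assert p1 <= p0 and r1 >= r0


# --- overstory selection -----------------------------------------------------

def stem_row(**kw):
    base = {"stem_id": "S0", "x": 10.0, "y": 10.0, "dbh_cm": 30.0, "height_m": 18.0,
            "status": "live", "plot_id": "PLOT000", "site": "SYNT", "year": 2016}
    base.update(kw)
    return base


@pytest.fixture
def flat_chm():
    from crownscape.types import Raster

    return Raster(0.0, 20.0, 1.0, np.full((20, 20), 19.0))


class TestSelectOverstoryStems:
    def test_dead_stem_removed(self, flat_chm):
        stems = pd.DataFrame([stem_row(status="dead")])
        kept, report = evaluation.select_overstory_stems(stems, flat_chm)
        assert len(kept) == 0 and report.n_not_live == 1

    def test_stem_near_canopy_height_kept(self, flat_chm):
        # height 18 m vs local CHM max 19 m, tolerance 3 m -> kept
        stems = pd.DataFrame([stem_row(height_m=18.0)])
        kept, _ = evaluation.select_overstory_stems(stems, flat_chm, height_tolerance_m=3.0)
        assert len(kept) == 1

    def test_overtopped_stem_removed(self, flat_chm):
        stems = pd.DataFrame([stem_row(height_m=10.0)])
        kept, report = evaluation.select_overstory_stems(stems, flat_chm, height_tolerance_m=3.0)
        assert len(kept) == 0 and report.n_below_canopy == 1

    def test_small_dbh_and_missing_coordinates_removed(self, flat_chm):
        stems = pd.DataFrame([stem_row(dbh_cm=5.0), stem_row(stem_id="S1", x=np.nan)])
        kept, report = evaluation.select_overstory_stems(stems, flat_chm)
        assert len(kept) == 0
        assert report.n_small_dbh == 1 and report.n_no_coordinates == 1

    def test_stem_outside_chm_counted_not_raised(self, flat_chm):
        stems = pd.DataFrame([stem_row(x=500.0)])
        kept, report = evaluation.select_overstory_stems(stems, flat_chm)
        assert len(kept) == 0 and report.n_outside_chm == 1

    def test_recovers_truth_overstory_on_noise_free_scene(self):
        # Sparse stand, error-free survey, dense LiDAR: with zero tolerance
        # and a tight search radius the kept set equals the truth overstory
        # set. The fixture seed gives a scene where no overstory stem is
        # overtopped by less than the margin (the rule's blind spot).
        scene = synthetic.generate_stem_map((0, 0, 100, 100), 0.004, seed=70)
        stems = synthetic.simulate_field_survey(
            scene, plot_layout="distributed", n_plots=8, geolocation_sd_m=0.0,
            height_error_sd_m=0.0, growth_rate_m_per_yr=0.0, lag_years=0.0, seed=71,
        )
        pts = synthetic.simulate_point_cloud(scene, 30.0, seed=72)
        chm = synthetic.rasterize_chm(pts, 0.5, scene.extent)
        kept, _ = evaluation.select_overstory_stems(
            stems, chm, min_dbh_cm=0.0, search_radius_m=0.5, height_tolerance_m=0.0
        )
        truth = scene.trees.set_index("tree_id")["canopy_position"]
        surveyed_overstory = {
            s for s in stems["stem_id"] if truth[s] == "overstory"
        }
        assert set(kept["stem_id"]) == surveyed_overstory


# --- stem recall -------------------------------------------------------------

class TestStemRecall:
    def test_disjoint_boxes_each_containing_a_stem(self):
        preds = pd.DataFrame(
            {"crown_id": ["A", "B"], "xmin": [0.0, 10.0], "ymin": [0.0, 10.0],
             "xmax": [5.0, 15.0], "ymax": [5.0, 15.0]}
        )
        stems = pd.DataFrame({"stem_id": ["s1", "s2"], "x": [1.0, 12.0], "y": [1.0, 12.0]})
        assert evaluation.stem_recall(preds, stems).recall == 1.0

    def test_shared_box_matches_only_one_stem(self):
        preds = pd.DataFrame(
            {"crown_id": ["A"], "xmin": [0.0], "ymin": [0.0], "xmax": [5.0], "ymax": [5.0]}
        )
        stems = pd.DataFrame({"stem_id": ["s1", "s2"], "x": [1.0, 2.0], "y": [1.0, 2.0]})
        result = evaluation.stem_recall(preds, stems)
        assert result.recall == 0.5 and result.n_matched == 1

    def test_zero_stems_gives_absent_recall(self):
        preds = random_boxes(np.random.default_rng(0), 3)
        stems = pd.DataFrame(columns=["stem_id", "x", "y"])
        assert evaluation.stem_recall(preds, stems).recall is None

    def test_containment_is_boundary_inclusive(self):
        preds = pd.DataFrame(
            {"crown_id": ["A"], "xmin": [0.0], "ymin": [0.0], "xmax": [5.0], "ymax": [5.0]}
        )
        stems = pd.DataFrame({"stem_id": ["s1"], "x": [5.0], "y": [0.0]})
        assert evaluation.stem_recall(preds, stems).recall == 1.0

    def test_matches_exhaustive_maximum_matching(self):
        for seed in range(60):
            rng = np.random.default_rng(1000 + seed)
            n_stems = int(rng.integers(1, 9))
            n_boxes = int(rng.integers(0, 9))
            preds = random_boxes(rng, n_boxes, extent=15.0, max_side=8.0)
            stems = pd.DataFrame(
                {"stem_id": [f"s{i}" for i in range(n_stems)],
                 "x": rng.uniform(0, 15, n_stems), "y": rng.uniform(0, 15, n_stems)}
            )
            result = evaluation.stem_recall(preds, stems)
            adj = [
                [
                    j
                    for j, b in enumerate(preds.itertuples(index=False))
                    if b.xmin <= s.x <= b.xmax and b.ymin <= s.y <= b.ymax
                ]
                for s in stems.itertuples(index=False)
            ]
            assert result.n_matched == max_matching_ref(adj, n_stems)

    def test_invariant_to_input_order(self):
        rng = np.random.default_rng(77)
        preds = random_boxes(rng, 20, extent=30.0)
        stems = pd.DataFrame(
            {"stem_id": [f"s{i}" for i in range(25)],
             "x": rng.uniform(0, 30, 25), "y": rng.uniform(0, 30, 25)}
        )
        r1 = evaluation.stem_recall(preds, stems)
        r2 = evaluation.stem_recall(
            preds.sample(frac=1, random_state=3),
            stems.sample(frac=1, random_state=4).reset_index(drop=True),
        )
        assert r1.n_matched == r2.n_matched


# --- stem/crown height pairing ----------------------------------------------

class TestPairStemsToCrowns:
    def test_no_matches_gives_empty_pairing(self):
        preds = random_boxes(np.random.default_rng(0), 2)
        stems = pd.DataFrame(
            [stem_row(x=500.0, y=500.0)], columns=list(stem_row().keys())
        )
        pairs = evaluation.pair_stems_to_crowns(stems, preds)
        assert len(pairs) == 0

    def test_every_pair_stem_inside_its_crown(self):
        scene = synthetic.generate_stem_map((0, 0, 120, 120), 0.01, seed=80)
        det = synthetic.simulate_detections(scene, seed=81)
        pts = synthetic.simulate_point_cloud(scene, 6.0, seed=82)
        det = det.assign(height_m=evaluation.pd.Series(
            __import__("crownscape").pipeline.attribute_height(det, pts)))
        stems = synthetic.simulate_field_survey(scene, n_plots=2, geolocation_sd_m=0.0,
                                                seed=83)
        result = evaluation.stem_recall(det, stems)
        merged = result.assignment.merge(stems, on="stem_id").merge(
            det, on="crown_id", suffixes=("_stem", "_crown")
        )
        for r in merged.itertuples(index=False):
            assert r.xmin <= r.x <= r.xmax and r.ymin <= r.y <= r.ymax

    def test_perfect_scene_reproduces_lagged_pairs(self):
        scene = synthetic.generate_stem_map((0, 0, 120, 120), 0.006, seed=84)
        det = synthetic.simulate_detections(scene, DetectorErrorModel.perfect(), seed=85)
        pts = synthetic.simulate_point_cloud(scene, 50.0, seed=86)
        from crownscape.pipeline import attribute_height

        det = det.assign(height_m=attribute_height(det, pts))
        stems = synthetic.simulate_field_survey(
            scene, n_plots=2, geolocation_sd_m=0.0, height_error_sd_m=0.0,
            growth_rate_m_per_yr=0.25, lag_years=4.0, seed=87,
        )
        truth_pos = scene.trees.set_index("tree_id")["canopy_position"]
        overstory_stems = stems[stems["stem_id"].map(truth_pos) == "overstory"]
        pairs = evaluation.pair_stems_to_crowns(overstory_stems, det)
        truth_h = scene.trees.set_index("tree_id")["height_m"]
        assert len(pairs) == len(overstory_stems) > 0
        for p in pairs.itertuples(index=False):
            # field height is exactly the lagged truth; predicted height is
            # the 99th LiDAR quantile, slightly below the apex
            assert p.predicted_height == pytest.approx(p.field_height + 1.0, abs=0.25)


# --- height validation -------------------------------------------------------

def synthetic_pairs(seed, n_sites=10, n_per_site=100, tau=1.0, sigma=1.5,
                    beta0=0.0, beta1=1.0):
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sites):
        u = rng.normal(0, tau)
        ph = rng.uniform(5, 35, n_per_site)
        fh = beta0 + beta1 * ph + u + rng.normal(0, sigma, n_per_site)
        rows.append(pd.DataFrame(
            {"field_height": fh, "predicted_height": ph, "site": f"S{s:02d}"}
        ))
    return pd.concat(rows, ignore_index=True)


class TestHeightValidation:
    def test_perfect_agreement(self):
        rng = np.random.default_rng(5)
        ph = rng.uniform(5, 35, 60)
        pairs = pd.DataFrame(
            {"field_height": np.tile(ph, 3), "predicted_height": np.tile(ph, 3),
             "site": np.repeat(["A", "B", "C"], 60)}
        )
        report = evaluation.height_validation(pairs)
        assert report.rmse_m == pytest.approx(0.0, abs=1e-4)
        assert report.slope == pytest.approx(1.0, abs=1e-4)
        assert report.site_intercept_var == pytest.approx(0.0, abs=1e-4)

    def test_shifting_all_field_heights_moves_intercept_only(self):
        pairs = synthetic_pairs(seed=10)
        r0 = evaluation.height_validation(pairs)
        shifted = pairs.assign(field_height=pairs["field_height"] + 5.0)
        r1 = evaluation.height_validation(shifted)
        assert r1.intercept - r0.intercept == pytest.approx(5.0, abs=0.05)
        assert np.sqrt(r1.residual_var) == pytest.approx(np.sqrt(r0.residual_var), rel=0.02)

    def test_single_site_falls_back_to_ols(self):
        pairs = synthetic_pairs(seed=11, n_sites=1)
        report = evaluation.height_validation(pairs)
        assert report.ols_fallback

    def test_mean_bias_exposes_taller_predictions(self):
        pairs = synthetic_pairs(seed=12, beta0=0.0)
        # predictions taller by ~1 m (growth lag): field = predicted - 1
        lagged = pairs.assign(field_height=pairs["predicted_height"] - 1.0)
        report = evaluation.height_validation(lagged)
        assert report.mean_bias_m == pytest.approx(1.0, abs=1e-6)

    def test_small_sites_excluded_from_fit(self):
        pairs = synthetic_pairs(seed=13, n_sites=3)
        tiny = pd.DataFrame(
            {"field_height": [10.0], "predicted_height": [11.0], "site": ["TINY"]}
        )
        report = evaluation.height_validation(pd.concat([pairs, tiny], ignore_index=True))
        assert report.n_sites == 3
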