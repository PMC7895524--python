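"""Validation of predicted crowns against image annotations and field stems.

Three complementary checks, in decreasing order of spatial specificity:

1. *Crown matching* — one-to-one greedy IoU matching between predicted and
   reference boxes; a true positive requires IoU strictly greater than the
   threshold (default 0.5). Precision is the matched fraction of
   predictions, recall the matched fraction of references.
2. *Stem recall* — the fraction of overstory field stems that fall inside
   some predicted box, with each prediction usable at most once; the
   exclusivity rule is resolved by maximum-cardinality bipartite matching,
   which is order-free and gives the rule its best-case value.
3. *Height validation* — field height regressed on LiDAR-attributed crown
   height with a site-level random intercept (REML); the headline figure
   is the RMSE of conditional residuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import maximum_bipartite_matching

from .geometry import iou, iou_matrix  # noqa: F401  (iou re-exported as part of the API)
from .types import ChmRaster, MatchResult

DEFAULT_IOU_THRESHOLD = 0.5


def match_crowns(
    predictions: pd.DataFrame,
    references: pd.DataFrame,
    iou_threshold: float = DEFAULT_IOU_THRESHOLD,
) -> MatchResult:
    """Greedy one-to-one IoU matching between predicted and reference boxes.

    All prediction-reference pairs with IoU strictly above the threshold
    are sorted by descending IoU, ties broken by ascending prediction id
    then reference id, and accepted greedily subject to the one-to-one
    constraint. The result is invariant to the input row order.
    """
    M = iou_matrix(predictions, references)
    pid = predictions["crown_id"].astype(str).to_numpy() if len(predictions) else np.array([], str)
    rid = references["crown_id"].astype(str).to_numpy() if len(references) else np.array([], str)

    ii, jj = np.nonzero(M > iou_threshold)
    candidates = sorted(
        zip(-M[ii, jj], pid[ii], rid[jj], ii, jj),
        key=lambda c: (c[0], c[1], c[2]),
    )
    used_pred: set[int] = set()
    used_ref: set[int] = set()
    pairs = []
    for neg_iou, p, r, i, j in candidates:
        if i in used_pred or j in used_ref:
            continue
        used_pred.add(i)
        used_ref.add(j)
        pairs.append({"pred_id": p, "ref_id": r, "iou": -neg_iou})
    pairs_df = pd.DataFrame(pairs, columns=["pred_id", "ref_id", "iou"])
    return MatchResult(
        pairs=pairs_df,
        unmatched_predictions=[pid[i] for i in range(len(pid)) if i not in used_pred],
        unmatched_references=[rid[j] for j in range(len(rid)) if j not in used_ref],
        iou_threshold=iou_threshold,
    )


def precision_recall(
    match: MatchResult, n_predictions: int, n_references: int
) -> tuple[float | None, float | None]:
    """(precision, recall) of a match; None where the denominator is 0."""
    tp = match.n_pairs
    precision = tp / n_predictions if n_predictions else None
    recall = tp / n_references if n_references else None
    return precision, recall


@dataclass
class OverstoryReport:
    n_in: int = 0
    n_kept: int = 0
    n_not_live: int = 0
    n_small_dbh: int = 0
    n_no_coordinates: int = 0
    n_outside_chm: int = 0
    n_below_canopy: int = 0


def select_overstory_stems(
    stems: pd.DataFrame,
    chm: ChmRaster,
    min_dbh_cm: float = 10.0,
    search_radius_m: float = 4.0,
    height_tolerance_m: float = 3.0,
) -> tuple[pd.DataFrame, OverstoryReport]:
    """Field stems likely to be visible from above.

    Keeps stems that are live, have DBH >= ``min_dbh_cm``, carry
    coordinates, and whose recorded height reaches to within
    ``height_tolerance_m`` of the local canopy surface — the maximum valid
    CHM value within ``search_radius_m`` of the stem (the radius absorbs
    stem geolocation error). Stems outside the CHM, or with no valid CHM
    cell nearby, are excluded and counted, not raised.

    Removal counts are attributed to the first failing criterion in the
    order: status, DBH, coordinates, CHM coverage, canopy height.
    """
    report = OverstoryReport(n_in=len(stems))
    keep_rows = []
    for s in stems.itertuples(index=True):
        if s.status != "live":
            report.n_not_live += 1
            continue
        if not (pd.notna(s.dbh_cm) and s.dbh_cm >= min_dbh_cm):
            report.n_small_dbh += 1
            continue
        if pd.isna(s.x) or pd.isna(s.y):
            report.n_no_coordinates += 1
            continue
        ext = chm.extent
        if not (ext.xmin <= s.x <= ext.xmax and ext.ymin <= s.y <= ext.ymax):
            report.n_outside_chm += 1
            continue
        local_max = chm.max_in_radius(s.x, s.y, search_radius_m)
        if np.isnan(local_max):
            report.n_outside_chm += 1
            continue
        if pd.isna(s.height_m) or s.height_m < local_max - height_tolerance_m:
            report.n_below_canopy += 1
            continue
        keep_rows.append(s.Index)
    kept = stems.loc[keep_rows].copy()
    report.n_kept = len(kept)
    return kept, report


@dataclass
class StemRecallResult:
    recall: float | None
    assignment: pd.DataFrame  # columns stem_id, crown_id
    n_stems: int
    n_matched: int


def stem_recall(predictions: pd.DataFrame, stems: pd.DataFrame) -> StemRecallResult:
    """Fraction of field stems lying inside some prediction, each
    prediction usable at most once.

    Containment is boundary-inclusive. The exclusive-assignment rule is
    resolved by maximum-cardinality matching on the stem-in-box bipartite
    graph, so the result does not depend on input order. With zero stems
    the recall is undefined (None).
    """
    n_stems = len(stems)
    if n_stems == 0:
        return StemRecallResult(None, pd.DataFrame(columns=["stem_id", "crown_id"]), 0, 0)
    sx = stems["x"].to_numpy(float)
    sy = stems["y"].to_numpy(float)
    inside = (
        (sx[:, None] >= predictions["xmin"].to_numpy()[None, :])
        & (sx[:, None] <= predictions["xmax"].to_numpy()[None, :])
        & (sy[:, None] >= predictions["ymin"].to_numpy()[None, :])
        & (sy[:, None] <= predictions["ymax"].to_numpy()[None, :])
    ) if len(predictions) else np.zeros((n_stems, 0), bool)
    graph = csr_matrix(inside)
    match = maximum_bipartite_matching(graph, perm_type="column")
    rows = []
    for i in range(n_stems):
        j = match[i]
        if j != -1:
            rows.append(
                {
                    "stem_id": str(stems["stem_id"].iloc[i]),
                    "crown_id": str(predictions["crown_id"].iloc[j]),
                }
            )
    assignment = pd.DataFrame(rows, columns=["stem_id", "crown_id"])
    return StemRecallResult(len(rows) / n_stems, assignment, n_stems, len(rows))


def pair_stems_to_crowns(
    stems: pd.DataFrame, predictions: pd.DataFrame
) -> pd.DataFrame:
    """Field/predicted height pairs for matched stems.

    Uses the :func:`stem_recall` assignment; each matched stem contributes
    one row ``(field_height, predicted_height, site)`` with the crown's
    LiDAR-attributed height. Pairs with an absent height on either side
    are dropped.
    """
    result = stem_recall(predictions, stems)
    if not len(result.assignment):
        return pd.DataFrame(columns=["field_height", "predicted_height", "site"])
    merged = result.assignment.merge(
        stems[["stem_id", "height_m", "site"]].rename(columns={"height_m": "field_height"}),
        on="stem_id",
    ).merge(
        predictions[["crown_id", "height_m"]].rename(columns={"height_m": "predicted_height"}),
        on="crown_id",
    )
    out = merged[["field_height", "predicted_height", "site"]].dropna()
    return out.reset_index(drop=True)


@dataclass
class HeightValidationReport:
    """Mixed-model fit of field height on predicted height."""

    intercept: float
    slope: float
    site_intercept_var: float
    residual_var: float
    rmse_m: float
    mean_bias_m: float  #: mean(predicted - field); positive = predictions taller
    n_pairs: int
    n_sites: int
    model: str = "field ~ predicted + (1 | site), REML"
    ols_fallback: bool = False


def height_validation(pairs: pd.DataFrame, min_pairs_per_site: int = 3) -> HeightValidationReport:
    """Validate attributed crown heights against field-measured heights.

    Fits ``field = b0 + b1 * predicted + u_site + e`` with a site-level
    random intercept by restricted maximum likelihood; sites with fewer
    than ``min_pairs_per_site`` pairs are excluded from the fit. The
    reported RMSE is the root mean square of conditional residuals, i.e.
    after subtracting each site's predicted intercept. With a single site
    the model degrades to ordinary least squares and the report flags it.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    counts = pairs.groupby("site").size()
    ok_sites = counts[counts >= min_pairs_per_site].index
    data = pairs[pairs["site"].isin(ok_sites)].reset_index(drop=True)
    if len(data) < 3:
        raise ValueError("too few height pairs for validation")
    n_sites = data["site"].nunique()

    if n_sites < 2:
        X = sm.add_constant(data["predicted_height"])
        fit = sm.OLS(data["field_height"], X).fit()
        resid = fit.resid.to_numpy()
        return HeightValidationReport(
            intercept=float(fit.params.iloc[0]),
            slope=float(fit.params.iloc[1]),
            site_intercept_var=0.0,
            residual_var=float(np.mean(resid**2)),
            rmse_m=float(np.sqrt(np.mean(resid**2))),
            mean_bias_m=float((data["predicted_height"] - data["field_height"]).mean()),
            n_pairs=len(data),
            n_sites=n_sites,
            model="field ~ predicted, OLS (single site)",
            ols_fallback=True,
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = smf.mixedlm(
            "field_height ~ predicted_height", data, groups=data["site"]
        ).fit(reml=True)
    fixed = fit.fe_params
    try:
        re = fit.random_effects  # site -> predicted intercept
        u = data["site"].map(lambda s: float(re[s].iloc[0])).to_numpy()
    except ValueError:
        # singular site covariance (tau^2 -> 0): all intercepts shrink to 0
        u = np.zeros(len(data))
    fitted = fixed.iloc[0] + fixed.iloc[1] * data["predicted_height"].to_numpy() + u
    resid = data["field_height"].to_numpy() - fitted
    return HeightValidationReport(
        intercept=float(fixed.iloc[0]),
        slope=float(fixed.iloc[1]),
        site_intercept_var=float(fit.cov_re.iloc[0, 0]),
        residual_var=float(fit.scale),
        rmse_m=float(np.sqrt(np.mean(resid**2))),
        mean_bias_m=float((data["predicted_height"] - data["field_height"]).mean()),
        n_pairs=len(data),
        n_sites=n_sites,
    )
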