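# Methods

## The problem

Landscape-scale tree inventories are increasingly built by detecting
individual crowns in airborne RGB imagery and enriching the detections with
LiDAR. The detector itself is a separate concern; everything after it —
confidence filtering, height attribution, the minimum-height rule that
separates trees from shrubs, and the validation of the released records
against image annotations and field surveys — is a reproducible, testable
pipeline. `crownscape` implements that pipeline together with a synthetic
forest-scene generator rich enough to exercise every stage, so the whole
workflow can be verified without airborne data or trained model weights.

## Data model

A crown record is an axis-aligned bounding box in planar meter coordinates
with a confidence score in [0, 1], an attributed tree height (m), a box
area (m²), and site/year labels. Released records satisfy: score ≥ 0.15,
height ≥ 3 m, area exactly width × height, and a non-degenerate box. A
"tree" is operationally anything at least 3 m tall; only overstory trees —
crowns visible from above — can appear, since subcanopy stems are invisible
to an airborne detector.

## Synthetic scenes

The generator draws stems from a homogeneous Poisson process (optionally a
Thomas cluster process with the same overall intensity), heights from a
lognormal law, and crown radii from the power allometry `r = a·h^b` with
lognormal noise. Defaults: density 0.01 stems/m², height median 12 m with
σ_log 0.45, `a = 0.5, b = 0.6`, radius noise σ 0.15 — a mid-density
temperate stand with crowns of 2–5 m radius. A tree is *understory* iff its
stem lies inside the crown disk of a tree taller by more than the overtop
margin (default 2 m); this is a stated stand-in for operational
overstory-selection protocols, whose exact field rules vary. The true crown
box of an overstory tree is the square circumscribing its crown disk,
clipped to the scene.

**Crown surface and LiDAR.** Each crown occupies the vertical band from
60 % of tree height to the apex. The default vertical profile is a
half-ellipsoid cap, `z(d) = 0.6h + 0.4h·√(1 − (d/r)²)`; `paraboloid` and
`cone` profiles are available. The ellipsoid default is deliberate: mature
crowns are flat-topped, and a flat-topped profile keeps a high quantile of
sparse returns close to the apex — with a paraboloid, the area fraction of
a crown's box above `h − δ` is `πδ/(1.6h)`, which puts the 99th-quantile
height ≈ 0.005·h below the apex (0.2 m at 40 m); the ellipsoid halves that
bias. The point cloud is Poisson with default 6 pts/m² (typical of
operational airborne surveys), heights equal the tallest crown surface over
each return (ground 0 elsewhere) plus optional truncated Gaussian noise.
The CHM is the per-cell maximum of return heights on a half-open grid
(upper-left origin), NaN where no return fell; default resolution 0.5 m.

**Detector error model.** True boxes are independently missed with
`miss_prob` (default 0.2); surviving adjacent pairs (boundary gap ≤ 1 m)
are merged into their union envelope with `merge_prob` (default 0.1),
emulating the undersegmentation of dense stands; edges are jittered with
σ = 0.5 m; false boxes arrive as Poisson(20/ha) with lognormal half-sizes
(median 2 m). Confidence scores are Beta(6, 2) for true and Beta(2, 4) for
false boxes, floored at 0.05, so the 0.15 release floor is genuinely
exercised from both sides. All RNG consumption orders are fixed and
documented in the docstrings; every generator is bit-reproducible from
`(params, seed)`.

**Field surveys.** Tower plots are 40 × 40 m with two of four 20 × 20 m
quadrants sampled; distributed plots are single 20 × 20 m squares. Plots
are placed uniformly without overlap. Recorded stems carry Gaussian
geolocation error (default σ 1 m in the generator, 0.5 m in the campaign),
a height measured `growth_rate × lag_years` before the overflight (defaults
0.25 m/yr × 3 yr — the field campaign predates the flight), Gaussian height
error (σ 0.5 m), and DBH from `dbh = a·h^b` (a = 1.0, b = 1.15, lognormal
noise σ 0.1; a 20 m tree ≈ 31 cm DBH).

## Pipeline choices

- Thresholds are boundary-inclusive on the keep side: score ≥ 0.15 kept,
  height ≥ 3 m kept — matching exclusion rules phrased as "below X removed".
- Height attribution is the 99th quantile (linear interpolation between
  order statistics — the most common definition, stated so results are
  portable) of return heights inside the box, membership
  boundary-inclusive on all four edges so apex returns on shared edges are
  never lost.
- When only a CHM is available, a box's height is the maximum valid CHM
  value among cells whose center falls inside the box; the same height
  backs both the 3 m filter and the released record, since maintaining two
  height definitions for one record would be incoherent.
- Boxes containing no LiDAR return are dropped but counted in the run
  report — they model the recall a height filter loses to sparse LiDAR
  coverage, and the count lets a user quantify that loss.
- Inputs must share one planar metric frame. The text formats carry no CRS,
  so frame mismatch is detected by its observable symptom: if height data
  exist but no box receives any height, the run aborts.

## Evaluation choices

- Crown matching: the true-positive rule is IoU **strictly greater** than
  0.5. The assignment is greedy over candidates sorted by descending IoU
  with deterministic tie-breaks (prediction id, then reference id) — the
  standard detection-evaluation rule, fully specified so results are
  order-invariant and reproducible.
- Stem recall resolves the "each prediction counts once" exclusivity rule
  by maximum-cardinality bipartite matching (via SciPy's Hopcroft–Karp)
  rather than any greedy order: it is order-free and gives the rule its
  best-case value, i.e. it is conservative about claiming *failures*.
  Containment is boundary-inclusive.
- Overstory stem selection keeps live stems with DBH ≥ 10 cm, coordinates,
  and recorded height within `height_tolerance` (default 3 m) of the local
  CHM maximum within `search_radius` (default 4 m, sized to absorb stem
  geolocation error). Removal counts are reported per criterion.
- Height validation regresses **field height on predicted height** (the
  direction is stated in the fit report, since the reverse is equally
  defensible) with a site random intercept by REML, via statsmodels
  `MixedLM`. The RMSE uses conditional residuals (site intercepts
  predicted); sites with fewer than 3 pairs are excluded; a single site
  degrades to OLS with a flag. The report also carries the mean signed
  bias (predicted − field), which exposes the systematic "predictions
  taller" effect a survey lag induces.

## Landscape summaries

Crowns are assigned to density-raster cells (default 10 m ≙ 100 m² cells)
and to simulated plots by box centroid — exactly one assignment per crown,
so counts conserve. Simulated inventory plots mimic the tower design:
10,000 40 m plots per site, two random 20 m quadrants each (800 m²
sampled). Field-plot densities count stems with coordinates and height
≥ 3 m, falling back to DBH ≥ 15 cm when height was never recorded. Land
exclusions (water, bare ground) enter only as a user-supplied binary mask.
The allometry summary reports per-site means/medians of height and area,
density per hectare, and the mean per-crown height:area ratio.

## Interchange formats

Crowns read/write as CSV and GeoJSON, points as XYZ CSV, rasters as ESRI
ASCII grid, configs as YAML — the plain-text dialects of the geospatial
stack, each byte-stable for identical records (coordinates/heights/areas at
3 decimals, scores at 4). The release validator checks area consistency
exactly in memory and to the documented formatting precision for records
read back from disk.

## Study sizes and what the tests show

The bundled campaign uses four 9 ha sites (≈ 2,900 overstory crowns,
≈ 2.2 M LiDAR returns, 12 tower plots) — large enough that binomial
standard errors on precision/recall are below one point, small enough to
run in seconds. Statistical acceptance checks are property-based: matching
equals brute-force oracles on enumerable instances; measured recall and
precision recover the generating miss and false-positive rates within 3
binomial SE over 20-seed ensembles; the mixed model recovers its generating
residual σ within 15 %; plot sampling recovers generating density within
Monte-Carlo error; the CLI chain is byte-identical across runs.

Passing these tests shows the *workflow* is correct and calibrated under
its stated error model. It does not show that real detector errors are
independent Bernoulli misses, that real crowns are ellipsoid-capped disks,
or that field geolocation error is Gaussian — real airborne campaigns add
registration offsets, within-crown height heterogeneity, species-specific
allometry, and detector biases correlated with stand structure, none of
which the generator claims to capture.

## Known limitations

- Crown truth is a disk/box; no polygon crowns and no cross-tile merging.
- No ground classification: LiDAR inputs are assumed height-normalized.
- The merge model pairs each box at most once per scene; chains of three
  or more undersegmented crowns are not emitted.
- Binary vector/raster formats (Shapefile, LAS/LAZ, GeoTIFF) are out of
  scope; the text dialects carry the same information.
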