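# Methods

This note documents the models, parameter defaults and numerical choices
behind `phckit`, and what the synthetic-landscape tests do and do not show
about real data.

## Synthetic landscapes and ground truth

The generator (`phckit.landscape`) emulates the statistical structure of a
montane conservation region on a planar 300 m grid (default 150×150 cells,
45 km × 45 km):

- **Terrain** is Gaussian-smoothed white noise (kernel σ = 10 cells)
  rescaled to 232–5787 m, the elevational span of the giant panda range.
  Smoothing of noise gives tunable spatial autocorrelation without any
  external DEM; a `flat_terrain` option produces a constant field with
  exactly zero slope and ruggedness downstream.
- **Land cover** has four classes (nonforest, broadleaf, mixed, conifer).
  A smooth noise field plus a mid-elevation preference term is thresholded
  at the quantile realizing the configured forest fraction (default 0.7);
  forest cells split into broadleaf/mixed/conifer along noisy elevation
  terciles, reproducing low-broadleaf-to-high-conifer zonation.
- **Features.** Population patches (default 5, radius 5 cells) sit on
  mid-high ground with enforced mutual separation, so they are disjoint by
  construction. Roads follow least-elevation routes across the grid
  (Dijkstra over an elevation-penalized grid graph), settlements sit in low
  valleys near roads, and reserves buffer a configurable fraction of the
  patches (default 0.8). Reserves are deliberately compact — they protect
  the patches, not the whole suitable range — so gap analysis has something
  to find.
- **Ground truth** is a logistic-linear suitability: standardized features
  (an optimal-elevation bell over 1000–3000 m, forest quality ordered
  conifer > mixed > broadleaf, slope, log distances to roads and
  settlements, reserve membership) with strong coefficients (|β| ≈ 0.5–2.5)
  and intercept −2, giving a realistic landscape prevalence of roughly
  0.3 rather than a 50/50 landscape.
- **Occurrences.** Presences are drawn along survey transects with
  probability proportional to true suitability; pseudo-absences are drawn
  uniformly from transect cells at least 2 km (Euclidean, from *every*
  presence) away, one per presence. The 2 km exclusion buffer reflects the
  ~5 km² home range: a transect cell that close to a presence cannot be
  treated as an absence. Infeasible configurations (every transect cell
  inside some buffer) raise an error naming the constraint rather than
  silently relaxing it.

All randomness flows from one root seed through named per-stage
`SeedSequence` splits, so identical configurations reproduce landscapes and
occurrence sets bit-for-bit.

**What this does not emulate:** spatially biased survey effort, observer
error and imperfect detection, temporal change, and the irregular geometry
of real administrative and reserve boundaries. Passing recovery tests on
these landscapes shows the pipeline machinery is correct and statistically
consistent under its own assumptions — not that any particular real
landscape satisfies those assumptions.

## Covariates

Nine layers on one shared grid: elevation, terrain ruggedness (mean
absolute elevation difference to the 8 neighbors), slope (degrees, from
central differences), 3-class aspect (north / east-west / south, flat cells
assigned east/west as the deterministic middle category), 4-class forest
composition, reserve membership, and Euclidean distances to reserves,
settlements and roads. Distances are computed between cell centers
(`scipy.ndimage.distance_transform_edt`), so a cell containing a feature is
exactly 0. Coarser grids aggregate by block mean (continuous) or majority
vote with ties to the smallest class code (categorical); trailing partial
blocks are truncated, and a non-integer aggregation factor is floored with
a warning.

Collinearity screening uses VIF_j = 1/(1 − R²_j) from OLS of each column on
the others, with a cap of 10⁶ for perfectly collinear columns. Aspect
enters as an integer ordinal and forest composition as one-hot dummies with
the nonforest reference dropped — encodings are a documented package
choice. The retention threshold defaults to 5 and is configurable.

## Habitat ensemble

`HabitatSuitabilityModel.fit()` draws a fresh stratified 70/30 split per
repeat (10 repeats by default; resampling rather than a fixed split keeps
the evaluation honest about split variance). The six families map to:

| family | implementation |
|---|---|
| CTA | decision tree (depth ≤ 8, ≥ 5 samples/leaf) |
| FDA | shrinkage LDA on a piecewise-linear spline basis |
| GBM | gradient boosting (100 trees, depth 3, lr 0.1) |
| GLM | ridge-stabilized logistic regression |
| MARS | hinge-spline basis + L1 logistic regression (an adaptive piecewise-linear analogue, written here because no maintained MARS implementation exists in the scientific Python stack) |
| RF | random forest (200 trees) |

Hyperparameters are fixed and seeded; they are deliberately mainstream
rather than tuned. The exclusion rule is a disjunction: a family is dropped
if mean AUC < 0.85 **or** mean TSS < 0.85. Survivors are refit on all data
and ensembled as a TSS-weighted mean (the common cross-validation-weighted
convention; an unweighted option exists, and a zero total weight falls back
to the unweighted mean). AUC uses the rank statistic with ties counted
half; TSS is the true skill statistic max(sensitivity + specificity − 1).

Binarization searches all unique predicted values for the threshold
maximizing sensitivity + specificity, breaking ties toward the smallest
threshold (deterministic and exact). By default the threshold is calibrated
on the ensemble's predictions at all occurrence points — the
calibration-data convention — with an explicit hook for a held-out set.

## Gap analysis

Habitat cells are classified by whether their center lies strictly inside
the reserve union (centers exactly on a boundary count as outside), so
inside + outside = total holds exactly in cell counts. Areas are cell
counts × (cell size/1000)² km².

## Circuit connectivity

Resistance is the reciprocal of suitability with a floor:
r = 1/max(s, ε), ε = 10⁻³ by default (the reciprocal is undefined at 0; the
floor caps resistance at 1000). The raster graph uses an 8-neighborhood by
default; the edge between neighboring cells has resistance equal to the
arithmetic mean of the two cell resistances times the step length (1
orthogonal, √2 diagonal) — the "average resistance" raster convention — with
4-neighborhood and harmonic-mean options exposed. Population patches are
merged into super-nodes that short-circuit their member cells; parallel
edges created by the merge combine by conductance addition. All patch
super-nodes remain in the graph during every pairwise solve, which lets one
LU factorization of the grounded Laplacian (node 0 grounded, residual norm
well below 10⁻¹⁰ at desk scales) serve every pair.

Per pair, injecting +1/−1 A at the two terminals yields node potentials;
effective resistance is the terminal potential difference, and the per-cell
current map is half the sum of absolute incident edge currents (terminals
set to the injected 1 A). Kirchhoff residuals are checked per solve.

Corridors: cost-weighted distance (CWD) from each patch is the shortest
path cost over edge resistances; the least-cost path (LCP) comes from
Dijkstra predecessors, its geometric length from the stored step lengths.
The corridor is the cell set with cwd_a + cwd_b − lcp_cost ≤ cutoff; the
cutoff defaults to 20% of the LCP cost, a documented stand-in for the
undisclosed widths used by corridor-mapping GUIs.

Centrality follows the all-pairs current-flow convention on the abstract
patch-link network (one node per patch, one link per corridor, link
resistance = LCP cost): for every unordered patch pair a unit current is
injected and each link accumulates the absolute current it carries.
Disconnected networks are handled per component with a warning. The dense
pseudoinverse used here truncates the Laplacian's null mode with an
explicit `rcond=1e-10`; NumPy's default tolerance can leave the null
singular value un-truncated and corrupt the result.

## Prioritization

Six metric scores, each in [0, 1]:

- **Length** — 1 at ≤ 2 km (the within-patch seasonal movement distance),
  0 at 25 km, removal above 25 km (the maximum known dispersal distance),
  and (25 − L)/25 in between. This is the interpolation that reproduces the
  published worked examples (5 km → 0.8, 20 km → 0.2); it implies a small
  jump from 1.0 to 0.92 at 2 km, which we keep rather than silently
  replacing the rule.
- **Elevation** — 1 inside 1000–3000 m, linear decay to 0 at the range
  extremes (0 m and 4122 m).
- **Centrality, forest cover** — increasing min–max rescaling; **distance
  to settlements** — increasing (farther is safer); **distance to
  reserves** — decreasing (closer is more feasible). Range defaults are the
  published observed spans, but since they are themselves observed ranges
  the pipeline recomputes them from the candidate set by default
  (`use_observed_ranges`).

The composite is the unweighted mean of the six scores (optional weights in
config). Ranking is descending by composite with deterministic tie-breaks
(higher centrality, then shorter length, then id); the top-k (default 6)
are flagged PHCs. Criterion groups — biophysical (length, elevation),
biotic (forest, centrality), anthropogenic (settlement and reserve
distance) — are "met" when the group's mean score reaches a configurable
threshold (default 0.75), giving the Venn-style classification of
near-miss corridors.

## Pipeline

Stages `simulate → covariates → habitat → gaps → connect → prioritize`
communicate only through files (ASCII grids, GeoJSON, CSV, JSON), so any
stage can be re-run or replaced with user-supplied data on the same planar
grid. `manifest.json` records the resolved configuration, its hash, the
seed, per-stage timings and a SHA-256 per output file; deterministic stages
reproduce checksums exactly under a fixed seed.

## Problem sizes

Defaults were chosen so a complete run is comfortable on a laptop core: the
150×150 default landscape yields a ~22 500-node resistance graph whose
factorization and per-pair solves take seconds; the full pipeline completes
in well under a minute, and the test suite (including two full-scale
recovery fits and one end-to-end run) in about half a minute.

## Known limitations

- The MARS and FDA family slots are spline-basis analogues, not the
  original adaptive-forward-selection algorithms; their role in the
  ensemble (flexible additive discriminators) is preserved.
- Circuit pairwise solves keep all patch super-nodes in the graph; tools
  that remove non-focal regions will give slightly different currents near
  uninvolved patches.
- Corridor delimitation (the CWD cutoff) and the criterion-group threshold
  are conventions, not estimated quantities; both are exposed in config.
- Gap fractions on synthetic landscapes are small by construction (compact
  reserves around patches) and are not calibrated to any real reserve
  system.
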