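# phckit

Tools for identifying **priority habitat corridors** (PHCs) on raster
landscapes: ensemble habitat-suitability modeling, gap analysis of reserve
coverage, circuit-theory connectivity with least-cost corridor extraction,
and multi-criteria corridor prioritization. The pipeline was designed for
the giant panda (*Ailuropoda melanoleuca*) conservation-planning problem —
many isolated populations, limited resources, and far more candidate
corridors than any agency can build — but every stage is generic to any
species with presence records and raster covariates.

The package ships a seeded synthetic-landscape generator that emulates a
montane study region (correlated terrain, four-class forest mosaic,
valley roads and settlements, reserves, survey transects) with a **known
ground-truth suitability function**, so the whole pipeline is testable for
parameter recovery without any external GIS data.

## Method

1. **Habitat model.** Presences come from survey transects; pseudo-absences
   are drawn on transects at least 2 km from every presence. Six classifier
   families — CTA, FDA, GBM, GLM, MARS, RF — are evaluated by repeated
   stratified 70/30 splits (10 repeats). AUC is the rank statistic
   P(score(presence) > score(absence)); TSS = max over thresholds of
   (sensitivity + specificity − 1). Families with mean AUC < 0.85 or mean
   TSS < 0.85 are dropped; survivors are refit on all data and combined as a
   TSS-weighted mean. The continuous map is binarized at the threshold
   maximizing sensitivity + specificity.
2. **Gap analysis.** The binary habitat map is overlaid with reserve
   polygons (cell-center membership) to report protected vs unprotected
   suitable area in km².
3. **Connectivity.** Resistance = 1 / max(suitability, ε). The raster
   becomes a resistor network (8-neighborhood, diagonal edges scaled by √2,
   edge resistance = mean of cell resistances); population patches are
   short-circuited super-nodes. For each patch pair, a grounded-Laplacian
   solve yields effective resistance and a per-cell current map; the
   least-cost path and a cost-weighted-distance swath around it form the
   corridor; current-flow centrality over the patch-link network measures
   each corridor's importance.
4. **Prioritization.** Each corridor ≤ 25 km is scored on six metrics
   (length, mean elevation, centrality, forest cover, distance to
   settlements, distance to reserves), each mapped linearly to [0, 1];
   corridors > 25 km (beyond the species' maximum dispersal distance) are
   removed. The composite is the mean of the six scores; the top-k become
   PHCs, and corridors are also classified by which of the biophysical /
   biotic / anthropogenic criterion groups they satisfy.

## Worked example

```python
from phckit import HabitatSuitabilityModel, LandscapeConfig, TrueSuitability
from phckit.landscape import (generate_terrain, generate_landcover, place_features,
                              generate_transects, sample_occurrences)
from phckit.covariates import build_stack

cfg = LandscapeConfig(random_seed=1)          # 150x150 cells at 300 m
elev = generate_terrain(cfg)
lc = generate_landcover(cfg, elev)
feats = place_features(cfg, elev)
stack = build_stack(elev, lc, feats)
truth = TrueSuitability().evaluate(stack)     # known ground truth
occ = sample_occurrences(truth, generate_transects(cfg, elev), cfg)

res = HabitatSuitabilityModel(occ, stack).fit(seed=42)
print(res.summary())
```

```
Habitat suitability ensemble
====================================================
algorithm          AUC           TSS    included
----------------------------------------------------
CTA         0.930±0.018   0.775±0.032       no
FDA         0.958±0.011   0.816±0.025       no
GBM         0.978±0.008   0.882±0.032      yes
GLM         0.949±0.012   0.816±0.031       no
MARS        0.967±0.009   0.851±0.024      yes
RF          0.984±0.006   0.889±0.029      yes
----------------------------------------------------
ensemble members: GBM, MARS, RF
```

Tree ensembles discriminate best here (as is typical for presence/absence
data with threshold-like responses); only GBM, MARS and RF clear the dual
0.85 filter. Binarizing,

```python
product = res.binarize()
print(f"threshold = {product.threshold:.3f}")
```

gives `threshold = 0.545` and a binary habitat map covering ~1 073 km² of
the 2 025 km² synthetic region.

The same run from the shell, end to end:

```sh
phckit run-all --seed 1 --outdir run1
```

writes the covariate stack, suitability/binary maps, gap report, per-pair
current maps, corridor geometries and the scored corridor table. With the
default five populations (10 candidate pairs), seed 1 keeps 7 corridors
under the 25 km dispersal limit; the top of `run1/scored_corridors.csv`:

```
 corridor_id  length_km  centrality  forest_cover_pct  composite  rank  is_phc                groups_met
           4       5.42        3.01             85.90       0.83     1    True anthropogenic+biophysical
           1      11.22        2.07             88.54       0.66     2    True anthropogenic+biophysical
           3      19.32        1.66             94.35       0.59     3    True             anthropogenic
```

The short, high-current corridor 4 ranks first: it is near the optimal
elevation band, well forested, far from settlements and adjacent to a
reserve — exactly the profile the multi-criteria filter is designed to
surface.

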