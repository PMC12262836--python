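"""Covariate stack construction: distance transforms, grid aggregation,
collinearity (VIF) screening, and design-matrix extraction at points.

The stack mirrors the nine predictors typical of montane habitat modeling:
elevation, terrain ruggedness, slope, aspect (3-class), forest composition
(4-class), reserve membership, and Euclidean distances to reserves,
settlements and roads — all on one shared planar grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry

from . import landscape as ls
from .raster import RasterGrid

__all__ = [
    "STACK_LAYERS",
    "VIFReport",
    "rasterize_features",
    "distance_transform",
    "aggregate_to_grid",
    "build_stack",
    "design_matrix",
    "compute_vif",
]

STACK_LAYERS = (
    "elevation",
    "ruggedness",
    "slope",
    "aspect",
    "forest_composition",
    "in_reserve",
    "dist_reserve",
    "dist_residential",
    "dist_road",
)

VIF_CAP = 1e6


def rasterize_features(features: list[BaseGeometry], ref: RasterGrid) -> np.ndarray:
    """Boolean mask of cells touched by any feature.

    Points mark the containing cell; lines mark every cell they cross
    (sampled at half-cell resolution); polygons mark cells whose center they
    cover.
    """
    if not features:
        raise ValueError("empty feature set: distance is undefined")
    mask = np.zeros(ref.shape, dtype=bool)
    xs, ys = ref.cell_centers()
    for geom in features:
        if geom.is_empty:
            continue
        if isinstance(geom, Point):
            try:
                mask[ref.index_of(geom.x, geom.y)] = True
            except IndexError:
                pass
        elif isinstance(geom, LineString):
            step = ref.cell_size_m / 2.0
            n = max(int(np.ceil(geom.length / step)), 1)
            for i in range(n + 1):
                p = geom.interpolate(i * geom.length / n)
                try:
                    mask[ref.index_of(p.x, p.y)] = True
                except IndexError:
                    pass
        else:  # polygonal
            mask |= shapely.covers(geom, shapely.points(np.stack([xs, ys], axis=-1)))
    return mask


def distance_transform(features: list[BaseGeometry], ref: RasterGrid) -> RasterGrid:
    """Per-cell Euclidean distance (m) to the nearest feature cell.

    Distances are measured between cell centers on the raster grid; cells
    containing a feature get 0.
    """
    mask = rasterize_features(features, ref)
    if not mask.any():
        raise ValueError("no feature intersects the raster extent")
    dist = ndimage.distance_transform_edt(~mask, sampling=ref.cell_size_m)
    return ref.like(dist)


def aggregate_to_grid(
    raster: RasterGrid, target_cell_m: float, categorical: bool = False
) -> RasterGrid:
    """Block-aggregate to a coarser grid: mean for continuous layers,
    majority (ties to the smallest class code) for categorical layers.

    Trailing rows/columns that do not fill a whole block are truncated; a
    non-integer aggregation factor is floored with a warning.
    """
    if target_cell_m < raster.cell_size_m:
        raise ValueError("target cell size must be >= source cell size")
    factor_f = target_cell_m / raster.cell_size_m
    factor = int(np.floor(factor_f + 1e-9))
    if abs(factor_f - factor) > 1e-9:
        warnings.warn(
            f"non-integer aggregation factor {factor_f:.4g}; "
            f"using block size {factor} (output cell {factor * raster.cell_size_m} m)"
        )
    if factor == 1:
        return RasterGrid(
            raster.values.copy(), raster.cell_size_m, raster.origin_xy,
            raster.nodata_mask.copy(),
        )
    nr = (raster.nrows // factor) * factor
    nc = (raster.ncols // factor) * factor
    blocks = raster.values[:nr, :nc].reshape(nr // factor, factor, nc // factor, factor)
    if categorical:
        flat = blocks.transpose(0, 2, 1, 3).reshape(nr // factor, nc // factor, -1)
        classes = np.unique(raster.values)
        counts = np.stack([(flat == k).sum(axis=-1) for k in classes], axis=-1)
        out = classes[np.argmax(counts, axis=-1)]  # argmax ties -> first class
    else:
        out = blocks.mean(axis=(1, 3))
    x0, y0 = raster.origin_xy
    new_cell = factor * raster.cell_size_m
    # keep the TOP-left corner aligned; the lower-left origin shifts when
    # trailing rows are truncated
    new_y0 = y0 + (raster.nrows - nr) * raster.cell_size_m
    return RasterGrid(out, new_cell, (x0, new_y0))


def build_stack(
    elevation: RasterGrid,
    landcover: RasterGrid,
    features: ls.LandscapeFeatures,
) -> dict[str, RasterGrid]:
    """Assemble the nine-layer covariate stack on the elevation grid."""
    topo = ls.derive_topography(elevation)
    reserve_mask = (
        rasterize_features(features.reserves, elevation)
        if features.reserves
        else np.zeros(elevation.shape, dtype=bool)
    )
    if features.reserves:
        dist_reserve = distance_transform(features.reserves, elevation)
    else:
        dist_reserve = elevation.like(np.full(elevation.shape, np.inf))
    stack = {
        "elevation": elevation,
        "ruggedness": topo["ruggedness"],
        "slope": topo["slope"],
        "aspect": topo["aspect"],
        "forest_composition": landcover,
        "in_reserve": elevation.like(reserve_mask.astype(int)),
        "dist_reserve": dist_reserve,
        "dist_residential": distance_transform(features.residential, elevation),
        "dist_road": distance_transform(features.roads, elevation),
    }
    return stack


def design_matrix(stack: dict[str, RasterGrid], xy: np.ndarray) -> pd.DataFrame:
    """Numeric covariate matrix at planar points.

    Aspect enters as an integer-coded ordinal; forest composition as one-hot
    dummies with the nonforest reference class dropped; remaining layers as
    their raw numeric values.
    """
    xy = np.asarray(xy, dtype=float)
    ref = stack["elevation"]
    rc = np.array([ref.index_of(x, y) for x, y in xy])
    cols: dict[str, np.ndarray] = {}
    for name in ("elevation", "ruggedness", "slope", "aspect", "in_reserve",
                 "dist_reserve", "dist_residential", "dist_road"):
        cols[name] = stack[name].values[rc[:, 0], rc[:, 1]].astype(float)
    lc = stack["forest_composition"].values[rc[:, 0], rc[:, 1]]
    for code, label in ((ls.BROADLEAF, "broadleaf"), (ls.MIXED, "mixed"),
                        (ls.CONIFER, "conifer")):
        cols[f"forest_{label}"] = (lc == code).astype(float)
    return pd.DataFrame(cols)


@dataclass
class VIFReport:
    """Per-variable variance inflation factors and the retained flags."""

    table: pd.DataFrame  # columns: variable, vif, retained
    threshold: float

    @property
    def retained(self) -> list[str]:
        return list(self.table.loc[self.table["retained"], "variable"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def compute_vif(design: pd.DataFrame, threshold: float = 5.0) -> VIFReport:
    """VIF_j = 1 / (1 - R^2_j) from regressing column j on all the others
    (with intercept).  Perfectly collinear columns get the cap value and are
    flagged not-retained.  Columns are retained iff VIF < threshold.
    """
    X = design.to_numpy(dtype=float)
    n, k = X.shape
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} sample points for {k} variables")
    rows = []
    for j, name in enumerate(design.columns):
        y = X[:, j]
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_tot = np.sum((y - y.mean()) ** 2)
        if ss_tot <= 0:  # constant column: undefined, treat as non-collinear
            vif = 1.0
        else:
            r2 = 1.0 - np.sum(resid**2) / ss_tot
            vif = VIF_CAP if r2 >= 1.0 - 1.0 / VIF_CAP else min(1.0 / (1.0 - r2), VIF_CAP)
        rows.append((name, vif, bool(vif < threshold)))
    table = pd.DataFrame(rows, columns=["variable", "vif", "retained"])
    return VIFReport(table, threshold)
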