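"""Seeded synthetic landscapes with known ground-truth habitat suitability.

This module emulates the statistical structure of a mountain study region so
that the whole corridor-prioritization pipeline can be exercised and tested
without any external GIS data: spatially correlated terrain, a four-class
forest mosaic whose composition tracks elevation, population patches on high
ground, roads and settlements in the valleys, nature reserves over a
configurable fraction of the patches, survey transects, and
presence/pseudo-absence occurrences drawn from a known suitability function.

Because the true suitability function is known, downstream habitat models can
be tested for parameter recovery (does the fitted ensemble reconstruct the
truth?) rather than merely for not crashing.

All geometry is planar meters; row 0 of every raster is the northern edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from scipy.special import expit
from shapely.geometry import LineString, Point, Polygon

from .raster import RasterGrid

__all__ = [
    "LandscapeConfig",
    "TrueSuitability",
    "SurveyTransect",
    "OccurrenceSet",
    "LandscapeFeatures",
    "generate_terrain",
    "derive_topography",
    "generate_landcover",
    "place_features",
    "generate_transects",
    "sample_occurrences",
]

ASPECT_NORTH, ASPECT_EASTWEST, ASPECT_SOUTH = 0, 1, 2
# land-cover codes
NONFOREST, BROADLEAF, MIXED, CONIFER = 0, 1, 2, 3
FOREST_CLASSES = (BROADLEAF, MIXED, CONIFER)


class PlacementError(RuntimeError):
    """Raised when disjoint feature placement is impossible on the grid."""


class InfeasibleSamplingError(RuntimeError):
    """Raised when the pseudo-absence distance constraint cannot be met."""


@dataclass
class LandscapeConfig:
    """Configuration of a synthetic landscape.

    Defaults describe a 45 km x 45 km mountain region on a 300 m grid with
    the elevational span of the giant panda range (232-5787 m), five isolated
    population patches, and survey pressure comparable (per unit area) to a
    transect-based sign census.
    """

    grid_rows: int = 150
    grid_cols: int = 150
    cell_size_m: float = 300.0
    elevation_range_m: tuple[float, float] = (232.0, 5787.0)
    n_populations: int = 5
    n_transects: int = 100
    n_presences: int = 400
    n_pseudo_absences: int | None = None  # None -> 1:1 with presences
    pseudo_absence_min_distance_m: float = 2000.0
    home_range_km2: float = 5.0
    forest_fraction: float = 0.7
    terrain_smoothness_cells: float = 10.0
    flat_terrain: bool = False
    n_roads: int = 3
    n_residential: int = 15
    patch_radius_cells: int = 5
    reserve_fraction: float = 0.8
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_rows < 10 or self.grid_cols < 10:
            raise ValueError("grid must be at least 10x10")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.pseudo_absence_min_distance_m <= 0:
            raise ValueError("pseudo_absence_min_distance_m must be positive")
        if self.n_populations < 2:
            raise ValueError("need at least 2 populations to form corridors")
        lo, hi = self.elevation_range_m
        if not lo < hi:
            raise ValueError("elevation_range_m must be an increasing interval")
        if not 0.0 <= self.forest_fraction <= 1.0:
            raise ValueError("forest_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["elevation_range_m"] = list(self.elevation_range_m)
        return d


@dataclass
class SurveyTransect:
    """A survey line: an identifier, an ordered polyline and its arc length."""

    id: int
    polyline: np.ndarray  # (n_vertices, 2) planar coordinates
    length_m: float

    @classmethod
    def from_vertices(cls, tid: int, vertices: np.ndarray) -> "SurveyTransect":
        vertices = np.asarray(vertices, dtype=float)
        if vertices.shape[0] < 2:
            raise ValueError("a transect needs at least 2 vertices")
        seg = np.diff(vertices, axis=0)
        return cls(tid, vertices, float(np.hypot(seg[:, 0], seg[:, 1]).sum()))

    def as_linestring(self) -> LineString:
        return LineString(self.polyline)


@dataclass
class OccurrenceSet:
    """Labeled presence / pseudo-absence points tied to survey transects."""

    records: pd.DataFrame  # columns: x, y, label, transect_id

    LABELS = ("presence", "pseudo_absence")

    def __post_init__(self) -> None:
        required = {"x", "y", "label", "transect_id"}
        if not required.issubset(self.records.columns):
            raise ValueError(f"records must have columns {sorted(required)}")
        bad = set(self.records["label"]) - set(self.LABELS)
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    @property
    def presences(self) -> pd.DataFrame:
        return self.records[self.records["label"] == "presence"]

    @property
    def pseudo_absences(self) -> pd.DataFrame:
        return self.records[self.records["label"] == "pseudo_absence"]

    def min_presence_distance(self) -> float:
        """Smallest distance from any pseudo-absence to its nearest presence."""
        pres = self.presences[["x", "y"]].to_numpy()
        absn = self.pseudo_absences[["x", "y"]].to_numpy()
        if len(pres) == 0 or len(absn) == 0:
            return np.inf
        d, _ = cKDTree(pres).query(absn)
        return float(np.min(d))

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))


@dataclass
class LandscapeFeatures:
    """Vector features of a synthetic landscape."""

    patches: list[Polygon]
    patch_cells: list[np.ndarray]  # (n, 2) row/col indices per population patch
    reserves: list[Polygon]
    roads: list[LineString]
    residential: list[Point]


@dataclass
class TrueSuitability:
    """Ground-truth suitability: a linear predictor through a logistic link.

    The coefficients act on interpretable transforms of the covariate stack
    (an elevational preference bell, forest quality, slope, log distances to
    roads/settlements, reserve membership), each standardized over valid
    cells, so "strong coefficients" have comparable meaning across layers.
    """

    coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "elevation_band": 2.5,
            "forest_quality": 2.0,
            "slope": -1.2,
            "dist_road": 0.8,
            "dist_residential": 1.0,
            "in_reserve": 0.5,
        }
    )
    intercept: float = -2.0
    optimal_elevation_m: tuple[float, float] = (1000.0, 3000.0)

    def features(self, stack: dict[str, RasterGrid]) -> dict[str, np.ndarray]:
        elev = stack["elevation"].values
        lo, hi = self.optimal_elevation_m
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        # 1 inside the optimal band, Gaussian decay outside it
        excess = np.maximum(np.abs(elev - mid) - half, 0.0)
        band = np.exp(-0.5 * (excess / 700.0) ** 2)
        lc = stack["forest_composition"].values
        quality = np.select(
            [lc == CONIFER, lc == MIXED, lc == BROADLEAF], [1.0, 0.8, 0.5], 0.0
        )
        return {
            "elevation_band": band,
            "forest_quality": quality,
            "slope": stack["slope"].values,
            "dist_road": np.log1p(stack["dist_road"].values),
            "dist_residential": np.log1p(stack["dist_residential"].values),
            "in_reserve": stack["in_reserve"].values,
        }

    def evaluate(self, stack: dict[str, RasterGrid]) -> RasterGrid:
        """Suitability in [0, 1] on the stack's grid (logistic link)."""
        feats = self.features(stack)
        ref = stack["elevation"]
        eta = np.full(ref.shape, self.intercept, dtype=float)
        for name, coef in self.coefficients.items():
            f = feats[name].astype(float)
            mu, sd = f.mean(), f.std()
            if sd > 0:
                f = (f - mu) / sd
            else:
                f = f - mu
            eta += coef * f
        return ref.like(expit(eta))


# ---------------------------------------------------------------------------
# terrain and topography


def generate_terrain(config: LandscapeConfig) -> RasterGrid:
    """Smooth correlated elevation field rescaled into the configured range.

    Gaussian smoothing of white noise gives a field with tunable spatial
    autocorrelation (``terrain_smoothness_cells`` is the kernel sigma).  With
    ``flat_terrain=True`` a constant mid-range field is returned, which makes
    downstream slope and ruggedness exactly zero.
    """
    rng = np.random.default_rng(config.random_seed)
    lo, hi = config.elevation_range_m
    shape = (config.grid_rows, config.grid_cols)
    if config.flat_terrain:
        return RasterGrid(np.full(shape, 0.5 * (lo + hi)), config.cell_size_m)
    noise = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(noise, sigma=config.terrain_smoothness_cells)
    smin, smax = smooth.min(), smooth.max()
    elev = lo + (smooth - smin) / (smax - smin) * (hi - lo)
    return RasterGrid(elev, config.cell_size_m)


def derive_topography(elevation: RasterGrid) -> dict[str, RasterGrid]:
    """Slope (deg), 3-class aspect and terrain ruggedness from elevation.

    Slope and aspect come from central-difference gradients of the elevation
    surface; aspect (the compass direction the cell faces, i.e. of steepest
    descent) is classified into north / east-west / south, with flat cells
    assigned east/west as the deterministic middle category.  Ruggedness is
    the mean absolute elevation difference to the 8 neighbors (TRI).
    """
    valid = ~elevation.nodata_mask
    if valid.sum() == 0:
        raise ValueError("elevation raster holds no valid cells")
    if elevation.nrows < 3 or elevation.ncols < 3:
        raise ValueError("need at least a 3x3 raster for topography")
    z = elevation.values.astype(float)
    cs = elevation.cell_size_m
    # axis 0 increases southward, so the map-frame northward derivative is
    # the negative of the row-wise gradient
    dz_drow, dz_dcol = np.gradient(z, cs)
    gx, gy = dz_dcol, -dz_drow
    slope = np.degrees(np.arctan(np.hypot(gx, gy)))

    # downslope (facing) direction; bearing measured clockwise from north
    bearing = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    aspect = np.full(z.shape, ASPECT_EASTWEST, dtype=int)
    steep = np.hypot(gx, gy) > 1e-12
    north = steep & ((bearing < 45.0) | (bearing >= 315.0))
    south = steep & (bearing >= 135.0) & (bearing < 225.0)
    aspect[north] = ASPECT_NORTH
    aspect[south] = ASPECT_SOUTH

    # TRI: mean |dz| to the 8 neighbors, edge-replicated
    acc = np.zeros_like(z)
    cnt = 0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            if dr == 0 and dc == 0:
                continue
            shifted = np.roll(np.roll(z, dr, axis=0), dc, axis=1)
            # undo wrap-around at the borders by clamping to the edge value
            if dr == 1:
                shifted[0, :] = z[0, :]
            elif dr == -1:
                shifted[-1, :] = z[-1, :]
            if dc == 1:
                shifted[:, 0] = z[:, 0]
            elif dc == -1:
                shifted[:, -1] = z[:, -1]
            acc += np.abs(z - shifted)
            cnt += 1
    tri = acc / cnt

    return {
        "slope": elevation.like(slope),
        "aspect": elevation.like(aspect),
        "ruggedness": elevation.like(tri),
    }


# ---------------------------------------------------------------------------
# land cover


def generate_landcover(config: LandscapeConfig, elevation: RasterGrid) -> RasterGrid:
    """Four-class forest mosaic whose composition tracks elevation.

    A smooth noise field plus an elevational suitability term is thresholded
    at the quantile that realizes ``forest_fraction`` of forest cells; forest
    cells are then split into broadleaf / mixed / conifer by (noisy)
    elevation terciles, reproducing the usual low-broadleaf-to-high-conifer
    zonation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 101]))
    z = elevation.values
    lo, hi = config.elevation_range_m
    frac = config.forest_fraction
    if frac == 0.0:
        return elevation.like(np.full(z.shape, NONFOREST, dtype=int))

    zn = (z - lo) / (hi - lo)
    # forests favor mid elevations; valley floors are cleared, peaks are bare
    elev_term = np.exp(-0.5 * ((zn - 0.45) / 0.30) ** 2)
    noise = ndimage.gaussian_filter(rng.standard_normal(z.shape), sigma=4.0)
    noise = (noise - noise.mean()) / (noise.std() + 1e-12)
    score = elev_term + 0.35 * noise
    cut = np.quantile(score, 1.0 - frac)
    forest = score >= cut

    lc = np.full(z.shape, NONFOREST, dtype=int)
    zone = zn + 0.08 * ndimage.gaussian_filter(rng.standard_normal(z.shape), sigma=3.0)
    fz = zone[forest]
    t1, t2 = np.quantile(fz, [1 / 3, 2 / 3]) if fz.size else (0.0, 0.0)
    sub = np.full(fz.shape, MIXED, dtype=int)
    sub[fz < t1] = BROADLEAF
    sub[fz >= t2] = CONIFER
    lc[forest] = sub
    return elevation.like(lc)


# ---------------------------------------------------------------------------
# vector features


def _grid_graph_lowland(elevation: np.ndarray, cell: float):
    """Sparse 8-neighbor graph with edge costs favoring low elevation."""
    nr, nc = elevation.shape
    idx = np.arange(nr * nc).reshape(nr, nc)
    zn = (elevation - elevation.min()) / (np.ptp(elevation) + 1e-12)
    cost = 1.0 + 8.0 * zn  # valleys are cheap
    rows, cols, data = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        a, b = idx[r0, c0].ravel(), idx[r1, c1].ravel()
        w = 0.5 * (cost[r0, c0].ravel() + cost[r1, c1].ravel())
        if dr and dc:
            w = w * np.sqrt(2.0)
        rows.append(a)
        cols.append(b)
        data.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    data = np.concatenate(data)
    n = nr * nc
    g = coo_matrix((data, (rows, cols)), shape=(n, n))
    return (g + g.T).tocsr()


def _disk_cells(center_rc, radius, shape) -> np.ndarray:
    r0, c0 = center_rc
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    mask = (rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2
    return np.argwhere(mask)


def place_features(config: LandscapeConfig, elevation: RasterGrid) -> LandscapeFeatures:
    """Population patches on high ground, roads/settlements in valleys,
    reserves over a configurable fraction of the patches.

    Patch centers are chosen greedily from the highest-suitability-elevation
    cells subject to a minimum mutual separation, so patches are pairwise
    disjoint; raises :class:`PlacementError` when the grid cannot hold the
    requested number.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 202]))
    z = elevation.values
    nr, nc = z.shape
    cs = elevation.cell_size_m
    radius = config.patch_radius_cells
    min_sep = 4 * radius + 4  # cells between centers -> disjoint with margin

    # prefer the giant-panda-like mid-high band rather than bare summits
    lo, hi = config.elevation_range_m
    zn = (z - lo) / (hi - lo)
    pref = np.exp(-0.5 * ((zn - 0.45) / 0.18) ** 2)
    margin = radius + 1
    interior = np.zeros_like(pref, dtype=bool)
    interior[margin : nr - margin, margin : nc - margin] = True
    order = np.argsort(-(pref + 1e-6 * rng.random(pref.shape)), axis=None)

    centers: list[tuple[int, int]] = []
    for flat in order:
        r, c = divmod(int(flat), nc)
        if not interior[r, c]:
            continue
        if all((r - r2) ** 2 + (c - c2) ** 2 >= min_sep**2 for r2, c2 in centers):
            centers.append((r, c))
        if len(centers) == config.n_populations:
            break
    if len(centers) < config.n_populations:
        raise PlacementError(
            f"cannot place {config.n_populations} disjoint patches of radius "
            f"{radius} cells on a {nr}x{nc} grid"
        )

    patches, patch_cells = [], []
    ref = elevation
    for r, c in centers:
        cells = _disk_cells((r, c), radius, z.shape)
        patch_cells.append(cells)
        x, y = ref.cell_center(r, c)
        patches.append(Point(x, y).buffer((radius + 0.5) * cs, quad_segs=16))

    n_res = int(round(config.reserve_fraction * config.n_populations))
    reserves = [patches[i].buffer(2.0 * cs) for i in range(n_res)]

    # roads: least-elevation routes across the grid (west->east, north->south)
    graph = _grid_graph_lowland(z, cs)
    idx = np.arange(nr * nc).reshape(nr, nc)
    roads: list[LineString] = []
    for k in range(config.n_roads):
        if k % 2 == 0:
            src = idx[int(rng.integers(2, nr - 2)), 0]
            candidates = idx[:, nc - 1]
        else:
            src = idx[0, int(rng.integers(2, nc - 2))]
            candidates = idx[nr - 1, :]
        dist, pred = dijkstra(graph, indices=src, return_predecessors=True)
        tgt = int(candidates[np.argmin(dist[candidates])])
        path = []
        node = tgt
        while node != -9999 and node != src:
            path.append(node)
            node = int(pred[node])
        path.append(src)
        coords = [ref.cell_center(*divmod(p, nc)) for p in reversed(path)]
        roads.append(LineString(coords))

    # settlements: low-elevation cells close to a road
    road_cells = set()
    for line in roads:
        for x, y in line.coords:
            road_cells.add(ref.index_of(x, y))
    road_arr = np.array(sorted(road_cells))
    tree = cKDTree(road_arr)
    all_rc = np.argwhere(np.ones_like(z, dtype=bool))
    d_cells, _ = tree.query(all_rc)
    near = (d_cells >= 1) & (d_cells <= 5)
    low = zn.ravel() <= np.quantile(zn, 0.45)
    eligible = np.flatnonzero(near & low)
    if eligible.size == 0:
        eligible = np.flatnonzero(near)
    take = min(config.n_residential, eligible.size)
    chosen = rng.choice(eligible, size=take, replace=False)
    residential = [Point(ref.cell_center(*divmod(int(i), nc))) for i in chosen]

    return LandscapeFeatures(patches, patch_cells, reserves, roads, residential)


def generate_transects(config: LandscapeConfig, elevation: RasterGrid) -> list[SurveyTransect]:
    """Random straight survey transects clipped to the grid extent."""
    rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 303]))
    nr, nc = elevation.shape
    cs = elevation.cell_size_m
    width, height = nc * cs, nr * cs
    x0, y0 = elevation.origin_xy
    transects = []
    for tid in range(config.n_transects):
        ax = x0 + rng.uniform(0.05, 0.95) * width
        ay = y0 + rng.uniform(0.05, 0.95) * height
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(0.15, 0.40) * min(width, height)
        bx = np.clip(ax + length * np.cos(theta), x0 + cs, x0 + width - cs)
        by = np.clip(ay + length * np.sin(theta), y0 + cs, y0 + height - cs)
        transects.append(SurveyTransect.from_vertices(tid, np.array([[ax, ay], [bx, by]])))
    return transects


# ---------------------------------------------------------------------------
# occurrences


def _transect_cells(transect: SurveyTransect, ref: RasterGrid) -> list[tuple[int, int]]:
    """Grid cells crossed by a transect polyline (ordered, deduplicated)."""
    step = ref.cell_size_m / 2.0
    line = transect.as_linestring()
    n = max(int(np.ceil(line.length / step)), 1)
    pts = [line.interpolate(i * line.length / n) for i in range(n + 1)]
    cells: list[tuple[int, int]] = []
    for p in pts:
        try:
            rc = ref.index_of(p.x, p.y)
        except IndexError:
            continue
        if not cells or cells[-1] != rc:
            cells.append(rc)
    # dedupe while keeping order
    seen, out = set(), []
    for rc in cells:
        if rc not in seen:
            seen.add(rc)
            out.append(rc)
    return out


def sample_occurrences(
    truth: RasterGrid,
    transects: list[SurveyTransect],
    config: LandscapeConfig,
    rng: np.random.Generator | None = None,
) -> OccurrenceSet:
    """Draw presences and distance-constrained pseudo-absences on transects.

    Presences are sampled among transect cells with probability proportional
    to the true suitability of the cell; pseudo-absences are sampled
    uniformly from the transect cells whose distance to EVERY presence is at
    least ``pseudo_absence_min_distance_m`` (an exclusion buffer around each
    presence).  Points are placed at cell centers, so every record lies
    within half a cell of its transect.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([config.random_seed, 404]))

    cell_tid: dict[tuple[int, int], int] = {}
    for t in transects:
        for rc in _transect_cells(t, truth):
            cell_tid.setdefault(rc, t.id)
    if not cell_tid:
        raise InfeasibleSamplingError("no transect crosses the raster")

    cells = np.array(list(cell_tid.keys()))
    tids = np.array([cell_tid[tuple(rc)] for rc in cells])
    suit = truth.values[cells[:, 0], cells[:, 1]].astype(float)
    if suit.sum() <= 0:
        raise InfeasibleSamplingError("transects only cross zero-suitability cells")

    n_pres = min(config.n_presences, int((suit > 0).sum()))
    p = suit / suit.sum()
    pres_idx = rng.choice(len(cells), size=n_pres, replace=False, p=p)
    xy = np.array([truth.cell_center(r, c) for r, c in cells])

    pres_xy = xy[pres_idx]
    d_near, _ = cKDTree(pres_xy).query(xy)
    eligible = np.flatnonzero(d_near >= config.pseudo_absence_min_distance_m)
    n_abs = config.n_pseudo_absences if config.n_pseudo_absences is not None else n_pres
    if eligible.size < n_abs:
        raise InfeasibleSamplingError(
            f"only {eligible.size} transect cells lie at least "
            f"{config.pseudo_absence_min_distance_m:.0f} m from every presence; "
            f"{n_abs} pseudo-absences requested"
        )
    abs_idx = rng.choice(eligible, size=n_abs, replace=False)

    rows = []
    for i in pres_idx:
        rows.append((xy[i, 0], xy[i, 1], "presence", int(tids[i])))
    for i in abs_idx:
        rows.append((xy[i, 0], xy[i, 1], "pseudo_absence", int(tids[i])))
    df = pd.DataFrame(rows, columns=["x", "y", "label", "transect_id"])
    return OccurrenceSet(df)
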