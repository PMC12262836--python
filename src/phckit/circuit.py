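"""Circuit-theory connectivity on raster resistance surfaces.

The landscape is discretized as a resistor network: every valid cell is a
node, neighboring cells are joined by a resistor whose value is the mean of
the two cell resistances times the geometric step length (1 cell for
orthogonal moves, sqrt(2) for diagonal).  Population patches enter as
super-nodes that short-circuit their member cells, the focal-region
convention of circuit-based connectivity tools.

Pairwise solves ground one node, factorize the grounded Laplacian once and
reuse it for every pair; effective resistance between two nodes is the
potential difference under a unit current injection.  Corridors are
extracted by cost-weighted distance: the least-cost path (LCP) between two
patches plus the swath of cells whose total detour cost stays within a
cutoff of the LCP cost.  Corridor centrality sums the current each corridor
carries over all-pairs unit injections on the abstract patch-link network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components, dijkstra
from scipy.sparse.linalg import splu

from .raster import RasterGrid

__all__ = [
    "ResistanceSurface",
    "ResistanceGraph",
    "PairSolution",
    "CorridorGeometry",
    "build_resistance",
    "build_graph",
    "solve_pair",
    "extract_corridor",
    "corridor_centrality",
]

_OFFSETS4 = ((0, 1), (1, 0))
_OFFSETS8 = ((0, 1), (1, 0), (1, 1), (1, -1))


class ConnectivityError(RuntimeError):
    """Terminals lie in disconnected components of the resistance graph."""


@dataclass
class ResistanceSurface:
    """Per-cell resistance: the reciprocal of habitat suitability.

    ``r = 1 / max(s, epsilon)``; the floor keeps resistance finite where
    suitability reaches zero.
    """

    grid: RasterGrid
    epsilon: float


def build_resistance(suitability: RasterGrid, epsilon: float = 1e-3) -> ResistanceSurface:
    s = suitability.values
    valid = ~suitability.nodata_mask
    if np.any((s[valid] < 0) | (s[valid] > 1)):
        raise ValueError("suitability must lie in [0, 1]")
    if not 0 < epsilon <= 1:
        raise ValueError("epsilon must lie in (0, 1]")
    r = np.where(valid, 1.0 / np.maximum(s, epsilon), np.nan)
    return ResistanceSurface(suitability.like(r), epsilon)


class ResistanceGraph:
    """Weighted graph over raster cells with optional patch super-nodes.

    Attributes
    ----------
    n_nodes : total node count (cells collapsed into their super-node)
    edges : (u, v, resistance, length_m) arrays after parallel-edge reduction
    cell_node : flat (nrows*ncols) array mapping cells to node ids (-1 = nodata)
    patch_nodes : node id of each patch super-node
    """

    def __init__(self, ref, cell_node, n_nodes, eu, ev, er, el, patch_nodes):
        self.ref = ref
        self.cell_node = cell_node
        self.n_nodes = n_nodes
        self.edge_u, self.edge_v = eu, ev
        self.edge_r, self.edge_len = er, el
        self.patch_nodes = patch_nodes
        self._lu = None
        self._ground = None
        self._labels = None
        # conductance matrix (duplicates of merged cells already reduced)
        cond = 1.0 / er
        W = coo_matrix((np.r_[cond, cond], (np.r_[eu, ev], np.r_[ev, eu])),
                       shape=(n_nodes, n_nodes)).tocsr()
        self.conductance = W

    # -- structure ----------------------------------------------------------

    def component_labels(self) -> np.ndarray:
        if self._labels is None:
            _, self._labels = connected_components(self.conductance, directed=False)
        return self._labels

    def laplacian(self) -> csr_matrix:
        W = self.conductance
        deg = np.asarray(W.sum(axis=1)).ravel()
        n = self.n_nodes
        D = csr_matrix((deg, (np.arange(n), np.arange(n))), shape=(n, n))
        return D - W

    def node_xy(self, node: int) -> tuple[float, float]:
        """Representative planar coordinate of a node (patch -> member mean)."""
        cells = np.flatnonzero(self.cell_node == node)
        nc = self.ref.ncols
        pts = np.array([self.ref.cell_center(c // nc, c % nc) for c in cells])
        return tuple(pts.mean(axis=0))

    def cost_graph(self) -> csr_matrix:
        """Symmetric CSR of edge traversal costs (resistances)."""
        n = self.n_nodes
        g = coo_matrix(
            (np.r_[self.edge_r, self.edge_r],
             (np.r_[self.edge_u, self.edge_v], np.r_[self.edge_v, self.edge_u])),
            shape=(n, n),
        )
        return g.tocsr()


def build_graph(
    resistance: ResistanceSurface,
    neighborhood: int = 8,
    patches: list[np.ndarray] | None = None,
    edge_average: str = "arithmetic",
) -> ResistanceGraph:
    """Discretize a resistance raster into a resistor network.

    Parameters
    ----------
    neighborhood : 4 or 8
        Orthogonal, or orthogonal plus diagonal moves (diagonals scaled by
        sqrt(2)).
    patches : list of (n, 2) row/col index arrays, optional
        Cell sets merged into super-nodes (short-circuited focal regions).
    edge_average : 'arithmetic' or 'harmonic'
        How the two endpoint cell resistances combine into the edge value.
    """
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    if edge_average not in ("arithmetic", "harmonic"):
        raise ValueError("edge_average must be 'arithmetic' or 'harmonic'")
    ref = resistance.grid
    r = ref.values
    valid = ~ref.nodata_mask
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid cells")
    nr, nc = ref.shape
    flat_valid = valid.ravel()

    # cell -> node mapping, merging patch cells into super-nodes
    cell_node = -np.ones(nr * nc, dtype=np.int64)
    cell_node[flat_valid] = np.arange(flat_valid.sum())
    n_base = int(flat_valid.sum())
    patch_nodes: list[int] = []
    if patches:
        next_id = n_base
        for cells in patches:
            cells = np.asarray(cells)
            flat = cells[:, 0] * nc + cells[:, 1]
            if np.any(cell_node[flat] < 0):
                raise ValueError("patch includes nodata cells")
            if np.any(cell_node[flat] >= n_base):
                raise ValueError("patches must not overlap")
            cell_node[flat] = next_id
            patch_nodes.append(next_id)
            next_id += 1
        # compact node ids (cells absorbed by patches leave gaps)
        used = np.unique(cell_node[cell_node >= 0])
        remap = -np.ones(used.max() + 1, dtype=np.int64)
        remap[used] = np.arange(used.size)
        cell_node[cell_node >= 0] = remap[cell_node[cell_node >= 0]]
        patch_nodes = [int(remap[p]) for p in patch_nodes]
        n_nodes = int(used.size)
    else:
        n_nodes = n_base

    offsets = _OFFSETS4 if neighborhood == 4 else _OFFSETS8
    cs = ref.cell_size_m
    eu_l, ev_l, er_l, el_l = [], [], [], []
    idx = np.arange(nr * nc).reshape(nr, nc)
    for dr, dc in offsets:
        r0 = slice(max(0, -dr), nr - max(0, dr))
        c0 = slice(max(0, -dc), nc - max(0, dc))
        r1 = slice(max(0, dr), nr - max(0, -dr))
        c1 = slice(max(0, dc), nc - max(0, -dc))
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        ok = flat_valid[a] & flat_valid[b]
        a, b = a[ok], b[ok]
        ra, rb = r.ravel()[a], r.ravel()[b]
        if edge_average == "arithmetic":
            base = 0.5 * (ra + rb)
        else:
            base = 2.0 * ra * rb / (ra + rb)
        factor = np.sqrt(2.0) if (dr and dc) else 1.0
        eu_l.append(cell_node[a])
        ev_l.append(cell_node[b])
        er_l.append(base * factor)
        el_l.append(np.full(a.shape, factor * cs))
    eu = np.concatenate(eu_l)
    ev = np.concatenate(ev_l)
    er = np.concatenate(er_l)
    el = np.concatenate(el_l)

    # drop intra-patch edges; reduce parallel edges (conductances add)
    keep = eu != ev
    eu, ev, er, el = eu[keep], ev[keep], er[keep], el[keep]
    lo = np.minimum(eu, ev)
    hi = np.maximum(eu, ev)
    key = lo * n_nodes + hi
    order = np.argsort(key, kind="stable")
    key, lo, hi, er, el = key[order], lo[order], hi[order], er[order], el[order]
    uniq, start = np.unique(key, return_index=True)
    cond_sum = np.add.reduceat(1.0 / er, start)
    # per-parallel-group geometric length: take the shortest member
    el_min = np.minimum.reduceat(el, start)
    eu_r, ev_r = lo[start], hi[start]
    er_r = 1.0 / cond_sum
    return ResistanceGraph(ref, cell_node, n_nodes, eu_r, ev_r, er_r, el_min, patch_nodes)


# ---------------------------------------------------------------------------
# pairwise circuit solves


@dataclass
class PairSolution:
    pair: tuple[int, int]
    effective_resistance: float
    potentials: np.ndarray
    current_map: RasterGrid = field(repr=False, default=None)
    max_kirchhoff_residual: float = 0.0


def _grounded_factor(graph: ResistanceGraph):
    """Cache an LU factorization of the Laplacian grounded at node 0."""
    if graph._lu is None:
        L = graph.laplacian().tolil()
        ground = 0
        keep = np.arange(graph.n_nodes) != ground
        Lg = L[keep][:, keep].tocsc()
        graph._lu = splu(Lg)
        graph._ground = ground
    return graph._lu, graph._ground


def solve_pair(
    graph: ResistanceGraph, node_a: int, node_b: int, with_current_map: bool = True
) -> PairSolution:
    """Unit-current injection at ``node_a``, extraction at ``node_b``.

    Returns the node potentials, the effective resistance (potential
    difference between the terminals) and a per-cell current map (half the
    sum of absolute incident edge currents; the terminal convention sets the
    focal nodes to the injected 1 A).
    """
    if node_a == node_b:
        raise ValueError("terminals must differ")
    labels = graph.component_labels()
    if labels[node_a] != labels[node_b]:
        raise ConnectivityError(f"nodes {node_a} and {node_b} are not connected")
    if labels[node_a] != labels[0]:
        # rare off-component pair: dense fallback on the component
        return _solve_in_component(graph, node_a, node_b, with_current_map)
    lu, ground = _grounded_factor(graph)
    n = graph.n_nodes
    rhs_full = np.zeros(n)
    rhs_full[node_a] += 1.0
    rhs_full[node_b] -= 1.0
    keep = np.arange(n) != ground
    v = np.zeros(n)
    v[keep] = lu.solve(rhs_full[keep])
    return _finish_solution(graph, node_a, node_b, v, with_current_map)


def _solve_in_component(graph, node_a, node_b, with_current_map):
    labels = graph.component_labels()
    comp = np.flatnonzero(labels == labels[node_a])
    sub = graph.laplacian()[comp][:, comp].toarray()
    pos = {int(g): i for i, g in enumerate(comp)}
    rhs = np.zeros(len(comp))
    rhs[pos[node_a]] += 1.0
    rhs[pos[node_b]] -= 1.0
    vg = np.zeros(len(comp))
    keep = np.arange(len(comp)) != 0
    vg[keep] = np.linalg.solve(sub[keep][:, keep], rhs[keep])
    v = np.zeros(graph.n_nodes)
    v[comp] = vg
    return _finish_solution(graph, node_a, node_b, v, with_current_map)


def _finish_solution(graph, node_a, node_b, v, with_current_map):
    eff = float(v[node_a] - v[node_b])
    edge_i = (v[graph.edge_u] - v[graph.edge_v]) / graph.edge_r
    # Kirchhoff residual: net current at every node minus the injections
    net = np.zeros(graph.n_nodes)
    np.add.at(net, graph.edge_u, -edge_i)
    np.add.at(net, graph.edge_v, edge_i)
    net[node_a] += 1.0
    net[node_b] -= 1.0
    resid = float(np.max(np.abs(net)))

    cmap = None
    if with_current_map:
        node_cur = np.zeros(graph.n_nodes)
        np.add.at(node_cur, graph.edge_u, np.abs(edge_i))
        np.add.at(node_cur, graph.edge_v, np.abs(edge_i))
        node_cur *= 0.5
        node_cur[node_a] = 1.0
        node_cur[node_b] = 1.0
        vals = np.zeros(graph.ref.shape)
        cell_ok = graph.cell_node >= 0
        vals.ravel()[cell_ok] = node_cur[graph.cell_node[cell_ok]]
        cmap = graph.ref.like(vals)
    return PairSolution((node_a, node_b), eff, v, cmap, resid)


# ---------------------------------------------------------------------------
# corridors


@dataclass
class CorridorGeometry:
    pair: tuple[int, int]  # patch indices into graph.patch_nodes
    lcp_nodes: list[int]
    lcp_cost: float
    length_km: float
    corridor_mask: np.ndarray  # boolean raster of corridor cells
    path_xy: np.ndarray  # (n, 2) planar coordinates along the LCP


def extract_corridor(
    graph: ResistanceGraph,
    patch_a: int,
    patch_b: int,
    cwd_cutoff: float | None = None,
    cutoff_fraction: float = 0.2,
) -> CorridorGeometry:
    """Least-cost corridor between two patch super-nodes.

    Cost-weighted distances (CWD) from each patch are shortest-path costs
    over the edge resistances; the corridor is the set of cells whose
    detour cost ``cwd_a + cwd_b - lcp_cost`` stays within the cutoff
    (``cutoff_fraction`` of the LCP cost unless an absolute ``cwd_cutoff``
    is given).  Length is the geometric arc length of the LCP in km.
    """
    if not (0 <= patch_a < len(graph.patch_nodes)) or not (0 <= patch_b < len(graph.patch_nodes)):
        raise IndexError("patch index out of range")
    if patch_a == patch_b:
        raise ValueError("patches must differ")
    na, nb = graph.patch_nodes[patch_a], graph.patch_nodes[patch_b]
    cost = graph.cost_graph()
    cwd_a, pred = dijkstra(cost, indices=na, return_predecessors=True)
    cwd_b = dijkstra(cost, indices=nb)
    lcp_cost = float(cwd_a[nb])
    if not np.isfinite(lcp_cost):
        raise ConnectivityError(f"no path between patches {patch_a} and {patch_b}")

    path = [nb]
    node = nb
    while node != na:
        node = int(pred[node])
        if node < 0:
            raise ConnectivityError("predecessor chain broken")
        path.append(node)
    path.reverse()

    # geometric length from stored edge lengths
    elen = {}
    for u, v, l in zip(graph.edge_u, graph.edge_v, graph.edge_len):
        elen[(int(u), int(v))] = float(l)
        elen[(int(v), int(u))] = float(l)
    length_m = sum(elen[(path[i], path[i + 1])] for i in range(len(path) - 1))

    cutoff = cwd_cutoff if cwd_cutoff is not None else cutoff_fraction * lcp_cost
    node_in = (cwd_a + cwd_b - lcp_cost) <= cutoff + 1e-12
    mask = np.zeros(graph.ref.shape, dtype=bool)
    cell_ok = graph.cell_node >= 0
    mask.ravel()[cell_ok] = node_in[graph.cell_node[cell_ok]]

    path_xy = np.array([graph.node_xy(n) for n in path])
    return CorridorGeometry(
        (patch_a, patch_b), path, lcp_cost, length_m / 1000.0, mask, path_xy
    )


# ---------------------------------------------------------------------------
# centrality on the patch-link network


def corridor_centrality(
    n_patches: int, links: list[tuple[int, int, float]]
) -> dict[tuple[int, int], float]:
    """Current-flow centrality of patch-network links.

    ``links`` holds (patch_i, patch_j, resistance) triples — one per
    corridor, with the LCP cost as the link resistance.  For every unordered
    patch pair, 1 A is injected/extracted and the absolute current through
    each link is accumulated; a link's centrality is that sum.  Disconnected
    networks are processed per component with a warning.
    """
    if n_patches < 2:
        raise ValueError("need at least 2 patches")
    for i, j, w in links:
        if w <= 0:
            raise ValueError("link resistances must be positive")
        if i == j:
            raise ValueError("self-links are not allowed")

    L = np.zeros((n_patches, n_patches))
    for i, j, w in links:
        c = 1.0 / w
        L[i, i] += c
        L[j, j] += c
        L[i, j] -= c
        L[j, i] -= c
    labels = _dense_components(n_patches, links)
    if len(set(labels)) > 1:
        warnings.warn("patch network is disconnected; centrality computed per component")

    # explicit cutoff so the Laplacian's null mode is truncated, not inverted
    Lp = np.linalg.pinv(L, rcond=1e-10)
    cent = {tuple(sorted((i, j))): 0.0 for i, j, _ in links}
    for s in range(n_patches):
        for t in range(s + 1, n_patches):
            if labels[s] != labels[t]:
                continue
            v = Lp[:, s] - Lp[:, t]
            for i, j, w in links:
                cur = abs((v[i] - v[j]) / w)
                cent[tuple(sorted((i, j)))] += cur
    return cent


def _dense_components(n: int, links) -> list[int]:
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j, _ in links:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    return [find(i) for i in range(n)]
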