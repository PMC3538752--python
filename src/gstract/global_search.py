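"""Global search (GS): A* minimum-cost pathway search between two ROIs.

The search space is a structured cubic lattice whose neighbor-offset set has
74 directions by default (all primitive integer offsets in {-2..2}^3 except
the (2,2,1) permutation class); a finer 98-offset set (adding that class)
serves angular-resolution experiments.  The lattice spacing is derived from
the configured average step length over the offset set (default 2 mm).

Each lattice edge is scored by a diffusion-affinity cost evaluated at the
segment midpoint:

    cost = length * (1 - p(v) * d(v) * FA),   clipped to [eps*length, length]

where p(v) = (v^T D v - lambda3) / lambda1 is the propagation probability
with the isotropic fraction removed (zero for any direction on an isotropic
tensor, maximal along e1), d(v) is the divergence-from-principal-direction
factor (|cos| to e1 for linear tensor shapes, cosine to the e1/e2 plane for
planar and spherical shapes), and FA the fractional anisotropy.  Edges whose
midpoint FA falls below the threshold are forbidden, as are turns exceeding
the bending-angle limit; the state space is (node, arrival-offset) so the
angle constraint is exact.  The cost floor eps*length keeps the Euclidean
heuristic h(n) = eps * dist(n, goal) admissible and consistent, so A*
returns true minimum-cost paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from numba import njit
from scipy.spatial import cKDTree

from .fibers import Fiber, FiberTract
from .local_tracking import ROI
from .tensor_field import (TensorField, eigendecompose, fractional_anisotropy,
                           tensor_to_matrix, westin_shape, SHAPE_LINEAR)


@dataclass
class GSParams:
    fa_threshold: float = 0.3
    fa_fallback: float = 0.15
    bending_angle_deg: float = 60.0
    average_step: float = 2.0  # mm, mean lattice step over the offset set
    n_offsets: int = 74
    cost_floor: float = 1e-3  # eps: lower clip factor on the edge cost

    def __post_init__(self) -> None:
        if not 0.0 < self.bending_angle_deg <= 90.0:
            raise ValueError("bending angle limit must be in (0, 90] degrees")
        if self.n_offsets not in (74, 98):
            raise ValueError("offset set must have 74 or 98 directions")


def neighbor_offsets(count: int = 74) -> np.ndarray:
    """Cubic-lattice neighbor offsets.

    All primitive (gcd 1) integer vectors in {-2..2}^3: the 26-neighborhood
    plus the (2,1,0) and (2,1,1) permutation classes gives 74 directions;
    adding the (2,2,1) class gives the finer 98-direction set.
    """
    offs = []
    for i in range(-2, 3):
        for j in range(-2, 3):
            for k in range(-2, 3):
                if i == j == k == 0:
                    continue
                g = math.gcd(math.gcd(abs(i), abs(j)), abs(k))
                if g != 1:
                    continue  # collinear with a shorter offset
                cls = tuple(sorted((abs(i), abs(j), abs(k))))
                if count == 74 and cls == (1, 2, 2):
                    continue
                offs.append((i, j, k))
    arr = np.array(offs, dtype=np.int64)
    if arr.shape[0] != count:
        raise AssertionError("offset construction is inconsistent")
    return arr


@dataclass
class SearchGrid:
    """Structured point lattice with a fixed neighbor-offset set."""

    origin: np.ndarray  # world mm of lattice index (0,0,0)
    spacing: float  # mm per unit lattice index
    shape: Tuple[int, int, int]
    offsets: np.ndarray  # (M, 3) int
    bbox: Tuple[np.ndarray, np.ndarray]  # world-mm lo/hi actually covered

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.offsets, axis=1)
        mean_step = float(norms.mean() * self.spacing)
        self.step_lengths = norms * self.spacing
        self.mean_step = mean_step

    def node_positions(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, float) * self.spacing


def build_grid(field: TensorField, bbox=None,
               params: Optional[GSParams] = None) -> SearchGrid:
    """Lattice covering the bounding box (or the whole field).

    Spacing is chosen so the mean neighbor step equals the configured
    average step.
    """
    params = params or GSParams()
    offs = neighbor_offsets(params.n_offsets)
    h = params.average_step / float(np.linalg.norm(offs, axis=1).mean())
    flo, fhi = field.world_bounds()
    if bbox is not None:
        blo, bhi = (np.asarray(b, float) for b in bbox)
        lo = np.maximum(flo, blo)
        hi = np.minimum(fhi, bhi)
    else:
        lo, hi = flo, fhi
    if np.any(lo > hi):
        raise ValueError("bounding box does not intersect the field")
    shape = tuple(int(np.floor((hi[a] - lo[a]) / h)) + 1 for a in range(3))
    return SearchGrid(origin=lo, spacing=h, shape=shape, offsets=offs,
                      bbox=(lo, hi))


# -- cost terms -------------------------------------------------------------

def _edge_terms(t6: np.ndarray, v: np.ndarray):
    """Vectorized (p_hat, divergence, FA) for tensors (N,6), unit dirs (N,3)."""
    es = eigendecompose(t6)
    lam = es.lambdas
    fa = fractional_anisotropy(lam)
    m = tensor_to_matrix(t6)
    vdv = np.einsum("ni,nij,nj->n", v, m, v)
    l1 = lam[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        p = (vdv - lam[:, 2]) / l1
    p = np.where(l1 > 0, np.clip(p, 0.0, None), 0.0)
    shape = westin_shape(lam)
    cos_e1 = np.abs(np.einsum("ni,ni->n", v, es.e1))
    sin_e3 = np.sqrt(np.clip(1.0 - np.einsum("ni,ni->n", v, es.e3) ** 2,
                             0.0, 1.0))
    d = np.where(shape.shape_class == SHAPE_LINEAR, cos_e1, sin_e3)
    return p, d, fa


def combine_cost(p: np.ndarray, d: np.ndarray, fa: np.ndarray,
                 length, cost_floor: float = 1e-3) -> np.ndarray:
    """length * (1 - p*d*FA), clipped to [cost_floor*length, length]."""
    raw = length * (1.0 - p * d * fa)
    return np.clip(raw, cost_floor * length, length)


def propagation_probability(t6: np.ndarray, v: np.ndarray) -> float:
    """p_hat(v) = (v^T D v - lambda3)/lambda1, clipped at 0.

    Zero for any direction on an isotropic tensor and maximal along e1.
    """
    p, _, _ = _edge_terms(np.asarray(t6, float)[None, :],
                          np.asarray(v, float)[None, :])
    return float(p[0])


def divergence_factor(t6: np.ndarray, v: np.ndarray) -> float:
    """Divergence from the principal diffusion direction, in [0, 1].

    |cos| of the angle to e1 for linear tensor shapes; cosine of the angle
    to the e1/e2 plane for planar and spherical shapes.
    """
    _, d, _ = _edge_terms(np.asarray(t6, float)[None, :],
                          np.asarray(v, float)[None, :])
    return float(d[0])


def step_cost(t6: np.ndarray, v: np.ndarray, length: float,
              params: Optional[GSParams] = None) -> float:
    """Edge cost length*(1 - p*d*FA), clipped to [eps*length, length].

    Infinite where the (midpoint) FA is below the threshold: the edge is
    forbidden.
    """
    params = params or GSParams()
    p, d, fa = _edge_terms(np.asarray(t6, float)[None, :],
                           np.asarray(v, float)[None, :])
    if fa[0] < params.fa_threshold:
        return math.inf
    return float(combine_cost(p[0], d[0], fa[0], length, params.cost_floor))


# -- state graph ------------------------------------------------------------

class EdgeGraph:
    """Precomputed valid nodes, edge destinations and edge costs.

    Nodes are lattice points inside the box with interpolated FA above the
    threshold; an edge additionally requires its midpoint FA to clear the
    threshold.  Costs are symmetric under edge reversal (the cost terms are
    even in the direction), which the builder exploits.
    """

    def __init__(self, grid: SearchGrid, field: TensorField,
                 fa_threshold: float, params: GSParams):
        self.grid = grid
        self.params = params
        self.fa_threshold = fa_threshold
        nx, ny, nz = grid.shape
        idx = np.indices(grid.shape).reshape(3, -1).T
        pos = grid.node_positions(idx)
        fa = field.fa_at(pos, mode="nan")
        valid = np.isfinite(fa) & (fa >= fa_threshold)
        self.node_lookup = np.full(nx * ny * nz, -1, dtype=np.int64)
        self.node_lookup[np.flatnonzero(valid)] = np.arange(valid.sum())
        self.nodes_ijk = idx[valid]
        self.node_pos = pos[valid]
        n = self.nodes_ijk.shape[0]
        offs = grid.offsets
        m = offs.shape[0]
        self.dest = np.full((n, m), -1, dtype=np.int64)
        self.cost = np.full((n, m), np.inf)
        if n == 0:
            self._compat(params)
            return

        # mirror index of each offset (-o)
        key = {tuple(o): i for i, o in enumerate(offs)}
        mirror = np.array([key[tuple(-o)] for o in offs], dtype=np.int64)
        self.mirror = mirror
        shape_arr = np.array(grid.shape)
        for k in range(m):
            nb = self.nodes_ijk + offs[k]
            inside = np.all((nb >= 0) & (nb < shape_arr), axis=1)
            flat = np.ravel_multi_index(nb[inside].T, grid.shape)
            ids = self.node_lookup[flat]
            col = np.full(n, -1, dtype=np.int64)
            col[np.flatnonzero(inside)] = ids
            self.dest[:, k] = col

        unit = offs / np.linalg.norm(offs, axis=1, keepdims=True)
        for k in range(m):
            if k > mirror[k]:
                continue  # filled by the mirror pass below
            sel = np.flatnonzero(self.dest[:, k] >= 0)
            if sel.size == 0:
                continue
            mids = self.node_pos[sel] + offs[k] * (grid.spacing / 2.0)
            t6 = field.interpolate(mids, mode="nan")
            ok = np.all(np.isfinite(t6), axis=1)
            p = np.zeros(sel.size)
            d = np.zeros(sel.size)
            fa_mid = np.zeros(sel.size)
            if np.any(ok):
                vv = np.broadcast_to(unit[k], (int(ok.sum()), 3))
                p[ok], d[ok], fa_mid[ok] = _edge_terms(t6[ok], vv)
            length = grid.step_lengths[k]
            c = combine_cost(p, d, fa_mid, length, params.cost_floor)
            c[~ok | (fa_mid < fa_threshold)] = np.inf
            self.cost[sel, k] = c
            # reversed edge: same midpoint, even cost terms
            dst = self.dest[sel, k]
            self.cost[dst, mirror[k]] = c
        self._compat(params)

    def _compat(self, params: GSParams) -> None:
        offs = self.grid.offsets.astype(float)
        unit = offs / np.linalg.norm(offs, axis=1, keepdims=True)
        cosmat = unit @ unit.T
        limit = math.cos(math.radians(params.bending_angle_deg))
        allowed = cosmat >= limit - 1e-12
        indptr = [0]
        idx: List[int] = []
        for i in range(allowed.shape[0]):
            js = np.flatnonzero(allowed[i])
            idx.extend(js.tolist())
            indptr.append(len(idx))
        self.compat_indptr = np.array(indptr, dtype=np.int64)
        self.compat_idx = np.array(idx, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.nodes_ijk.shape[0]

    def nodes_in_mask(self, field: TensorField, mask: np.ndarray) -> np.ndarray:
        """Ids of valid nodes whose nearest voxel lies in the mask."""
        if self.n_nodes == 0:
            return np.empty(0, dtype=np.int64)
        ijk = np.round(field.world_to_voxel(self.node_pos)).astype(int)
        n = np.array(mask.shape)
        ok = np.all((ijk >= 0) & (ijk < n), axis=1)
        hit = np.zeros(self.n_nodes, dtype=bool)
        sub = ijk[ok]
        hit[np.flatnonzero(ok)] = mask[sub[:, 0], sub[:, 1], sub[:, 2]]
        return np.flatnonzero(hit)


@njit(cache=True)
def _search_kernel(dest, cost, compat_indptr, compat_idx, h_node,
                   start_states, start_dists, start_parents,
                   goal_mask, stop_at_goal):
    """Dijkstra / A* over states s = node * M + arrival_offset.

    h_node is the per-node heuristic (zeros => plain Dijkstra).  Priority
    ties break FIFO via an insertion counter.  Returns (found_state, dist,
    parent); found_state is -1 when run to exhaustion or unreachable.
    Parent encoding: -1 unvisited, <= -2 virtual start at node (-2 - node).
    """
    n_nodes, m = dest.shape
    nstates = n_nodes * m
    dist = np.full(nstates, np.inf)
    parent = np.full(nstates, np.int64(-1))
    cap = 4 * nstates // 2 + start_states.shape[0] + 64
    hk = np.empty(cap)
    hc = np.empty(cap, np.int64)
    hs = np.empty(cap, np.int64)
    size = 0
    counter = 0
    for i in range(start_states.shape[0]):
        s = start_states[i]
        if start_dists[i] < dist[s]:
            dist[s] = start_dists[i]
            parent[s] = start_parents[i]
    for i in range(start_states.shape[0]):
        s = start_states[i]
        key = dist[s] + h_node[s // m]
        hk[size] = key
        hc[size] = counter
        hs[size] = s
        counter += 1
        j = size
        size += 1
        while j > 0:
            p = (j - 1) >> 1
            if hk[p] > hk[j] or (hk[p] == hk[j] and hc[p] > hc[j]):
                hk[p], hk[j] = hk[j], hk[p]
                hc[p], hc[j] = hc[j], hc[p]
                hs[p], hs[j] = hs[j], hs[p]
                j = p
            else:
                break
    found = np.int64(-1)
    while size > 0:
        key = hk[0]
        s = hs[0]
        size -= 1
        hk[0] = hk[size]
        hc[0] = hc[size]
        hs[0] = hs[size]
        j = 0
        while True:
            l = 2 * j + 1
            r = l + 1
            sm = j
            if l < size and (hk[l] < hk[sm] or (hk[l] == hk[sm] and hc[l] < hc[sm])):
                sm = l
            if r < size and (hk[r] < hk[sm] or (hk[r] == hk[sm] and hc[r] < hc[sm])):
                sm = r
            if sm == j:
                break
            hk[sm], hk[j] = hk[j], hk[sm]
            hc[sm], hc[j] = hc[j], hc[sm]
            hs[sm], hs[j] = hs[j], hs[sm]
            j = sm
        node = s // m
        if key > dist[s] + h_node[node] + 1e-12:
            continue  # stale heap entry
        if stop_at_goal and goal_mask[node]:
            found = s
            break
        ds = dist[s]
        arr = s % m
        for t in range(compat_indptr[arr], compat_indptr[arr + 1]):
            k = compat_idx[t]
            nd = dest[node, k]
            if nd < 0:
                continue
            c = cost[node, k]
            if c == np.inf:
                continue
            ndist = ds + c
            ns = nd * m + k
            if ndist < dist[ns]:
                dist[ns] = ndist
                parent[ns] = s
                if size == hk.shape[0]:
                    ncap = hk.shape[0] * 2
                    nhk = np.empty(ncap)
                    nhc = np.empty(ncap, np.int64)
                    nhs = np.empty(ncap, np.int64)
                    nhk[:size] = hk
                    nhc[:size] = hc
                    nhs[:size] = hs
                    hk, hc, hs = nhk, nhc, nhs
                hk[size] = ndist + h_node[nd]
                hc[size] = counter
                hs[size] = ns
                counter += 1
                j = size
                size += 1
                while j > 0:
                    p = (j - 1) >> 1
                    if hk[p] > hk[j] or (hk[p] == hk[j] and hc[p] > hc[j]):
                        hk[p], hk[j] = hk[j], hk[p]
                        hc[p], hc[j] = hc[j], hc[p]
                        hs[p], hs[j] = hs[j], hs[p]
                        j = p
                    else:
                        break
    return found, dist, parent


def _initial_states(graph: EdgeGraph, start_nodes: np.ndarray):
    """Virtual-start expansion: the first segment has no bend constraint."""
    m = graph.grid.offsets.shape[0]
    states, dists, parents = [], [], []
    for n0 in start_nodes:
        for k in range(m):
            nd = graph.dest[n0, k]
            c = graph.cost[n0, k]
            if nd >= 0 and np.isfinite(c):
                states.append(nd * m + k)
                dists.append(c)
                parents.append(-2 - int(n0))
    return (np.array(states, dtype=np.int64),
            np.array(dists, dtype=float),
            np.array(parents, dtype=np.int64))


def _extract_path(graph: EdgeGraph, state: int, parent: np.ndarray) -> List[int]:
    """Node-id chain from the virtual start to ``state`` (inclusive)."""
    m = graph.grid.offsets.shape[0]
    nodes = []
    s = state
    while s >= 0:
        nodes.append(int(s // m))
        s = int(parent[s])
    nodes.append(-2 - s)  # the virtual-start node
    nodes.reverse()
    return nodes


def astar_search(graph: EdgeGraph, start_nodes: np.ndarray,
                 goal_nodes: np.ndarray):
    """Minimum-cost node path from the start set to any goal node.

    Returns ``(node_id_path, cost)`` or ``None`` when no connection exists.
    The heuristic is eps * Euclidean distance to the nearest goal node,
    admissible and consistent given the cost floor.
    """
    start_nodes = np.asarray(start_nodes, dtype=np.int64)
    goal_nodes = np.asarray(goal_nodes, dtype=np.int64)
    if start_nodes.size == 0 or goal_nodes.size == 0:
        return None
    common = np.intersect1d(start_nodes, goal_nodes)
    if common.size:
        return [int(common[0])], 0.0
    goal_mask = np.zeros(graph.n_nodes, dtype=np.bool_)
    goal_mask[goal_nodes] = True
    tree = cKDTree(graph.node_pos[goal_nodes])
    hdist, _ = tree.query(graph.node_pos)
    h_node = graph.params.cost_floor * hdist
    states, dists, parents = _initial_states(graph, start_nodes)
    if states.size == 0:
        return None
    found, dist, parent = _search_kernel(
        graph.dest, graph.cost, graph.compat_indptr, graph.compat_idx,
        h_node, states, dists, parents, goal_mask, True)
    if found < 0:
        return None
    return _extract_path(graph, int(found), parent), float(dist[found])


def all_shortest_paths(graph: EdgeGraph, start_nodes: np.ndarray,
                       goal_nodes: np.ndarray):
    """One minimum-cost path per start node, via a single backward Dijkstra.

    Runs Dijkstra once from the goal set over the reversed state graph
    (exact because edge costs are even in the direction and the bending
    constraint is symmetric) and reads off each start node's optimal path.
    Returns ``{start_node_id: (node_id_path, cost)}`` for reachable starts.
    """
    start_nodes = np.asarray(start_nodes, dtype=np.int64)
    goal_nodes = np.asarray(goal_nodes, dtype=np.int64)
    out = {}
    if start_nodes.size == 0 or goal_nodes.size == 0:
        return out
    m = graph.grid.offsets.shape[0]
    states, dists, parents = _initial_states(graph, goal_nodes)
    if states.size == 0:
        return out
    goal_mask = np.zeros(graph.n_nodes, dtype=np.bool_)
    _, dist, parent = _search_kernel(
        graph.dest, graph.cost, graph.compat_indptr, graph.compat_idx,
        np.zeros(graph.n_nodes), states, dists, parents, goal_mask, False)
    goal_set = set(int(g) for g in goal_nodes)
    for n in start_nodes:
        n = int(n)
        if n in goal_set:
            out[n] = ([n], 0.0)
            continue
        block = dist[n * m:(n + 1) * m]
        k = int(np.argmin(block))
        if not np.isfinite(block[k]):
            continue
        chain = _extract_path(graph, n * m + k, parent)
        # backward chain runs goal -> start; flip to start -> goal
        out[n] = (chain[::-1], float(block[k]))
    return out


def reconstruct_pathway(field: TensorField, roi_a: ROI, roi_b: ROI,
                        bbox=None, params: Optional[GSParams] = None
                        ) -> FiberTract:
    """GS tract: one minimum-cost path per qualifying start node in roi_a.

    Identical node paths are deduplicated.  On global failure the FA
    threshold falls back from the default 0.3 to 0.15; failure at both
    thresholds yields an empty tract with ``provenance['failed'] = True``.
    ROI padding is never applied for GS.
    """
    params = params or GSParams()
    fibers: List[Fiber] = []
    used_thr = None
    for thr in (params.fa_threshold, params.fa_fallback):
        grid = build_grid(field, bbox=bbox, params=params)
        graph = EdgeGraph(grid, field, thr, params)
        starts = graph.nodes_in_mask(field, roi_a.mask)
        goals = graph.nodes_in_mask(field, roi_b.mask)
        paths = all_shortest_paths(graph, starts, goals)
        seen = set()
        fibers = []
        for n0, (chain, cost) in sorted(paths.items()):
            key = tuple(chain)
            if key in seen or len(chain) < 2:
                continue
            seen.add(key)
            pts = graph.node_pos[np.array(chain)]
            fibers.append(Fiber(pts, {"method": "gs", "start_node": int(n0),
                                      "cost": cost, "fa_threshold": thr}))
        if fibers:
            used_thr = thr
            break
        if thr == params.fa_fallback:
            break
    prov = {"method": "gs", "fa_threshold": used_thr,
            "bending_angle_deg": params.bending_angle_deg,
            "average_step": params.average_step,
            "n_offsets": params.n_offsets,
            "failed": not fibers}
    return FiberTract(fibers, prov)
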