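"""Independent brute-force oracles used by the tests.

These deliberately use plain Python loops, dicts and heapq so that they
share no search/aggregation code with the implementations they check.
"""

import heapq
import math

import numpy as np


def dijkstra_best_cost(graph, start_nodes, goal_nodes):
    """Exhaustive Dijkstra over the (node, arrival-offset) state space.

    Uses the graph's edge-cost table but none of its search machinery.
    Returns the minimum path cost from the start set to any goal node, or
    None when unreachable.
    """
    m = graph.grid.offsets.shape[0]
    goal = set(int(g) for g in goal_nodes)
    if goal & set(int(s) for s in start_nodes):
        return 0.0
    succ = [graph.compat_idx[graph.compat_indptr[k]:graph.compat_indptr[k + 1]]
            for k in range(m)]
    dist = {}
    pq = []
    cnt = 0
    for n0 in start_nodes:
        for k in range(m):
            nd = int(graph.dest[n0, k])
            c = float(graph.cost[n0, k])
            if nd >= 0 and math.isfinite(c):
                s = (nd, k)
                if c < dist.get(s, math.inf):
                    dist[s] = c
                    heapq.heappush(pq, (c, cnt, s))
                    cnt += 1
    while pq:
        d, _, s = heapq.heappop(pq)
        if d > dist.get(s, math.inf):
            continue
        node, arr = s
        if node in goal:
            return d
        for k in succ[arr]:
            nd = int(graph.dest[node, k])
            if nd < 0:
                continue
            c = float(graph.cost[node, k])
            if not math.isfinite(c):
                continue
            ns = (nd, int(k))
            ndist = d + c
            if ndist < dist.get(ns, math.inf):
                dist[ns] = ndist
                heapq.heappush(pq, (ndist, cnt, ns))
                cnt += 1
    return None


def naive_closest_point_pairs(pi, pj):
    """All-pairs nearest search, bidirectional, deduplicated."""
    pairs = set()
    for i in range(len(pi)):
        best, bj = math.inf, -1
        for j in range(len(pj)):
            d = float(np.linalg.norm(pi[i] - pj[j]))
            if d < best:
                best, bj = d, j
        pairs.add((i, bj))
    for j in range(len(pj)):
        best, bi = math.inf, -1
        for i in range(len(pi)):
            d = float(np.linalg.norm(pi[i] - pj[j]))
            if d < best:
                best, bi = d, i
        pairs.add((bi, j))
    return pairs


def naive_mean_closest_distance(pi, pj):
    pairs = naive_closest_point_pairs(pi, pj)
    return sum(float(np.linalg.norm(pi[i] - pj[j])) for i, j in
               sorted(pairs)) / len(pairs)


def naive_tract_similarity(f_points, g_points, pair_distance):
    """Exhaustive closest-fiber relation and S statistics.

    ``pair_distance(a, b)`` supplies the per-pair distance (so the trimming
    convention under test is shared, while relation-building and the
    statistics are recomputed independently).
    """
    nf, ng = len(f_points), len(g_points)
    d = [[pair_distance(a, b) for b in range(ng)] for a in range(nf)]
    rel = set()
    for a in range(nf):
        best = min(range(ng), key=lambda b: (d[a][b], b))
        rel.add((a, best))
    for b in range(ng):
        best = min(range(nf), key=lambda a: (d[a][b], a))
        rel.add((best, b))
    dists = [d[a][b] for a, b in sorted(rel)]
    return rel, sum(dists) / len(dists), min(dists)
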