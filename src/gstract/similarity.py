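"""Fiber-tract comparison: resampling, trimming, closest-point distances,
tract-level similarity and FA similarity.

The tract similarity S pairs every fiber of one tract with its closest
fiber of the other tract (and vice versa), excluding duplicate pairs so that
outliers are emphasized rather than washed out; S_avg is the mean and S_min
the minimum of the per-pair distances.  The per-pair distance is the mean of
closest-point distances over the deduplicated bidirectional closest-point
relation, computed after the pair has been normalized: grid-bound or
unevenly sampled fibers are resampled to the trackers' constant step, and
protruding end segments are trimmed — at most one fiber per end, and never
when both ends diverge.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Set, Tuple

import numpy as np
from scipy.spatial.distance import cdist

from .fibers import Fiber, FiberTract, is_uniformly_sampled, \
    polyline_arclength_resample
from .tensor_field import TensorField

DEFAULT_STEP = 0.5  # mm, the SP/TD propagation step


@dataclass
class TrimmedPair:
    """A fiber pair after normalization and trimming."""

    fi: Fiber
    fj: Fiber
    removed_i: Tuple[float, float]  # arc length removed from fi (start, end)
    removed_j: Tuple[float, float]
    refused: Tuple[bool, bool] = (False, False)  # trim refused per end


@dataclass
class SimilarityReport:
    s_avg: float  # mm
    s_min: float  # mm
    n_pairs: int
    fa_f: Optional[float] = None
    fa_g: Optional[float] = None
    out_of_field_points: int = 0

    def as_dict(self) -> dict:
        return {"s_avg": self.s_avg, "s_min": self.s_min,
                "n_pairs": self.n_pairs, "fa_f": self.fa_f,
                "fa_g": self.fa_g,
                "out_of_field_points": self.out_of_field_points}


def resample_fiber(f: Fiber, step: float = DEFAULT_STEP) -> Fiber:
    """Equal arc-length resampling at the trackers' constant step.

    Endpoints are preserved and output points lie on the input polyline (no
    spatial smoothing).
    """
    if len(f) < 2:
        raise ValueError("cannot resample a degenerate fiber")
    pts = polyline_arclength_resample(f.points, step)
    prov = dict(f.provenance)
    prov["resampled_step"] = step
    return Fiber(pts, prov)


def _normalize(f: Fiber, step: float) -> Fiber:
    """Resample unless the fiber is already uniformly sampled at <= step."""
    seg = f.segment_lengths
    if is_uniformly_sampled(f.points) and seg[0] <= step * (1 + 1e-6):
        return f
    return resample_fiber(f, step)


def closest_point_pairs(fi: Fiber, fj: Fiber) -> Set[Tuple[int, int]]:
    """Deduplicated bidirectional closest-point index pairs (i on fi, j on fj).

    Ties break toward the lower index.
    """
    d = cdist(fi.points, fj.points)
    pairs = {(i, int(j)) for i, j in enumerate(np.argmin(d, axis=1))}
    pairs |= {(int(i), j) for j, i in enumerate(np.argmin(d, axis=0))}
    return pairs


def mean_closest_distance(fi: Fiber, fj: Fiber) -> float:
    """Mean Euclidean distance over the deduplicated closest-point relation.

    Symmetric by construction.
    """
    pairs = closest_point_pairs(fi, fj)
    idx = np.array(sorted(pairs))
    return float(np.linalg.norm(fi.points[idx[:, 0]] - fj.points[idx[:, 1]],
                                axis=1).mean())


def _end_indices(n: int) -> Tuple[int, int]:
    return 0, n - 1


def trim_pair(fi: Fiber, fj: Fiber) -> TrimmedPair:
    """Trim protruding end segments of a fiber pair.

    End correspondence uses the orientation of fj that minimizes the summed
    endpoint-to-endpoint distances.  At each end: the closest point on the
    other fiber to each fiber's endpoint is found; if exactly one of the two
    closest points is an interior point (exact index test), the segment
    beyond it on that fiber is removed.  Diverging ends (both interior) and
    fully matched ends (both endpoints) are left untouched.  A trim that
    would leave fewer than 2 points is refused and recorded.
    """
    pi = fi.points
    pj = fj.points
    d_fwd = (np.linalg.norm(pi[0] - pj[0]) + np.linalg.norm(pi[-1] - pj[-1]))
    d_rev = (np.linalg.norm(pi[0] - pj[-1]) + np.linalg.norm(pi[-1] - pj[0]))
    reverse = d_rev < d_fwd
    qj = pj[::-1] if reverse else pj

    d = cdist(pi, qj)
    ni, nj = pi.shape[0], qj.shape[0]
    # slice bounds into fi and the oriented fj
    lo_i, hi_i = 0, ni
    lo_j, hi_j = 0, nj
    refused = [False, False]

    for end in (0, 1):
        ei = 0 if end == 0 else ni - 1
        ej = 0 if end == 0 else nj - 1
        cj = int(np.argmin(d[ei, :]))  # closest point on fj to fi's endpoint
        ci = int(np.argmin(d[:, ej]))  # closest point on fi to fj's endpoint
        cj_interior = cj not in (0, nj - 1)
        ci_interior = ci not in (0, ni - 1)
        if cj_interior == ci_interior:
            continue  # diverging (both interior) or matched (both ends)
        if cj_interior:
            # fj protrudes beyond fi at this end
            if end == 0:
                if nj - cj >= 2:
                    lo_j = max(lo_j, cj)
                else:
                    refused[end] = True
            else:
                if cj + 1 >= 2:
                    hi_j = min(hi_j, cj + 1)
                else:
                    refused[end] = True
        else:
            # fi protrudes beyond fj at this end
            if end == 0:
                if ni - ci >= 2:
                    lo_i = max(lo_i, ci)
                else:
                    refused[end] = True
            else:
                if ci + 1 >= 2:
                    hi_i = min(hi_i, ci + 1)
                else:
                    refused[end] = True

    if hi_i - lo_i < 2:
        lo_i, hi_i, refused = 0, ni, [True, True]
    if hi_j - lo_j < 2:
        lo_j, hi_j, refused = 0, nj, [True, True]

    def _arc(points, lo, hi):
        seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
        return (float(seg[:lo].sum()), float(seg[hi - 1:].sum()))

    ti = Fiber(pi[lo_i:hi_i].copy(), dict(fi.provenance))
    tj_pts = qj[lo_j:hi_j]
    removed_j = _arc(qj, lo_j, hi_j)
    if reverse:
        tj_pts = tj_pts[::-1]
        removed_j = (removed_j[1], removed_j[0])
    tj = Fiber(tj_pts.copy(), dict(fj.provenance))
    return TrimmedPair(fi=ti, fj=tj, removed_i=_arc(pi, lo_i, hi_i),
                       removed_j=removed_j, refused=tuple(refused))


def _pair_distance_matrix(f: List[Fiber], g: List[Fiber]):
    nf, ng = len(f), len(g)
    dmat = np.empty((nf, ng))
    trimmed = {}
    for a in range(nf):
        for b in range(ng):
            tp = trim_pair(f[a], g[b])
            trimmed[(a, b)] = tp
            dmat[a, b] = mean_closest_distance(tp.fi, tp.fj)
    return dmat, trimmed


def _closest_fiber_relation(dmat: np.ndarray) -> Set[Tuple[int, int]]:
    """Bidirectional closest-fiber pairs, duplicates excluded, ties -> lower
    index."""
    rel = {(a, int(np.argmin(dmat[a, :]))) for a in range(dmat.shape[0])}
    rel |= {(int(np.argmin(dmat[:, b])), b) for b in range(dmat.shape[1])}
    return rel


def tract_similarity(f: FiberTract, g: FiberTract,
                     field: Optional[TensorField] = None,
                     step: float = DEFAULT_STEP) -> SimilarityReport:
    """Tract-level similarity S_avg / S_min with optional FA similarity.

    Both tracts are normalized (resampled where not uniformly sampled),
    every candidate pair is trimmed, the duplicate-excluding closest-fiber
    relation is formed, and the report averages the per-pair mean
    closest-point distances.  With ``field`` given, per-tract average FA is
    sampled at every point of every trimmed fiber participating in the
    relation (out-of-field points are excluded and counted).
    """
    if len(f) == 0 or len(g) == 0:
        raise ValueError("tract similarity needs two non-empty tracts")
    fn = [_normalize(fi, step) for fi in f]
    gn = [_normalize(gj, step) for gj in g]
    dmat, trimmed = _pair_distance_matrix(fn, gn)
    rel = _closest_fiber_relation(dmat)
    dists = np.array([dmat[a, b] for (a, b) in sorted(rel)])
    report = SimilarityReport(s_avg=float(dists.mean()),
                              s_min=float(dists.min()),
                              n_pairs=len(rel))
    if field is not None:
        report.fa_f, report.fa_g, report.out_of_field_points = _fa_of_relation(
            rel, trimmed, field)
    return report


def _fa_of_relation(rel, trimmed, field: TensorField):
    def _avg(points_list):
        vals = []
        lost = 0
        for pts in points_list:
            fa = field.fa_at(pts, mode="nan")
            ok = np.isfinite(fa)
            lost += int((~ok).sum())
            vals.append(fa[ok])
        v = np.concatenate(vals) if vals else np.empty(0)
        return (float(v.mean()) if v.size else float("nan")), lost

    fa_f, lost_f = _avg([trimmed[(a, b)].fi.points for (a, b) in sorted(rel)])
    fa_g, lost_g = _avg([trimmed[(a, b)].fj.points for (a, b) in sorted(rel)])
    return fa_f, fa_g, lost_f + lost_g


def fa_similarity(f: FiberTract, g: FiberTract, field: TensorField,
                  step: float = DEFAULT_STEP) -> Tuple[float, float]:
    """Per-tract average FA over the trimmed, correlated fibers."""
    rep = tract_similarity(f, g, field=field, step=step)
    return rep.fa_f, rep.fa_g
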