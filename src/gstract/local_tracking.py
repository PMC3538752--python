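"""Deterministic reference trackers: streamline propagation (SP) and tensor
deflection (TD).

Both trackers seed at every voxel center whose FA clears the threshold, run
bidirectionally (ortho- and retrograde from the seed), terminate when the
interpolated FA drops below the threshold, the fiber leaves the volume, or a
step cap is hit, and keep only fibers that intersect both end ROIs.  Fibers
are NOT clipped to the ROIs.

Eigenvector sign coherence: the major eigenvector's sign is flipped wherever
its dot product with the incoming direction is negative, at every evaluation
including all four Runge-Kutta stages; the seed uses +e1 forward, -e1
backward.

The propagation loops are vectorized over all seeds at once; tracking a
single seed is the batch of one, so there is exactly one code path.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import List, Optional, Tuple

import numpy as np
from scipy.ndimage import binary_dilation

from .fibers import Fiber, FiberTract
from .tensor_field import TensorField, eigendecompose, fractional_anisotropy

MAX_ROI_PADDING = 4


@dataclass
class ROI:
    """Voxel mask with a record of the dilation already applied."""

    mask: np.ndarray
    padding: int = 0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.padding > MAX_ROI_PADDING:
            raise ValueError(f"ROI padding must not exceed {MAX_ROI_PADDING}")

    def voxel_count(self) -> int:
        return int(self.mask.sum())


@dataclass
class TrackingParams:
    step_length: float = 0.5  # mm
    fa_threshold: float = 0.25
    max_steps: int = 2000
    seed_density: int = 1  # seeds per voxel (along each axis subdivision)

    def __post_init__(self) -> None:
        if not self.step_length > 0:
            raise ValueError("step_length must be positive")
        if not 0 <= self.fa_threshold < 1:
            raise ValueError("fa_threshold must be in [0, 1)")


def pad_roi(roi: ROI, voxels: int) -> ROI:
    """Morphological box dilation by ``voxels`` voxels in each dimension."""
    if voxels < 0:
        raise ValueError("padding must be non-negative")
    total = roi.padding + voxels
    if total > MAX_ROI_PADDING:
        raise ValueError(f"total ROI padding must not exceed {MAX_ROI_PADDING}")
    if voxels == 0:
        return ROI(roi.mask.copy(), roi.padding)
    mask = binary_dilation(roi.mask, structure=np.ones((3, 3, 3), bool),
                           iterations=voxels)
    return ROI(mask, total)


def seed_points(field: TensorField, params: TrackingParams) -> np.ndarray:
    """World-mm seed points: voxel centers with FA >= threshold.

    ``seed_density`` > 1 subdivides each qualifying voxel into density^3
    uniformly spaced seeds.
    """
    idx = np.argwhere(field.fa >= params.fa_threshold)
    if idx.size == 0:
        return np.empty((0, 3))
    d = params.seed_density
    if d <= 1:
        return field.voxel_to_world(idx.astype(float))
    offs = (np.arange(d) + 0.5) / d - 0.5
    sub = np.array(np.meshgrid(offs, offs, offs)).reshape(3, -1).T
    pts = (idx[:, None, :] + sub[None, :, :]).reshape(-1, 3)
    return field.voxel_to_world(pts)


# -- batched direction evaluation -------------------------------------------

def _eigen_at(field: TensorField, pts: np.ndarray):
    """Interpolated-tensor e1, FA and validity at a batch of points."""
    t = field.interpolate(pts, mode="nan")
    valid = np.all(np.isfinite(t), axis=1)
    e1 = np.zeros_like(pts)
    fa = np.zeros(pts.shape[0])
    if np.any(valid):
        es = eigendecompose(t[valid])
        e1[valid] = es.e1
        fa[valid] = fractional_anisotropy(es.lambdas)
    return e1, fa, valid, t


def _coherent_e1(field: TensorField, pts: np.ndarray, ref: np.ndarray):
    """Sign-coherent major eigenvector field evaluated at ``pts``."""
    e1, fa, valid, _ = _eigen_at(field, pts)
    flip = np.sum(e1 * ref, axis=1) < 0.0
    e1[flip] *= -1.0
    return e1, fa, valid


def _deflect(field: TensorField, pts: np.ndarray, vin: np.ndarray):
    """TD update: normalize((D / lambda1) @ v_in)."""
    _, fa, valid, t = _eigen_at(field, pts)
    out = np.zeros_like(vin)
    if np.any(valid):
        from .tensor_field import tensor_to_matrix

        tv = t[valid]
        es = eigendecompose(tv)
        l1 = es.lambdas[:, 0]
        good = l1 > 0
        m = tensor_to_matrix(tv)
        v = np.einsum("nij,nj->ni", m, vin[valid])
        with np.errstate(invalid="ignore", divide="ignore"):
            v = v / l1[:, None]
        nrm = np.linalg.norm(v, axis=1)
        ok = good & (nrm > 0)
        v[ok] = v[ok] / nrm[ok, None]
        # degenerate tensor: keep the incoming direction
        v[~ok] = vin[valid][~ok]
        out[valid] = v
    return out, fa, valid


def _propagate_half(field: TensorField, seeds: np.ndarray, v0: np.ndarray,
                    params: TrackingParams, method: str):
    """March all seeds until termination; returns per-seed point lists.

    The seed point itself is not stored (the caller owns it).
    """
    n = seeds.shape[0]
    pts = seeds.copy()
    vin = v0.copy()
    alive = np.ones(n, dtype=bool)
    h = params.step_length
    trails: List[List[np.ndarray]] = [[] for _ in range(n)]
    for _ in range(params.max_steps):
        if not np.any(alive):
            break
        p = pts[alive]
        v = vin[alive]
        if method == "sp":
            k1, _, ok1 = _coherent_e1(field, p, v)
            k2, _, ok2 = _coherent_e1(field, p + 0.5 * h * k1, k1)
            k3, _, ok3 = _coherent_e1(field, p + 0.5 * h * k2, k2)
            k4, _, ok4 = _coherent_e1(field, p + h * k3, k3)
            direction = k1 + 2.0 * k2 + 2.0 * k3 + k4
            nrm = np.linalg.norm(direction, axis=1)
            stage_ok = ok1 & ok2 & ok3 & ok4 & (nrm > 1e-12)
            direction[stage_ok] /= nrm[stage_ok, None]
            # keep orientation coherent with the incoming direction
            flip = np.sum(direction * v, axis=1) < 0.0
            direction[flip] *= -1.0
        else:  # td
            direction, _, stage_ok = _deflect(field, p, v)
        newp = p + h * direction
        fa_new = field.fa_at(newp, mode="nan")
        keep = stage_ok & np.isfinite(fa_new) & (fa_new >= params.fa_threshold)
        alive_idx = np.flatnonzero(alive)
        for j, i in enumerate(alive_idx):
            if keep[j]:
                trails[i].append(newp[j])
        pts[alive_idx[keep]] = newp[keep]
        vin[alive_idx[keep]] = direction[keep]
        alive[alive_idx[~keep]] = False
    return trails


def _track_batch(field: TensorField, seeds: np.ndarray,
                 params: TrackingParams, method: str) -> List[Optional[Fiber]]:
    """Bidirectional tracking of all seeds; None where no fiber results."""
    if method not in ("sp", "td"):
        raise ValueError("method must be 'sp' or 'td'")
    seeds = np.atleast_2d(np.asarray(seeds, dtype=float))
    n = seeds.shape[0]
    e1, fa, valid = _coherent_e1(field, seeds, np.zeros_like(seeds) + 1e-30)
    # seeds below the FA threshold produce no fiber
    startable = valid & (fa >= params.fa_threshold)
    fwd = _propagate_half(field, seeds, e1, params, method)
    bwd = _propagate_half(field, seeds, -e1, params, method)
    fibers: List[Optional[Fiber]] = []
    for i in range(n):
        if not startable[i]:
            fibers.append(None)
            continue
        pts = bwd[i][::-1] + [seeds[i]] + fwd[i]
        if len(pts) < 2:
            fibers.append(None)
            continue
        prov = {"method": method, "seed": seeds[i].tolist(),
                "step_length": params.step_length,
                "fa_threshold": params.fa_threshold}
        fibers.append(Fiber(np.asarray(pts), prov))
    return fibers


def track_sp(field: TensorField, seed: np.ndarray,
             params: TrackingParams) -> Optional[Fiber]:
    """4th-order Runge-Kutta streamline through one seed (both directions)."""
    return _track_batch(field, np.asarray(seed)[None, :], params, "sp")[0]


def track_td(field: TensorField, seed: np.ndarray,
             params: TrackingParams) -> Optional[Fiber]:
    """Tensor-deflection fiber through one seed (both directions)."""
    return _track_batch(field, np.asarray(seed)[None, :], params, "td")[0]


def _intersects(field: TensorField, fiber: Fiber, mask: np.ndarray) -> bool:
    """True if any fiber sample point falls in a mask voxel."""
    ijk = np.round(field.world_to_voxel(fiber.points)).astype(int)
    n = np.array(mask.shape)
    ok = np.all((ijk >= 0) & (ijk < n), axis=1)
    if not np.any(ok):
        return False
    ijk = ijk[ok]
    return bool(np.any(mask[ijk[:, 0], ijk[:, 1], ijk[:, 2]]))


def run_tracker(field: TensorField, roi_a: ROI, roi_b: ROI,
                params: TrackingParams, method: str,
                fibers: Optional[List[Fiber]] = None) -> FiberTract:
    """Whole-volume seeding + tracking, filtered to ROI-connecting fibers.

    ``fibers`` allows reuse of an already-tracked whole-volume fiber set
    (tracking is independent of the ROIs; only the filter changes).
    """
    if roi_a.voxel_count() == 0 or roi_b.voxel_count() == 0:
        raise ValueError("ROIs must be non-empty")
    if fibers is None:
        fibers = track_volume(field, params, method)
    kept = [f for f in fibers
            if _intersects(field, f, roi_a.mask) and _intersects(field, f, roi_b.mask)]
    prov = {"method": method, "step_length": params.step_length,
            "fa_threshold": params.fa_threshold,
            "roi_a_padding": roi_a.padding, "roi_b_padding": roi_b.padding}
    return FiberTract(kept, prov)


def track_volume(field: TensorField, params: TrackingParams,
                 method: str) -> List[Fiber]:
    """All fibers from whole-volume seeding (no ROI filtering)."""
    seeds = seed_points(field, params)
    if seeds.shape[0] == 0:
        return []
    return [f for f in _track_batch(field, seeds, params, method) if f is not None]


def adaptive_reconstruct(field: TensorField, roi_a: ROI, roi_b: ROI,
                         method: str,
                         params: Optional[TrackingParams] = None,
                         thresholds: Tuple[float, float] = (0.25, 0.2),
                         max_padding: int = MAX_ROI_PADDING):
    """FA-relaxation / ROI-padding protocol with the tract selection rule.

    For each threshold (default 0.25 then the relaxed 0.2) the ROIs are
    padded 0..max_padding voxels until a connecting tract is found.  The
    stricter-threshold tract is selected iff it required no more than two
    additional paddings compared to the relaxed threshold; otherwise the
    relaxed tract is selected.  Returns ``(tract, record)``; on total
    failure the tract is empty and ``record['failed']`` is True.
    """
    base = params or TrackingParams()
    results = {}
    for thr in thresholds:
        p = TrackingParams(step_length=base.step_length, fa_threshold=thr,
                           max_steps=base.max_steps,
                           seed_density=base.seed_density)
        fibers = track_volume(field, p, method)
        found = None
        for pad in range(0, max_padding + 1):
            tract = run_tracker(field, pad_roi(roi_a, pad), pad_roi(roi_b, pad),
                                p, method, fibers=fibers)
            if len(tract) > 0:
                found = (pad, tract)
                break
        results[thr] = found
    strict, relaxed = thresholds
    pad_s = results[strict][0] if results[strict] else None
    pad_r = results[relaxed][0] if results[relaxed] else None
    record = {"thresholds": list(thresholds), "method": method,
              "padding": {str(strict): pad_s, str(relaxed): pad_r},
              "failed": False}
    if pad_s is not None and (pad_r is None or pad_s - pad_r <= 2):
        record["chosen_threshold"] = strict
        return results[strict][1], record
    if pad_r is not None:
        record["chosen_threshold"] = relaxed
        return results[relaxed][1], record
    record["failed"] = True
    record["chosen_threshold"] = None
    return FiberTract([], {"method": method}), record
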