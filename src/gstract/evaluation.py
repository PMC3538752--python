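"""Experiment harness: phantom benchmark suite, group statistics, reports.

The suite generates each configured phantom at each SNR, fits tensors from
the noisy DWI, derives the per-phantom FA threshold (a fixed offset below
the average FA in the main part of the pathway), runs each tracking method,
and records connection success, pairwise tract similarities, spiral
first-cycle coverage and runtimes.  All randomness flows from the single
configured seed.
"""

from __future__ import annotations

import itertools
import json
import time
from dataclasses import dataclass, field as dc_field, asdict
from math import comb
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy import stats as sps

from .fibers import FiberTract
from .global_search import GSParams, reconstruct_pathway
from .local_tracking import (MAX_ROI_PADDING, ROI, TrackingParams, pad_roi,
                             run_tracker, track_volume)
from .phantom import PhantomDataset, PhantomSpec, make_phantom
from .similarity import tract_similarity


@dataclass
class ExperimentConfig:
    phantoms: Sequence[str] = ("branching", "kissing", "spiral")
    snrs: Sequence[float] = (15.0, 30.0)
    methods: Sequence[str] = ("sp", "td", "gs")
    seed: int = 0
    fa_offset: float = 0.1  # threshold = core mean FA - offset
    step_length: float = 0.5
    max_steps: int = 2000
    gs_average_step: float = 2.0
    gs_n_offsets: int = 74
    gs_bending_angle_deg: float = 60.0
    compare_pairs: bool = True

    def __post_init__(self) -> None:
        for m in self.methods:
            if m not in ("sp", "td", "gs"):
                raise ValueError(f"unknown method {m!r}")


@dataclass
class BenchmarkReport:
    config: dict
    cells: Dict[str, dict] = dc_field(default_factory=dict)
    similarity: Dict[str, dict] = dc_field(default_factory=dict)
    coverage: Dict[str, float] = dc_field(default_factory=dict)

    def to_json(self, path=None, include_runtimes: bool = True) -> str:
        """JSON report; without runtimes the payload is seed-deterministic
        byte for byte."""
        cells = self.cells
        if not include_runtimes:
            cells = {k: {kk: vv for kk, vv in v.items() if kk != "runtime_s"}
                     for k, v in cells.items()}
        payload = {"config": self.config, "cells": cells,
                   "similarity": self.similarity, "coverage": self.coverage}
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tables(self):
        """(cells, similarity) as pandas DataFrames."""
        import pandas as pd

        cells = pd.DataFrame([{"cell": k, **v} for k, v in
                              sorted(self.cells.items())])
        sim = pd.DataFrame([{"pair": k, **v} for k, v in
                            sorted(self.similarity.items())])
        return cells, sim


def _phantom_seed(base_seed: int, kind: str, snr: float) -> int:
    # deterministic, collision-free small-int seed per (kind, snr)
    k = ("straight", "branching", "kissing", "spiral").index(kind)
    s = int(round(snr))
    return (base_seed * 1009 + k * 101 + s) % (2 ** 31)


def first_cycle_coverage(dataset: PhantomDataset, tract: FiberTract) -> float:
    """Arc-length fraction of the ground-truth first cycle lying within one
    tube radius of the longest fiber in ``tract`` (0 for an empty tract).

    The first cycle is the centerline prefix accumulating 360 degrees of
    turning around the spiral center.
    """
    if len(tract) == 0:
        return 0.0
    curve = dataset.bundle.curves[0]
    rel = curve.points - dataset.spec.center
    theta = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    turned = np.abs(theta - theta[0])
    first = curve.points[turned <= 2.0 * np.pi]
    longest = max(tract, key=lambda f: f.length)
    tree = cKDTree(longest.points)
    dist, _ = tree.query(first)
    return float(np.mean(dist <= dataset.spec.tube_radius))


def run_phantom_suite(config: ExperimentConfig) -> BenchmarkReport:
    """Run every (phantom, SNR, method) cell and assemble the report."""
    report = BenchmarkReport(config=asdict(config))
    tracts: Dict[Tuple[str, float, str], FiberTract] = {}
    datasets: Dict[Tuple[str, float], PhantomDataset] = {}

    for kind, snr in itertools.product(config.phantoms, config.snrs):
        spec = PhantomSpec(kind=kind, snr=snr,
                           seed=_phantom_seed(config.seed, kind, snr))
        ds = make_phantom(spec)
        datasets[(kind, snr)] = ds
        fitted = ds.fitted_field()
        thr = ds.core_mean_fa(fitted) - config.fa_offset
        for method in config.methods:
            key = f"{kind}/{snr:g}/{method}"
            t0 = time.perf_counter()
            try:
                if method == "gs":
                    gsp = GSParams(fa_threshold=thr, fa_fallback=thr,
                                   average_step=config.gs_average_step,
                                   n_offsets=config.gs_n_offsets,
                                   bending_angle_deg=config.gs_bending_angle_deg)
                    tract = reconstruct_pathway(fitted, ds.roi_a, ds.roi_b,
                                                params=gsp)
                else:
                    tp = TrackingParams(step_length=config.step_length,
                                        fa_threshold=thr,
                                        max_steps=config.max_steps)
                    fibers = track_volume(fitted, tp, method)
                    # SP/TD may need the incremental ROI-padding protocol
                    tract = FiberTract([])
                    padding = None
                    for pad in range(MAX_ROI_PADDING + 1):
                        tract = run_tracker(fitted, pad_roi(ds.roi_a, pad),
                                            pad_roi(ds.roi_b, pad), tp,
                                            method, fibers=fibers)
                        if len(tract) > 0:
                            padding = pad
                            break
                    if kind == "spiral":
                        from_a = run_tracker(fitted, ds.roi_a, ds.roi_a, tp,
                                             method, fibers=fibers)
                        report.coverage[key] = first_cycle_coverage(ds, from_a)
                status = "connected" if len(tract) > 0 else "failed"
                tracts[(kind, snr, method)] = tract
                cell = {"status": status, "n_fibers": len(tract),
                        "fa_threshold": round(thr, 6)}
                if method != "gs":
                    cell["roi_padding"] = padding
            except Exception as exc:  # a stage failure never aborts the suite
                cell = {"status": "error", "error": repr(exc)}
                tract = FiberTract([])
                tracts[(kind, snr, method)] = tract
            cell["runtime_s"] = round(time.perf_counter() - t0, 3)
            report.cells[key] = cell
            if kind == "spiral" and method == "gs":
                report.coverage[key] = first_cycle_coverage(ds, tract)

        if config.compare_pairs:
            for m1, m2 in itertools.combinations(config.methods, 2):
                t1 = tracts.get((kind, snr, m1))
                t2 = tracts.get((kind, snr, m2))
                if t1 is None or t2 is None or not len(t1) or not len(t2):
                    continue
                rep = tract_similarity(t1, t2, field=fitted,
                                       step=config.step_length)
                pair_key = f"{kind}/{snr:g}/{m1}-{m2}"
                report.similarity[pair_key] = {
                    k: (round(v, 6) if isinstance(v, float) else v)
                    for k, v in rep.as_dict().items()}
    return report


# -- group statistics -------------------------------------------------------

def mann_whitney_u(sample_a: Sequence[float], sample_b: Sequence[float],
                   alpha: float = 0.05):
    """Mann-Whitney U with a two-sided p-value.

    Exact enumeration over all group assignments (handles ties through
    midranks) for combined n <= 12; tie-corrected normal approximation
    otherwise.  Returns ``(U, p, significant)`` with U = min(U1, U2).
    All-tied samples return p = 1.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    u1 = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u2 = n1 * n2 - u1
    u = min(u1, u2)
    if np.all(pooled == pooled[0]):
        return u, 1.0, False
    mu = n1 * n2 / 2.0
    dev = abs(u1 - mu)
    if n1 + n2 <= 12:
        # exact: enumerate which pooled observations belong to group A
        from itertools import combinations

        total = comb(n1 + n2, n1)
        hits = 0
        for pick in combinations(range(n1 + n2), n1):
            u1_perm = ranks[list(pick)].sum() - n1 * (n1 + 1) / 2.0
            if abs(u1_perm - mu) >= dev - 1e-12:
                hits += 1
        p = hits / total
    else:
        _, p = sps.mannwhitneyu(a, b, alternative="two-sided",
                                method="asymptotic")
        p = float(p)
    return u, p, p < alpha
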