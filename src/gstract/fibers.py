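"""Fiber containers shared by the trackers and the similarity metrics.

A fiber is an ordered 3D polyline in world millimetres.  Fibers carry a
provenance mapping (method name, seed, parameters) so that tracts written to
disk remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np


@dataclass
class Fiber:
    """Ordered polyline in world mm.

    Invariants: at least 2 points, consecutive points distinct, hence a
    strictly increasing arc length.
    """

    points: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise ValueError("fiber points must be an (N, 3) array")
        if pts.shape[0] < 2:
            raise ValueError("a fiber needs at least 2 points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0.0):
            raise ValueError("consecutive fiber points must be distinct")
        self.points = pts

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def segment_lengths(self) -> np.ndarray:
        return np.linalg.norm(np.diff(self.points, axis=0), axis=1)

    @property
    def arc_lengths(self) -> np.ndarray:
        """Cumulative arc length per point, starting at 0."""
        return np.concatenate([[0.0], np.cumsum(self.segment_lengths)])

    @property
    def length(self) -> float:
        return float(self.segment_lengths.sum())

    def reversed(self) -> "Fiber":
        return Fiber(self.points[::-1].copy(), dict(self.provenance))


@dataclass
class FiberTract:
    """A set of fibers with shared provenance (method, ROI pair, thresholds)."""

    fibers: list
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self) -> Iterator[Fiber]:
        return iter(self.fibers)

    def __getitem__(self, i: int) -> Fiber:
        return self.fibers[i]


def polyline_arclength_resample(points: np.ndarray, step: float) -> np.ndarray:
    """Resample a polyline at equal arc-length spacing ``step``.

    Output points lie exactly on the input polyline (linear interpolation
    between input vertices, no smoothing); the first and last input points
    are preserved.  The final spacing may be shorter than ``step``.
    """
    pts = np.asarray(points, dtype=float)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total < step:
        raise ValueError("polyline shorter than the resampling step")
    targets = np.arange(0.0, total, step)
    if total - targets[-1] > 1e-12:
        targets = np.concatenate([targets, [total]])
    else:
        targets[-1] = total
    out = np.column_stack([np.interp(targets, s, pts[:, k]) for k in range(3)])
    out[0] = pts[0]
    out[-1] = pts[-1]
    return out


def is_uniformly_sampled(points: np.ndarray, rtol: float = 1e-6) -> bool:
    """True if all segments (except possibly the last) share one length."""
    seg = np.linalg.norm(np.diff(np.asarray(points, float), axis=0), axis=1)
    if seg.size <= 1:
        return True
    body = seg[:-1]
    ref = body[0]
    ok = np.allclose(body, ref, rtol=rtol, atol=1e-9)
    return ok and seg[-1] <= ref * (1 + rtol) + 1e-9
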