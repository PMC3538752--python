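"""DTI software phantoms: ground-truth geometry, tensors, DWI and noise.

The generator emulates clinical-protocol software phantoms: tube-shaped
bundles (straight, branching, kissing, and an inward Archimedean spiral with
more than three turns) rasterized into a prolate tensor field at 2 mm
isotropic voxels, forward-simulated into a 6-direction b=1000 s/mm^2 DWI
stack with Rician noise at a configurable SNR, plus end-region masks and the
true centerlines.

Noise convention: SNR = S0 / sigma on the b=0 image; Rician magnitude noise
sqrt((v + n1)^2 + n2^2) with n1, n2 ~ N(0, sigma^2).  The unit Gaussian
draws depend only on the seed, so realizations at different SNR with the
same seed differ only by the sigma scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field, asdict
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree

from .local_tracking import ROI
from .tensor_field import OBLIQUE_DOUBLE_GRADIENTS, TensorField, fit_tensors

PHANTOM_KINDS = ("straight", "branching", "kissing", "spiral")


@dataclass
class PhantomSpec:
    """Geometry, acquisition and noise parameters of one phantom."""

    kind: str = "straight"
    snr: float = 30.0
    seed: int = 0
    voxel_size: float = 2.0
    shape: Optional[Tuple[int, int, int]] = None
    tube_radius: float = 4.0
    # straight
    straight_length: float = 60.0
    # branching: trunk along +x splitting into two arms, filleted junction
    trunk_length: float = 30.0
    arm_length: float = 30.0
    branch_angle_deg: float = 40.0
    fillet_radius: float = 10.0
    # kissing: two circular arcs tangent at the volume center
    kiss_radius: float = 30.0
    kiss_half_angle_deg: float = 60.0
    # spiral: planar Archimedean r(theta) = r0 + k*theta, > 3 turns.
    # The radial pitch must exceed the tube diameter so that consecutive
    # whorls are separated by background; otherwise the tube sweeps a solid
    # disc and the phantom no longer represents a spiral pathway.
    spiral_turns: float = 3.5
    spiral_r0: float = 41.0
    spiral_r_end: float = 6.0
    # acquisition
    b_value: float = 1000.0
    s0: float = 1000.0
    # tensor profile: prolate eigenvalues in the bundle, isotropic outside
    lambdas: Tuple[float, float, float] = (1.7e-3, 3e-4, 3e-4)
    background_diffusivity: float = 7e-4

    def __post_init__(self) -> None:
        if self.kind not in PHANTOM_KINDS:
            raise ValueError(f"unknown phantom kind {self.kind!r}")
        if self.kind == "spiral":
            if not self.spiral_turns > 3.0:
                raise ValueError("the spiral must make more than three turns")
            pitch = (self.spiral_r0 - self.spiral_r_end) / self.spiral_turns
            if pitch <= 2.0 * self.tube_radius:
                raise ValueError(
                    "spiral radial pitch must exceed the tube diameter; "
                    "overlapping whorls merge into a disc")
        if not self.snr > 0:
            raise ValueError("snr must be positive")
        if self.tube_radius < self.voxel_size:
            raise ValueError("tube radius must be at least one voxel")
        if self.shape is None:
            self.shape = (48, 48, 16) if self.kind == "spiral" else (64, 64, 64)

    @property
    def gradients(self) -> np.ndarray:
        return OBLIQUE_DOUBLE_GRADIENTS

    @property
    def center(self) -> np.ndarray:
        return (np.array(self.shape, float) - 1.0) * self.voxel_size / 2.0

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size] * 3 + [1.0])

    @property
    def sample_step(self) -> float:
        """Centerline arc-length sampling, <= voxel/4 by contract."""
        return self.voxel_size / 4.0


@dataclass
class Curve:
    """Dense centerline polyline with unit tangents."""

    points: np.ndarray  # (N, 3) world mm
    tangents: np.ndarray  # (N, 3) unit vectors


@dataclass
class GroundTruthBundle:
    curves: List[Curve]
    tube_radius: float

    @property
    def endpoints(self) -> np.ndarray:
        """Unique curve endpoints (shared junction endpoints deduplicated)."""
        pts = []
        for c in self.curves:
            pts.append(c.points[0])
            pts.append(c.points[-1])
        uniq: List[np.ndarray] = []
        for p in pts:
            if not any(np.linalg.norm(p - q) < 1e-6 for q in uniq):
                uniq.append(p)
        return np.array(uniq)


@dataclass
class PhantomDataset:
    """Everything a tracking experiment needs, with ground truth attached."""

    spec: PhantomSpec
    bundle: GroundTruthBundle
    field: TensorField  # noiseless ground-truth tensors
    clean_dwi: np.ndarray
    noisy_dwi: np.ndarray
    bvals: np.ndarray
    bvecs: np.ndarray
    roi_a: ROI
    roi_b: ROI
    centerline_distance: np.ndarray  # per-voxel distance to nearest centerline

    def fitted_field(self, noisy: bool = True) -> TensorField:
        dwi = self.noisy_dwi if noisy else self.clean_dwi
        return fit_tensors(dwi, self.bvals, self.bvecs, affine=self.spec.affine)

    def tube_mask(self, radius_factor: float = 1.0) -> np.ndarray:
        return self.centerline_distance <= self.spec.tube_radius * radius_factor

    def core_mean_fa(self, field: Optional[TensorField] = None) -> float:
        """Average FA in the main part of the pathway (inner half-radius)."""
        f = self.field if field is None else field
        return float(f.fa[self.tube_mask(0.5)].mean())


# -- geometry ---------------------------------------------------------------

def _resample(points: np.ndarray, step: float) -> np.ndarray:
    from .fibers import polyline_arclength_resample

    return polyline_arclength_resample(points, step)


def _tangents(points: np.ndarray) -> np.ndarray:
    t = np.gradient(points, axis=0)
    return t / np.linalg.norm(t, axis=1, keepdims=True)


def _fillet(p_prev: np.ndarray, corner: np.ndarray, p_next: np.ndarray,
            radius: float, step: float) -> np.ndarray:
    """Polyline corner rounded by a tangent circular arc of given radius."""
    u = corner - p_prev
    v = p_next - corner
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    cosang = float(np.clip(u @ v, -1.0, 1.0))
    theta = np.arccos(cosang)
    if theta < 1e-9:
        return np.array([p_prev, p_next])
    t = radius * np.tan(theta / 2.0)
    a = corner - t * u  # arc start
    b = corner + t * v  # arc end
    n = v - u * cosang
    n = n / np.linalg.norm(n)  # unit normal toward the turn, perp to u
    centre = a + radius * n
    # rotate the radius vector (a - centre) toward (b - centre)
    k = int(np.ceil(radius * theta / step)) + 1
    ang = np.linspace(0.0, theta, k)
    r0 = a - centre
    axis = np.cross(u, n)
    axis = axis / np.linalg.norm(axis)
    arc = [centre + r0 * np.cos(s) + np.cross(axis, r0) * np.sin(s)
           for s in ang]
    return np.vstack([[p_prev], arc, [p_next]])


def build_geometry(spec: PhantomSpec) -> GroundTruthBundle:
    """Ground-truth centerlines for the requested phantom kind."""
    c = spec.center
    step = spec.sample_step
    x = np.array([1.0, 0.0, 0.0])

    if spec.kind == "straight":
        half = spec.straight_length / 2.0
        raw = [np.array([c - half * x, c + half * x])]
    elif spec.kind == "branching":
        start = c - spec.trunk_length * x
        raw = []
        for sgn in (+1.0, -1.0):
            ang = np.deg2rad(spec.branch_angle_deg)
            arm_dir = np.array([np.cos(ang), sgn * np.sin(ang), 0.0])
            tip = c + spec.arm_length * arm_dir
            raw.append(_fillet(start, c, tip, spec.fillet_radius, step))
    elif spec.kind == "kissing":
        phi = np.deg2rad(spec.kiss_half_angle_deg)
        ang = np.linspace(-phi, phi, 512)
        R = spec.kiss_radius
        raw = []
        for sgn in (+1.0, -1.0):
            pts = np.column_stack([
                R * np.sin(ang),
                sgn * R * (1.0 - np.cos(ang)),
                np.zeros_like(ang),
            ]) + c
            raw.append(pts)
    else:  # spiral
        theta_max = spec.spiral_turns * 2.0 * np.pi
        k = (spec.spiral_r_end - spec.spiral_r0) / theta_max
        # dense parameter sampling before arc-length resampling
        theta = np.linspace(0.0, theta_max, 8192)
        r = spec.spiral_r0 + k * theta
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta),
                               np.zeros_like(theta)]) + c
        raw = [pts]

    curves = []
    lo = np.zeros(3)
    hi = (np.array(spec.shape, float) - 1.0) * spec.voxel_size
    for pts in raw:
        pts = _resample(pts, step)
        if np.any(pts - spec.tube_radius < lo) or np.any(pts + spec.tube_radius > hi):
            raise ValueError("phantom geometry exits the volume")
        curves.append(Curve(points=pts, tangents=_tangents(pts)))
    return GroundTruthBundle(curves=curves, tube_radius=spec.tube_radius)


# -- rasterization ----------------------------------------------------------

def _prolate(tangent: np.ndarray, lambdas) -> np.ndarray:
    """Axially symmetric tensor with e1 = tangent, (..., 6) components."""
    l1, l2, _ = lambdas
    t = tangent
    out = np.empty(t.shape[:-1] + (6,))
    d = l1 - l2
    out[..., 0] = l2 + d * t[..., 0] * t[..., 0]
    out[..., 1] = l2 + d * t[..., 1] * t[..., 1]
    out[..., 2] = l2 + d * t[..., 2] * t[..., 2]
    out[..., 3] = d * t[..., 0] * t[..., 1]
    out[..., 4] = d * t[..., 0] * t[..., 2]
    out[..., 5] = d * t[..., 1] * t[..., 2]
    return out


def _voxel_centers(spec: PhantomSpec) -> np.ndarray:
    idx = np.indices(spec.shape).reshape(3, -1).T
    return idx * spec.voxel_size


def rasterize_tensors(bundle: GroundTruthBundle, spec: PhantomSpec,
                      return_distance: bool = False):
    """Voxelize the bundle into a tensor field.

    In-tube voxels get a prolate tensor aligned with the local tangent;
    overlap voxels (kissing, branching) get the component-wise mean of all
    contributing prolate tensors; background voxels are isotropic.
    """
    centers = _voxel_centers(spec)
    nvox = centers.shape[0]
    acc = np.zeros((nvox, 6))
    count = np.zeros(nvox, dtype=int)
    min_dist = np.full(nvox, np.inf)
    for curve in bundle.curves:
        tree = cKDTree(curve.points)
        dist, idx = tree.query(centers)
        min_dist = np.minimum(min_dist, dist)
        inside = dist <= bundle.tube_radius
        acc[inside] += _prolate(curve.tangents[idx[inside]], spec.lambdas)
        count[inside] += 1
    iso = np.zeros(6)
    iso[:3] = spec.background_diffusivity
    data = np.tile(iso, (nvox, 1))
    tube = count > 0
    data[tube] = acc[tube] / count[tube, None]
    field = TensorField(data.reshape(spec.shape + (6,)), affine=spec.affine)
    if return_distance:
        return field, min_dist.reshape(spec.shape)
    return field


# -- signal simulation ------------------------------------------------------

def simulate_dwi(field: TensorField, spec: PhantomSpec):
    """Noiseless DWI stack: one b=0 volume plus one per gradient.

    Returns ``(dwi, bvals, bvecs)`` with S = S0 * exp(-b g^T D g).
    """
    g = np.asarray(spec.gradients, float)
    if not np.allclose(np.linalg.norm(g, axis=1), 1.0, atol=1e-9):
        raise ValueError("gradient directions must be unit-norm")
    nx, ny, nz = field.shape
    k = g.shape[0]
    dwi = np.empty((nx, ny, nz, k + 1))
    dwi[..., 0] = spec.s0
    d = field.data
    for i, gi in enumerate(g):
        q = (d[..., 0] * gi[0] ** 2 + d[..., 1] * gi[1] ** 2
             + d[..., 2] * gi[2] ** 2
             + 2 * d[..., 3] * gi[0] * gi[1]
             + 2 * d[..., 4] * gi[0] * gi[2]
             + 2 * d[..., 5] * gi[1] * gi[2])
        dwi[..., i + 1] = spec.s0 * np.exp(-spec.b_value * q)
    bvals = np.concatenate([[0.0], np.full(k, spec.b_value)])
    bvecs = np.vstack([np.zeros(3), g])
    return dwi, bvals, bvecs


def add_rician_noise(images: np.ndarray, snr: float, seed: int,
                     s0: float = 1000.0) -> np.ndarray:
    """Rician noise: v -> sqrt((v + n1)^2 + n2^2), sigma = S0 / snr.

    The unit-variance draws depend only on the seed, so the same seed at two
    SNRs yields noise differing only by the sigma scaling.
    """
    if not snr > 0:
        raise ValueError("snr must be positive")
    rng = np.random.default_rng(seed)
    n1 = rng.standard_normal(images.shape)
    n2 = rng.standard_normal(images.shape)
    sigma = s0 / snr
    return np.sqrt((images + sigma * n1) ** 2 + (sigma * n2) ** 2)


# -- ROIs -------------------------------------------------------------------

def _slab_mask(spec: PhantomSpec, endpoint: np.ndarray, tangent: np.ndarray,
               thickness_voxels: int = 1) -> np.ndarray:
    """Axis-aligned one-voxel slab through the endpoint covering the tube."""
    axis = int(np.argmax(np.abs(tangent)))
    centers = _voxel_centers(spec).reshape(spec.shape + (3,))
    along = np.abs(centers[..., axis] - endpoint[axis])
    lateral = np.delete(centers - endpoint, axis, axis=-1)
    lat_dist = np.linalg.norm(lateral, axis=-1)
    half = thickness_voxels * spec.voxel_size / 2.0
    return (along <= half + 1e-9) & (lat_dist <= spec.tube_radius + spec.voxel_size)


def place_rois(bundle: GroundTruthBundle, spec: PhantomSpec) -> Tuple[ROI, ROI]:
    """End-region slabs covering the full tube diameter.

    roi_a sits at the first curve's first endpoint (the trunk end / the
    spiral's outer end); roi_b at the last endpoint, covering both leaf ends
    for the branching phantom.
    """
    first = bundle.curves[0]
    mask_a = _slab_mask(spec, first.points[0], first.tangents[0])
    if spec.kind == "branching":
        mask_b = np.zeros(spec.shape, dtype=bool)
        for curve in bundle.curves:
            mask_b |= _slab_mask(spec, curve.points[-1], curve.tangents[-1])
    else:
        mask_b = _slab_mask(spec, first.points[-1], first.tangents[-1])
    if not np.any(mask_a) or not np.any(mask_b):
        raise ValueError("ROI endpoints fall outside the volume")
    if np.any(mask_a & mask_b):
        raise ValueError("end ROIs overlap; phantom geometry too small")
    return ROI(mask_a), ROI(mask_b)


# -- assembly ---------------------------------------------------------------

def make_phantom(spec: PhantomSpec) -> PhantomDataset:
    """Build the full synthetic dataset for one spec (deterministic)."""
    bundle = build_geometry(spec)
    field, dist = rasterize_tensors(bundle, spec, return_distance=True)
    clean, bvals, bvecs = simulate_dwi(field, spec)
    noisy = add_rician_noise(clean, spec.snr, spec.seed, s0=spec.s0)
    roi_a, roi_b = place_rois(bundle, spec)
    return PhantomDataset(spec=spec, bundle=bundle, field=field,
                          clean_dwi=clean, noisy_dwi=noisy, bvals=bvals,
                          bvecs=bvecs, roi_a=roi_a, roi_b=roi_b,
                          centerline_distance=dist)


def write_phantom(dataset: PhantomDataset, outdir) -> None:
    """Write DWI/b0/FA/masks as NIfTI, bval/bvec text, centerlines, spec."""
    import pathlib

    import nibabel as nib
    from nibabel.streamlines import Tractogram, save as trk_save

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    aff = dataset.spec.affine

    def _save(arr, name, dtype=np.float32):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), str(out / name))

    _save(dataset.noisy_dwi, "dwi.nii.gz")
    _save(dataset.noisy_dwi[..., 0], "b0.nii.gz")
    _save(dataset.field.fa, "fa.nii.gz")
    _save(dataset.roi_a.mask, "roi_a.nii.gz", dtype=np.uint8)
    _save(dataset.roi_b.mask, "roi_b.nii.gz", dtype=np.uint8)
    np.savetxt(out / "dwi.bval", dataset.bvals[None], fmt="%g")
    np.savetxt(out / "dwi.bvec", dataset.bvecs.T, fmt="%.8f")
    tg = Tractogram([c.points for c in dataset.bundle.curves],
                    affine_to_rasmm=np.eye(4))
    trk_save(tg, str(out / "centerlines.trk"))
    spec_dict = asdict(dataset.spec)
    (out / "spec.json").write_text(json.dumps(spec_dict, indent=2))
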