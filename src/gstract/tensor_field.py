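"""Diffusion-tensor data model.

Tensors are stored as 6 unique components in the order
``(dxx, dyy, dzz, dxy, dxz, dyz)``; any array whose last axis has length 6 in
this order is accepted by the functions below.  World coordinates are
millimetres; voxel indices are 0-based and voxel centers sit at integer
indices under the affine.

The tensor fit is the classical log-linear least-squares solution of the
mono-exponential signal model ``S_k = S0 * exp(-b_k g_k^T D g_k)``, which is
exact for the six-direction clinical protocol this package emulates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

TENSOR_COMPONENTS = ("dxx", "dyy", "dzz", "dxy", "dxz", "dyz")

#: Oblique double gradient encoding scheme: six non-collinear unit directions
#: (+-1,1,0), (+-1,0,1), (0,1,+-1), normalized.
OBLIQUE_DOUBLE_GRADIENTS = np.array(
    [
        [1, 1, 0],
        [-1, 1, 0],
        [1, 0, 1],
        [-1, 0, 1],
        [0, 1, 1],
        [0, 1, -1],
    ],
    dtype=float,
) / np.sqrt(2.0)


class OutOfBoundsError(ValueError):
    """A world point fell outside the field's interpolatable domain."""


def tensor_to_matrix(t6: np.ndarray) -> np.ndarray:
    """(..., 6) component vector -> (..., 3, 3) symmetric matrix."""
    t6 = np.asarray(t6, dtype=float)
    m = np.empty(t6.shape[:-1] + (3, 3), dtype=float)
    m[..., 0, 0] = t6[..., 0]
    m[..., 1, 1] = t6[..., 1]
    m[..., 2, 2] = t6[..., 2]
    m[..., 0, 1] = m[..., 1, 0] = t6[..., 3]
    m[..., 0, 2] = m[..., 2, 0] = t6[..., 4]
    m[..., 1, 2] = m[..., 2, 1] = t6[..., 5]
    return m


def matrix_to_tensor(m: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrix -> (..., 6) component vector."""
    m = np.asarray(m, dtype=float)
    return np.stack(
        [m[..., 0, 0], m[..., 1, 1], m[..., 2, 2],
         m[..., 0, 1], m[..., 0, 2], m[..., 1, 2]],
        axis=-1,
    )


@dataclass
class EigenSystem:
    """Eigenvalues in non-increasing order with orthonormal eigenvectors."""

    lambdas: np.ndarray  # (..., 3), lambda1 >= lambda2 >= lambda3
    vectors: np.ndarray  # (..., 3, 3), vectors[..., :, i] is e_{i+1}

    @property
    def lambda1(self) -> np.ndarray:
        return self.lambdas[..., 0]

    @property
    def e1(self) -> np.ndarray:
        return self.vectors[..., :, 0]

    @property
    def e2(self) -> np.ndarray:
        return self.vectors[..., :, 1]

    @property
    def e3(self) -> np.ndarray:
        return self.vectors[..., :, 2]


@dataclass
class ShapeCoefficients:
    """Westin linear/planar/spherical shape fractions (cl + cp + cs = 1)."""

    cl: np.ndarray
    cp: np.ndarray
    cs: np.ndarray
    shape_class: np.ndarray  # 0 linear, 1 planar, 2 spherical
    degenerate: np.ndarray  # True where lambda1 <= 0 (shape undefined)


SHAPE_LINEAR, SHAPE_PLANAR, SHAPE_SPHERICAL = 0, 1, 2


def eigendecompose(t6: np.ndarray) -> EigenSystem:
    """Ordered eigensystem of one tensor or a batch of tensors.

    Eigenvalues come out non-increasing; eigenvector signs are arbitrary
    (sign coherence is the trackers' responsibility).
    """
    t6 = np.asarray(t6, dtype=float)
    if not np.all(np.isfinite(t6)):
        raise ValueError("non-finite tensor components")
    m = tensor_to_matrix(t6)
    w, v = np.linalg.eigh(m)  # ascending
    return EigenSystem(lambdas=w[..., ::-1].copy(), vectors=v[..., :, ::-1].copy())


def fractional_anisotropy(lambdas: np.ndarray) -> np.ndarray:
    """FA = sqrt(3/2) * ||lambda - mean|| / ||lambda||, clipped to [0, 1].

    Accepts eigenvalues (..., 3).  All-zero tensors return 0 by convention;
    negative eigenvalues are clamped to 0 before evaluation.
    """
    lam = np.clip(np.asarray(lambdas, dtype=float), 0.0, None)
    norm2 = np.sum(lam * lam, axis=-1)
    mean = np.mean(lam, axis=-1, keepdims=True)
    dev2 = np.sum((lam - mean) ** 2, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5 * dev2 / norm2)
    fa = np.where(norm2 > 0.0, fa, 0.0)
    return np.clip(fa, 0.0, 1.0)


def westin_shape(lambdas: np.ndarray) -> ShapeCoefficients:
    """Westin shape fractions cl=(l1-l2)/l1, cp=(l2-l3)/l1, cs=l3/l1.

    The class is the argmax; ties break in the order linear > planar >
    spherical.  Non-positive lambda1 yields the spherical class with the
    degenerate flag set.
    """
    lam = np.asarray(lambdas, dtype=float)
    l1, l2, l3 = lam[..., 0], lam[..., 1], lam[..., 2]
    degenerate = l1 <= 0.0
    safe = np.where(degenerate, 1.0, l1)
    cl = np.where(degenerate, 0.0, (l1 - l2) / safe)
    cp = np.where(degenerate, 0.0, (l2 - l3) / safe)
    cs = np.where(degenerate, 1.0, l3 / safe)
    stacked = np.stack([cl, cp, cs], axis=-1)
    # argmax returns the first maximum, which is exactly the stated tie order
    shape_class = np.argmax(stacked, axis=-1)
    shape_class = np.where(degenerate, SHAPE_SPHERICAL, shape_class)
    return ShapeCoefficients(cl=cl, cp=cp, cs=cs,
                             shape_class=shape_class, degenerate=degenerate)


class TensorField:
    """3D grid of diffusion tensors with voxel geometry.

    Parameters
    ----------
    data : (nx, ny, nz, 6) array of tensor components.
    affine : 4x4 voxel-index -> world-mm map (must be invertible).
    """

    def __init__(self, data: np.ndarray, affine: Optional[np.ndarray] = None,
                 voxel_size: Optional[Tuple[float, float, float]] = None):
        data = np.asarray(data, dtype=float)
        if data.ndim != 4 or data.shape[-1] != 6:
            raise ValueError("tensor field data must be (nx, ny, nz, 6)")
        if affine is None:
            vs = (1.0, 1.0, 1.0) if voxel_size is None else tuple(voxel_size)
            affine = np.diag(list(vs) + [1.0])
        affine = np.asarray(affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        self.data = data
        self.affine = affine
        self._inv_affine = np.linalg.inv(affine)
        self._fa: Optional[np.ndarray] = None
        self.fit_failed: Optional[np.ndarray] = None

    # -- geometry ----------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def voxel_size(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.asarray(xyz, dtype=float)
        return xyz @ self._inv_affine[:3, :3].T + self._inv_affine[:3, 3]

    def world_bounds(self) -> Tuple[np.ndarray, np.ndarray]:
        """Axis-aligned world box spanned by the voxel-center lattice."""
        n = np.array(self.shape, dtype=float) - 1.0
        corners = np.array([[i, j, k] for i in (0, n[0]) for j in (0, n[1])
                            for k in (0, n[2])])
        w = self.voxel_to_world(corners)
        return w.min(axis=0), w.max(axis=0)

    # -- per-voxel measures ------------------------------------------------
    @property
    def fa(self) -> np.ndarray:
        """Per-voxel FA map, computed once and cached."""
        if self._fa is None:
            es = eigendecompose(self.data.reshape(-1, 6))
            self._fa = fractional_anisotropy(es.lambdas).reshape(self.shape)
        return self._fa

    # -- interpolation -----------------------------------------------------
    def interpolate(self, points: np.ndarray, mode: str = "raise") -> np.ndarray:
        """Trilinear component-wise interpolation at world-mm points.

        ``mode='raise'`` raises :class:`OutOfBoundsError` for points outside
        the voxel-center lattice; ``mode='nan'`` returns NaN rows instead
        (trackers treat these as termination).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        vox = self.world_to_voxel(pts)
        n = np.array(self.shape)
        inside = np.all((vox >= 0.0) & (vox <= n - 1), axis=1)
        if mode == "raise" and not np.all(inside):
            raise OutOfBoundsError("point outside tensor field domain")
        out = np.full((pts.shape[0], 6), np.nan)
        if np.any(inside):
            v = vox[inside]
            i0 = np.maximum(np.minimum(np.floor(v).astype(int), n - 2), 0)
            f = v - i0
            acc = np.zeros((v.shape[0], 6))
            for dx in (0, 1):
                wx = f[:, 0] if dx else 1.0 - f[:, 0]
                ix = np.minimum(i0[:, 0] + dx, n[0] - 1)
                for dy in (0, 1):
                    wy = f[:, 1] if dy else 1.0 - f[:, 1]
                    iy = np.minimum(i0[:, 1] + dy, n[1] - 1)
                    for dz in (0, 1):
                        wz = f[:, 2] if dz else 1.0 - f[:, 2]
                        iz = np.minimum(i0[:, 2] + dz, n[2] - 1)
                        w = (wx * wy * wz)[:, None]
                        acc += w * self.data[ix, iy, iz]
            out[inside] = acc
        if np.asarray(points).ndim == 1:
            return out[0]
        return out

    def fa_at(self, points: np.ndarray, mode: str = "raise") -> np.ndarray:
        """FA of the trilinearly interpolated tensor at world-mm points.

        NaN where out of bounds under ``mode='nan'``.
        """
        t = np.atleast_2d(self.interpolate(points, mode=mode))
        ok = np.all(np.isfinite(t), axis=1)
        fa = np.full(t.shape[0], np.nan)
        if np.any(ok):
            es = eigendecompose(t[ok])
            fa[ok] = fractional_anisotropy(es.lambdas)
        if np.asarray(points).ndim == 1:
            return fa[0]
        return fa


def design_matrix(bvals: np.ndarray, bvecs: np.ndarray) -> np.ndarray:
    """Rows mapping (ln S0, dxx, dyy, dzz, dxy, dxz, dyz) -> ln S_k."""
    bvals = np.asarray(bvals, dtype=float)
    g = np.asarray(bvecs, dtype=float)
    X = np.empty((len(bvals), 7))
    X[:, 0] = 1.0
    X[:, 1] = -bvals * g[:, 0] ** 2
    X[:, 2] = -bvals * g[:, 1] ** 2
    X[:, 3] = -bvals * g[:, 2] ** 2
    X[:, 4] = -bvals * 2.0 * g[:, 0] * g[:, 1]
    X[:, 5] = -bvals * 2.0 * g[:, 0] * g[:, 2]
    X[:, 6] = -bvals * 2.0 * g[:, 1] * g[:, 2]
    return X


def fit_tensors(dwi: np.ndarray, bvals: np.ndarray, bvecs: np.ndarray,
                affine: Optional[np.ndarray] = None) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Parameters
    ----------
    dwi : (nx, ny, nz, K) signal stack, K >= 7, including >= 1 b=0 volume.
    bvals : (K,) b-values in s/mm^2.
    bvecs : (K, 3) unit gradient directions (ignored where b = 0).

    Voxels with any non-positive signal cannot be log-transformed; they
    receive the zero tensor and are flagged in ``field.fit_failed``.
    """
    dwi = np.asarray(dwi, dtype=float)
    bvals = np.asarray(bvals, dtype=float)
    bvecs = np.asarray(bvecs, dtype=float)
    if dwi.ndim != 4:
        raise ValueError("dwi must be a 4D (x, y, z, volume) stack")
    if dwi.shape[-1] != len(bvals) or len(bvals) != len(bvecs):
        raise ValueError("dwi volume count, bvals and bvecs must agree")
    if not np.any(bvals == 0):
        raise ValueError("at least one b=0 reference volume is required")
    dw = bvals > 0
    if np.linalg.matrix_rank(design_matrix(bvals[dw], bvecs[dw])[:, 1:]) < 6:
        raise ValueError("need >= 6 non-collinear diffusion directions")

    X = design_matrix(bvals, bvecs)
    pinv = np.linalg.pinv(X)
    flat = dwi.reshape(-1, dwi.shape[-1])
    ok = np.all(flat > 0.0, axis=1)
    coef = np.zeros((flat.shape[0], 7))
    if np.any(ok):
        coef[ok] = np.log(flat[ok]) @ pinv.T
    tensors = coef[:, 1:]
    tensors[~ok] = 0.0
    field = TensorField(tensors.reshape(dwi.shape[:3] + (6,)), affine=affine)
    field.fit_failed = (~ok).reshape(dwi.shape[:3])
    return field


def interpolate_tensor(field: TensorField, point: np.ndarray) -> np.ndarray:
    """Trilinearly interpolated tensor components at one world-mm point."""
    return field.interpolate(point, mode="raise")


# -- NIfTI / FSL-style I/O --------------------------------------------------

def load_dwi(nifti_path, bval_path, bvec_path):
    """Read a 4D DWI NIfTI plus FSL-style *.bval / *.bvec text files."""
    import nibabel as nib

    img = nib.load(str(nifti_path))
    bvals = np.loadtxt(str(bval_path)).ravel()
    bvecs = np.loadtxt(str(bvec_path))
    if bvecs.shape[0] == 3 and bvecs.shape != (3, 3):
        bvecs = bvecs.T
    return np.asarray(img.get_fdata()), bvals, bvecs, img.affine


def save_field(field: TensorField, tensor_path, fa_path=None) -> None:
    """Write the 6-component tensor volume (and optionally the FA map)."""
    import nibabel as nib

    nib.save(nib.Nifti1Image(field.data.astype(np.float32), field.affine),
             str(tensor_path))
    if fa_path is not None:
        nib.save(nib.Nifti1Image(field.fa.astype(np.float32), field.affine),
                 str(fa_path))
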