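"""16-dimensional local texture features on a regular 3D sampling grid.

At every sampling centre a cubic patch is read out of four volumes — the raw
intensities and the three voxelwise Hessian eigenvalue fields (sorted
lambda1 >= lambda2 >= lambda3 by signed value) — and four statistical moments
(mean, standard deviation, skewness, kurtosis) are computed on each patch.
Concatenating the four moment quadruples gives the 16-vector; intensity
moments capture attenuation, the eigenvalue moments capture local geometry
(blob-like, tube-like, plate-like second-order structure).

Conventions (all deliberately exact so tests can be bit-level):

* Hessian by second-order central finite differences on the raw volume with
  replicate padding; diagonal terms use f[i+1] - 2 f[i] + f[i-1], mixed terms
  apply the first-difference operator twice.  Exact on quadratics.
* Moments are population (biased) moments; kurtosis is non-excess; a
  zero-variance patch has skewness = kurtosis = 0 by convention.
* A patch of size s at centre c spans the half-open index range
  [c - s//2, c - s//2 + s) per axis; only centres whose full patch lies
  inside the volume are sampled, on a lattice of stride ``step`` starting at
  the smallest valid centre; centres are ordered lexicographically (x, y, z).

This module is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .volume import Volume

FEATURE_DIM = 16

#: Column names of the feature matrix, in order.
FEATURE_NAMES = tuple(
    f"{channel}_{moment}"
    for channel in ("intensity", "lambda1", "lambda2", "lambda3")
    for moment in ("mean", "sd", "skewness", "kurtosis")
)


@dataclass
class EigenvalueVolumes:
    """Voxelwise Hessian eigenvalue fields, sorted lambda1 >= lambda2 >= lambda3."""

    lambda1: np.ndarray
    lambda2: np.ndarray
    lambda3: np.ndarray


@dataclass
class FeatureMatrix:
    """m x 16 local feature vectors plus sampling provenance."""

    rows: np.ndarray
    voi_id: str = ""
    patch_size: int = 0
    step: int = 0
    centers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if self.rows.ndim != 2 or self.rows.shape[1] != FEATURE_DIM:
            raise ValueError(
                f"feature matrix must be m x {FEATURE_DIM}, got {self.rows.shape}"
            )
        if not np.isfinite(self.rows).all():
            raise ValueError("feature matrix contains non-finite entries")

    @property
    def n_rows(self) -> int:
        return self.rows.shape[0]


def _diff1(v: np.ndarray, axis: int) -> np.ndarray:
    """First derivative, central differences, replicate boundary."""
    p = np.pad(v, [(1, 1) if a == axis else (0, 0) for a in range(v.ndim)], mode="edge")
    up = np.take(p, np.arange(2, v.shape[axis] + 2), axis=axis)
    dn = np.take(p, np.arange(0, v.shape[axis]), axis=axis)
    return (up - dn) / 2.0


def _diff2(v: np.ndarray, axis: int) -> np.ndarray:
    """Second derivative, f[i+1] - 2 f[i] + f[i-1], replicate boundary."""
    p = np.pad(v, [(1, 1) if a == axis else (0, 0) for a in range(v.ndim)], mode="edge")
    up = np.take(p, np.arange(2, v.shape[axis] + 2), axis=axis)
    dn = np.take(p, np.arange(0, v.shape[axis]), axis=axis)
    return up - 2.0 * v + dn


def hessian_components(voxels: np.ndarray) -> dict[str, np.ndarray]:
    """The six distinct entries of the discrete Hessian at every voxel."""
    v = np.asarray(voxels, dtype=np.float64)
    dx = _diff1(v, 0)
    dy = _diff1(v, 1)
    return {
        "xx": _diff2(v, 0),
        "yy": _diff2(v, 1),
        "zz": _diff2(v, 2),
        "xy": _diff1(dx, 1),
        "xz": _diff1(dx, 2),
        "yz": _diff1(dy, 2),
    }


def hessian_eigen(volume: Volume | np.ndarray) -> EigenvalueVolumes:
    """Voxelwise eigenvalues of the discrete Hessian, sorted descending.

    A flat volume has zero second derivatives everywhere and therefore yields
    all-zero eigenvalue fields.
    """
    voxels = volume.voxels if isinstance(volume, Volume) else np.asarray(voxels_arg(volume))
    h = hessian_components(voxels)
    shape = voxels.shape
    H = np.empty(shape + (3, 3), dtype=np.float64)
    H[..., 0, 0] = h["xx"]
    H[..., 1, 1] = h["yy"]
    H[..., 2, 2] = h["zz"]
    H[..., 0, 1] = H[..., 1, 0] = h["xy"]
    H[..., 0, 2] = H[..., 2, 0] = h["xz"]
    H[..., 1, 2] = H[..., 2, 1] = h["yz"]
    eig = np.linalg.eigvalsh(H.reshape(-1, 3, 3))  # ascending
    eig = eig[:, ::-1].reshape(shape + (3,))  # descending by signed value
    return EigenvalueVolumes(
        lambda1=np.ascontiguousarray(eig[..., 0]),
        lambda2=np.ascontiguousarray(eig[..., 1]),
        lambda3=np.ascontiguousarray(eig[..., 2]),
    )


def voxels_arg(v) -> np.ndarray:
    arr = np.asarray(v, dtype=np.float64)
    if arr.ndim != 3:
        raise ValueError(f"expected a 3D grid, got ndim={arr.ndim}")
    return arr


def sampling_centers(
    voi_shape: tuple[int, int, int], step: int, patch_size: int
) -> np.ndarray:
    """Regular lattice of patch centres whose full patch fits in the volume.

    Returns an (m, 3) integer array in lexicographic (x, y, z) order.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1, got {step}")
    if patch_size < 1:
        raise ValueError(f"patch_size must be >= 1, got {patch_size}")
    half = patch_size // 2
    per_axis = []
    for dim in voi_shape:
        if patch_size > dim:
            raise ValueError(
                f"patch of size {patch_size} does not fit in a volume of "
                f"extent {dim}"
            )
        # valid centres c satisfy c - half >= 0 and c - half + patch_size <= dim
        per_axis.append(np.arange(half, dim - patch_size + half + 1, step))
    grids = np.meshgrid(*per_axis, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def patch_moments(patch: np.ndarray) -> tuple[float, float, float, float]:
    """(mean, sd, skewness, kurtosis) of one patch, population convention."""
    x = np.asarray(patch, dtype=np.float64).ravel()
    if x.size == 0:
        raise ValueError("patch is empty")
    m = _moments_of_rows(x[None, :])
    return tuple(float(v) for v in m[0])


def _moments_of_rows(x: np.ndarray) -> np.ndarray:
    """Rows of (mean, sd, skew, kurt) for a (m, p) matrix of flattened patches."""
    mu = x.mean(axis=1)
    d = x - mu[:, None]
    var = np.mean(d * d, axis=1)
    sd = np.sqrt(var)
    out = np.zeros((x.shape[0], 4))
    out[:, 0] = mu
    out[:, 1] = sd
    ok = sd > 0
    if np.any(ok):
        z = d[ok] / sd[ok, None]
        out[ok, 2] = np.mean(z**3, axis=1)
        out[ok, 3] = np.mean(z**4, axis=1)
    return out


def _gather_patches(voxels: np.ndarray, centers: np.ndarray, patch_size: int) -> np.ndarray:
    """(m, patch_size**3) matrix of flattened patches at the given centres."""
    s = patch_size
    starts = centers - s // 2
    windows = sliding_window_view(voxels, (s, s, s))
    return windows[starts[:, 0], starts[:, 1], starts[:, 2]].reshape(len(centers), -1)


def extract_features(
    volume: Volume | np.ndarray,
    patch_size: int,
    step: int = 4,
    expected_shape: tuple[int, int, int] | None = None,
) -> FeatureMatrix:
    """Extract the m x 16 feature matrix of one VOI.

    The Hessian eigenvalue fields are computed once for the whole volume and
    then patched, so every patch sees eigenvalues of the full-volume Hessian
    (not of a Hessian recomputed per patch).

    ``expected_shape`` is the pipeline's shape gate: pass (32, 32, 32) to
    reject off-size volumes; leave ``None`` to accept any shape the patch
    fits in.
    """
    if isinstance(volume, Volume):
        if expected_shape is not None:
            volume.require_shape(expected_shape)
        volume.require_finite()
        voxels = volume.voxels
        voi_id = volume.identifier
    else:
        voxels = voxels_arg(volume)
        if expected_shape is not None and tuple(voxels.shape) != tuple(expected_shape):
            raise ValueError(
                f"volume has shape {voxels.shape}, expected {tuple(expected_shape)}"
            )
        voi_id = ""
    centers = sampling_centers(voxels.shape, step, patch_size)
    eig = hessian_eigen(Volume(voxels))
    blocks = []
    for channel in (voxels, eig.lambda1, eig.lambda2, eig.lambda3):
        patches = _gather_patches(channel, centers, patch_size)
        blocks.append(_moments_of_rows(patches))
    rows = np.hstack(blocks)
    return FeatureMatrix(
        rows=rows, voi_id=voi_id, patch_size=patch_size, step=step, centers=centers
    )


__all__ = [
    "FEATURE_DIM",
    "FEATURE_NAMES",
    "EigenvalueVolumes",
    "FeatureMatrix",
    "extract_features",
    "hessian_components",
    "hessian_eigen",
    "patch_moments",
    "sampling_centers",
]
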