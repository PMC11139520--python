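"""Displacement vector fields (DVF) and their training losses.

The DVF assigns to every foreground voxel the displacement to its nearest
background voxel; background voxels carry the zero vector.  Taking the L2
norm per voxel turns a DVF into the Euclidean distance map of the
foreground, which is what the watershed post-processing consumes.

Conventions used throughout the package
---------------------------------------
* 3D grids are indexed ``(z, y, x)``.
* A field is a float array of shape ``(3, nz, ny, nx)`` with channel order
  ``(dx, dy, dz)`` so that channel values are ``(x - x', y - y', z - z')``
  for nearest background voxel ``(x', y', z')``.
* When several background voxels are equidistant, the one with the smallest
  linear index in z-major ``(z, y, x)`` order is chosen.  This tie-break is
  a package convention, stated here once and relied on by the tests.
* Nearest background is searched within the volume only: the region outside
  the grid is not treated as background (volumes are crops of larger
  stacks, so borders behave as foreground continuation).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "LossWeights",
    "compute_dvf",
    "dvf_to_distance",
    "displacement_loss",
    "direction_loss",
    "total_loss",
    "displacement_loss_grad",
    "direction_loss_grad",
    "total_loss_grad",
]


@dataclass(frozen=True)
class LossWeights:
    """Weights of the combined loss ``omega1 * L_d + omega2 * L_r``.

    Defaults (7, 1) follow the values fixed after the weighting ablation.
    """

    omega1: float = 7.0
    omega2: float = 1.0

    def __post_init__(self) -> None:
        if self.omega1 < 0 or self.omega2 < 0:
            raise ValueError("loss weights must be non-negative")
        if self.omega1 + self.omega2 <= 0:
            raise ValueError("at least one loss weight must be positive")


def _validate_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.ndim != 3:
        raise ValueError(f"instance mask must be 3D, got shape {mask.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        if np.issubdtype(mask.dtype, np.floating) and np.all(mask == np.round(mask)):
            mask = mask.astype(np.int64)
        else:
            raise ValueError("instance mask must be integer-valued")
    if mask.min() < 0:
        raise ValueError("instance mask labels must be non-negative")
    return mask


def compute_dvf(mask: np.ndarray, spacing: tuple[float, float, float] | None = None) -> np.ndarray:
    """Ground-truth displacement vector field of an instance mask.

    Parameters
    ----------
    mask
        3D integer array; 0 is background, positive values are instances.
    spacing
        Optional physical voxel size ``(sz, sy, sx)`` used to weight the
        Euclidean distance when finding the nearest background voxel.  The
        returned displacements are always index differences (voxel units).

    Returns
    -------
    ndarray of shape ``(3, nz, ny, nx)`` with channels ``(dx, dy, dz)``.
    """
    mask = _validate_mask(mask)
    fg = mask > 0
    field = np.zeros((3,) + mask.shape, dtype=np.float64)
    if not fg.any():
        return field
    if fg.all():
        raise ValueError("mask has no background voxel; DVF is undefined")

    sz, sy, sx = (1.0, 1.0, 1.0) if spacing is None else tuple(float(s) for s in spacing)
    if min(sz, sy, sx) <= 0:
        raise ValueError("spacing components must be positive")

    # Exact distances from the sampled EDT; pointers are resolved separately
    # so the documented tie-break (smallest z-major linear index) holds.
    dist = ndi.distance_transform_edt(fg, sampling=(sz, sy, sx))
    d2 = dist**2

    nz, ny, nx = mask.shape
    zz, yy, xx = np.nonzero(fg)
    vox_d2 = d2[zz, yy, xx]
    # Group foreground voxels by their (squared) distance; for each group
    # enumerate every integer offset of exactly that length and keep, per
    # voxel, the in-bounds background target with the smallest linear index.
    key = np.round(vox_d2, 6)
    bg = ~fg
    lin_best = np.full(zz.shape, np.iinfo(np.int64).max, dtype=np.int64)

    for r2 in np.unique(key):
        sel = key == r2
        gz, gy, gx = zz[sel], yy[sel], xx[sel]
        off = _offsets_for_radius(float(r2), sz, sy, sx)
        best = np.full(gz.shape, np.iinfo(np.int64).max, dtype=np.int64)
        for oz, oy, ox in off:
            tz, ty, tx = gz + oz, gy + oy, gx + ox
            ok = (
                (tz >= 0) & (tz < nz) & (ty >= 0) & (ty < ny) & (tx >= 0) & (tx < nx)
            )
            if not ok.any():
                continue
            lin = np.full(gz.shape, np.iinfo(np.int64).max, dtype=np.int64)
            cand = (tz[ok] * ny + ty[ok]) * nx + tx[ok]
            cand = np.where(bg[tz[ok], ty[ok], tx[ok]], cand, np.iinfo(np.int64).max)
            lin[ok] = cand
            best = np.minimum(best, lin)
        lin_best[sel] = best

    if np.any(lin_best == np.iinfo(np.int64).max):  # pragma: no cover - safety net
        raise RuntimeError("failed to resolve nearest background voxel")

    bz = lin_best // (ny * nx)
    by = (lin_best // nx) % ny
    bx = lin_best % nx
    field[0, zz, yy, xx] = xx - bx  # dx
    field[1, zz, yy, xx] = yy - by  # dy
    field[2, zz, yy, xx] = zz - bz  # dz
    return field


def _offsets_for_radius(r2: float, sz: float, sy: float, sx: float) -> np.ndarray:
    """All integer offsets (oz, oy, ox) whose spacing-weighted squared length equals r2."""
    r = np.sqrt(r2)
    mz, my, mx = int(r / sz + 1e-9), int(r / sy + 1e-9), int(r / sx + 1e-9)
    oz = np.arange(-mz, mz + 1)
    oy = np.arange(-my, my + 1)
    ox = np.arange(-mx, mx + 1)
    OZ, OY, OX = np.meshgrid(oz, oy, ox, indexing="ij")
    n2 = (OZ * sz) ** 2 + (OY * sy) ** 2 + (OX * sx) ** 2
    hit = np.abs(n2 - r2) < 1e-6
    return np.stack([OZ[hit], OY[hit], OX[hit]], axis=1)


def _validate_field(field: np.ndarray) -> np.ndarray:
    field = np.asarray(field, dtype=np.float64)
    if field.ndim != 4 or field.shape[0] != 3:
        raise ValueError(f"displacement field must have shape (3, nz, ny, nx), got {field.shape}")
    return field


def dvf_to_distance(field: np.ndarray) -> np.ndarray:
    """Per-voxel L2 norm of the displacement field (the distance map P)."""
    field = _validate_field(field)
    return np.sqrt((field**2).sum(axis=0))


def _check_pair(pred: np.ndarray, gt: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = _validate_field(pred)
    gt = _validate_field(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"field shapes differ: {pred.shape} vs {gt.shape}")
    return pred, gt


def displacement_loss(pred: np.ndarray, gt: np.ndarray) -> float:
    """Mean squared displacement error: sum of squared vector differences over 3N."""
    pred, gt = _check_pair(pred, gt)
    n_vox = pred[0].size
    return float(((pred - gt) ** 2).sum() / (3.0 * n_vox))


def displacement_loss_grad(pred: np.ndarray, gt: np.ndarray) -> np.ndarray:
    pred, gt = _check_pair(pred, gt)
    return 2.0 * (pred - gt) / (3.0 * pred[0].size)


def direction_loss(pred: np.ndarray, gt: np.ndarray, eps: float = 1e-8) -> float:
    """One minus the mean cosine similarity over voxels where both vectors are non-degenerate.

    Voxels where either vector has norm <= eps (background ground truth,
    collapsed predictions) are excluded from the mean: the cosine is
    undefined at the zero vector and epsilon-padding would bias background
    toward arbitrary directions.  Returns 0 (with a warning) if no voxel
    qualifies.  Range [0, 2].
    """
    pred, gt = _check_pair(pred, gt)
    np_norm = np.sqrt((pred**2).sum(axis=0))
    ng_norm = np.sqrt((gt**2).sum(axis=0))
    valid = (np_norm > eps) & (ng_norm > eps)
    if not valid.any():
        warnings.warn("direction_loss: no voxel with two non-zero vectors; returning 0")
        return 0.0
    cos = (pred * gt).sum(axis=0)[valid] / (np_norm[valid] * ng_norm[valid])
    return float(1.0 - cos.mean())


def direction_loss_grad(pred: np.ndarray, gt: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Gradient of direction_loss with respect to the predicted field."""
    pred, gt = _check_pair(pred, gt)
    np_norm = np.sqrt((pred**2).sum(axis=0))
    ng_norm = np.sqrt((gt**2).sum(axis=0))
    valid = (np_norm > eps) & (ng_norm > eps)
    grad = np.zeros_like(pred)
    n_valid = int(valid.sum())
    if n_valid == 0:
        return grad
    # d/dp [ p.g / (|p||g|) ] = g/(|p||g|) - (p.g) p / (|p|^3 |g|)
    dot = (pred * gt).sum(axis=0)
    denom = np.where(valid, np_norm * ng_norm, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(valid, dot / (np_norm**3 * ng_norm), 0.0)
    term = gt / denom - pred * coef
    grad[:, valid] = -term[:, valid] / n_valid
    return grad


def total_loss(pred: np.ndarray, gt: np.ndarray, w: LossWeights = LossWeights()) -> float:
    """Weighted sum ``omega1 * L_d + omega2 * L_r``."""
    return w.omega1 * displacement_loss(pred, gt) + w.omega2 * direction_loss(pred, gt)


def total_loss_grad(
    pred: np.ndarray, gt: np.ndarray, w: LossWeights = LossWeights()
) -> np.ndarray:
    return w.omega1 * displacement_loss_grad(pred, gt) + w.omega2 * direction_loss_grad(pred, gt)
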