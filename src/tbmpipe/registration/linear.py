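"""Rigid / affine registration by direct maximization of normalized
cross-correlation over a multi-resolution pyramid.

The optimizer is Powell's direction-set method on a 6- (rigid) or
12-parameter (affine) pose, composed as a delta on top of any initial
transform; deterministic and derivative-free.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates
from scipy.optimize import minimize

from ..core_image import Volume, voxel_to_world_grid, world_to_voxel
from .similarity import ncc
from .transforms import AffineTransform


def sample_at_world(v: Volume, points: np.ndarray, order: int = 1,
                    cval: float = 0.0) -> np.ndarray:
    """Sample an image at world-mm points (linear by default, 0 outside)."""
    vox = world_to_voxel(points, v.affine)
    return map_coordinates(v.data, np.moveaxis(vox, -1, 0), order=order,
                           mode="constant", cval=cval)


def _decimate(v: Volume, step: int) -> Volume:
    if step == 1:
        return v
    data = gaussian_filter(v.data, sigma=0.5 * step)[::step, ::step, ::step]
    aff = v.affine.copy()
    aff[:3, :3] *= step
    return Volume(np.ascontiguousarray(data), aff)


def _rotation(rx: float, ry: float, rz: float) -> np.ndarray:
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    Rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    Ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    Rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return Rz @ Ry @ Rx


def _matrix_from_params(p: np.ndarray, center: np.ndarray,
                        dof_class: str) -> np.ndarray:
    m3 = _rotation(*p[3:6])
    if dof_class == "affine":
        shear = np.eye(3)
        shear[0, 1], shear[0, 2], shear[1, 2] = p[9], p[10], p[11]
        m3 = m3 @ shear @ np.diag(np.exp(p[6:9]))
    m = np.eye(4)
    m[:3, :3] = m3
    m[:3, 3] = center + p[:3] - m3 @ center
    return m


def _intensity_centroid(v: Volume) -> np.ndarray:
    w = np.abs(v.data)
    total = w.sum()
    if total <= 0:
        raise ValueError("constant image: no intensity centroid")
    pts = voxel_to_world_grid(v.shape, v.affine)
    return (pts * w[..., None]).sum(axis=(0, 1, 2)) / total


def register_linear(
    moving: Volume,
    fixed: Volume,
    dof_class: str = "affine",
    similarity: str = "NCC",
    init: AffineTransform | None = None,
    levels: tuple[int, ...] = (4, 2, 1),
    maxiter: int = 6,
    init_translation: bool = True,
    sample_step: int = 1,
) -> AffineTransform:
    """Find the world-space transform (fixed coords -> moving coords) that
    maximizes NCC to a local optimum.

    Guarantees ``NCC(result) >= NCC(init) - 1e-9``: if the optimizer cannot
    improve on the initial transform, the initial transform is returned.
    """
    if similarity != "NCC":
        raise ValueError("linear registration supports similarity='NCC' only")
    if dof_class not in ("rigid", "affine"):
        raise ValueError("dof_class must be 'rigid' or 'affine'")
    for name, img in (("moving", moving), ("fixed", fixed)):
        if np.ptp(img.data) == 0:
            raise ValueError(f"constant {name} image")

    base = np.eye(4) if init is None else init.matrix.copy()
    if init is None and init_translation:
        shift = _intensity_centroid(moving) - _intensity_centroid(fixed)
        base[:3, 3] = shift

    nparams = 6 if dof_class == "rigid" else 12
    scales = np.concatenate([
        np.full(3, 0.5 * float(np.mean(fixed.spacing))),  # translation, mm
        np.full(3, 0.05),  # rotation, rad
        np.full(6, 0.05),  # log-scale + shear
    ])[:nparams]

    params = np.zeros(nparams)
    for step in levels:
        fx = _decimate(fixed, step)
        mv = _decimate(moving, step)
        pts = voxel_to_world_grid(fx.shape, fx.affine)
        fdat = fx.data
        if sample_step > 1 and step == 1:
            sl = (slice(None, None, sample_step),) * 3
            pts = pts[sl]
            fdat = fdat[sl]
        center = np.asarray(fx.affine[:3, 3]) + \
            fx.affine[:3, :3] @ ((np.asarray(fx.shape) - 1) / 2.0)

        def objective(p: np.ndarray) -> float:
            m = _matrix_from_params(p, center, dof_class) @ base
            warped = sample_at_world(mv, pts @ m[:3, :3].T + m[:3, 3])
            if np.ptp(warped) == 0:
                raise ValueError(
                    "no overlap between images after initialization")
            return -ncc(fdat, warped)

        res = minimize(
            objective, params, method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-4, "ftol": 1e-9,
                     "direc": np.diag(scales)},
        )
        params = res.x

    final_matrix = _matrix_from_params(
        params, center, dof_class) @ base
    # enforce the no-regression contract at full resolution
    pts_full = voxel_to_world_grid(fixed.shape, fixed.affine)

    def _score(m: np.ndarray) -> float:
        warped = sample_at_world(moving, pts_full @ m[:3, :3].T + m[:3, 3])
        if np.ptp(warped) == 0:
            return -np.inf
        return ncc(fixed.data, warped)

    if init is not None and _score(final_matrix) < _score(base) - 1e-9:
        final_matrix = base

    if dof_class == "rigid":
        # re-orthonormalize against accumulated float error
        u, _, vt = np.linalg.svd(final_matrix[:3, :3])
        final_matrix[:3, :3] = u @ vt
    return AffineTransform(final_matrix, dof_class)
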