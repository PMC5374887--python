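"""Non-rigid registration: cubic B-spline FFD driven by NMI gradient ascent.

The moving image is pulled through ``T(x) = A(x + U(x))`` (global affine
``A`` applied after the FFD displacement ``U``, the package-wide composition
order). The control points are optimized with L-BFGS on the penalized
objective ``NMI - bending_weight * roughness``; the gradient is the
voxelwise NMI force chained through the sampled moving-image gradient and
projected onto the control grid. The accepted-iterate similarity trace is
monotone up to the line-search tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import minimize

from ..core_image import Volume, voxel_to_world_grid
from .bspline import BSplineTransform
from .linear import sample_at_world
from .similarity import NMIEstimator
from .transforms import AffineTransform, CompositeTransform


@dataclass
class NRRResult:
    transform: BSplineTransform
    similarity_trace: list[float] = field(default_factory=list)
    bending_trace: list[float] = field(default_factory=list)


def _smoothed(v: Volume, sigma_vox: float) -> Volume:
    if sigma_vox <= 0:
        return v
    return v.copy(data=gaussian_filter(v.data, sigma=sigma_vox))


def register_nonrigid(
    moving: Volume,
    fixed: Volume,
    control_spacing_vox: int = 4,
    similarity: str = "NMI",
    bending_weight: float = 5e-5,
    pre_affine: AffineTransform | None = None,
    init: BSplineTransform | None = None,
    n_steps: int = 40,
    bins: int = 128,
    smooth_sigma_vox: float = 1.0,
) -> NRRResult:
    """Optimize an FFD on the fixed grid so the warped moving image matches.

    Returns the transform plus the per-step NMI trace (non-decreasing within
    the line-search tolerance). ``init`` continues a previous optimization;
    ``pre_affine`` holds the fixed global alignment (not optimized here).
    """
    if similarity != "NMI":
        raise ValueError("non-rigid registration supports similarity='NMI'")
    for name, img in (("moving", moving), ("fixed", fixed)):
        if np.ptp(img.data) == 0:
            raise ValueError(f"constant {name} image: degenerate histogram")

    affine = pre_affine if pre_affine is not None else \
        AffineTransform.identity()
    if init is not None:
        if tuple(init.ref_shape) != tuple(fixed.shape):
            raise ValueError("init transform geometry mismatch with fixed")
        bspl = init.copy()
        bspl.spacing_vox = control_spacing_vox if \
            init.spacing_vox == control_spacing_vox else init.spacing_vox
    else:
        bspl = BSplineTransform.identity(fixed.shape, fixed.affine,
                                         control_spacing_vox)

    fx = _smoothed(fixed, smooth_sigma_vox)
    mv = _smoothed(moving, smooth_sigma_vox)
    # moving gradient w.r.t. world mm, precomputed on the moving grid
    inv_m3 = np.linalg.inv(mv.affine[:3, :3])
    grads_vox = np.gradient(mv.data)
    grad_mm = [Volume(sum(grads_vox[a] * inv_m3[a, c] for a in range(3)),
                      mv.affine) for c in range(3)]

    est = NMIEstimator(fx.data,
                       (float(mv.data.min()), float(mv.data.max())),
                       bins=bins)
    pts0 = voxel_to_world_grid(fixed.shape, fixed.affine)
    a3t = affine.matrix[:3, :3].T

    cshape = bspl.coefs.shape
    proto = bspl

    def _unpack(x: np.ndarray) -> BSplineTransform:
        t = proto.copy()
        t.coefs = x.reshape(cshape)
        return t

    trace: list[float] = []
    btrace: list[float] = []

    def fun_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        t = _unpack(x)
        pts = affine.apply(pts0 + t.displacement())
        warped = sample_at_world(mv, pts)
        value, force = est.value_and_force(warped)
        g_world = np.stack([sample_at_world(g, pts) for g in grad_mm],
                           axis=-1)
        dsim_du = (force[..., None] * g_world) @ a3t.T
        grad = t.project_voxelwise(dsim_du)
        energy, bend_grad = t.bending_energy()
        obj = value - bending_weight * energy
        gobj = grad - bending_weight * bend_grad
        return -obj, -gobj.ravel()

    def record(x: np.ndarray) -> None:
        t = _unpack(x)
        pts = affine.apply(pts0 + t.displacement())
        value = est.value(sample_at_world(mv, pts))
        energy, _ = t.bending_energy()
        trace.append(value)
        btrace.append(energy)

    x0 = bspl.coefs.ravel().copy()
    record(x0)
    res = minimize(fun_and_grad, x0, jac=True, method="L-BFGS-B",
                   callback=record,
                   options={"maxiter": n_steps, "maxls": 10,
                            "ftol": 1e-12, "gtol": 1e-10})
    x_best = res.x
    # never return something worse than the starting point
    if fun_and_grad(x_best)[0] > fun_and_grad(x0)[0]:
        x_best = x0
    bspl = _unpack(x_best)
    return NRRResult(bspl, trace, btrace)


def warp_through(moving: Volume, transform: CompositeTransform,
                 reference: Volume, order: int = 1) -> Volume:
    """Resample ``moving`` onto the reference grid through a composite map."""
    pts = transform.apply_on_reference(reference)
    return Volume(sample_at_world(moving, pts, order=order),
                  reference.affine.copy())
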