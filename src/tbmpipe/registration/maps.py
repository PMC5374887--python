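"""Log-Jacobian-determinant maps and mean-positional-distance maps."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..core_image import DisplacementField, Volume
from .bspline import BSplineTransform
from .transforms import AffineTransform, CompositeTransform


@dataclass
class JacobianMap:
    """Per-voxel log det J of an average-space -> subject transform.

    Sign convention: positive where the subject is locally *larger* than the
    average. Voxels with non-positive determinant are NaN and flagged rather
    than clamped.
    """

    log_jdet: np.ndarray
    affine: np.ndarray
    source: str  # "composite" | "nonrigid_only"
    flagged: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.log_jdet.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(np.asarray(self.affine)[:3, :3], axis=0)


@dataclass
class MPDMap:
    """Per-voxel mean positional distance (mm) over N non-rigid fields."""

    data: np.ndarray
    affine: np.ndarray
    n: int


def _det3(j: np.ndarray) -> np.ndarray:
    """Determinant of (..., 3, 3) without the LAPACK overhead."""
    return (
        j[..., 0, 0] * (j[..., 1, 1] * j[..., 2, 2]
                        - j[..., 1, 2] * j[..., 2, 1])
        - j[..., 0, 1] * (j[..., 1, 0] * j[..., 2, 2]
                          - j[..., 1, 2] * j[..., 2, 0])
        + j[..., 0, 2] * (j[..., 1, 0] * j[..., 2, 1]
                          - j[..., 1, 1] * j[..., 2, 0])
    )


def jacobian_log_det(
    t: AffineTransform | BSplineTransform | CompositeTransform,
    reference: Volume,
    source: str = "composite",
    mask: np.ndarray | None = None,
    max_flagged_fraction: float = 1e-3,
) -> JacobianMap:
    """log det of the spatial Jacobian of ``t`` on the reference grid.

    ``source="composite"`` includes the global affine factor (a constant
    log-offset); ``source="nonrigid_only"`` uses the FFD part alone. For a
    pure affine the result is ``log |det M|`` everywhere, exactly.

    Raises if more than ``max_flagged_fraction`` of the (masked) voxels have
    det <= 0; those voxels are NaN in the returned map either way.
    """
    if source not in ("composite", "nonrigid_only"):
        raise ValueError("source must be 'composite' or 'nonrigid_only'")

    if isinstance(t, AffineTransform):
        affine_part = 0.0 if source == "nonrigid_only" else t.log_det()
        log_jdet = np.full(reference.shape, affine_part)
        return JacobianMap(log_jdet, reference.affine.copy(), source,
                           np.zeros(reference.shape, dtype=bool))

    if isinstance(t, BSplineTransform):
        bspl, affine = t, None
    elif isinstance(t, CompositeTransform):
        bspl, affine = t.bspline, t.affine
    else:
        raise TypeError(f"unsupported transform type {type(t).__name__}")

    offset = 0.0
    if source == "composite" and affine is not None:
        offset = affine.log_det()

    if bspl is None:
        log_jdet = np.full(reference.shape, offset)
        return JacobianMap(log_jdet, reference.affine.copy(), source,
                           np.zeros(reference.shape, dtype=bool))

    if tuple(bspl.ref_shape) != tuple(reference.shape):
        raise ValueError("transform is not defined over the reference grid")

    dvox = bspl.displacement_gradient_vox()  # (..., 3 comp, 3 vox-axis)
    inv_a3 = np.linalg.inv(reference.affine[:3, :3])
    dmm = dvox @ inv_a3  # derivative w.r.t. world mm
    jac = dmm + np.eye(3)
    det = _det3(jac)
    flagged = det <= 0
    log_jdet = np.where(flagged, np.nan, np.log(np.where(flagged, 1.0, det)))
    log_jdet = log_jdet + offset
    region = mask if mask is not None else np.ones(reference.shape, bool)
    frac = float(flagged[region].mean()) if region.any() else 0.0
    if frac > max_flagged_fraction:
        raise ValueError(
            f"{frac:.2%} of voxels have non-invertible local Jacobian "
            f"(> {max_flagged_fraction:.2%})")
    return JacobianMap(log_jdet, reference.affine.copy(), source, flagged)


def mean_positional_distance(
    fields: list[DisplacementField], reference: Volume
) -> MPDMap:
    """Per-voxel mean Euclidean norm of N non-rigid displacement fields (mm).

    Fields must already live on the reference geometry and must not contain
    global (rigid/affine) components.
    """
    if not fields:
        raise ValueError("need at least one displacement field")
    acc = np.zeros(reference.shape)
    for f in fields:
        if "global" in f.parts:
            raise ValueError(
                "MPD is defined on non-rigid fields only; got a field with "
                "global components baked in")
        if f.shape != tuple(reference.shape) or \
                not np.allclose(f.affine, reference.affine, atol=1e-6):
            raise ValueError("field geometry differs from the reference")
        acc += f.magnitude()
    return MPDMap(acc / len(fields), reference.affine.copy(), len(fields))
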