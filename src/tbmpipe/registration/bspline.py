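"""Cubic B-spline free-form deformation on a regular control-point grid.

Control points are spaced every ``spacing_vox`` voxels of the reference
grid; the control values are the spline *coefficients* (classic FFD, not an
interpolating spline). Dense displacements, analytic spatial derivatives
and the adjoint projection used by the optimizer are all separable matrix
products along the three axes, so everything here is plain dense algebra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def cubic_bspline(t: np.ndarray) -> np.ndarray:
    """Cubic B-spline kernel, support |t| < 2."""
    t = np.abs(np.asarray(t, dtype=float))
    out = np.zeros_like(t)
    m1 = t < 1
    m2 = (t >= 1) & (t < 2)
    out[m1] = (4 - 6 * t[m1] ** 2 + 3 * t[m1] ** 3) / 6.0
    out[m2] = (2 - t[m2]) ** 3 / 6.0
    return out


def cubic_bspline_deriv(t: np.ndarray) -> np.ndarray:
    """d/dt of the cubic B-spline kernel."""
    t = np.asarray(t, dtype=float)
    s = np.sign(t)
    a = np.abs(t)
    out = np.zeros_like(a)
    m1 = a < 1
    m2 = (a >= 1) & (a < 2)
    out[m1] = s[m1] * (-2 * a[m1] + 1.5 * a[m1] ** 2)
    out[m2] = s[m2] * (-0.5 * (2 - a[m2]) ** 2)
    return out


def n_control_points(n_vox: int, spacing_vox: int) -> int:
    return int(np.ceil((n_vox - 1) / spacing_vox)) + 3


def basis_matrix(n_vox: int, spacing_vox: int,
                 deriv: bool = False) -> np.ndarray:
    """Dense (n_vox x n_ctrl) spline basis along one axis.

    Control point ``i`` sits at voxel coordinate ``(i - 1) * spacing_vox``.
    ``deriv=True`` gives d/d(voxel) of the basis.
    """
    nc = n_control_points(n_vox, spacing_vox)
    vox = np.arange(n_vox, dtype=float)[:, None]
    ctrl = np.arange(nc, dtype=float)[None, :]
    t = vox / spacing_vox + 1.0 - ctrl
    if deriv:
        return cubic_bspline_deriv(t) / spacing_vox
    return cubic_bspline(t)


def _separable_apply(mats: list[np.ndarray], coefs: np.ndarray) -> np.ndarray:
    """Apply (n_vox x n_ctrl) matrices along the first three coef axes."""
    out = coefs
    for axis, m in enumerate(mats):
        out = np.moveaxis(np.tensordot(m, out, axes=([1], [axis])), 0, axis)
    return out


@dataclass
class BSplineTransform:
    """FFD displacement (mm, world axes) over a fixed reference geometry."""

    coefs: np.ndarray  # (ncx, ncy, ncz, 3)
    spacing_vox: int
    ref_shape: tuple[int, int, int]
    ref_affine: np.ndarray

    _basis: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.spacing_vox < 2:
            raise ValueError("control spacing must be >= 2 voxels")
        self.coefs = np.asarray(self.coefs, dtype=np.float64)
        self.ref_affine = np.asarray(self.ref_affine, dtype=np.float64)
        expect = tuple(n_control_points(n, self.spacing_vox)
                       for n in self.ref_shape)
        if self.coefs.shape != (*expect, 3):
            raise ValueError(
                f"coefs shape {self.coefs.shape} != expected {(*expect, 3)}")

    @classmethod
    def identity(cls, ref_shape, ref_affine,
                 spacing_vox: int = 4) -> "BSplineTransform":
        shape = tuple(int(n) for n in ref_shape)
        nc = tuple(n_control_points(n, spacing_vox) for n in shape)
        return cls(np.zeros((*nc, 3)), spacing_vox, shape,
                   np.asarray(ref_affine, float))

    def _mat(self, axis: int, deriv: bool) -> np.ndarray:
        key = (axis, deriv)
        if key not in self._basis:
            self._basis[key] = basis_matrix(self.ref_shape[axis],
                                            self.spacing_vox, deriv)
        return self._basis[key]

    def displacement(self) -> np.ndarray:
        """Dense displacement (mm) on the reference grid, shape (*shape, 3)."""
        mats = [self._mat(a, False) for a in range(3)]
        return _separable_apply(mats, self.coefs)

    def displacement_gradient_vox(self) -> np.ndarray:
        """d(displacement)/d(voxel index): shape (*shape, 3, 3).

        ``out[..., c, a]`` is the derivative of mm-component ``c`` with
        respect to voxel index along axis ``a``.
        """
        grads = []
        for a in range(3):
            mats = [self._mat(ax, ax == a) for ax in range(3)]
            grads.append(_separable_apply(mats, self.coefs))
        return np.stack(grads, axis=-1)

    def project_voxelwise(self, dense: np.ndarray) -> np.ndarray:
        """Adjoint of :meth:`displacement`: project a dense per-voxel field
        (*shape, 3) onto control-point space (the gradient chain rule)."""
        mats = [self._mat(a, False).T for a in range(3)]
        return _separable_apply(mats, dense)

    def bending_energy(self) -> tuple[float, np.ndarray]:
        """Quadratic roughness penalty on the control grid and its gradient.

        Sum of squared second differences of the coefficients along each
        axis — a discrete stand-in for the thin-plate bending energy.
        """
        energy = 0.0
        grad = np.zeros_like(self.coefs)
        for a in range(3):
            d2 = np.diff(self.coefs, n=2, axis=a)
            energy += float(np.sum(d2**2))
            g = np.zeros_like(self.coefs)
            sl = [slice(None)] * 4
            sl[a] = slice(0, -2)
            g[tuple(sl)] += d2
            sl[a] = slice(1, -1)
            g[tuple(sl)] -= 2 * d2
            sl[a] = slice(2, None)
            g[tuple(sl)] += d2
            grad += 2 * g
        return energy, grad

    def copy(self) -> "BSplineTransform":
        return BSplineTransform(self.coefs.copy(), self.spacing_vox,
                                tuple(self.ref_shape), self.ref_affine.copy())
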