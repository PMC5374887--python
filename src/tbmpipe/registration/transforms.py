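"""World-space affine transforms and affine∘FFD composites."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from ..core_image import DisplacementField, Volume, voxel_to_world_grid
from .bspline import BSplineTransform

DOF = {"rigid": 6, "affine": 12}


@dataclass
class AffineTransform:
    """4x4 world-mm transform; ``rigid`` restricts to rotation + translation."""

    matrix: np.ndarray
    dof_class: str = "affine"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.shape != (4, 4):
            raise ValueError("affine matrix must be 4x4")
        if self.dof_class not in DOF:
            raise ValueError(f"dof_class must be one of {list(DOF)}")
        m = self.matrix[:3, :3]
        if abs(np.linalg.det(m)) < 1e-12:
            raise ValueError("affine transform is singular")
        if self.dof_class == "rigid":
            if not np.allclose(m @ m.T, np.eye(3), atol=1e-6) or \
                    np.linalg.det(m) < 0:
                raise ValueError(
                    "rigid transform requires an orthonormal, det +1 block")

    @classmethod
    def identity(cls, dof_class: str = "affine") -> "AffineTransform":
        return cls(np.eye(4), dof_class)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return points @ self.matrix[:3, :3].T + self.matrix[:3, 3]

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix), self.dof_class)

    def compose(self, other: "AffineTransform") -> "AffineTransform":
        """self ∘ other: first apply ``other``, then ``self``."""
        cls = "rigid" if self.dof_class == other.dof_class == "rigid" \
            else "affine"
        return AffineTransform(self.matrix @ other.matrix, cls)

    def log_det(self) -> float:
        return float(np.log(abs(np.linalg.det(self.matrix[:3, :3]))))

    def save(self, path) -> None:
        np.savetxt(Path(path), self.matrix, header=self.dof_class)

    @classmethod
    def load(cls, path) -> "AffineTransform":
        text = Path(path).read_text().splitlines()
        dof = text[0].lstrip("# ").strip() if text[0].startswith("#") \
            else "affine"
        return cls(np.loadtxt(path), dof if dof in DOF else "affine")


@dataclass
class CompositeTransform:
    """Average-space -> subject map ``T(x) = A(x + U(x))``.

    The non-rigid displacement ``U`` acts first (in average space), then the
    global affine; this composition order is fixed package-wide.
    """

    affine: AffineTransform
    bspline: BSplineTransform | None = None

    def apply_on_reference(self, reference: Volume) -> np.ndarray:
        """Mapped world coordinates of every reference-grid voxel."""
        pts = voxel_to_world_grid(reference.shape, reference.affine)
        if self.bspline is not None:
            pts = pts + self.bspline.displacement()
        return self.affine.apply(pts)

    def displacement_field(self, reference: Volume,
                           nonrigid_only: bool = False) -> DisplacementField:
        """The composite (or non-rigid-only) displacement on a reference grid."""
        pts = voxel_to_world_grid(reference.shape, reference.affine)
        if nonrigid_only:
            if self.bspline is None:
                return DisplacementField(np.zeros((*reference.shape, 3)),
                                         reference.affine, frozenset())
            u = self.bspline.displacement()
            parts = {"nonrigid"} if np.any(u != 0) else set()
            return DisplacementField(u, reference.affine, frozenset(parts))
        mapped = self.apply_on_reference(reference)
        u = mapped - pts
        parts: set[str] = set()
        if not np.allclose(self.affine.matrix, np.eye(4), atol=1e-12):
            parts.add("global")
        if self.bspline is not None and np.any(self.bspline.coefs != 0):
            parts.add("nonrigid")
        if not parts and np.any(u != 0):  # numerically zero affine residue
            parts.add("global")
        return DisplacementField(u, reference.affine, frozenset(parts))
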