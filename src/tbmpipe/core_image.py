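"""Image containers, NIfTI-1 I/O, orientation handling and resampling.

Conventions (fixed for the whole package):

* voxel indices are 0-based;
* world coordinates are in mm, obtained through the NIfTI affine;
* displacement fields are stored in mm along the *world* axes, so a field
  survives moving between grids of different resolution;
* out-of-domain samples are filled with the background value 0, which is
  what a skull-stripped image contains there anyway.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

GROUPS = ("WT", "TG", "TG_DOX")
MODALITIES = ("invivo", "exvivo")

MANIFEST_COLUMNS = [
    "subject_id",
    "group",
    "modality",
    "volume_path",
    "labelmap_path",
    "rng_seed",
]


def _check_geometry(shape: tuple[int, ...], affine: np.ndarray) -> None:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    rot = affine[:3, :3]
    if abs(np.linalg.det(rot)) < 1e-12:
        raise ValueError("affine 3x3 block is singular")
    spacing = np.linalg.norm(rot, axis=0)
    if np.any(spacing <= 0):
        raise ValueError("voxel spacing must be positive on all axes")


@dataclass
class Volume:
    """A 3D scalar image with its voxel-to-world affine.

    ``spacing`` and ``orientation`` are derived from the affine so they can
    never disagree with it (the spec invariant "spacing equals column norms
    of the affine's 3x3 block" holds by construction).
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got {self.data.ndim}D")
        _check_geometry(self.data.shape, self.affine)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite voxels")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        """Per-axis voxel size in mm (column norms of the affine block)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def orientation(self) -> str:
        """Closest 3-letter axis code, e.g. ``'RAS'``."""
        return "".join(nib.orientations.aff2axcodes(self.affine))

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(
            self.data.copy() if data is None else data, self.affine.copy()
        )

    def world_coordinates(self) -> np.ndarray:
        """World (mm) coordinates of every voxel centre, shape ``(*shape, 3)``."""
        return voxel_to_world_grid(self.shape, self.affine)


@dataclass
class LabelMap:
    """Integer region labels sharing the geometry of a companion Volume."""

    labels: np.ndarray
    affine: np.ndarray
    legend: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            rounded = np.rint(np.asarray(self.labels, dtype=float))
            if not np.allclose(rounded, self.labels):
                raise ValueError("label map has non-integer values")
            self.labels = rounded.astype(np.int32)
        if self.labels.ndim != 3:
            raise ValueError("LabelMap must be 3D")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _check_geometry(self.labels.shape, self.affine)
        if self.legend:
            present = set(np.unique(self.labels).tolist()) - {0}
            missing = present - set(self.legend)
            if missing:
                raise ValueError(f"labels {sorted(missing)} missing from legend")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def region_mask(self, name_or_id: str | int) -> np.ndarray:
        """Boolean mask of one named (or numbered) region."""
        if isinstance(name_or_id, str):
            ids = [k for k, v in self.legend.items() if v == name_or_id]
            if not ids:
                raise KeyError(f"region {name_or_id!r} not in legend")
            name_or_id = ids[0]
        return self.labels == name_or_id


@dataclass
class DisplacementField:
    """Dense per-voxel displacement vectors in mm along world axes.

    ``parts`` records which transform components are baked into the field
    (subset of ``{"global", "nonrigid"}``); an empty ``parts`` set means the
    field must be identically zero.
    """

    vectors: np.ndarray
    affine: np.ndarray
    parts: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("vectors must have shape (nx, ny, nz, 3)")
        self.affine = np.asarray(self.affine, dtype=np.float64)
        _check_geometry(self.vectors.shape[:3], self.affine)
        self.parts = frozenset(self.parts)
        unknown = self.parts - {"global", "nonrigid"}
        if unknown:
            raise ValueError(f"unknown parts {sorted(unknown)}")
        if not self.parts and np.any(self.vectors != 0):
            raise ValueError("field with parts={} must be identically zero")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.vectors.shape[:3]  # type: ignore[return-value]

    @property
    def spacing(self) -> np.ndarray:
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def magnitude(self) -> np.ndarray:
        """Per-voxel Euclidean norm of the displacement, in mm."""
        return np.sqrt(np.sum(self.vectors**2, axis=-1))


def zero_field(shape: Sequence[int], affine: np.ndarray) -> DisplacementField:
    return DisplacementField(
        np.zeros((*tuple(shape), 3)), np.asarray(affine, float), frozenset()
    )


def voxel_to_world_grid(shape: Sequence[int], affine: np.ndarray) -> np.ndarray:
    """World coordinates (mm) of all voxel centres, shape ``(*shape, 3)``."""
    idx = np.indices(tuple(shape), dtype=np.float64)  # (3, nx, ny, nz)
    pts = np.moveaxis(idx, 0, -1)
    return pts @ np.asarray(affine, float)[:3, :3].T + affine[:3, 3]


def world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    """Map world-mm points (..., 3) to continuous voxel indices (..., 3)."""
    inv = np.linalg.inv(np.asarray(affine, float))
    return points @ inv[:3, :3].T + inv[:3, 3]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def read_nifti(path: str | os.PathLike) -> Volume:
    """Read a 3D NIfTI-1 file into a :class:`Volume`.

    Raises on missing files, non-3D images and non-finite voxels; no partial
    object is ever returned.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim == 4 and data.shape[-1] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path} is {data.ndim}D; only 3D volumes are supported"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError(f"{path} contains non-finite voxels")
    return Volume(data, np.asarray(img.affine, dtype=np.float64))


def write_nifti(v: Volume | LabelMap, path: str | os.PathLike) -> None:
    """Write a Volume (float64) or LabelMap (int16/int32) as NIfTI-1."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if isinstance(v, LabelMap):
        data = v.labels.astype(np.int32)
    else:
        data = v.data.astype(np.float64)
    img = nib.Nifti1Image(data, v.affine)
    nib.save(img, str(path))


def read_labelmap(
    path: str | os.PathLike, legend: Mapping[int, str] | None = None
) -> LabelMap:
    vol = read_nifti(path)
    return LabelMap(np.rint(vol.data).astype(np.int32), vol.affine,
                    dict(legend or {}))


def read_field(path: str | os.PathLike,
               parts: Iterable[str] = ("nonrigid",)) -> DisplacementField:
    """Read a displacement field stored as a NIfTI with vector dim last."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such NIfTI file: {path}")
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    data = np.squeeze(data)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path} is not a 3-component displacement field")
    return DisplacementField(data, np.asarray(img.affine, float),
                             frozenset(parts))


def write_field(f: DisplacementField, path: str | os.PathLike) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(f.vectors.astype(np.float64), f.affine)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def reorient(v: Volume, target: str) -> Volume:
    """Permute/flip the data grid so its axis codes become ``target``.

    World coordinates of every voxel are preserved; only the storage order
    changes. The target must be a 3-letter axis code reachable by
    permutation and flips (e.g. RAS, LPS, ASL).
    """
    target = target.upper()
    try:
        target_ornt = nib.orientations.axcodes2ornt(tuple(target))
    except Exception as exc:  # pragma: no cover - nibabel message wrapped
        raise ValueError(f"unreachable orientation code {target!r}") from exc
    if np.any(np.isnan(target_ornt)):
        raise ValueError(f"unreachable orientation code {target!r}")
    current = nib.orientations.io_orientation(v.affine)
    xform = nib.orientations.ornt_transform(current, target_ornt)
    new_data = nib.orientations.apply_orientation(v.data, xform)
    new_affine = v.affine @ nib.orientations.inv_ornt_aff(xform, v.shape)
    return Volume(np.ascontiguousarray(new_data), new_affine)


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------

_INTERP_ORDER = {"linear": 1, "nearest": 0}


def resample(
    v: Volume | LabelMap,
    field: DisplacementField,
    interpolation: str = "linear",
) -> Volume | LabelMap:
    """Pull ``v`` back through ``field`` onto the field's grid.

    For each output voxel with world coordinate ``x`` the source image is
    sampled at ``x + u(x)``; ``field`` therefore maps output coordinates
    into the source image's world space. Out-of-domain samples are 0.
    """
    if interpolation not in _INTERP_ORDER:
        raise ValueError(f"interpolation must be one of {list(_INTERP_ORDER)}")
    if isinstance(v, LabelMap) and interpolation != "nearest":
        raise ValueError("LabelMap resampling requires nearest interpolation")
    pts = voxel_to_world_grid(field.shape, field.affine) + field.vectors
    vox = world_to_voxel(pts, v.affine)
    coords = np.moveaxis(vox, -1, 0)
    source = v.labels if isinstance(v, LabelMap) else v.data
    out = map_coordinates(
        source.astype(np.float64),
        coords,
        order=_INTERP_ORDER[interpolation],
        mode="constant",
        cval=0.0,
    )
    if isinstance(v, LabelMap):
        return LabelMap(np.rint(out).astype(np.int32), field.affine.copy(),
                        dict(v.legend))
    return Volume(out, field.affine.copy())


def resample_field(field: DisplacementField, shape: Sequence[int],
                   affine: np.ndarray) -> DisplacementField:
    """Linearly resample a displacement field onto another grid.

    The vectors are world-mm quantities, so only the sampling positions
    change; out-of-domain samples are zero.
    """
    pts = voxel_to_world_grid(shape, affine)
    vox = world_to_voxel(pts, field.affine)
    coords = np.moveaxis(vox, -1, 0)
    out = np.empty((*tuple(shape), 3))
    for c in range(3):
        out[..., c] = map_coordinates(field.vectors[..., c], coords, order=1,
                                      mode="constant", cval=0.0)
    return DisplacementField(out, np.asarray(affine, float).copy(),
                             field.parts)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    group: str
    modality: str
    volume_path: str
    labelmap_path: str
    rng_seed: int

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.modality not in MODALITIES:
            raise ValueError(f"unknown modality {self.modality!r}")


@dataclass
class CohortManifest:
    """Subject records driving group-wise analysis."""

    subjects: list[SubjectRecord]
    root: Path = field(default_factory=Path)

    def __post_init__(self) -> None:
        keys = [(s.subject_id, s.modality) for s in self.subjects]
        if len(keys) != len(set(keys)):
            raise ValueError("subject_id x modality must be unique")

    def __len__(self) -> int:
        return len(self.subjects)

    def select(self, group: str | None = None,
               modality: str | None = None) -> list[SubjectRecord]:
        out = self.subjects
        if group is not None:
            out = [s for s in out if s.group == group]
        if modality is not None:
            out = [s for s in out if s.modality == modality]
        return list(out)

    def resolve(self, rel: str) -> Path:
        p = Path(rel)
        return p if p.is_absolute() else self.root / p

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [dataclasses.asdict(s) for s in self.subjects],
            columns=MANIFEST_COLUMNS,
        )

    def save(self, path: str | os.PathLike) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(path, index=False)


def load_manifest(path: str | os.PathLike,
                  check_paths: bool = True) -> CohortManifest:
    path = Path(path)
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns {sorted(missing)}")
    records = [
        SubjectRecord(
            subject_id=str(r.subject_id),
            group=str(r.group),
            modality=str(r.modality),
            volume_path=str(r.volume_path),
            labelmap_path=str(r.labelmap_path),
            rng_seed=int(r.rng_seed),
        )
        for r in df.itertuples()
    ]
    manifest = CohortManifest(records, root=path.parent)
    if check_paths:
        for s in manifest.subjects:
            for rel in (s.volume_path, s.labelmap_path):
                if not manifest.resolve(rel).exists():
                    raise FileNotFoundError(
                        f"manifest entry {s.subject_id}/{s.modality}: "
                        f"missing file {rel}"
                    )
    return manifest
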