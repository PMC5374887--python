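"""Seeded synthetic in vivo / ex vivo mouse-brain cohorts.

The phantom stands in for a paired two-modality MRI study of three groups
(WT, untreated transgenic, treated transgenic). Every deformation imposed
on a subject is analytic, so the Jacobian ground truth that the TBM
pipeline must recover is known exactly:

* local atrophy is a smooth, compactly supported radial contraction of a
  target blob whose interior volume scales by exactly ``1 - fraction``;
* group-level total-brain-volume deficits and the ex vivo fixation
  shrinkage are uniform scalings about the brain centre, so det J equals
  ``1 - deficit`` everywhere;
* the ex vivo preparation additionally displaces the brainstem and
  olfactory bulb by up to a configurable peak (default 0.5 mm);
* per-subject anatomical variability is a smooth random warp shared by the
  two modalities of the same subject (a paired design).

Intensities are piecewise-constant tissue means (calibrated against the
reference SNR/CNR tables in :mod:`tbmpipe.quality`) plus additive Gaussian
noise. Everything is a pure function of ``(spec, group, modality, index)``.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml
from scipy.ndimage import gaussian_filter, map_coordinates

from . import quality
from .core_image import (
    GROUPS,
    MODALITIES,
    CohortManifest,
    DisplacementField,
    LabelMap,
    SubjectRecord,
    Volume,
    voxel_to_world_grid,
    write_field,
    write_nifti,
)

# ---------------------------------------------------------------------------
# Canonical anatomy (normalized coordinates: half field of view = 1)
# ---------------------------------------------------------------------------

REGION_IDS: dict[int, str] = {
    1: "cortex",
    2: "hippocampus",
    3: "caudate putamen",
    4: "thalamus",
    5: "hypothalamus",
    6: "midbrain",
    7: "corpus callosum",
    8: "cerebellum",
    9: "olfactory bulb",
    10: "brainstem",
    11: "ventricles",
    12: "noise",
}
NOISE_LABEL = 12
BRAIN_MASK_LABEL = 255

#: Outer brain ellipsoid (cortex surface), normalized (center, semi-axes).
BRAIN_ELLIPSOID = ((0.0, 0.0, 0.0), (0.60, 0.70, 0.52))
#: Inner ellipsoid bounding the deep gray; cortex is the shell between them.
_INNER_SCALE = 0.80
#: Corpus callosum occupies the outer part of the inner ellipsoid.
_CC_INNER = 0.78

#: Blob regions painted over the cortex/cc/midbrain base, in paint order.
REGION_BLOBS: dict[str, list[tuple[tuple[float, float, float],
                                   tuple[float, float, float]]]] = {
    "caudate putamen": [
        ((-0.26, 0.24, 0.03), (0.14, 0.18, 0.14)),
        ((+0.26, 0.24, 0.03), (0.14, 0.18, 0.14)),
    ],
    "thalamus": [((0.0, -0.08, 0.0), (0.23, 0.18, 0.15))],
    "hypothalamus": [((0.0, 0.05, -0.24), (0.18, 0.13, 0.10))],
    "hippocampus": [
        ((-0.23, -0.25, 0.09), (0.13, 0.20, 0.12)),
        ((+0.23, -0.25, 0.09), (0.13, 0.20, 0.12)),
    ],
    "ventricles": [
        ((-0.14, 0.12, 0.13), (0.05, 0.14, 0.08)),
        ((+0.14, 0.12, 0.13), (0.05, 0.14, 0.08)),
        ((0.0, -0.16, -0.08), (0.035, 0.13, 0.07)),
    ],
    "olfactory bulb": [((0.0, 0.62, -0.07), (0.18, 0.17, 0.15))],
    "cerebellum": [((0.0, -0.60, 0.08), (0.30, 0.21, 0.21))],
    "brainstem": [((0.0, -0.56, -0.22), (0.16, 0.26, 0.14))],
}

_NOISE_BOX_CENTER = (-0.84, -0.84, -0.84)
_NOISE_BOX_HALF = 0.115


#: Noise SD at which the default tissue means hit the reference SNR table.
REFERENCE_NOISE_SD = 10.0


def _default_tissue_means() -> dict:
    """Tissue means reproducing the reference SNR table at the reference
    noise SD (mean = SNR x REFERENCE_NOISE_SD).

    The in vivo corpus callosum is the one deliberate departure: the
    reference tables give it a higher SNR than cortex yet a *positive*
    gray-white CNR; the phantom resolves the tension in favour of the CNR,
    so its signed gray-white contrast matches the reference in both
    modalities.
    """
    means: dict[str, dict[str, float]] = {m: {} for m in MODALITIES}
    for region, per_mod in quality.REFERENCE_SNR.items():
        for mod in MODALITIES:
            means[mod][region] = per_mod[mod] * REFERENCE_NOISE_SD
    for mod in MODALITIES:
        means[mod]["corpus callosum"] = (
            means[mod]["cortex"]
            - quality.REFERENCE_CNR[mod] * REFERENCE_NOISE_SD
        )
    means["invivo"]["ventricles"] = 25.0 * REFERENCE_NOISE_SD
    means["exvivo"]["ventricles"] = 3.0 * REFERENCE_NOISE_SD
    return means


@dataclass
class PhantomSpec:
    """All knobs of the synthetic cohort; the cohort is a pure function of it."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    spacing_invivo: float = 0.15
    spacing_exvivo: float = 0.12
    n_per_group: tuple[int, int, int] = (8, 10, 7)  # WT, TG, TG_DOX
    atrophy_fraction_TG: float = 0.25
    atrophy_fraction_TGDOX: float = 0.10
    atrophy_regions: tuple[str, ...] = ("hippocampus", "caudate putamen")
    tbv_deficit_TG: float = 0.21
    tbv_deficit_TGDOX: float = 0.06
    ventricle_expansion_invivo: float = 0.30
    ventricle_expansion_exvivo: float = 0.08
    exvivo_volume_shrinkage: float = 0.10
    exvivo_extra_distortion_mm: float = 0.5
    tissue_means: dict | None = None
    noise_sd: dict = field(
        default_factory=lambda: {"invivo": 10.0, "exvivo": 10.0})
    subject_variability_sd: float = 0.03
    skull_rind_intensity: float = 60.0
    transition_mm: float = 0.45
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("atrophy_fraction_TG", "atrophy_fraction_TGDOX",
                     "tbv_deficit_TG", "tbv_deficit_TGDOX",
                     "exvivo_volume_shrinkage"):
            val = getattr(self, name)
            if not 0.0 <= val < 1.0:
                raise ValueError(f"{name} must be in [0, 1), got {val}")
        if self.spacing_invivo <= 0 or self.spacing_exvivo <= 0:
            raise ValueError("spacings must be positive")
        if self.tissue_means is None:
            self.tissue_means = _default_tissue_means()
        unknown = set(self.atrophy_regions) - set(REGION_BLOBS)
        if unknown:
            raise ValueError(f"atrophy_regions not blob regions: {unknown}")

    # -- geometry ----------------------------------------------------------

    def shape_for(self, modality: str) -> tuple[int, int, int]:
        if modality == "invivo":
            return tuple(self.grid_shape)
        ratio = self.spacing_invivo / self.spacing_exvivo
        return tuple(int(np.ceil(n * ratio)) for n in self.grid_shape)

    def spacing_for(self, modality: str) -> float:
        return self.spacing_invivo if modality == "invivo" else self.spacing_exvivo

    def affine_for(self, modality: str) -> np.ndarray:
        shape = np.asarray(self.shape_for(modality), float)
        sp = self.spacing_for(modality)
        aff = np.eye(4)
        aff[:3, :3] = np.diag([sp] * 3)
        aff[:3, 3] = -(shape - 1) / 2.0 * sp
        return aff

    @property
    def half_fov_mm(self) -> np.ndarray:
        return np.asarray(self.grid_shape, float) * self.spacing_invivo / 2.0

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k in ("grid_shape", "n_per_group", "atrophy_regions"):
            d[k] = list(d[k])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PhantomSpec":
        d = yaml.safe_load(Path(path).read_text())
        for k in ("grid_shape", "n_per_group", "atrophy_regions"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


# ---------------------------------------------------------------------------
# Analytic transforms (all maps are from subject/world points back toward the
# template unless the method name says otherwise)
# ---------------------------------------------------------------------------


def _smoothstep_window(rho: np.ndarray, rho_in: float,
                       rho_out: float) -> tuple[np.ndarray, np.ndarray]:
    """Plateau-1 window with a C1 smoothstep taper; returns (W, dW/drho)."""
    rho = np.asarray(rho, float)
    w = np.ones_like(rho)
    dw = np.zeros_like(rho)
    t = (rho - rho_in) / (rho_out - rho_in)
    mid = (rho > rho_in) & (rho < rho_out)
    tm = t[mid]
    w[mid] = 1.0 - (3 * tm**2 - 2 * tm**3)
    dw[mid] = -6 * tm * (1 - tm) / (rho_out - rho_in)
    w[rho >= rho_out] = 0.0
    return w, dw


class RadialBlobTransform:
    """Radial volume change of an ellipsoidal blob, compactly supported.

    The forward map (template -> subject) scales the blob interior uniformly
    so its volume changes by exactly ``1 - fraction`` and blends back to the
    identity across a transition shell. The backward map inverts the radial
    profile by table lookup.
    """

    def __init__(self, center_mm: Sequence[float], semi_mm: Sequence[float],
                 fraction: float, transition_mm: float = 0.45) -> None:
        self.center = np.asarray(center_mm, float)
        self.semi = np.asarray(semi_mm, float)
        self.fraction = float(fraction)
        self.scale = (1.0 - self.fraction) ** (1.0 / 3.0)
        geo = float(np.exp(np.mean(np.log(self.semi))))
        self.rho_out = 1.0 + transition_mm / geo
        rho = np.linspace(0.0, self.rho_out * 1.05, 4096)
        g, _ = self._profile(rho)
        if np.any(np.diff(g) <= 0):
            raise ValueError(
                "radial profile not monotone; reduce |fraction| or widen the "
                "transition shell")
        self._rho_tab = rho
        self._g_tab = g

    def _profile(self, rho: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        w, dw = _smoothstep_window(rho, 1.0, self.rho_out)
        a = self.scale - 1.0
        g = rho * (1.0 + a * w)
        gp = 1.0 + a * (w + rho * dw)
        return g, gp

    def _xi(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        xi = (points - self.center) / self.semi
        r = np.linalg.norm(xi, axis=-1)
        return xi, r

    def backward(self, points: np.ndarray) -> np.ndarray:
        """Map subject points to template points (inverse of the forward map)."""
        xi, r = self._xi(points)
        rho = np.interp(r, self._g_tab, self._rho_tab)
        inside = (r > 0) & (r < self._g_tab[-1])
        factor = np.ones_like(r)
        factor[inside] = rho[inside] / r[inside]
        return self.center + xi * factor[..., None] * self.semi

    def forward_logdet(self, points: np.ndarray) -> np.ndarray:
        """log det of the forward Jacobian at template points."""
        _, rho = self._xi(points)
        g, gp = self._profile(rho)
        ld = np.zeros_like(rho)
        nz = rho > 0
        ld[nz] = np.log(gp[nz]) + 2 * np.log(g[nz] / rho[nz])
        ld[~nz] = 3 * np.log(self.scale)
        ld[rho >= self.rho_out] = 0.0
        return ld


class GlobalScaleTransform:
    """Uniform isotropic scaling about a fixed centre; det J is exact."""

    def __init__(self, center_mm: Sequence[float], volume_factor: float) -> None:
        if volume_factor <= 0:
            raise ValueError("volume factor must be positive")
        self.center = np.asarray(center_mm, float)
        self.volume_factor = float(volume_factor)
        self.scale = self.volume_factor ** (1.0 / 3.0)

    def backward(self, points: np.ndarray) -> np.ndarray:
        return self.center + (points - self.center) / self.scale

    def forward_logdet(self, points: np.ndarray) -> np.ndarray:
        return np.full(points.shape[:-1], np.log(self.volume_factor))


class DistortionField:
    """Smooth, compactly supported backward displacement around listed blobs."""

    def __init__(self, blobs: Sequence[tuple[np.ndarray, np.ndarray,
                                             np.ndarray]]) -> None:
        # each entry: (center_mm, semi_mm, displacement_vector_mm)
        self.blobs = [(np.asarray(c, float), np.asarray(s, float),
                       np.asarray(d, float)) for c, s, d in blobs]

    def __call__(self, points: np.ndarray) -> np.ndarray:
        u = np.zeros_like(points)
        for center, semi, vec in self.blobs:
            xi = (points - center) / semi
            rho = np.linalg.norm(xi, axis=-1)
            w, _ = _smoothstep_window(rho, 0.5, 1.5)
            u = u + w[..., None] * vec
        return u


class SmoothRandomField:
    """Seeded smooth random backward displacement over a world-space box.

    Coarse Gaussian coefficients are interpolated with a cubic B-spline so
    the field is a continuous function of world position, independent of the
    grid it is later sampled on (the two modalities of one subject share it).
    """

    def __init__(self, rng: np.random.Generator, lo_mm: np.ndarray,
                 hi_mm: np.ndarray, sd_mm: float, n_ctrl: int = 8) -> None:
        self.lo = np.asarray(lo_mm, float)
        self.hi = np.asarray(hi_mm, float)
        self.n = int(n_ctrl)
        coefs = rng.normal(size=(self.n, self.n, self.n, 3))
        for c in range(3):
            coefs[..., c] = gaussian_filter(coefs[..., c], sigma=1.0,
                                            mode="nearest")
        # calibrate per-component SD over the central (brain-ish) box
        probe = self.lo + (self.hi - self.lo) * np.random.default_rng(0).uniform(
            0.15, 0.85, size=(4096, 3))
        raw = self._eval(coefs, probe)
        sd_raw = float(np.mean(np.std(raw, axis=0)))
        self.coefs = coefs * (sd_mm / sd_raw if sd_raw > 0 else 0.0)

    def _eval(self, coefs: np.ndarray, points: np.ndarray) -> np.ndarray:
        t = (points - self.lo) / (self.hi - self.lo) * (self.n - 1)
        coords = np.moveaxis(t, -1, 0)
        out = np.empty(points.shape)
        for c in range(3):
            out[..., c] = map_coordinates(coefs[..., c], coords, order=3,
                                          mode="nearest", prefilter=False)
        return out

    def __call__(self, points: np.ndarray) -> np.ndarray:
        return self._eval(self.coefs, points)


# ---------------------------------------------------------------------------
# Template
# ---------------------------------------------------------------------------


class TemplateModel:
    """Analytic canonical brain: labels and intensity at arbitrary mm points."""

    def __init__(self, spec: PhantomSpec, modality: str) -> None:
        if modality not in MODALITIES:
            raise ValueError(f"unknown modality {modality!r}")
        self.spec = spec
        self.modality = modality
        self.half = spec.half_fov_mm
        self.brain_center = np.asarray(BRAIN_ELLIPSOID[0]) * self.half
        self.brain_semi = np.asarray(BRAIN_ELLIPSOID[1]) * self.half
        self.means = spec.tissue_means[modality]

    def blob_mm(self, region: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(np.asarray(c) * self.half, np.asarray(s) * self.half)
                for c, s in REGION_BLOBS[region]]

    def _rho0(self, points: np.ndarray) -> np.ndarray:
        xi = (points - self.brain_center) / self.brain_semi
        return np.linalg.norm(xi, axis=-1)

    def labels_at(self, points: np.ndarray) -> np.ndarray:
        rho0 = self._rho0(points)
        labels = np.zeros(points.shape[:-1], dtype=np.int32)
        labels[rho0 <= 1.0] = 1  # cortex
        inner = self.brain_semi * _INNER_SCALE
        rho1 = np.linalg.norm((points - self.brain_center) / inner, axis=-1)
        labels[rho1 <= 1.0] = 7  # corpus callosum shell
        labels[rho1 <= _CC_INNER] = 6  # midbrain base
        name_to_id = {v: k for k, v in REGION_IDS.items()}
        for region, blobs in REGION_BLOBS.items():
            rid = name_to_id[region]
            for c, s in blobs:
                xi = (points - np.asarray(c) * self.half) / (
                    np.asarray(s) * self.half)
                labels[np.linalg.norm(xi, axis=-1) <= 1.0] = rid
        # noise ROI: background box near a grid corner
        nu = points / self.half
        box = np.all(np.abs(nu - np.asarray(_NOISE_BOX_CENTER))
                     <= _NOISE_BOX_HALF, axis=-1)
        labels[box & (labels == 0)] = NOISE_LABEL
        return labels

    def intensity_at(self, points: np.ndarray,
                     labels: np.ndarray | None = None) -> np.ndarray:
        if labels is None:
            labels = self.labels_at(points)
        out = np.zeros(labels.shape, dtype=np.float64)
        name_to_id = {v: k for k, v in REGION_IDS.items()}
        for region, mean in self.means.items():
            rid = name_to_id.get(region)
            if rid is not None:
                out[labels == rid] = mean
        # thin bright skull rind just outside the cortex, for masking tests
        rho0 = self._rho0(points)
        rind = (rho0 > 1.02) & (rho0 <= 1.12) & (labels == 0)
        out[rind] = self.spec.skull_rind_intensity
        return out

    def legend(self) -> dict[int, str]:
        legend = {0: "background"}
        legend.update(REGION_IDS)
        legend[BRAIN_MASK_LABEL] = "brain mask"
        return legend


def build_template(spec: PhantomSpec,
                   modality: str = "invivo") -> tuple[Volume, LabelMap]:
    """Render the canonical brain on the requested modality's grid."""
    model = TemplateModel(spec, modality)
    affine = spec.affine_for(modality)
    shape = spec.shape_for(modality)
    pts = voxel_to_world_grid(shape, affine)
    labels = model.labels_at(pts)
    intensity = model.intensity_at(pts, labels)
    lm = LabelMap(labels, affine, model.legend())
    brain = quality.brain_mask_array(lm)
    idx = np.argwhere(brain)
    margin = min(int(idx.min()),
                 int(min(np.asarray(shape) - 1 - idx.max(axis=0))))
    if margin < 3:
        raise ValueError(
            f"grid too small: brain margin is {margin} voxels (< 3); "
            "use a larger grid_shape")
    for rid in set(REGION_IDS) - {NOISE_LABEL}:
        if not np.any(labels == rid):
            raise ValueError(f"region {REGION_IDS[rid]!r} is empty on this grid")
    return Volume(intensity, affine), lm


# ---------------------------------------------------------------------------
# Subjects
# ---------------------------------------------------------------------------


def _group_params(spec: PhantomSpec, group: str) -> tuple[float, float]:
    """(local atrophy fraction, TBV deficit) for a group."""
    if group == "WT":
        return 0.0, 0.0
    if group == "TG":
        return spec.atrophy_fraction_TG, spec.tbv_deficit_TG
    if group == "TG_DOX":
        return spec.atrophy_fraction_TGDOX, spec.tbv_deficit_TGDOX
    raise ValueError(f"unknown group {group!r}")


def _subject_rng(spec: PhantomSpec, group: str, index: int,
                 *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        [spec.seed, GROUPS.index(group), int(index), *extra])


def _backward_chain(spec: PhantomSpec, group: str, modality: str,
                    index: int) -> list[Callable[[np.ndarray], np.ndarray]]:
    """Ordered maps taking subject world points back to template points."""
    model = TemplateModel(spec, modality)
    frac, deficit = _group_params(spec, group)
    chain: list[Callable[[np.ndarray], np.ndarray]] = []

    if modality == "exvivo":
        shrink = GlobalScaleTransform(model.brain_center,
                                      1.0 - spec.exvivo_volume_shrinkage)
        chain.append(shrink.backward)
        if spec.exvivo_extra_distortion_mm > 0:
            peak = spec.exvivo_extra_distortion_mm
            blobs = []
            # brainstem bends inward and down; olfactory bulb shifts inward
            # by a smaller amount — deliberately non-affine-like so the
            # pattern survives global alignment
            for c, s in model.blob_mm("brainstem"):
                blobs.append((c, s, peak * np.array([0.0, 0.8, -0.6])))
            for c, s in model.blob_mm("olfactory bulb"):
                blobs.append((c, s, 0.3 * peak * np.array([0.0, -1.0, 0.0])))
            dist = DistortionField(blobs)
            chain.append(lambda p, d=dist: p + d(p))

    if spec.subject_variability_sd > 0:
        rng = _subject_rng(spec, group, index, 1)
        lo = -model.half * 1.0
        hi = model.half * 1.0
        warp = SmoothRandomField(rng, lo, hi, spec.subject_variability_sd)
        chain.append(lambda p, w=warp: p + w(p))

    if deficit > 0:
        gscale = GlobalScaleTransform(model.brain_center, 1.0 - deficit)
        chain.append(gscale.backward)

    blob_transforms = group_blob_transforms(spec, group, modality)
    for blob in blob_transforms:
        chain.append(blob.backward)
    return chain


def group_blob_transforms(spec: PhantomSpec, group: str,
                          modality: str) -> list[RadialBlobTransform]:
    """The local (blob-level) volume-change transforms imposed on a group."""
    model = TemplateModel(spec, modality)
    frac, _ = _group_params(spec, group)
    out: list[RadialBlobTransform] = []
    if frac > 0:
        for region in spec.atrophy_regions:
            for c, s in model.blob_mm(region):
                out.append(RadialBlobTransform(c, s, frac, spec.transition_mm))
    if group in ("TG", "TG_DOX"):
        expansion = (spec.ventricle_expansion_invivo if modality == "invivo"
                     else spec.ventricle_expansion_exvivo)
        if group == "TG_DOX":
            expansion *= 0.4  # treated group: damped ventricular change
        if expansion > 0:
            for c, s in model.blob_mm("ventricles"):
                out.append(RadialBlobTransform(c, s, -expansion,
                                               spec.transition_mm))
    return out


def synthesize_subject(
    spec: PhantomSpec, group: str, modality: str, index: int
) -> tuple[Volume, LabelMap, DisplacementField]:
    """Generate one subject image, its label map and the exact composite
    backward displacement field (subject grid -> template space, mm)."""
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}")
    if modality not in MODALITIES:
        raise ValueError(f"unknown modality {modality!r}")
    model = TemplateModel(spec, modality)
    affine = spec.affine_for(modality)
    shape = spec.shape_for(modality)
    if spec.subject_variability_sd > 0:
        # sub-voxel scanner-positioning jitter: shifts the sampling grid, not
        # the anatomy, and makes mask-count volume estimates unbiased across
        # a group; off when subject variability is disabled so a WT subject
        # reproduces the template bit-for-bit
        jitter_rng = _subject_rng(spec, group, index, 3,
                                  MODALITIES.index(modality))
        affine = affine.copy()
        affine[:3, 3] += jitter_rng.uniform(-0.5, 0.5, 3) * \
            spec.spacing_for(modality)
    pts = voxel_to_world_grid(shape, affine)

    p = pts
    for step in _backward_chain(spec, group, modality, index):
        p = step(p)
    labels = model.labels_at(p)
    intensity = model.intensity_at(p, labels)

    u = p - pts
    frac, deficit = _group_params(spec, group)
    parts: set[str] = set()
    if modality == "exvivo" or deficit > 0:
        parts.add("global")
    if np.any(u != 0):
        parts.add("nonrigid")
    if not parts and np.any(u != 0):  # pragma: no cover - defensive
        raise RuntimeError("nonzero field with empty parts")
    fld = DisplacementField(u, affine,
                            frozenset(parts if np.any(u != 0) else set()))

    rng = _subject_rng(spec, group, index, 2, MODALITIES.index(modality))
    sd = float(spec.noise_sd[modality])
    if sd > 0:
        intensity = intensity + rng.normal(0.0, sd, size=intensity.shape)
    return Volume(intensity, affine), LabelMap(labels, affine,
                                               model.legend()), fld


def imposed_region_volume_change(spec: PhantomSpec, group: str, modality: str,
                                 region: str) -> float:
    """Expected det J (template -> subject), averaged over a region's interior.

    Exact inside atrophy blobs; global factors multiply everywhere.
    """
    frac, deficit = _group_params(spec, group)
    det = 1.0
    if region in spec.atrophy_regions and frac > 0:
        det *= 1.0 - frac
    if region == "ventricles" and group in ("TG", "TG_DOX"):
        expansion = (spec.ventricle_expansion_invivo if modality == "invivo"
                     else spec.ventricle_expansion_exvivo)
        if group == "TG_DOX":
            expansion *= 0.4
        det *= 1.0 + expansion
    det *= 1.0 - deficit
    if modality == "exvivo":
        det *= 1.0 - spec.exvivo_volume_shrinkage
    return det


def calibrate_noise(spec: PhantomSpec) -> dict[str, dict[str, float]]:
    """Expected region SNR table (tissue mean / noise SD) per modality."""
    out: dict[str, dict[str, float]] = {}
    for region in quality.REFERENCE_SNR:
        out[region] = {}
        for mod in MODALITIES:
            sd = float(spec.noise_sd[mod])
            if sd == 0:
                raise ValueError("noise_sd must be nonzero to calibrate SNR")
            out[region][mod] = spec.tissue_means[mod][region] / sd
    return out


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------


@dataclass
class GroundTruth:
    """Per-subject ground truth written alongside a synthesized cohort."""

    true_tbv: dict[str, dict[str, float]]  # subject_id -> modality -> mm^3
    field_paths: dict[str, dict[str, str]]
    spec: PhantomSpec

    def save(self, path) -> None:
        payload = {
            "true_tbv": self.true_tbv,
            "field_paths": self.field_paths,
            "spec": {k: (list(v) if isinstance(v, tuple) else v)
                     for k, v in dataclasses.asdict(self.spec).items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def subject_ids(spec: PhantomSpec) -> list[tuple[str, str, int]]:
    out = []
    for group, n in zip(GROUPS, spec.n_per_group):
        for i in range(n):
            out.append((f"{group}{i:02d}", group, i))
    return out


def synthesize_cohort(spec: PhantomSpec, out_dir,
                      modalities: Sequence[str] = MODALITIES
                      ) -> CohortManifest:
    """Write the full cohort (volumes, labels, fields, manifest, ground truth)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not os.access(out_dir, os.W_OK):  # pragma: no cover
        raise PermissionError(f"output directory {out_dir} is not writable")
    records: list[SubjectRecord] = []
    tbv: dict[str, dict[str, float]] = {}
    fpaths: dict[str, dict[str, str]] = {}
    for sid, group, index in subject_ids(spec):
        tbv[sid] = {}
        fpaths[sid] = {}
        for mod in modalities:
            vol, labels, fld = synthesize_subject(spec, group, mod, index)
            vpath = f"{sid}_{mod}.nii.gz"
            lpath = f"{sid}_{mod}_labels.nii.gz"
            fpath = f"{sid}_{mod}_field.nii.gz"
            write_nifti(vol, out_dir / vpath)
            write_nifti(labels, out_dir / lpath)
            write_field(fld, out_dir / fpath)
            mask = quality.brain_mask_array(labels)
            tbv[sid][mod] = float(np.count_nonzero(mask)) * labels.voxel_volume
            fpaths[sid][mod] = fpath
            records.append(SubjectRecord(
                subject_id=sid, group=group, modality=mod,
                volume_path=vpath, labelmap_path=lpath,
                rng_seed=int(spec.seed)))
    manifest = CohortManifest(records, root=out_dir)
    manifest.save(out_dir / "manifest.csv")
    GroundTruth(tbv, fpaths, spec).save(out_dir / "ground_truth.json")
    spec.to_yaml(out_dir / "phantom_spec.yaml")
    return manifest
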