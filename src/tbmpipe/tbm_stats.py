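"""Voxelwise statistics on log-Jacobian maps.

Pipeline order is fixed: log-determinant maps are smoothed first, then
tested voxel by voxel (two-tailed pooled-variance t-tests, a two-group
general linear model), then corrected with the Benjamini-Hochberg false
discovery rate step-up over the analysis mask. Effect-size (Cohen's d with
pooled SD) and per-voxel sample-size maps use the same group stacks.

Degenerate voxels (zero variance, non-invertible Jacobian) are excluded
from the multiple-testing family so the family size m stays well defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.ndimage import gaussian_filter

from .core_image import LabelMap, Volume
from .registration.maps import JacobianMap

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class StatConfig:
    """Smoothing, significance and power-analysis settings."""

    fwhm_mm: float = 0.2
    q: float = 0.05
    alpha: float = 0.05
    beta: float = 0.2
    effect_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.fwhm_mm <= 0:
            raise ValueError("fwhm_mm must be positive")
        for name in ("q", "alpha", "beta", "effect_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {v}")

    @property
    def z_alpha_half(self) -> float:
        """Two-sided critical z, rounded to 2 decimals (1.96 at alpha=.05)."""
        return float(np.round(sps.norm.ppf(1.0 - self.alpha / 2.0), 2))

    @property
    def z_one_minus_beta(self) -> float:
        """Power z, rounded to 2 decimals (0.84 at beta=.2)."""
        return float(np.round(sps.norm.ppf(1.0 - self.beta), 2))


@dataclass
class StatMaps:
    """Voxelwise t / p / FDR-significance maps sharing one geometry."""

    t_map: np.ndarray
    p_map: np.ndarray
    affine: np.ndarray
    df: int
    mask: np.ndarray
    direction: np.ndarray  # sign of (group A mean - group B mean)
    fdr_mask: np.ndarray | None = None
    degenerate: np.ndarray | None = None
    q: float | None = None

    def signed_threshold_map(self) -> np.ndarray:
        """t values where FDR-significant, 0 elsewhere (negative = group A
        locally smaller than group B)."""
        if self.fdr_mask is None:
            raise ValueError("run fdr_correct first")
        return np.where(self.fdr_mask, self.t_map, 0.0)


@dataclass
class PowerMaps:
    """Cohen's d and per-voxel animals-per-arm maps."""

    cohens_d: np.ndarray | None
    n_arm: np.ndarray | None
    wt_stdev: np.ndarray | None
    pooled_stdev: np.ndarray | None
    affine: np.ndarray | None = None
    z_alpha_half: float = 1.96
    z_one_minus_beta: float = 0.84
    degenerate: np.ndarray | None = None


def _stack(jmaps: Sequence[JacobianMap]) -> np.ndarray:
    shapes = {m.shape for m in jmaps}
    if len(shapes) != 1:
        raise ValueError("Jacobian maps are not in a common space")
    return np.stack([m.log_jdet for m in jmaps], axis=0)


# ---------------------------------------------------------------------------
# Smoothing
# ---------------------------------------------------------------------------


def smooth_map(m: JacobianMap, fwhm_mm: float,
               mask: np.ndarray | None = None) -> JacobianMap:
    """Gaussian smoothing with sigma = FWHM / (2 sqrt(2 ln 2)) per axis,
    converted from mm to voxels; renormalized at mask edges so constants
    (and masked means) are preserved.

    A FWHM below half a voxel is a warning-level no-op.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    spacing = m.spacing
    if fwhm_mm < 0.5 * float(np.min(spacing)):
        warnings.warn("FWHM smaller than half a voxel; smoothing skipped",
                      stacklevel=2)
        return JacobianMap(m.log_jdet.copy(), np.array(m.affine).copy(),
                           m.source, m.flagged)
    sigma_vox = (fwhm_mm * FWHM_TO_SIGMA) / spacing
    valid = np.isfinite(m.log_jdet)
    if mask is not None:
        valid &= mask.astype(bool)
    data = np.where(valid, m.log_jdet, 0.0)
    num = gaussian_filter(data, sigma=sigma_vox)
    den = gaussian_filter(valid.astype(float), sigma=sigma_vox)
    out = np.full_like(data, np.nan)
    ok = valid & (den > 1e-12)
    out[ok] = num[ok] / den[ok]
    return JacobianMap(out, np.array(m.affine).copy(), m.source, ~ok)


# ---------------------------------------------------------------------------
# Mass-univariate tests
# ---------------------------------------------------------------------------


def voxelwise_ttest(jmaps_a: Sequence[JacobianMap],
                    jmaps_b: Sequence[JacobianMap],
                    mask: LabelMap | np.ndarray) -> StatMaps:
    """Two-sample, two-tailed pooled-variance t-test at every masked voxel.

    Equivalent to the two-group GLM (intercept + group indicator). Voxels
    with zero pooled variance get t = 0, p = 1 and are flagged degenerate.
    """
    if len(jmaps_a) < 2 or len(jmaps_b) < 2:
        raise ValueError("need at least 2 subjects per group")
    a = _stack(jmaps_a)
    b = _stack(jmaps_b)
    if a.shape[1:] != b.shape[1:]:
        raise ValueError("groups are not in a common space")
    m = mask.labels > 0 if isinstance(mask, LabelMap) else mask.astype(bool)
    finite = np.all(np.isfinite(a), axis=0) & np.all(np.isfinite(b), axis=0)
    analysis = m & finite

    na, nb = a.shape[0], b.shape[0]
    mean_a, mean_b = a.mean(axis=0), b.mean(axis=0)
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    df = na + nb - 2
    pooled = ((na - 1) * var_a + (nb - 1) * var_b) / df
    se = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    degenerate = analysis & (se <= 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_b) / se, 0.0)
    t = np.where(analysis, t, 0.0)
    p = np.where(analysis, 2.0 * sps.t.sf(np.abs(t), df), 1.0)
    p[degenerate] = 1.0
    t[degenerate] = 0.0
    direction = np.sign(mean_a - mean_b) * analysis
    return StatMaps(t, p, np.array(jmaps_a[0].affine).copy(), df,
                    analysis & ~degenerate, direction, degenerate=degenerate)


def bh_threshold(p_values: np.ndarray, q: float,
                 dependence: bool = False) -> float:
    """Benjamini-Hochberg step-up critical p: reject all p <= p(k*), where
    k* = max{k : p(k) <= k q / (c m)}; c = 1 (independence) or the harmonic
    correction for arbitrary dependence. Returns -inf if nothing is rejected.
    """
    p = np.sort(np.asarray(p_values, float).ravel())
    m = p.size
    if m == 0:
        raise ValueError("empty p-value family")
    c = float(np.sum(1.0 / np.arange(1, m + 1))) if dependence else 1.0
    thresh = np.arange(1, m + 1) * q / (m * c)
    passing = np.nonzero(p <= thresh)[0]
    if passing.size == 0:
        return -np.inf
    return float(p[passing[-1]])


def fdr_correct(stat: StatMaps, q: float = 0.05,
                mask: np.ndarray | None = None,
                dependence: bool = False) -> StatMaps:
    """Fill ``stat.fdr_mask`` with the BH step-up decision over the masked
    voxel family (degenerate voxels excluded)."""
    family = stat.mask if mask is None else (stat.mask & mask.astype(bool))
    if not family.any():
        raise ValueError("empty analysis mask")
    crit = bh_threshold(stat.p_map[family], q, dependence)
    fdr = np.zeros_like(family)
    fdr[family] = stat.p_map[family] <= crit
    stat.fdr_mask = fdr
    stat.q = q
    return stat


# ---------------------------------------------------------------------------
# Effect sizes and sample sizes
# ---------------------------------------------------------------------------


def pooled_stdev(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """sqrt of the (n-1)-weighted average of the two group variances."""
    na, nb = a.shape[0], b.shape[0]
    var_a = a.var(axis=0, ddof=1)
    var_b = b.var(axis=0, ddof=1)
    return np.sqrt(((na - 1) * var_a + (nb - 1) * var_b) / (na + nb - 2))


def effect_size_maps(jmaps_ut: Sequence[JacobianMap],
                     jmaps_wt: Sequence[JacobianMap],
                     cfg: StatConfig | None = None) -> PowerMaps:
    """Cohen's d per voxel: (UT mean - WT mean) / pooled SD."""
    cfg = cfg or StatConfig()
    if len(jmaps_ut) < 2 or len(jmaps_wt) < 2:
        raise ValueError("need at least 2 subjects per group")
    ut = _stack(jmaps_ut)
    wt = _stack(jmaps_wt)
    sp = pooled_stdev(ut, wt)
    degenerate = sp <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(degenerate, np.nan, (ut.mean(0) - wt.mean(0)) / sp)
    return PowerMaps(
        cohens_d=d, n_arm=None, wt_stdev=wt.std(0, ddof=1), pooled_stdev=sp,
        affine=np.array(jmaps_wt[0].affine).copy(),
        z_alpha_half=cfg.z_alpha_half,
        z_one_minus_beta=cfg.z_one_minus_beta, degenerate=degenerate)


def n_arm_from_stdev(wt_stdev: np.ndarray | float,
                     cfg: StatConfig | None = None) -> np.ndarray:
    """Animals per study arm: ceil(2 (z_a + z_b)^2 sd^2 / effect^2), floor 2."""
    cfg = cfg or StatConfig()
    if cfg.effect_fraction == 0:
        raise ValueError("effect_fraction must be nonzero")
    sd = np.asarray(wt_stdev, dtype=float)
    z = cfg.z_alpha_half + cfg.z_one_minus_beta
    n = np.ceil(2.0 * z**2 * sd**2 / cfg.effect_fraction**2)
    n = np.where(np.isfinite(n), n, 2.0)  # NaN-SD voxels fall to the floor
    return np.maximum(n, 2.0).astype(np.int64)


def sample_size_map(jmaps_wt: Sequence[JacobianMap],
                    cfg: StatConfig | None = None) -> PowerMaps:
    """Per-voxel N per arm to detect ``cfg.effect_fraction`` given the WT SD.

    Zero-SD voxels report the floor of 2 and are flagged degenerate.
    """
    cfg = cfg or StatConfig()
    if len(jmaps_wt) < 2:
        raise ValueError("need at least 2 WT subjects")
    wt = _stack(jmaps_wt)
    sd = wt.std(0, ddof=1)
    return PowerMaps(
        cohens_d=None, n_arm=n_arm_from_stdev(sd, cfg), wt_stdev=sd,
        pooled_stdev=None, affine=np.array(jmaps_wt[0].affine).copy(),
        z_alpha_half=cfg.z_alpha_half,
        z_one_minus_beta=cfg.z_one_minus_beta, degenerate=(sd <= 0))


# ---------------------------------------------------------------------------
# End-to-end group comparison
# ---------------------------------------------------------------------------


def tbm_compare(
    manifest,
    groups: tuple[str, str],
    modality: str,
    cfg: StatConfig | None = None,
    source: str = "composite",
    out_dir=None,
    groupwise_kwargs: dict | None = None,
    mask_quantile: float = 0.5,
):
    """Full TBM comparison of two groups within one modality.

    Runs group-wise registration over the pooled subjects, computes per
    subject log-Jacobian maps in average space, smooths them, tests group A
    against group B voxelwise, FDR-corrects, and derives effect-size and
    sample-size maps (group A plays the test role, group B the reference/WT
    role). Returns ``(StatMaps, PowerMaps, GroupwiseResult)`` and optionally
    writes all maps as NIfTI under ``out_dir``.
    """
    from .core_image import read_nifti, write_nifti
    from .registration import groupwise_register, jacobian_log_det

    cfg = cfg or StatConfig()
    group_a, group_b = groups
    recs_a = manifest.select(group_a, modality)
    recs_b = manifest.select(group_b, modality)
    if len(recs_a) < 3 or len(recs_b) < 3:
        raise ValueError(
            f"need >=3 subjects per group for modality {modality!r}; got "
            f"{len(recs_a)} vs {len(recs_b)}")
    images = [read_nifti(manifest.resolve(r.volume_path))
              for r in recs_a + recs_b]

    gw = groupwise_register(images, **(groupwise_kwargs or {}))
    average = gw.average_image

    pos = average.data[average.data > 0]
    threshold = float(np.quantile(pos, mask_quantile)) * 0.5 if pos.size \
        else 0.0
    mask = average.data > threshold

    jmaps = []
    for t in gw.transforms:
        jm = jacobian_log_det(t, average, source=source, mask=mask)
        jmaps.append(smooth_map(jm, cfg.fwhm_mm, mask))
    jmaps_a = jmaps[:len(recs_a)]
    jmaps_b = jmaps[len(recs_a):]

    stat = voxelwise_ttest(jmaps_a, jmaps_b, mask)
    stat = fdr_correct(stat, cfg.q)
    power = effect_size_maps(jmaps_a, jmaps_b, cfg)
    power.n_arm = sample_size_map(jmaps_b, cfg).n_arm

    if out_dir is not None:
        from pathlib import Path
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        aff = average.affine
        write_nifti(average, out_dir / "average.nii.gz")
        write_nifti(Volume(stat.t_map, aff), out_dir / "t_map.nii.gz")
        write_nifti(Volume(stat.p_map, aff), out_dir / "p_map.nii.gz")
        write_nifti(Volume(stat.fdr_mask.astype(float), aff),
                    out_dir / "fdr_mask.nii.gz")
        write_nifti(Volume(stat.signed_threshold_map(), aff),
                    out_dir / "t_signed_thresholded.nii.gz")
        write_nifti(Volume(np.nan_to_num(power.cohens_d), aff),
                    out_dir / "cohens_d.nii.gz")
        write_nifti(Volume(power.n_arm.astype(float), aff),
                    out_dir / "n_arm.nii.gz")
    return stat, power, gw
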