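"""ROI-based SNR / CNR, total brain volume and group contrast reporting.

The module also carries the reference calibration tables used to set the
phantom's default tissue intensities: per-region mean SNR for the in vivo
and ex vivo wild-type protocols, the gray-white CNR for both, and the two
protocol resolutions. These are design targets for the synthetic cohort,
not measurements of it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_image import LabelMap, Volume

#: Per-region mean SNR design targets for wild-type brains (unitless).
REFERENCE_SNR: dict[str, dict[str, float]] = {
    "caudate putamen": {"invivo": 14.4, "exvivo": 9.3},
    "cerebellum": {"invivo": 7.6, "exvivo": 11.4},
    "corpus callosum": {"invivo": 15.6, "exvivo": 4.2},
    "cortex": {"invivo": 14.2, "exvivo": 10.0},
    "hippocampus": {"invivo": 19.3, "exvivo": 10.8},
    "hypothalamus": {"invivo": 11.2, "exvivo": 11.5},
    "olfactory bulb": {"invivo": 14.8, "exvivo": 10.9},
    "midbrain": {"invivo": 11.1, "exvivo": 6.9},
    "thalamus": {"invivo": 12.4, "exvivo": 7.8},
}

#: Gray-white (cortex minus corpus callosum) CNR design targets.
REFERENCE_CNR: dict[str, float] = {"invivo": 1.5, "exvivo": 5.8}

#: Isotropic acquisition resolutions of the two reference protocols, in mm.
PROTOCOL_RESOLUTION_MM: dict[str, float] = {"invivo": 0.150, "exvivo": 0.040}

#: Legend names that are never part of the brain.
NON_BRAIN_REGIONS = {"background", "noise", "brain mask"}


def _region_values(v: Volume, labels: LabelMap, region: str | int) -> np.ndarray:
    if v.data.shape != labels.shape:
        raise ValueError("volume and label map shapes differ")
    mask = labels.region_mask(region)
    if not mask.any():
        raise ValueError(f"region {region!r} is empty")
    return v.data[mask]


def roi_snr(
    v: Volume,
    labels: LabelMap,
    signal_region: str | int,
    noise_region: str | int = "noise",
    ddof: int = 1,
) -> float:
    """Mean signal in a region divided by the SD of the background noise.

    The noise region must sit in a ghost-free patch of background; this is
    the caller's responsibility. Sample SD (``ddof=1``) is the default
    convention; population SD is available via ``ddof=0``.
    """
    signal = _region_values(v, labels, signal_region)
    noise = _region_values(v, labels, noise_region)
    if noise.size < 2:
        raise ValueError("noise region too small to estimate an SD")
    sd = float(np.std(noise, ddof=ddof))
    if sd == 0:
        raise ValueError("noise region has zero standard deviation")
    return float(np.mean(signal)) / sd


def gray_white_cnr(
    v: Volume,
    labels: LabelMap,
    gray_region: str | int = "cortex",
    white_region: str | int = "corpus callosum",
    noise_region: str | int = "noise",
    ddof: int = 1,
) -> float:
    """Signed (gray mean - white mean) / noise SD; may be negative."""
    gray = _region_values(v, labels, gray_region)
    white = _region_values(v, labels, white_region)
    noise = _region_values(v, labels, noise_region)
    sd = float(np.std(noise, ddof=ddof))
    if sd == 0:
        raise ValueError("noise region has zero standard deviation")
    return (float(np.mean(gray)) - float(np.mean(white))) / sd


def voxel_volume_snr_factor(
    spacing_a: Sequence[float], spacing_b: Sequence[float]
) -> float:
    """Theoretical SNR gain of grid ``a`` over grid ``b``: voxel-volume ratio."""
    a = np.asarray(spacing_a, dtype=float)
    b = np.asarray(spacing_b, dtype=float)
    if a.shape != (3,) or b.shape != (3,):
        raise ValueError("spacings must be length-3 mm triples")
    if np.any(a <= 0) or np.any(b <= 0):
        raise ValueError("spacings must be positive")
    return float(np.prod(a) / np.prod(b))


def brain_mask_array(labels: LabelMap) -> np.ndarray:
    """Boolean brain mask: every labelled region that is brain tissue."""
    if labels.legend:
        brain_ids = [
            k for k, name in labels.legend.items()
            if k != 0 and name not in NON_BRAIN_REGIONS
        ]
        mask = np.isin(labels.labels, brain_ids)
    else:
        mask = labels.labels > 0
    return mask


def total_brain_volume(
    mask: LabelMap,
    scale_factors: Sequence[float] = (1.0, 1.0, 1.0),
) -> float:
    """Brain-mask voxel count x voxel volume x per-axis scale corrections (mm^3).

    ``scale_factors`` accept externally calibrated per-axis gradient scaling
    corrections; defaults to no correction.
    """
    m = brain_mask_array(mask)
    if not m.any():
        raise ValueError("brain mask is empty")
    factors = np.asarray(scale_factors, dtype=float)
    if factors.shape != (3,):
        raise ValueError("scale_factors must be a length-3 triple")
    return float(np.count_nonzero(m)) * mask.voxel_volume * float(np.prod(factors))


def percent_difference(value_a: float, value_b: float,
                       rounded: bool = True) -> float:
    """Relative increase of ``a`` over the reference ``b``: 100 (a - b) / b.

    Rounded to the nearest integer percent for reporting by default.
    """
    if value_b <= 0:
        raise ValueError("reference value must be positive")
    pct = 100.0 * (value_a - value_b) / value_b
    return float(np.rint(pct)) if rounded else float(pct)


def percent_smaller(value: float, reference: float,
                    rounded: bool = True) -> float:
    """How much smaller ``value`` is than the larger ``reference``:
    100 (reference - value) / reference."""
    if reference <= 0:
        raise ValueError("reference value must be positive")
    pct = 100.0 * (reference - value) / reference
    return float(np.rint(pct)) if rounded else float(pct)


@dataclass
class QualityReport:
    """Per-region SNR plus gray-white CNR for one image."""

    modality: str
    region_snr: dict[str, float]
    cnr: float
    noise_sd: float
    region_means: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"modality": self.modality, "region": r, "snr": s,
             "mean": self.region_means.get(r, np.nan)}
            for r, s in self.region_snr.items()
        ]
        return pd.DataFrame(rows)


def quality_report(
    v: Volume,
    labels: LabelMap,
    modality: str,
    regions: Sequence[str] | None = None,
    noise_region: str = "noise",
) -> QualityReport:
    """SNR for every requested region plus the gray-white CNR."""
    if regions is None:
        regions = list(REFERENCE_SNR)
    noise = _region_values(v, labels, noise_region)
    sd = float(np.std(noise, ddof=1))
    snr = {r: roi_snr(v, labels, r, noise_region) for r in regions}
    means = {r: float(np.mean(_region_values(v, labels, r))) for r in regions}
    cnr = gray_white_cnr(v, labels, noise_region=noise_region)
    return QualityReport(modality, snr, cnr, sd, means)


@dataclass
class VolumeReport:
    """Per-subject total brain volumes with group summaries."""

    rows: pd.DataFrame  # columns: subject_id, group, modality, tbv_mm3

    def group_means(self, modality: str | None = None) -> pd.Series:
        df = self.rows
        if modality is not None:
            df = df[df.modality == modality]
        if df.empty:
            raise ValueError("no subjects in report for requested modality")
        return df.groupby("group")["tbv_mm3"].mean()

    def group_sds(self, modality: str | None = None) -> pd.Series:
        df = self.rows
        if modality is not None:
            df = df[df.modality == modality]
        return df.groupby("group")["tbv_mm3"].std(ddof=1)


def group_volume_contrasts(
    report: VolumeReport, modality: str | None = None
) -> pd.DataFrame:
    """Pairwise percentage contrasts between group mean TBVs.

    Two explicitly named conventions per ordered pair (a, b):
    ``pct_increase`` = 100 (mean_a - mean_b) / mean_b, and ``pct_smaller`` =
    100 (mean_b - mean_a) / mean_b (how much smaller a is than b).
    """
    means = report.group_means(modality)
    if len(means) < 2:
        raise ValueError("need at least two groups with subjects")
    rows = []
    for ga in means.index:
        for gb in means.index:
            if ga == gb:
                continue
            rows.append({
                "group_a": ga,
                "group_b": gb,
                "mean_a": means[ga],
                "mean_b": means[gb],
                "pct_increase": percent_difference(means[ga], means[gb],
                                                  rounded=False),
                "pct_smaller": 100.0 * (means[gb] - means[ga]) / means[gb],
            })
    return pd.DataFrame(rows)
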