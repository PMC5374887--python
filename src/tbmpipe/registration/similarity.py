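"""Similarity metrics: normalized cross-correlation and normalized mutual
information (Studholme form, Parzen-windowed joint histogram).

NMI additionally returns the voxelwise derivative with respect to the
moving-image intensity, which the FFD optimizer turns into control-point
gradients by the chain rule.
"""

from __future__ import annotations

import numpy as np

from .bspline import cubic_bspline, cubic_bspline_deriv

_EPS = 1e-12


def ncc(fixed: np.ndarray, moving: np.ndarray,
        mask: np.ndarray | None = None) -> float:
    """Pearson correlation of the two intensity samples."""
    f = fixed[mask] if mask is not None else fixed.ravel()
    m = moving[mask] if mask is not None else moving.ravel()
    f = f - f.mean()
    m = m - m.mean()
    denom = np.sqrt((f @ f) * (m @ m))
    if denom < _EPS:
        raise ValueError("constant image: NCC undefined")
    return float((f @ m) / denom)


class NMIEstimator:
    """Joint-histogram NMI with a cubic B-spline Parzen window on the moving
    intensity axis and hard binning on the fixed axis.

    The fixed image and its bin assignment are frozen at construction; the
    moving intensity range is frozen too, so that NMI values are comparable
    across optimizer iterations.
    """

    def __init__(self, fixed: np.ndarray, moving_range: tuple[float, float],
                 bins: int = 64) -> None:
        fixed = np.asarray(fixed, float).ravel()
        flo, fhi = float(fixed.min()), float(fixed.max())
        if fhi - flo < _EPS:
            raise ValueError("constant fixed image: joint histogram degenerate")
        mlo, mhi = moving_range
        if mhi - mlo < _EPS:
            raise ValueError("constant moving image: joint histogram degenerate")
        self.bins = int(bins)
        self.fbin = np.clip(
            ((fixed - flo) / (fhi - flo) * self.bins).astype(np.int64),
            0, self.bins - 1)
        self.mlo = float(mlo)
        # moving axis gets 2 pad bins per side for the Parzen support
        self.mwidth = float(mhi - mlo) / self.bins
        self.mbins = self.bins + 4

    def _moving_coords(self, moving: np.ndarray) -> tuple[np.ndarray,
                                                          np.ndarray]:
        t = (np.asarray(moving, float).ravel() - self.mlo) / self.mwidth + 2.0
        t = np.clip(t, 1.0, self.mbins - 2.0)
        base = np.floor(t).astype(np.int64)
        return t, base

    def value_and_force(self, moving: np.ndarray
                        ) -> tuple[float, np.ndarray]:
        """NMI and d(NMI)/d(moving intensity) per voxel."""
        shape = moving.shape
        t, base = self._moving_coords(moving)
        n = t.size
        hist = np.zeros(self.bins * self.mbins)
        idxs = []
        for off in (-1, 0, 1, 2):
            j = np.clip(base + off, 0, self.mbins - 1)
            w = cubic_bspline(t - (base + off))
            hist += np.bincount(self.fbin * self.mbins + j, weights=w,
                                minlength=hist.size)
            idxs.append(j)
        p = hist.reshape(self.bins, self.mbins) / n
        pf = p.sum(axis=1)
        pm = p.sum(axis=0)

        def _entropy(q):
            q = q[q > _EPS]
            return float(-(q * np.log(q)).sum())

        hf, hm, hj = _entropy(pf), _entropy(pm), _entropy(p)
        if hj < _EPS:
            raise ValueError("degenerate joint histogram")
        nmi = (hf + hm) / hj

        logp = np.log(np.maximum(p, _EPS))
        logpf = np.log(np.maximum(pf, _EPS))
        logpm = np.log(np.maximum(pm, _EPS))
        # d(NMI)/dp(i,j), constant offsets dropped (they cancel voxelwise)
        lut = (-logpf[:, None] - logpm[None, :] + nmi * logp) / hj

        force = np.zeros(n)
        for off, j in zip((-1, 0, 1, 2), idxs):
            dw = cubic_bspline_deriv(t - (base + off))
            force += lut[self.fbin, j] * dw
        force /= n * self.mwidth
        return nmi, force.reshape(shape)

    def value(self, moving: np.ndarray) -> float:
        return self.value_and_force(moving)[0]


def nmi(fixed: np.ndarray, moving: np.ndarray, bins: int = 64) -> float:
    """One-shot NMI of two images."""
    est = NMIEstimator(fixed, (float(moving.min()), float(moving.max())),
                       bins)
    return est.value(moving)
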