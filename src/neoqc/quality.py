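"""Voxelwise quality maps: temporal SNR and contrast-to-noise ratio.

tSNR is the per-voxel temporal mean over the temporal standard deviation
(sample SD, divisor T−1 — used consistently across the toolkit). CNR
fits group spatial maps to the series by spatial (stage-1 dual)
regression; the fitted part is the contrast, the residual the noise, and
CNR is SD_t(contrast)/SD_t(noise).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DesignMatrixError
from .similarity import dual_regression_stage1
from .types import BrainMask, ICDecomposition, Volume4D

__all__ = ["MetricMap", "compute_tsnr", "compute_cnr"]


@dataclass
class MetricMap:
    """A 3D metric map, zero outside the mask.

    ``n_degenerate`` counts in-mask voxels where the metric was undefined
    (zero temporal variance for tSNR, zero residual for CNR); those
    voxels hold the stated degenerate value (0 and inf respectively).
    """

    data: np.ndarray
    mask: BrainMask
    n_degenerate: int = 0
    name: str = ""

    def in_mask(self) -> np.ndarray:
        return self.data[self.mask.data]

    def mean(self, finite_only: bool = True) -> float:
        """Mean over in-mask voxels (the scalar used for QC gating)."""
        v = self.in_mask()
        if finite_only:
            v = v[np.isfinite(v)]
        return float(v.mean())


def compute_tsnr(vol: Volume4D, mask: BrainMask) -> MetricMap:
    """Temporal mean / temporal SD per in-mask voxel.

    Zero-variance voxels get tSNR 0 and are counted as degenerate.
    """
    mask.check_grid(vol)
    if vol.n_frames < 2:
        raise DegenerateInputError("need at least 2 frames for tSNR")
    series = vol.data[mask.data].astype(float)  # V x T
    mean = series.mean(axis=1)
    sd = series.std(axis=1, ddof=1)
    degenerate = sd == 0
    tsnr = np.zeros_like(mean)
    np.divide(mean, sd, out=tsnr, where=~degenerate)
    out = np.zeros(vol.spatial_shape)
    out[mask.data] = tsnr
    return MetricMap(out, mask, int(degenerate.sum()), name="tSNR")


def compute_cnr(
    vol: Volume4D,
    group_maps: ICDecomposition | np.ndarray,
    mask: BrainMask,
    two_stage: bool = False,
) -> MetricMap:
    """Contrast-to-noise ratio against a set of group spatial maps.

    Stage-1 spatial regression of the demeaned series on the demeaned
    maps yields component time courses; contrast = maps·timecourses,
    noise = data − contrast (per voxel, in demeaned space). CNR is the
    ratio of their sample SDs. ``two_stage=True`` instead takes the
    contrast from the stage-2 refit (subject maps × time courses).
    Voxels with zero residual variance are flagged infinite and counted.
    """
    maps = group_maps.maps if isinstance(group_maps, ICDecomposition) else group_maps
    mask.check_grid(vol)
    tcs, M, D = dual_regression_stage1(maps, vol, mask, normalise=False)
    fit = M @ tcs.T  # V x T
    if two_stage:
        subject_maps, _ = _stage2(D, tcs)
        fit = subject_maps @ tcs.T
    noise = D - fit
    sd_fit = fit.std(axis=1, ddof=1)
    sd_noise = noise.std(axis=1, ddof=1)
    # zero residual only ever happens up to float rounding, so the
    # infinite-CNR flag uses a tolerance relative to the data scale
    tol = 1e-9 * (np.abs(D).max() + np.finfo(float).tiny)
    degenerate = sd_noise <= tol
    cnr = np.full(sd_fit.shape, np.inf)
    np.divide(sd_fit, sd_noise, out=cnr, where=~degenerate)
    out = np.zeros(vol.spatial_shape)
    out[mask.data] = cnr
    return MetricMap(out, mask, int(degenerate.sum()), name="CNR")


def _stage2(D: np.ndarray, tcs: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pinv = np.linalg.pinv(tcs)
    maps = D @ pinv.T
    return maps, pinv


def aggregate_maps(maps: list[MetricMap]) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise group mean and SD across per-scan metric maps."""
    if not maps:
        raise ValueError("no maps")
    shapes = {m.data.shape for m in maps}
    if len(shapes) > 1:
        raise DesignMatrixError(f"maps on different grids: {shapes}")
    stack = np.stack([m.data for m in maps])
    return stack.mean(axis=0), stack.std(axis=0, ddof=1 if len(maps) > 1 else 0)
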