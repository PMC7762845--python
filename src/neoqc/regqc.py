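"""Registration quality scored as normalised mutual information.

NMI here is Studholme's (H(A)+H(B))/H(A,B), bounded in [1, 2] with 2 at
perfect dependence, computed from a joint histogram of min–max scaled
intensities over a mask. Both images must already live on the same grid
(the toolkit never resamples). Cohort-level z-scoring of per-scan NMI
uses the robust (median/MAD) convention of the QC gate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GridMismatchError
from .qc import robust_z
from .types import BrainMask, Volume3D

__all__ = ["NMIScore", "normalized_mutual_information", "group_nmi_z"]

DEFAULT_BINS = 64


@dataclass
class NMIScore:
    """NMI value plus the joint histogram it was computed from."""

    nmi: float
    bins: int
    joint_histogram: np.ndarray

    def __post_init__(self) -> None:
        self.joint_histogram = np.asarray(self.joint_histogram)


def _bin_indices(x: np.ndarray, bins: int) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise DegenerateInputError("constant image: zero intensity range")
    idx = np.floor((x - lo) / (hi - lo) * bins).astype(int)
    return np.minimum(idx, bins - 1)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def normalized_mutual_information(
    source: Volume3D,
    reference: Volume3D,
    mask: BrainMask | None = None,
    bins: int = DEFAULT_BINS,
) -> NMIScore:
    """NMI between two same-grid images over a mask.

    Each image is independently min–max scaled over the mask into
    ``bins`` equal-width bins; entropies are in bits with 0·log0 = 0.
    No Parzen smoothing — reproducibility matters more than
    registration-grade smoothness for QC.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if source.data.shape != reference.data.shape:
        raise GridMismatchError(
            f"grids differ: {source.data.shape} vs {reference.data.shape}"
        )
    if mask is not None:
        mask.check_grid(source)
        m = mask.data
    else:
        m = np.ones(source.data.shape, dtype=bool)
    a = np.asarray(source.data, dtype=float)[m]
    b = np.asarray(reference.data, dtype=float)[m]
    ia = _bin_indices(a, bins)
    ib = _bin_indices(b, bins)
    joint = np.zeros((bins, bins))
    np.add.at(joint, (ia, ib), 1.0)
    p = joint / joint.sum()
    h_a = _entropy_bits(p.sum(axis=1))
    h_b = _entropy_bits(p.sum(axis=0))
    h_ab = _entropy_bits(p.ravel())
    if h_ab == 0:
        # single occupied joint cell: both marginals are constant too
        raise DegenerateInputError("degenerate histogram: one occupied bin")
    return NMIScore(float((h_a + h_b) / h_ab), bins, joint)


def group_nmi_z(scores: np.ndarray) -> np.ndarray:
    """Robust z-scores of per-scan NMI values for one registration stage.

    Higher NMI means better alignment, so z is not sign-flipped: more
    positive z = more similar.
    """
    return robust_z(np.asarray(scores, dtype=float), direction="higher_better")
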