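"""Selecting the least motion-contaminated spin-echo EPI volume per
phase-encode direction.

Subject movement during a spin-echo EPI acquisition leaves slice-to-slice
intensity striping. The z-smoothness score quantifies it: for each
adjacent slice pair the (population) standard deviation of the in-mask
voxelwise slice difference is computed, and a reduction (min by default)
collapses the Z−1 pair statistics to one score per volume. Lower is
smoother. Selection picks the minimum-score volume per direction; the
score only ranks — no absolute "good enough" threshold is defined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, GridMismatchError
from .types import BrainMask, Volume3D

__all__ = ["ZSmoothnessScore", "z_smoothness", "select_best_pair"]

_REDUCTIONS = {"min": np.min, "mean": np.mean, "max": np.max}


@dataclass
class ZSmoothnessScore:
    """Per-volume stripe-contamination score (lower = smoother)."""

    score: float
    per_slice_pair: np.ndarray
    reduction: str

    def __post_init__(self) -> None:
        self.per_slice_pair = np.asarray(self.per_slice_pair, dtype=float)


def z_smoothness(
    vol: Volume3D,
    mask: BrainMask | None = None,
    reduction: str = "min",
) -> ZSmoothnessScore:
    """Score slice-to-slice striping of a 3D volume.

    With ``mask=None`` the whole slice is used. A slice pair whose mask
    intersection is empty contributes NaN and is ignored by the
    reduction; if every pair is empty the metric is undefined.
    """
    if reduction not in _REDUCTIONS:
        raise ValueError(f"reduction must be one of {sorted(_REDUCTIONS)}")
    data = np.asarray(vol.data, dtype=float)
    nz = data.shape[2]
    if nz < 2:
        raise DegenerateInputError("need at least 2 slices in z")
    if mask is not None:
        if mask.data.shape != data.shape:
            raise GridMismatchError(
                f"mask grid {mask.data.shape} != volume grid {data.shape}"
            )
        m = mask.data
    else:
        m = np.ones(data.shape, dtype=bool)

    pair_sd = np.full(nz - 1, np.nan)
    for k in range(nz - 1):
        both = m[:, :, k] & m[:, :, k + 1]
        if not both.any():
            continue
        diff = data[:, :, k + 1][both] - data[:, :, k][both]
        pair_sd[k] = diff.std()  # population SD: defined even for 1 voxel
    valid = pair_sd[np.isfinite(pair_sd)]
    if valid.size == 0:
        raise DegenerateInputError("empty mask intersection for every slice pair")
    score = float(_REDUCTIONS[reduction](valid))
    return ZSmoothnessScore(score, pair_sd, reduction)


def select_best_pair(
    volumes: list[Volume3D],
    pe_tags: list[str],
    mask: BrainMask | None = None,
    reduction: str = "min",
) -> tuple[dict[str, int], np.ndarray]:
    """Pick the smoothest volume per phase-encode direction.

    Returns ``(best, scores)`` where ``best`` maps each direction tag to
    the index (into ``volumes``) of its minimum-score member — ties
    broken by lowest acquisition index — and ``scores`` holds every
    volume's score for reporting.
    """
    if len(volumes) != len(pe_tags):
        raise ValueError("one phase-encode tag per volume required")
    if not volumes:
        raise ValueError("no volumes given")
    scores = np.array(
        [z_smoothness(v, mask, reduction).score for v in volumes]
    )
    best: dict[str, int] = {}
    for tag in dict.fromkeys(pe_tags):  # first-seen order
        idxs = [i for i, t in enumerate(pe_tags) if t == tag]
        # np.argmin returns the first minimum -> lowest-index tie-break
        best[tag] = idxs[int(np.argmin(scores[idxs]))]
    return best, scores
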