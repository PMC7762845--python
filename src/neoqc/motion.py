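"""Per-frame motion surrogates: framewise displacement and DVARS.

Both series follow the first-frame convention value = 0 at frame 0
(backward differences are undefined there), and outlier flagging uses a
strict inequality so a value exactly at threshold is not flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError
from .types import BrainMask, MotionTrace, Volume4D

__all__ = [
    "FrameSeries",
    "OutlierFlags",
    "compute_fd",
    "fd_outliers",
    "compute_dvars",
    "dvars_outliers",
]

#: Default sphere radius (mm) for converting rotations to arc displacement.
#: The literature convention; configurable because neonatal heads are smaller.
DEFAULT_HEAD_RADIUS_MM = 50.0

#: Default framewise-displacement outlier threshold (mm).
FD_THRESHOLD_MM = 0.25


@dataclass
class FrameSeries:
    """A length-T per-frame metric series (``values[0] == 0``)."""

    values: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("FrameSeries must be 1D")

    @property
    def n_frames(self) -> int:
        return self.values.size

    def mean(self, skip_first: bool = True) -> float:
        """Mean over frames, by default excluding the conventionally-zero
        frame 0 (the value used for QC gating)."""
        v = self.values[1:] if skip_first else self.values
        return float(v.mean())


@dataclass
class OutlierFlags:
    """Boolean per-frame outlier flags plus the threshold that produced them."""

    flags: np.ndarray
    threshold: float

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.flags.ndim != 1:
            raise ValueError("flags must be 1D")
        if self.flags.size and self.flags[0]:
            raise ValueError("frame 0 can never be an outlier (no difference)")

    @property
    def frames(self) -> np.ndarray:
        return np.flatnonzero(self.flags)

    @property
    def count(self) -> int:
        return int(self.flags.sum())


def compute_fd(
    trace: MotionTrace,
    head_radius: float = DEFAULT_HEAD_RADIUS_MM,
    mode: str = "mean",
    convert_rotations: bool = True,
) -> FrameSeries:
    """Framewise displacement from rigid-body motion parameters.

    Rotations (radians) are converted to arc displacement at
    ``head_radius`` mm, then FD[t] is the **average** of the six absolute
    backward differences. ``mode="sum"`` gives the Power et al. sum
    variant for cross-tool comparison; ``convert_rotations=False``
    averages raw radians with millimetres (provided for parity with
    pipelines that skip the conversion — rarely what you want).
    """
    if trace.n_frames < 2:
        raise DegenerateInputError("need at least 2 frames for FD")
    if head_radius <= 0:
        raise ValueError("head_radius must be positive (mm)")
    params = trace.params.copy()
    if convert_rotations:
        params[:, :3] *= head_radius
    diffs = np.abs(np.diff(params, axis=0))
    agg = diffs.mean(axis=1) if mode == "mean" else diffs.sum(axis=1)
    if mode not in ("mean", "sum"):
        raise ValueError(f"unknown FD mode {mode!r}")
    fd = np.concatenate([[0.0], agg])
    return FrameSeries(fd, name="FD")


def fd_outliers(fd: FrameSeries, threshold: float = FD_THRESHOLD_MM) -> OutlierFlags:
    """Binarise FD at a fixed displacement threshold (default 0.25 mm)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    if (fd.values < 0).any():
        raise ValueError("FD must be non-negative")
    flags = fd.values > threshold
    flags[0] = False
    return OutlierFlags(flags, threshold)


def compute_dvars(vol: Volume4D, mask: BrainMask) -> FrameSeries:
    """RMS intensity difference between successive frames over the mask.

    DVARS[t] = sqrt(mean over in-mask voxels of (I[t] − I[t−1])²); no
    intensity normalisation is applied, so values are in the image's
    native intensity units.
    """
    mask.check_grid(vol)
    if vol.n_frames < 2:
        raise DegenerateInputError("need at least 2 frames for DVARS")
    series = vol.data[mask.data]  # V x T
    d = np.diff(series.astype(float), axis=1)
    dvars = np.sqrt(np.mean(d * d, axis=0))
    return FrameSeries(np.concatenate([[0.0], dvars]), name="DVARS")


def dvars_outliers(dvars: FrameSeries) -> OutlierFlags:
    """Binarise DVARS at P75 + 1.5·IQR of its own distribution.

    The threshold is computed from frames 1..T−1 (frame 0 is
    conventionally zero and excluded) with linear-interpolation
    quantiles, so the rule is reproducible bit-for-bit.
    """
    if dvars.n_frames < 2:
        raise DegenerateInputError("need at least 2 frames")
    body = dvars.values[1:]
    q1, q3 = np.percentile(body, [25, 75])  # linear interpolation
    threshold = float(q3 + 1.5 * (q3 - q1))
    flags = dvars.values > threshold
    flags[0] = False
    return OutlierFlags(flags, threshold)
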