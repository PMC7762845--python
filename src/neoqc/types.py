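"""In-memory containers shared by every stage of the toolkit.

Conventions used throughout:

* voxel indices are 0-based; world coordinates come only from the affine;
* axes are (X, Y, Z[, T]) and are never silently re-ordered;
* rotations are radians, translations millimetres, repetition time seconds;
* paired images must share a voxel grid exactly — see
  :class:`neoqc.errors.GridMismatchError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, GridMismatchError

#: Canonical motion-parameter column order: 3 rotations (rad) then 3
#: translations (mm), the MCFLIRT convention.
ROTATIONS_FIRST = "rotations_first"
#: EDDY-style order: 3 translations (mm) then 3 rotations (rad).
TRANSLATIONS_FIRST = "translations_first"

#: Component labels an IC decomposition may carry.
SIGNAL, NOISE, UNKNOWN = "signal", "noise", "unknown"

#: Tissue groups used for voxplot row ordering (display order).
TISSUE_GROUPS = ("GM", "WM", "SC", "CB", "BS")


def _check_affine(affine: np.ndarray) -> np.ndarray:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    return affine


@dataclass
class Volume3D:
    """A single 3D image with voxel geometry."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume3D needs 3 axes, got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("zero-sized spatial dimension")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass
class Volume4D:
    """A 4D functional time series (X, Y, Z, T) with geometry and TR."""

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tr: float = 1.0
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"Volume4D needs 4 axes, got {self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("zero-sized dimension")
        if self.tr <= 0:
            raise ValueError("tr must be positive (seconds)")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        self.affine = _check_affine(self.affine)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def spatial_shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def frame(self, t: int) -> Volume3D:
        return Volume3D(self.data[..., t], self.voxel_size, self.affine)

    def mean_volume(self) -> Volume3D:
        return Volume3D(self.data.mean(axis=3), self.voxel_size, self.affine)


@dataclass
class BrainMask:
    """Binary spatial mask on the grid of its parent volume."""

    data: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.data.any():
            raise DegenerateInputError("mask is empty")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_grid(self, vol: Volume3D | Volume4D) -> None:
        spatial = vol.shape[:3]
        if spatial != self.data.shape:
            raise GridMismatchError(
                f"mask grid {self.data.shape} != volume grid {spatial}"
            )


@dataclass
class TissueSegmentation:
    """Integer-labelled discrete segmentation plus label→tissue-group map.

    ``label_map`` maps every nonzero label value to one of the tissue
    groups in :data:`TISSUE_GROUPS` (several labels may share a group,
    as when a 9-label segmentation collapses to 5 display groups).
    """

    data: np.ndarray
    label_map: dict[int, str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("segmentation must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("segmentation labels must be integer")
        present = set(np.unique(self.data)) - {0}
        missing = present - set(self.label_map)
        if missing:
            raise ValueError(f"labels {sorted(missing)} absent from label_map")

    def group_mask(self, group: str) -> np.ndarray:
        """Boolean mask of all labels assigned to ``group``."""
        labels = [k for k, g in self.label_map.items() if g == group]
        return np.isin(self.data, labels)


@dataclass
class MotionTrace:
    """Per-frame rigid-body parameters in canonical order.

    Columns 0–2 are rotations (radians), columns 3–5 translations (mm);
    see :data:`ROTATIONS_FIRST`. Files in other conventions are permuted
    on read — see :func:`neoqc.io.read_motion_trace`.
    """

    params: np.ndarray

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(f"motion trace must be T x 6, got {self.params.shape}")
        if not np.isfinite(self.params).all():
            raise ValueError("motion trace contains non-finite entries")

    @property
    def n_frames(self) -> int:
        return self.params.shape[0]

    @property
    def rotations(self) -> np.ndarray:
        return self.params[:, :3]

    @property
    def translations(self) -> np.ndarray:
        return self.params[:, 3:]


@dataclass
class ICDecomposition:
    """A spatial ICA decomposition: maps, mixing matrix and labels.

    ``maps`` holds K spatial maps stacked on axis 3 (X, Y, Z, K);
    ``mixing`` is T×K; ``labels`` is length K with entries in
    {``signal``, ``noise``, ``unknown``}.
    """

    maps: np.ndarray
    mixing: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps, dtype=float)
        self.mixing = np.asarray(self.mixing, dtype=float)
        if self.maps.ndim != 4:
            raise ValueError("maps must be (X, Y, Z, K)")
        k = self.maps.shape[3]
        if k < 1:
            raise ValueError("need at least one component")
        if self.mixing.ndim != 2 or self.mixing.shape[1] != k:
            raise ValueError(
                f"mixing shape {self.mixing.shape} inconsistent with K={k}"
            )
        if len(self.labels) != k:
            raise ValueError("labels length must equal K")
        bad = set(self.labels) - {SIGNAL, NOISE, UNKNOWN}
        if bad:
            raise ValueError(f"unknown labels: {bad}")

    @property
    def n_components(self) -> int:
        return self.maps.shape[3]

    @property
    def n_frames(self) -> int:
        return self.mixing.shape[0]

    def noise_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == NOISE]

    def signal_indices(self) -> list[int]:
        return [i for i, lab in enumerate(self.labels) if lab == SIGNAL]
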