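"""Reading and writing every external representation the toolkit touches.

Images are NIfTI-1 (plain or gzipped) via nibabel; motion traces and
mixing matrices are whitespace-delimited text; component noise labels use
the hand-label dialect where the last non-empty line of the file is a
bracketed, comma-separated list of 1-based noise-component indices (all
preceding lines are comments).
"""

from __future__ import annotations

import os
import re
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import FileFormatError, MissingFileError
from .types import (
    NOISE,
    ROTATIONS_FIRST,
    SIGNAL,
    TRANSLATIONS_FIRST,
    ICDecomposition,
    MotionTrace,
    Volume3D,
    Volume4D,
)

__all__ = [
    "read_volume",
    "write_volume",
    "read_motion_trace",
    "write_motion_trace",
    "read_ic_decomposition",
    "write_ic_decomposition",
]


def _require(path: str | os.PathLike) -> Path:
    p = Path(path)
    if not p.exists():
        raise MissingFileError(f"no such file: {p}")
    return p


def read_volume(path: str | os.PathLike) -> Volume3D | Volume4D:
    """Load a NIfTI image, dispatching on header dimensionality.

    4D images return a :class:`Volume4D` with ``tr`` taken from the
    header's time step; 3D images return a :class:`Volume3D`. Trailing
    singleton time axes are honoured as stored (a 4D file with T=1 is
    still 4D).
    """
    p = _require(path)
    try:
        img = nib.load(str(p))
    except Exception as exc:  # nibabel raises several unrelated types
        raise FileFormatError(f"not a readable NIfTI file: {p} ({exc})") from exc
    try:
        data = np.asanyarray(img.dataobj)
    except Exception as exc:
        raise FileFormatError(f"could not read image data from {p} ({exc})") from exc
    if data.ndim not in (3, 4):
        raise FileFormatError(f"{p}: expected 3 or 4 axes, got {data.ndim}")
    if min(data.shape) < 1:
        raise FileFormatError(f"{p}: zero-sized dimension {data.shape}")
    zooms = img.header.get_zooms()
    voxel_size = tuple(float(z) for z in zooms[:3])
    affine = np.asarray(img.affine, dtype=float)
    if data.ndim == 3:
        return Volume3D(data, voxel_size, affine)
    tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return Volume4D(data, voxel_size, tr, affine)


def write_volume(vol: Volume3D | Volume4D, path: str | os.PathLike) -> None:
    """Write a volume as NIfTI-1, preserving geometry (and TR when 4D)."""
    img = nib.Nifti1Image(np.asarray(vol.data), vol.affine)
    if isinstance(vol, Volume4D):
        img.header.set_zooms((*vol.voxel_size, vol.tr))
        img.header.set_xyzt_units("mm", "sec")
    else:
        img.header.set_zooms(vol.voxel_size)
        img.header.set_xyzt_units("mm")
    img.to_filename(str(path))


def read_motion_trace(
    path: str | os.PathLike, column_order: str = ROTATIONS_FIRST
) -> MotionTrace:
    """Read a T×6 rigid-body parameter file into canonical order.

    ``column_order`` declares the on-disk convention and is never
    auto-detected: silently confusing radians with millimetres would
    corrupt every downstream motion metric.
    """
    p = _require(path)
    try:
        arr = np.loadtxt(str(p), ndmin=2)
    except ValueError as exc:
        raise FileFormatError(f"{p}: non-numeric token ({exc})") from exc
    if arr.shape[1] != 6:
        raise FileFormatError(f"{p}: expected 6 columns, got {arr.shape[1]}")
    if column_order == ROTATIONS_FIRST:
        pass
    elif column_order == TRANSLATIONS_FIRST:
        arr = arr[:, [3, 4, 5, 0, 1, 2]]
    else:
        raise ValueError(f"unknown column_order {column_order!r}")
    return MotionTrace(arr)


def write_motion_trace(trace: MotionTrace, path: str | os.PathLike) -> None:
    np.savetxt(str(path), trace.params, fmt="%.10g")


_LABEL_LINE = re.compile(r"^\[(.*)\]$")


def _parse_noise_labels(text: str, k: int, path: Path) -> list[str]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FileFormatError(f"{path}: empty label file")
    m = _LABEL_LINE.match(lines[-1])
    if m is None:
        raise FileFormatError(
            f"{path}: last non-empty line is not a bracketed index list"
        )
    body = m.group(1).strip()
    labels = [SIGNAL] * k
    if not body:
        return labels
    for tok in body.split(","):
        try:
            idx = int(tok)
        except ValueError as exc:
            raise FileFormatError(f"{path}: bad component index {tok!r}") from exc
        if not 1 <= idx <= k:
            raise FileFormatError(
                f"{path}: noise index {idx} out of range 1..{k}"
            )
        labels[idx - 1] = NOISE
    return labels


def read_ic_decomposition(
    maps_path: str | os.PathLike,
    mixing_path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
) -> ICDecomposition:
    """Assemble an IC decomposition from its three on-disk pieces.

    ``maps_path`` is a K-volume 4D NIfTI, ``mixing_path`` a T×K text
    matrix, ``labels_path`` (optional) a noise-index label file; with no
    label file every component is labelled signal.
    """
    maps_vol = read_volume(maps_path)
    if not isinstance(maps_vol, Volume4D):
        raise FileFormatError(f"{maps_path}: component maps must be 4D")
    k = maps_vol.n_frames
    mp = _require(mixing_path)
    try:
        mixing = np.loadtxt(str(mp), ndmin=2)
    except ValueError as exc:
        raise FileFormatError(f"{mp}: non-numeric token ({exc})") from exc
    if mixing.shape[1] != k:
        raise FileFormatError(
            f"K mismatch: {maps_path} has {k} maps, {mp} has "
            f"{mixing.shape[1]} columns"
        )
    if labels_path is None:
        labels = [SIGNAL] * k
    else:
        lp = _require(labels_path)
        labels = _parse_noise_labels(lp.read_text(), k, lp)
    return ICDecomposition(maps_vol.data, mixing, labels)


def write_ic_decomposition(
    ics: ICDecomposition,
    maps_path: str | os.PathLike,
    mixing_path: str | os.PathLike,
    labels_path: str | os.PathLike | None = None,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> None:
    aff = np.eye(4) if affine is None else affine
    write_volume(Volume4D(ics.maps, voxel_size, 1.0, aff), maps_path)
    np.savetxt(str(mixing_path), ics.mixing, fmt="%.10g")
    if labels_path is not None:
        noise = [str(i + 1) for i in ics.noise_indices()]
        Path(labels_path).write_text("[" + ", ".join(noise) + "]\n")
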