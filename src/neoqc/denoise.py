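"""Temporal high-pass filtering and simultaneous nuisance regression.

The drift filter subtracts a Gaussian-weighted running-line fit (local
linear trend) from every voxel series and restores its original mean, so
slow drifts below the cutoff period are removed while fluctuations well
above it pass nearly untouched. Nuisance regression then removes the
noise-IC time courses and the six motion parameters in one joint
ordinary-least-squares fit ("aggressive" mode), or — when signal time
courses are supplied — only the unique nuisance contribution of a joint
[signal, nuisance] fit ("nonaggressive" mode, the FIX convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, DesignMatrixError
from .motion import OutlierFlags
from .types import ICDecomposition, MotionTrace, Volume4D

__all__ = [
    "NuisanceMatrix",
    "highpass_filter",
    "build_nuisance_matrix",
    "regress_nuisance",
]

DEFAULT_CUTOFF_S = 150.0


@dataclass
class NuisanceMatrix:
    """T×P design of demeaned nuisance regressors with provenance tags.

    Tags record where each column came from (``noise_ic:3``,
    ``motion:rot_x``, ``spike:41``) so rank-deficiency errors can name
    the offending regressors.
    """

    columns: np.ndarray
    tags: list[str]

    def __post_init__(self) -> None:
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2:
            raise ValueError("design must be T x P")
        if self.columns.shape[1] != len(self.tags):
            raise ValueError("one tag per column required")
        if self.columns.shape[1] < 1:
            raise DesignMatrixError("empty nuisance design")
        # demeaned columns are an invariant (regression idempotence and
        # mean preservation rely on it), so enforce rather than trust
        self.columns = self.columns - self.columns.mean(axis=0, keepdims=True)
        norms = np.linalg.norm(self.columns, axis=0)
        dead = [t for t, n in zip(self.tags, norms) if n == 0]
        if dead:
            raise DesignMatrixError(
                f"all-zero (or constant) nuisance columns: {dead}"
            )

    @property
    def n_frames(self) -> int:
        return self.columns.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.columns.shape[1]


def _runline_smoother(t: int, sigma: float) -> np.ndarray:
    """T×T Gaussian-weighted local linear smoother matrix.

    Row i holds the weights producing the running-line trend estimate at
    frame i; the kernel is truncated at ±4σ.
    """
    s = np.zeros((t, t))
    half = max(1, int(np.ceil(4 * sigma)))
    base = np.arange(-half, half + 1)
    wbase = np.exp(-0.5 * (base / sigma) ** 2)
    for i in range(t):
        lo = max(0, i - half)
        hi = min(t, i + half + 1)
        x = np.arange(lo, hi) - i
        w = wbase[x + half]
        sw = w.sum()
        sx = (w * x).sum()
        sxx = (w * x * x).sum()
        den = sw * sxx - sx * sx
        if den <= 0:  # degenerate window (single frame): plain average
            s[i, lo:hi] = w / sw
        else:
            s[i, lo:hi] = (sxx - sx * x) * w / den
    return s


def highpass_filter(
    vol: Volume4D, cutoff_s: float = DEFAULT_CUTOFF_S
) -> Volume4D:
    """Remove slow drifts below the cutoff period, preserving the mean.

    Per voxel, the trend from a Gaussian-weighted running-line fit
    (kernel SD = cutoff_s/(2π·tr) frames, so a sinusoid at the cutoff
    period sits at the Gaussian's standard frequency) is subtracted and
    the original temporal mean restored.
    """
    if cutoff_s <= 2 * vol.tr:
        raise DegenerateInputError(
            f"cutoff {cutoff_s}s must exceed 2·tr = {2 * vol.tr:.3f}s"
        )
    t = vol.n_frames
    sigma = cutoff_s / (2 * np.pi * vol.tr)
    smoother = _runline_smoother(t, sigma)
    flat = vol.data.reshape(-1, t).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    resid = flat - flat @ smoother.T
    # the smoother is not exactly mean-preserving at the run edges, so
    # re-centre the residual before restoring the original mean
    out = resid - resid.mean(axis=1, keepdims=True) + mean
    return Volume4D(
        out.reshape(vol.data.shape), vol.voxel_size, vol.tr, vol.affine
    )


_MOTION_TAGS = ["rot_x", "rot_y", "rot_z", "trans_x", "trans_y", "trans_z"]


def build_nuisance_matrix(
    ics: ICDecomposition | None = None,
    trace: MotionTrace | None = None,
    include_spikes: bool = False,
    fd_flags: OutlierFlags | None = None,
    dvars_flags: OutlierFlags | None = None,
) -> NuisanceMatrix:
    """Assemble the demeaned nuisance design.

    Columns are the mixing time courses of components labelled noise,
    the six motion parameters, and (with ``include_spikes``) one
    indicator column per outlier frame, frames flagged by both FD and
    DVARS merged into a single column. Everything is demeaned.
    """
    blocks: list[np.ndarray] = []
    tags: list[str] = []
    t = None
    if ics is not None:
        idx = ics.noise_indices()
        if idx:
            blocks.append(ics.mixing[:, idx])
            tags.extend(f"noise_ic:{i + 1}" for i in idx)
            t = ics.n_frames
    if trace is not None:
        blocks.append(trace.params)
        tags.extend(f"motion:{m}" for m in _MOTION_TAGS)
        if t is not None and trace.n_frames != t:
            raise DesignMatrixError(
                f"motion trace T={trace.n_frames} != mixing T={t}"
            )
        t = trace.n_frames
    if not blocks:
        raise DesignMatrixError(
            "empty design: no noise components and no motion trace"
        )
    if include_spikes:
        frames: set[int] = set()
        for fl in (fd_flags, dvars_flags):
            if fl is not None:
                if fl.flags.size != t:
                    raise DesignMatrixError("outlier flags length mismatch")
                frames.update(int(f) for f in fl.frames)
        for f in sorted(frames):
            col = np.zeros((t, 1))
            col[f, 0] = 1.0
            blocks.append(col)
            tags.append(f"spike:{f}")
    design = np.hstack(blocks)
    design = design - design.mean(axis=0, keepdims=True)
    return NuisanceMatrix(design, tags)


def _check_rank(x: np.ndarray, tags: list[str]) -> None:
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        # name a minimal set of offending columns by greedy elimination
        keep: list[int] = []
        offending: list[str] = []
        for j in range(x.shape[1]):
            trial = x[:, keep + [j]]
            if np.linalg.matrix_rank(trial) == len(keep) + 1:
                keep.append(j)
            else:
                offending.append(tags[j])
        raise DesignMatrixError(
            f"rank-deficient design (rank {rank} < {x.shape[1]}); "
            f"collinear columns: {offending}"
        )


def regress_nuisance(
    vol: Volume4D,
    design: NuisanceMatrix,
    mode: str = "aggressive",
    signal_mixing: np.ndarray | None = None,
) -> Volume4D:
    """Regress the nuisance design out of every voxel series.

    ``aggressive``: OLS of the demeaned series on the design; the
    residual plus the original mean is returned. ``nonaggressive``: the
    full [signal, nuisance] design is fitted jointly and only the
    nuisance partition's fitted contribution is subtracted, preserving
    variance shared with the signal time courses.
    """
    t = vol.n_frames
    if design.n_frames != t:
        raise DesignMatrixError(
            f"design T={design.n_frames} != volume T={t}"
        )
    if design.n_regressors >= t:
        raise DesignMatrixError("need P < T")
    flat = vol.data.reshape(-1, t).astype(float)
    mean = flat.mean(axis=1, keepdims=True)
    demeaned = flat - mean

    if mode == "aggressive":
        x = design.columns
        _check_rank(x, design.tags)
        beta = np.linalg.pinv(x) @ demeaned.T  # P x V
        out = demeaned - (x @ beta).T
    elif mode == "nonaggressive":
        if signal_mixing is None:
            raise ValueError("nonaggressive mode needs signal time courses")
        sig = np.asarray(signal_mixing, dtype=float)
        if sig.ndim != 2 or sig.shape[0] != t:
            raise DesignMatrixError("signal_mixing must be T x K_signal")
        sig = sig - sig.mean(axis=0, keepdims=True)
        full = np.hstack([sig, design.columns])
        tags = [f"signal:{j + 1}" for j in range(sig.shape[1])] + design.tags
        _check_rank(full, tags)
        beta = np.linalg.pinv(full) @ demeaned.T  # (Ks+P) x V
        noise_fit = design.columns @ beta[sig.shape[1]:, :]
        out = demeaned - noise_fit.T
    else:
        raise ValueError(f"unknown mode {mode!r}")

    out = out + mean
    return Volume4D(
        out.reshape(vol.data.shape), vol.voxel_size, vol.tr, vol.affine
    )
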