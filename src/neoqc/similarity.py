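"""Dual regression against group spatial maps and the similarity
statistics used to evaluate pre-processing quality.

Dual regression maps a set of K group spatial maps into a single scan in
two least-squares stages: (1) spatial regression of the demeaned in-mask
data on the demeaned maps gives subject-specific time courses; (2)
temporal regression of the demeaned data on those (variance-normalised)
time courses gives subject-specific spatial maps. Partial-correlation
network matrices summarise the time courses; spatial and netmat Pearson
correlations against group references quantify how well a scan expresses
the group's network structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, DesignMatrixError
from .types import BrainMask, ICDecomposition, Volume4D

__all__ = [
    "TimecourseSet",
    "NetMat",
    "SimilarityResult",
    "dual_regression",
    "spatial_similarity",
    "partial_netmat",
    "netmat_similarity",
    "group_average_netmat",
]

#: |r| is clipped here before atanh so Fisher z stays finite.
FISHER_CLIP = 1.0 - 1e-7


@dataclass
class TimecourseSet:
    """T×K subject-specific component time courses."""

    tcs: np.ndarray
    normalised: bool = False

    def __post_init__(self) -> None:
        self.tcs = np.asarray(self.tcs, dtype=float)
        if self.tcs.ndim != 2:
            raise ValueError("time courses must be T x K")

    @property
    def n_components(self) -> int:
        return self.tcs.shape[1]

    @property
    def n_frames(self) -> int:
        return self.tcs.shape[0]


@dataclass
class NetMat:
    """K×K Fisher-z partial-correlation network matrix, zero diagonal."""

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        k = self.values.shape[0]
        if self.values.shape != (k, k):
            raise ValueError("netmat must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("netmat must be symmetric")

    @property
    def n_components(self) -> int:
        return self.values.shape[0]

    def upper_triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_components, k=1)
        return self.values[iu]


@dataclass
class SimilarityResult:
    """Per-component spatial correlations plus scalar netmat correlation."""

    spatial_r: np.ndarray
    netmat_r: float | None = None

    def __post_init__(self) -> None:
        self.spatial_r = np.asarray(self.spatial_r, dtype=float)

    @property
    def mean_spatial_r(self) -> float:
        return float(self.spatial_r.mean())


def _demean_rows(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=1, keepdims=True)


def _demean_cols(a: np.ndarray) -> np.ndarray:
    return a - a.mean(axis=0, keepdims=True)


def dual_regression_stage1(
    maps: np.ndarray,
    vol: Volume4D,
    mask: BrainMask,
    normalise: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Spatial multiple regression of the data on the group maps.

    Maps and data are both demeaned across voxels (and the data across
    time first), the standard convention — it makes the regression
    insensitive to per-frame global intensity and gives an exactly zero
    residual in the noiseless rank-K limit. Returns ``(tcs, M, D)``:
    time courses (T×K), the spatially demeaned in-mask map matrix (V×K)
    and the temporally+spatially demeaned in-mask data (V×T).
    """
    mask.check_grid(vol)
    if maps.shape[:3] != vol.spatial_shape:
        raise DesignMatrixError(
            f"group maps grid {maps.shape[:3]} != functional grid "
            f"{vol.spatial_shape}"
        )
    k = maps.shape[3]
    if k >= vol.n_frames:
        raise DesignMatrixError(f"need K < T, got K={k}, T={vol.n_frames}")
    M = _demean_cols(maps[mask.data].astype(float))  # V x K
    if np.linalg.matrix_rank(M) < k:
        raise DesignMatrixError("group maps are collinear over the mask")
    D = _demean_cols(_demean_rows(vol.data[mask.data].astype(float)))  # V x T
    tcs = (np.linalg.pinv(M) @ D).T  # T x K
    if normalise:
        sd = tcs.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        tcs = tcs / sd
    return tcs, M, D


def dual_regression(
    group_maps: ICDecomposition | np.ndarray,
    vol: Volume4D,
    mask: BrainMask,
    normalise: bool = True,
) -> tuple[TimecourseSet, np.ndarray]:
    """Full two-stage dual regression.

    Returns the stage-1 time courses (variance-normalised by default)
    and the stage-2 subject spatial maps as an (X, Y, Z, K) array that
    is zero outside the mask.
    """
    maps = group_maps.maps if isinstance(group_maps, ICDecomposition) else group_maps
    tcs, _, _ = dual_regression_stage1(maps, vol, mask, normalise=normalise)
    x = _demean_cols(tcs)
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise DesignMatrixError("stage-1 time courses are collinear")
    # stage 2 is a per-voxel temporal regression on the demeaned tcs
    D = _demean_rows(vol.data[mask.data].astype(float))
    betas = D @ np.linalg.pinv(x).T  # V x K
    out = np.zeros(maps.shape)
    out[mask.data] = betas
    return TimecourseSet(tcs, normalised=normalise), out


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xd = x - x.mean()
    yd = y - y.mean()
    nx, ny = np.linalg.norm(xd), np.linalg.norm(yd)
    if nx == 0 or ny == 0:
        raise DegenerateInputError("zero-variance input to correlation")
    return float(np.clip(xd @ yd / (nx * ny), -1.0, 1.0))


def spatial_similarity(
    subject_maps: np.ndarray,
    group_maps: ICDecomposition | np.ndarray,
    mask: BrainMask,
) -> np.ndarray:
    """Per-component Pearson correlation over in-mask voxels."""
    gmaps = group_maps.maps if isinstance(group_maps, ICDecomposition) else group_maps
    if subject_maps.shape != gmaps.shape:
        raise DesignMatrixError(
            f"map stacks differ: {subject_maps.shape} vs {gmaps.shape}"
        )
    s = subject_maps[mask.data]
    g = gmaps[mask.data]
    return np.array([_pearson(s[:, j], g[:, j]) for j in range(s.shape[1])])


def partial_netmat(tcs: TimecourseSet | np.ndarray, ridge: float = 0.0) -> NetMat:
    """Fisher-z partial-correlation matrix of component time courses.

    Partial correlations come from the inverse covariance:
    r_ij = −Ω_ij/√(Ω_ii·Ω_jj). ``ridge`` adds λ·mean(diag(C)) to the
    covariance diagonal for ill-conditioned small-T cases; the default
    is unregularised (appropriate for K ≪ T).
    """
    a = tcs.tcs if isinstance(tcs, TimecourseSet) else np.asarray(tcs, dtype=float)
    t, k = a.shape
    if t <= k + 1:
        raise DegenerateInputError(f"need T > K+1, got T={t}, K={k}")
    c = np.cov(a, rowvar=False)
    if ridge > 0:
        c = c + ridge * np.mean(np.diag(c)) * np.eye(k)
    try:
        omega = np.linalg.inv(c)
    except np.linalg.LinAlgError as exc:
        raise DesignMatrixError("singular time-course covariance") from exc
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    np.fill_diagonal(pc, 0.0)
    z = np.arctanh(np.clip(pc, -FISHER_CLIP, FISHER_CLIP))
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2  # enforce exact symmetry against float noise
    return NetMat(z)


def netmat_similarity(subject: NetMat, group: NetMat) -> float:
    """Pearson correlation of the two netmats' upper triangles."""
    if subject.n_components != group.n_components:
        raise DesignMatrixError("netmat sizes differ")
    if subject.n_components < 3:
        raise DegenerateInputError(
            "need K >= 3 (at least 2 off-diagonal pairs) for a correlation"
        )
    return _pearson(subject.upper_triangle(), group.upper_triangle())


def group_average_netmat(netmats: list[NetMat]) -> NetMat:
    """Element-wise mean in Fisher-z space."""
    if not netmats:
        raise ValueError("no netmats")
    k = netmats[0].n_components
    if any(n.n_components != k for n in netmats):
        raise DesignMatrixError("netmat sizes differ")
    return NetMat(np.mean([n.values for n in netmats], axis=0))


def evaluate_similarity(
    group_maps: ICDecomposition | np.ndarray,
    vol: Volume4D,
    mask: BrainMask,
    group_netmat: NetMat | None = None,
) -> SimilarityResult:
    """Convenience wrapper: dual-regress and score one scan."""
    tcs, subject_maps = dual_regression(group_maps, vol, mask)
    spatial = spatial_similarity(subject_maps, group_maps, mask)
    nm_r = None
    if group_netmat is not None:
        nm_r = netmat_similarity(partial_netmat(tcs), group_netmat)
    return SimilarityResult(spatial, nm_r)
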