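"""Z-scored carpet plots ("voxplots") with tissue-grouped rows.

The heat-map holds every in-mask voxel's time series with its temporal
mean and linear trend removed; the **whole** heat-map (not each row) is
then standardised to zero mean and unit SD, and displayed with a
diverging colour map so motion-contaminated frames appear as vertical
stripes. Rows are ordered by tissue group (GM, WM, SC, CB, BS) and, in
each group, by anatomical raster order, with optional even-stride
subsampling so large scans stay plottable without a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import GridMismatchError
from .motion import FrameSeries
from .types import TISSUE_GROUPS, TissueSegmentation, Volume4D

__all__ = ["VoxplotData", "build_voxplot", "render_voxplot"]


@dataclass
class VoxplotData:
    """Standardised voxel×time heat-map plus aligned nuisance traces."""

    heatmap: np.ndarray
    row_groups: list[tuple[str, int, int]]  # (group, row_start, row_stop)
    fd: FrameSeries | None = None
    dvars: FrameSeries | None = None

    def __post_init__(self) -> None:
        self.heatmap = np.asarray(self.heatmap, dtype=float)
        if self.heatmap.ndim != 2:
            raise ValueError("heatmap must be rows x T")
        stop = 0
        for _, lo, hi in self.row_groups:
            if lo != stop or hi < lo:
                raise ValueError("row groups must partition the rows in order")
            stop = hi
        if stop != self.heatmap.shape[0]:
            raise ValueError("row groups do not cover all rows")


def _detrend(series: np.ndarray) -> np.ndarray:
    """Remove per-row mean and linear trend (least squares)."""
    t = series.shape[1]
    x = np.arange(t) - (t - 1) / 2
    sxx = (x * x).sum()
    out = series - series.mean(axis=1, keepdims=True)
    slope = (out @ x) / sxx
    return out - slope[:, None] * x[None, :]


def build_voxplot(
    vol: Volume4D,
    seg: TissueSegmentation,
    fd: FrameSeries | None = None,
    dvars: FrameSeries | None = None,
    subsample_cap: int | None = None,
) -> VoxplotData:
    """Assemble the z-scored, tissue-ordered heat-map.

    ``subsample_cap`` limits rows **per tissue group** by even-stride
    selection. Empty tissue groups are dropped. Standardisation of an
    all-zero (constant/trend-only) heat-map is skipped, leaving zeros.
    """
    if seg.data.shape != vol.spatial_shape:
        raise GridMismatchError(
            f"segmentation grid {seg.data.shape} != functional "
            f"grid {vol.spatial_shape}"
        )
    for tr_series, label in ((fd, "FD"), (dvars, "DVARS")):
        if tr_series is not None and tr_series.n_frames != vol.n_frames:
            raise ValueError(f"{label} trace length != T")
    rows: list[np.ndarray] = []
    groups: list[tuple[str, int, int]] = []
    start = 0
    for group in TISSUE_GROUPS:
        gm = seg.group_mask(group)
        if not gm.any():
            continue
        series = vol.data[gm].astype(float)  # raster order within group
        if subsample_cap is not None and series.shape[0] > subsample_cap:
            idx = np.linspace(0, series.shape[0] - 1, subsample_cap).astype(int)
            series = series[idx]
        rows.append(series)
        groups.append((group, start, start + series.shape[0]))
        start += series.shape[0]
    if not rows:
        raise ValueError("no tissue group overlaps the volume")
    raw = np.vstack(rows)
    heat = _detrend(raw)
    sd = heat.std()
    # a pure constant-plus-trend input detrends to numerical dust; treat
    # it as an all-zero map instead of amplifying rounding noise
    scale = max(1.0, float(np.abs(raw).max()))
    if sd > 1e-10 * scale:
        heat = (heat - heat.mean()) / sd
    else:
        heat = np.zeros_like(heat)
    return VoxplotData(heat, groups, fd, dvars)


_GROUP_COLOURS = {
    "GM": "#1f77b4",
    "WM": "#ff7f0e",
    "SC": "#2ca02c",
    "CB": "#d62728",
    "BS": "#9467bd",
}


def render_voxplot(
    data: VoxplotData,
    path: str,
    title: str | None = None,
    vlim: float | None = None,
) -> None:
    """Write the voxplot as a PNG/SVG.

    The colour scale is symmetric about zero (``±vlim``, default the
    98th percentile of |z|), with tissue side-bands and FD/DVARS panels
    sharing the time axis.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib import gridspec

    n_traces = sum(x is not None for x in (data.fd, data.dvars))
    fig = plt.figure(figsize=(8, 5))
    gs = gridspec.GridSpec(
        1 + n_traces,
        2,
        width_ratios=[0.03, 1],
        height_ratios=[4] + [1] * n_traces,
        hspace=0.15,
        wspace=0.02,
    )
    ax = fig.add_subplot(gs[0, 1])
    if vlim is None:
        vlim = float(np.percentile(np.abs(data.heatmap), 98)) or 1.0
    ax.imshow(
        data.heatmap,
        aspect="auto",
        cmap="RdBu_r",
        vmin=-vlim,
        vmax=vlim,
        interpolation="none",
    )
    ax.set_yticks([])
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    band = fig.add_subplot(gs[0, 0], sharey=ax)
    for group, lo, hi in data.row_groups:
        band.axhspan(lo, hi, color=_GROUP_COLOURS.get(group, "grey"))
        band.text(
            0.5, (lo + hi) / 2, group, rotation=90, fontsize=6,
            ha="center", va="center",
        )
    band.set_xticks([])
    band.set_yticks([])
    row = 1
    t = data.heatmap.shape[1]
    for series, label in ((data.dvars, "DVARS"), (data.fd, "FD")):
        if series is None:
            continue
        axt = fig.add_subplot(gs[row, 1])
        axt.plot(np.arange(t), series.values, lw=0.8, color="k")
        axt.set_xlim(0, t - 1)
        axt.set_ylabel(label, fontsize=7)
        axt.tick_params(labelsize=6)
        row += 1
    fig.savefig(path, dpi=100, bbox_inches="tight", metadata={"Software": None})
    plt.close(fig)
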