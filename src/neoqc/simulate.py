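"""Fully ground-truthed synthetic resting-state scans.

The generator emulates the artefact taxonomy seen in heavily
motion-confounded (neonatal) multiband EPI so that every downstream
stage — motion metrics, nuisance regression, dual regression, QC
gating, voxplots — can be exercised and validated without any real
acquisition:

* **RSN signal**: spatially disjoint Gaussian blobs whose time courses
  are sparse neural events convolved with a neonatal-like double-gamma
  HRF (delayed, smaller peak, deeper undershoot than the adult shape).
* **Motion spikes**: step discontinuities in the rigid-body trace,
  mirrored in the image as a 1-voxel shift plus a brain-edge intensity
  ring at the same frames.
* **Slice striping** ("venetian blind"): alternating-slice intensity
  modulation of the baseline, intensified at spike frames.
* **Slow drift**: a sinusoid-plus-ramp below the usual high-pass cutoff.

Everything additive is also recorded as a ground-truth factor model
(spatial map × time course, labelled signal or noise), so the generated
volume equals baseline + maps·timecourses + spike-shift effects + noise
by construction, and parameter-recovery tests can compare against the
exact truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .qc import GATE_METRICS, QCRecord
from .types import (
    NOISE,
    SIGNAL,
    BrainMask,
    ICDecomposition,
    MotionTrace,
    TissueSegmentation,
    Volume3D,
    Volume4D,
)

__all__ = [
    "SimulationConfig",
    "SyntheticScan",
    "neonatal_hrf",
    "simulate_scan",
    "simulate_sevol_series",
    "simulate_qc_cohort",
]


@dataclass
class SimulationConfig:
    """All knobs of one synthetic realisation; the seed fixes everything.

    Defaults are desk-scale study conditions: a 20×20×12 grid over 600
    frames at the fast-TR regime (0.392 s, ~235 s of data), four
    networks, 2%-of-baseline BOLD amplitude, six 1 mm motion spikes,
    mild striping and a 300 s drift.
    """

    shape: tuple[int, int, int, int] = (20, 20, 12, 600)
    tr: float = 0.392
    n_networks: int = 4
    baseline: float = 1000.0
    signal_amplitude: float = 20.0
    # haemodynamic response (neonatal-like defaults: later, smaller peak
    # and deeper undershoot than the canonical adult response; the exact
    # infant parameters are not standardised, so these are qualitative)
    hrf_peak_time_s: float = 7.0
    hrf_peak_amplitude: float = 1.0
    hrf_undershoot_depth: float = 0.5
    hrf_undershoot_time_s: float = 16.0
    # motion artefact
    n_motion_spikes: int = 6
    spike_magnitude_mm: float = 1.0
    # stripe artefact (fraction of baseline, on alternating slices)
    stripe_period: int = 2
    stripe_amplitude: float = 0.03
    # slow drift (intensity units / seconds)
    drift_amplitude: float = 10.0
    drift_period_s: float = 300.0
    noise_sd: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        x, y, z, t = self.shape
        if min(x, y, z) < 4 or t < 2:
            raise ValueError(f"grid {self.shape} too small")
        for name in (
            "signal_amplitude",
            "hrf_peak_amplitude",
            "hrf_undershoot_depth",
            "spike_magnitude_mm",
            "stripe_amplitude",
            "drift_amplitude",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_motion_spikes >= t:
            raise ValueError("more spike frames than frames")
        if self.stripe_period < 1:
            raise ValueError("stripe_period must be >= 1")


@dataclass
class SyntheticScan:
    """A generated scan plus its complete ground truth."""

    volume: Volume4D
    truth: ICDecomposition
    motion: MotionTrace
    artefact_frames: np.ndarray
    segmentation: TissueSegmentation
    mask: BrainMask
    config: SimulationConfig = field(repr=False, default=None)

    @property
    def truth_maps(self) -> np.ndarray:
        """Spatial maps of the signal (network) components only."""
        return self.truth.maps[..., self.truth.signal_indices()]

    @property
    def truth_timecourses(self) -> np.ndarray:
        return self.truth.mixing[:, self.truth.signal_indices()]

    @property
    def noise_mixing(self) -> np.ndarray:
        return self.truth.mixing[:, self.truth.noise_indices()]


def neonatal_hrf(
    t: np.ndarray,
    peak_time_s: float = 7.0,
    peak_amplitude: float = 1.0,
    undershoot_depth: float = 0.5,
    undershoot_time_s: float = 16.0,
) -> np.ndarray:
    """Double-gamma haemodynamic response sampled at times ``t`` (s).

    Parameterised directly by the features that distinguish the infant
    from the adult response: time-to-peak, peak amplitude, and
    undershoot depth as a fraction of the peak.
    """
    t = np.asarray(t, dtype=float)

    def bump(mode: float, shape_k: float) -> np.ndarray:
        theta = mode / (shape_k - 1)
        g = np.zeros_like(t)
        pos = t > 0
        g[pos] = t[pos] ** (shape_k - 1) * np.exp(-t[pos] / theta)
        peak = mode ** (shape_k - 1) * np.exp(-(shape_k - 1))
        return g / peak

    h = bump(peak_time_s, 6.0) - undershoot_depth * bump(undershoot_time_s, 12.0)
    return peak_amplitude * h


def _ellipsoid_radius(shape: tuple[int, int, int]) -> np.ndarray:
    """Normalised ellipsoidal radius (1.0 at the 'brain' surface)."""
    x, y, z = shape
    ii, jj, kk = np.meshgrid(
        np.arange(x), np.arange(y), np.arange(z), indexing="ij"
    )
    cx, cy, cz = (x - 1) / 2, (y - 1) / 2, (z - 1) / 2
    return np.sqrt(
        ((ii - cx) / (0.92 * x / 2)) ** 2
        + ((jj - cy) / (0.92 * y / 2)) ** 2
        + ((kk - cz) / (0.92 * z / 2)) ** 2
    )


def _phantom(shape: tuple[int, int, int]) -> tuple[BrainMask, TissueSegmentation]:
    """Concentric-shell head phantom: GM shell, WM core, SC blob and
    CB+BS lobes in the lowest slices."""
    r = _ellipsoid_radius(shape)
    inside = r <= 1.0
    z = shape[2]
    low = np.zeros(shape, dtype=bool)
    low[:, :, : max(2, z // 6)] = True
    seg = np.zeros(shape, dtype=np.int16)
    seg[inside & (r <= 1.0)] = 1  # GM (outer shell by later overwrite)
    seg[inside & (r < 0.62)] = 2  # WM
    seg[inside & (r < 0.25)] = 3  # SC
    # brainstem: central column in the low slices; cerebellum: the rest
    mid_x = shape[0] // 2
    bs = inside & low & (np.abs(np.arange(shape[0])[:, None, None] - mid_x) <= 2)
    cb = inside & low & ~bs
    seg[cb] = 4
    seg[bs] = 5
    label_map = {1: "GM", 2: "WM", 3: "SC", 4: "CB", 5: "BS"}
    return BrainMask(inside), TissueSegmentation(seg, label_map)


def _network_maps(
    shape: tuple[int, int, int], n: int, mask: np.ndarray
) -> np.ndarray:
    """``n`` spatially disjoint Gaussian blobs inside the mask."""
    x, y, z = shape
    sigma = 1.6
    cut = 2.5 * sigma
    ring = 0.30 * min(x, y)
    centres = []
    for j in range(n):
        ang = 2 * np.pi * j / n
        centres.append(
            (
                (x - 1) / 2 + ring * np.cos(ang),
                (y - 1) / 2 + ring * np.sin(ang),
                (z - 1) / 2,
            )
        )
    for a in range(n):
        for b in range(a + 1, n):
            d = np.linalg.norm(np.subtract(centres[a], centres[b]))
            if d < 2 * cut:
                raise ValueError(
                    f"grid {shape} too small to host {n} disjoint networks"
                )
    ii, jj, kk = np.meshgrid(
        np.arange(x), np.arange(y), np.arange(z), indexing="ij"
    )
    maps = np.zeros((*shape, n))
    for j, (cx, cy, cz) in enumerate(centres):
        d2 = (ii - cx) ** 2 + (jj - cy) ** 2 + (kk - cz) ** 2
        blob = np.exp(-d2 / (2 * sigma**2))
        blob[d2 > cut**2] = 0.0
        maps[..., j] = blob * mask
    return maps


def _signal_timecourses(
    rng: np.random.Generator, t_frames: int, tr: float, cfg: SimulationConfig
) -> np.ndarray:
    """Sparse events convolved with the HRF, standardised per component.

    Networks share a common event stream with fixed alternating-sign
    loadings, so the cohort has a stable between-network (partial)
    correlation structure for netmat recovery to find — resting-state
    time courses are correlated, not independent.
    """
    hrf_t = np.arange(0, 30.0, tr)
    hrf = neonatal_hrf(
        hrf_t,
        cfg.hrf_peak_time_s,
        cfg.hrf_peak_amplitude,
        cfg.hrf_undershoot_depth,
        cfg.hrf_undershoot_time_s,
    )

    def stream() -> np.ndarray:
        events = rng.binomial(1, 0.06, size=t_frames) * rng.exponential(
            1.0, size=t_frames
        )
        conv = np.convolve(events, hrf)[:t_frames]
        if conv.std() == 0:  # pathologically short run with no events
            conv = hrf[:t_frames].copy()
        return conv - conv.mean()

    shared = stream()
    shared /= max(shared.std(), 1e-12)
    tcs = np.empty((t_frames, cfg.n_networks))
    for j in range(cfg.n_networks):
        loading = 0.7 if j % 2 == 0 else -0.7
        conv = stream() + loading * shared
        tcs[:, j] = conv / max(conv.std(), 1e-12)
    return tcs


def simulate_scan(config: SimulationConfig | None = None, **overrides) -> SyntheticScan:
    """Generate one fully ground-truthed synthetic scan.

    Keyword overrides are applied on top of ``config`` (or the default
    configuration), e.g. ``simulate_scan(seed=3, noise_sd=0.0)``.
    """
    cfg = config or SimulationConfig()
    if overrides:
        cfg = replace(cfg, **overrides)
    x, y, z, t = cfg.shape
    rng = np.random.default_rng(cfg.seed)
    mask, seg = _phantom((x, y, z))
    m3 = mask.data

    sig_maps = _network_maps((x, y, z), cfg.n_networks, m3) * cfg.signal_amplitude
    sig_tcs = _signal_timecourses(rng, t, cfg.tr, cfg)

    # --- noise factors (each an exact spatial-map x time-course pair) ---
    noise_maps: list[np.ndarray] = []
    noise_tcs: list[np.ndarray] = []

    time_s = np.arange(t) * cfg.tr
    if cfg.drift_amplitude > 0:
        # random phase and ramp sign: scanner drift differs per session
        phase = rng.uniform(0, 2 * np.pi)
        ramp_sign = rng.choice([-1.0, 1.0])
        drift_tc = np.sin(2 * np.pi * time_s / cfg.drift_period_s + phase) + (
            ramp_sign * (time_s / time_s[-1] - 0.5)
        )
        noise_maps.append(cfg.drift_amplitude * m3.astype(float))
        noise_tcs.append(drift_tc)

    spike_frames = np.sort(
        rng.choice(np.arange(2, t - 2), size=cfg.n_motion_spikes, replace=False)
    ) if cfg.n_motion_spikes else np.array([], dtype=int)
    spike_tc = np.zeros(t)
    spike_tc[spike_frames] = 1.0

    if cfg.stripe_amplitude > 0:
        pattern = np.zeros((x, y, z))
        pattern[:, :, :: 2 * cfg.stripe_period] = 1.0
        pattern[:, :, cfg.stripe_period :: 2 * cfg.stripe_period] = -1.0
        # random slice offset: where the interleave lands differs by scan
        pattern = np.roll(pattern, rng.integers(0, 2 * cfg.stripe_period), axis=2)
        stripe_map = cfg.stripe_amplitude * cfg.baseline * pattern * m3
        # low-level striping that fluctuates slowly throughout (spin
        # history varies continuously with posture) and intensifies at
        # spike frames
        wiggle = ndimage.gaussian_filter1d(rng.standard_normal(t), sigma=8.0)
        wiggle = 0.1 * wiggle / max(wiggle.std(), 1e-12)
        stripe_tc = np.clip(0.2 + wiggle, 0.0, None) + 0.8 * spike_tc
        noise_maps.append(stripe_map)
        noise_tcs.append(stripe_tc)

    eroded = ndimage.binary_erosion(m3)
    ring = m3 & ~eroded
    if cfg.n_motion_spikes and cfg.spike_magnitude_mm > 0:
        ring_map = 0.05 * cfg.baseline * cfg.spike_magnitude_mm * ring
        noise_maps.append(ring_map.astype(float))
        noise_tcs.append(spike_tc)

    # --- motion trace: smooth wander plus step discontinuities ---
    wander = ndimage.gaussian_filter1d(
        rng.standard_normal((t, 6)), sigma=10.0, axis=0
    )
    wander *= 0.02 / max(wander.std(), 1e-12)
    params = wander.copy()
    params[:, :3] *= 1.0 / 50.0  # keep wander comparable in arc terms
    for f in spike_frames:
        params[f, 3:] += cfg.spike_magnitude_mm
        params[f, :3] += cfg.spike_magnitude_mm / 50.0  # arc-equivalent @50mm
    motion = MotionTrace(params)

    # --- compose the 4D data ---
    data = np.zeros((x, y, z, t))
    data += (cfg.baseline * m3.astype(float))[..., None]
    flat_factors = [(sig_maps[..., j], sig_tcs[:, j]) for j in range(cfg.n_networks)]
    flat_factors += list(zip(noise_maps, noise_tcs))
    for smap, tc in flat_factors:
        data += smap[..., None] * tc[None, None, None, :]

    # spike image effect beyond the ring: 1-voxel in-plane shift,
    # consistent with the translation step in the trace
    for f in spike_frames:
        frame = data[..., f]
        data[..., f] = np.where(m3, np.roll(frame, 1, axis=0), frame)

    if cfg.noise_sd > 0:
        data += rng.normal(0.0, cfg.noise_sd, size=data.shape) * m3[..., None]

    k_sig, k_noise = cfg.n_networks, len(noise_maps)
    truth = ICDecomposition(
        np.concatenate(
            [sig_maps] + [nm[..., None] for nm in noise_maps], axis=3
        ) if k_noise else sig_maps,
        np.column_stack([sig_tcs] + noise_tcs) if k_noise else sig_tcs,
        [SIGNAL] * k_sig + [NOISE] * k_noise,
    )
    vol = Volume4D(data, (2.0, 2.0, 2.0), cfg.tr)
    return SyntheticScan(vol, truth, motion, spike_frames, seg, mask, cfg)


def simulate_sevol_series(
    stripe_amplitudes: list[float],
    pe_tags: list[str] | None = None,
    shape: tuple[int, int, int] = (24, 24, 16),
    noise_sd: float = 2.0,
    baseline: float = 1000.0,
    stripe_period: int = 1,
    seed: int = 0,
) -> tuple[list[Volume3D], list[str]]:
    """Spin-echo EPI volume series sharing anatomy, with per-volume
    alternating-slice striping of the given amplitudes (fractions of the
    local intensity).

    ``pe_tags`` defaults to the first half "AP" and the second half
    "PA". Volume ``i`` is multiplied by ``1 ± stripe_amplitudes[i]`` on
    alternating slice bands of width ``stripe_period``.
    """
    n = len(stripe_amplitudes)
    if n < 1:
        raise ValueError("need at least one volume")
    if any(a < 0 for a in stripe_amplitudes):
        raise ValueError("stripe amplitudes must be non-negative")
    if pe_tags is None:
        pe_tags = ["AP"] * (n - n // 2) + ["PA"] * (n // 2)
    if len(pe_tags) != n:
        raise ValueError("one phase-encode tag per volume required")
    rng = np.random.default_rng(seed)
    r = _ellipsoid_radius(shape)
    anatomy = baseline * np.clip(1.0 - 0.6 * r**2, 0.0, None)
    texture = ndimage.gaussian_filter(rng.standard_normal(shape), 1.5)
    anatomy = anatomy * (1.0 + 0.1 * texture)
    modulation = np.ones(shape[2])
    modulation[::2 * stripe_period] = 1.0
    half = np.zeros(shape[2], dtype=bool)
    for start in range(stripe_period, shape[2], 2 * stripe_period):
        half[start : start + stripe_period] = True
    vols = []
    for amp in stripe_amplitudes:
        factor = np.where(half, 1.0 - amp, 1.0 + amp)
        v = anatomy * factor[None, None, :]
        v = v + rng.normal(0.0, noise_sd, size=shape)
        vols.append(Volume3D(v, (2.0, 2.0, 2.0)))
    return vols, list(pe_tags)


def simulate_qc_cohort(
    n_scans: int = 30,
    seed: int = 0,
    corrupt_index: int | None = None,
    corrupt_metric: str = "mean_dvars",
    corrupt_factor: float = 10.0,
) -> list[QCRecord]:
    """Per-scan QC metric records for gate testing.

    The cohort emulates the two-subcohort composition of a
    developmental study — alternating preterm and term-equivalent
    scans — whose QC metrics sit in systematically offset, narrow
    age-group bands (head size, motion levels and tissue contrast all
    shift with age). Each clean metric is drawn uniformly within its
    scan's age-group band; the spread of a screened cohort is bounded,
    and the balanced bimodal mixture keeps the cohort MAD stable.
    ``corrupt_index`` optionally multiplies one scan's
    ``corrupt_metric`` by ``corrupt_factor`` (direction of worsening
    handled per metric).
    """
    # (preterm centre, term centre, within-group half-width)
    bands = {
        "mean_dvars": (27.0, 33.0, 1.2),
        "mean_tsnr": (40.0, 50.0, 2.0),
        "func_to_sbref_nmi": (1.22, 1.28, 0.012),
        "sbref_to_struct_nmi": (1.17, 1.23, 0.012),
        "struct_to_template_nmi": (1.15, 1.21, 0.012),
        "fieldmap_to_struct_nmi": (1.12, 1.18, 0.012),
    }
    assert set(bands) == set(GATE_METRICS)
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n_scans):
        term = i % 2  # balanced preterm/term alternation
        metrics = {}
        for m, (pre_c, term_c, w) in bands.items():
            c = term_c if term else pre_c
            metrics[m] = float(rng.uniform(c - w, c + w))
        records.append(QCRecord(f"scan{i:03d}", metrics))
    if corrupt_index is not None:
        rec = records[corrupt_index]
        if corrupt_metric == "mean_dvars":  # worse = larger
            rec.metrics[corrupt_metric] *= corrupt_factor
        else:  # worse = smaller
            rec.metrics[corrupt_metric] /= corrupt_factor
    return records
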