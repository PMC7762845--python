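# Methods

This note documents the models, conventions and numerical choices
behind `neoqc`, and what the synthetic-data study does and does not
establish.

## Conventions used everywhere

Axes are (X, Y, Z, T); voxel indices are 0-based; world coordinates
come only from the affine. Nothing in the toolkit resamples: paired
images must share a voxel grid exactly, and mismatches raise
`GridMismatchError` rather than broadcasting. Rotations are radians,
translations millimetres, TR seconds. Temporal standard deviations use
the sample form (divisor T−1) throughout; the one deliberate exception
is the z-smoothness score, which uses the population SD so that
single-pair and two-voxel slices remain well defined. Per-frame
difference series (FD, DVARS) are 0 at frame 0 and outlier rules use
strict inequalities, so a value exactly at threshold never flags.

Motion-parameter files are read with an explicit column-order tag
(rotations-first canonical, translations-first supported) and never
auto-detected: silently confusing radians with millimetres corrupts
every downstream metric, and the on-disk units of third-party traces
are not reliably discoverable. Noise-label files follow the hand-label
dialect in which the last non-empty line is a bracketed, 1-based,
comma-separated list of noise-component indices; everything above it is
comment.

## Motion metrics

FD is the **average** of the six absolute backward parameter
differences, with rotations converted to arc length at a configurable
head radius (default 50 mm, the literature convention; neonatal heads
are smaller, so the radius is surfaced, not hidden). A `sum` mode
reproduces the Power variant for cross-tool comparison, and a raw mode
skips the rotation conversion entirely. DVARS applies no intensity
normalisation; its adaptive threshold (P75 + 1.5·IQR of frames 1..T−1,
linear-interpolation quantiles) is therefore reproducible bit-for-bit
on any given series.

## z-smoothness and volume selection

The score is computed per adjacent slice pair as the SD of the
voxelwise slice difference over the mask intersection of the two
slices, then reduced across pairs. The `min` reduction is the default;
because a minimum is insensitive to isolated bad slices, selection
robustness properties use the `mean` reduction, and both are exposed.
Masked computation is the default with whole-slice as an option. The
operation only *ranks* volumes — no absolute "good enough" threshold is
defined, because none can be justified without reference data; reports
surface the scores for human review.

## High-pass filter

Slow drifts are removed by subtracting a Gaussian-weighted running-line
(local linear) fit from each voxel series and restoring the original
temporal mean exactly. The kernel SD is `cutoff_s/(2π·tr)` frames: the
sinusoid at the cutoff period then sits at the Gaussian's standard
frequency, which places the half-power point near the cutoff and gives
the expected behaviour on either side — measured empirically at
TR = 0.392 s with a 150 s cutoff, a 300 s-period sinusoid is attenuated
by ~88% while a 20 s period passes essentially untouched (<0.01%
attenuation). A wider kernel (e.g. the `cutoff/(2·tr)` convention some
tools use) leaves most of the energy a full octave below cutoff in
place, which defeats the filter's purpose here. The smoother matrix is
precomputed (T×T, truncated at ±4σ) so filtering is a single matrix
product over voxels. Nuisance regressors are *not* pre-filtered by the
toolkit; callers who filter the data should pass consistent regressors
(the built design uses the raw time courses, and the regression's
demeaning absorbs the mean discrepancy — a deliberate simplification
flagged here as an assumption).

## Nuisance regression

"Aggressive" mode is a per-voxel OLS of the demeaned series on the
demeaned design (noise-IC time courses + 6 motion parameters +
optional one-hot spike columns, FD/DVARS frames merged by union), with
the residual returned on the original mean. Demeaned columns are an
enforced invariant of the design container: idempotence and exact mean
preservation depend on it. "Nonaggressive" mode fits the joint
[signal, nuisance] design and subtracts only the nuisance partition's
contribution, preserving variance shared with the signal time courses —
the convention of classifier-based IC cleanup. The mode is always
explicit. Spike regressors are off by default, consistent with a
minimal-preprocessing philosophy. Rank-deficient designs fail with the
provenance tags of a minimal set of offending columns (greedy
elimination), so collinear regressors are nameable.

## Dual regression, netmats, similarity

Stage 1 regresses the spatially-and-temporally demeaned in-mask data on
the spatially demeaned group maps (a multiple regression across
voxels); the per-frame spatial demeaning makes the stage insensitive to
global intensity and gives an exactly zero residual in the noiseless
rank-K limit. Stage-1 time courses are variance-normalised by default
(configurable) before stage 2 and before netmats. Stage 2 is a
per-voxel temporal regression on the demeaned time courses. Partial
correlations come from the inverse covariance,
r_ij = −Ω_ij/√(Ω_ii·Ω_jj), unregularised by default (appropriate for
K ≪ T) with an optional ridge for small-T work; Fisher z uses atanh
with |r| clipped at 1−10⁻⁷. Netmat similarity is the Pearson
correlation of upper triangles and requires K ≥ 3 (fewer gives <2
off-diagonal pairs, an undefined correlation). CNR uses the stage-1
fit as the contrast (contrast = data − residual algebraically forces
this); a two-stage option exists. Voxels whose residual SD is below
10⁻⁹ of the data scale are flagged infinite-CNR and counted — an exact
zero test would never fire in floating point.

## Registration QC

NMI uses Studholme's normalised form (H(A)+H(B))/H(A,B), bounded in
[1, 2] with 2 at perfect dependence, so "more positive = more similar"
holds for the z-scored cohort view. Intensities are min–max scaled over
the mask into 64 equal-width bins by default (configurable); entropies
are in bits with 0·log 0 = 0; no Parzen smoothing, since QC needs
reproducibility more than registration-grade smoothness. Bin count and
entropy base are pinned in one place rather than inferred.

## Robust-z QC gate

Per metric, z = (x − median)/(1.4826·MAD), the 1.4826 consistency
constant making −2.5 interpretable on a σ-like scale; the constant is
pinned and printed in the HTML report. MAD = 0 yields z = 0 for all
(a constant cohort flags nobody). Directions: mean DVARS is
lower-better; mean tSNR and all NMI metrics are higher-better. A scan
fails if *any* gate metric is strictly below the threshold (−2.5
default); failures across several metrics count once (set union).
Reports are self-contained HTML (embedded base64 figures) with a
pinnable timestamp for byte-identical re-rendering.

## Voxplot

Per voxel the temporal mean and linear trend are removed; the **whole
heat-map** is then standardised to zero mean and unit SD (not each row —
global standardisation preserves relative artefact amplitude across
rows). Rows are ordered by tissue group (GM, WM, SC, CB, BS), within
group by anatomical raster order (arbitrary but stated), and
subsampling is even-stride so plots reproduce without a seed. A
detrended map whose SD is below 10⁻¹⁰ of the input scale is treated as
all-zero rather than amplifying rounding dust. The mapping from a
many-label segmentation to the five display groups is a configurable
table.

## Synthetic data: what it emulates, and what it does not

`simulate_scan` composes, additively on a concentric-shell head phantom
(GM shell, WM core, subcortical blob, cerebellum + brainstem lobes in
the lowest slices):

- **Network signal**: spatially disjoint Gaussian blobs (error if the
  grid cannot host them disjointly) times event streams convolved with
  a double-gamma HRF parameterised by peak time (7 s), peak amplitude,
  and undershoot depth (0.5 of peak at 16 s) — a neonatal-like shape
  (later, smaller peak, deeper undershoot than the adult canonical
  form). Exact infant HRF parameters are not standardised; these
  defaults are documented approximations, not claims. Networks share a
  common event stream with fixed ±0.7 loadings so the cohort has a
  stable between-network partial-correlation structure for netmat
  recovery to find.
- **Motion spikes**: step discontinuities applied to all six trace
  parameters (rotations scaled by 1/50 mm⁻¹ so the arc displacement
  matches), mirrored in the image as a 1-voxel in-plane shift plus a
  brain-edge intensity ring at the same frames. A spike of magnitude m
  therefore yields FD = m exactly, making the ≥0.5 mm detectability
  property hold by construction.
- **Slice striping**: an alternating-slice pattern (random per-scan
  offset) times an envelope that fluctuates slowly and intensifies at
  spike frames — spin history varies continuously with posture, and
  the fluctuation also keeps the envelope linearly independent of the
  spike indicator.
- **Slow drift**: sinusoid (300 s period, random phase) plus a ramp of
  random sign.
- **Gaussian noise** inside the mask.

Every additive artefact is recorded as an exact spatial-map ×
time-course factor labelled `noise` in the ground-truth decomposition,
so with the image-shift effect disabled the data equal
baseline + maps·timecourses exactly, and the true noise time courses
can serve as an oracle nuisance design. Default conditions are a
20×20×12 grid, 600 frames at TR 0.392 s (~235 s of data), four
networks at 2%-of-baseline amplitude, six 1 mm spikes, 3% striping, 1%
drift and noise SD 5 on a baseline of 1000. The run length matters: it
must be long relative to the smoothness scales of the drift and motion
wander, otherwise chance in-sample correlation between smooth nuisance
regressors and smooth signal makes aggressive regression remove real
signal — a genuine property of short runs, not an artefact of the
generator.

`simulate_qc_cohort` generates gate-metric records emulating the
two-subcohort composition of a developmental study: alternating
preterm and term-equivalent scans whose metrics occupy systematically
offset, narrow age-group bands (uniform within band). The balanced
bimodal mixture keeps the cohort MAD stable under small-n estimation —
every deviation from the cohort median is close to the mode
separation — so a screened clean cohort stays well inside the −2.5
gate while a corrupted scan is flagged unambiguously.

**Limits.** The generator contains no MR physics: no k-space, no
multiband reconstruction or inter-slice leakage model, no B0 field or
distortion, no physiological noise, and the striping model is a
qualitative stand-in whose realism is untested by design. Passing the
recovery suite therefore shows the *algorithms* behave correctly and
reproduce the expected directions of effect (denoising raises tSNR and
spatial/netmat similarity; cleanup of spike frames is soft, reducing
but not zeroing DVARS) on data whose ground truth is known — it does
not certify performance on real acquisitions, where artefact structure
is richer and signal amplitude lower.

## Evaluation protocol choices

The group netmat reference for the synthetic similarity study is the
Fisher-z average of the cohort's *ground-truth* netmats. With ground
truth available this is the correct reference; pooling pre- and
post-denoise subject netmats (the unbiasing device used when no truth
exists) is biased toward artefact structure at small n, because the
phantom's artefact geometry is shared across scans and their netmat
signatures correlate. Desk-scale problem sizes (10-seed recovery
cohorts, 50 selection draws, 20 gate cohorts of 30 scans) were chosen
as the package's default study conditions; all are configurable.
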