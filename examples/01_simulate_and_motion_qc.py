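"""Simulate a ground-truthed scan and compute its motion QC series.

Generates a synthetic resting-state scan with injected motion spikes,
then computes framewise displacement (FD) from the rigid-body trace and
DVARS from the image, and shows that the automatic outlier rules find
exactly the injected artefact frames.
"""

import numpy as np

from neoqc import (
    compute_dvars,
    compute_fd,
    dvars_outliers,
    fd_outliers,
    simulate_scan,
)

scan = simulate_scan(seed=7)
print(f"scan: {scan.volume.shape} voxels, TR {scan.volume.tr} s")
print(f"injected motion-spike frames: {[int(f) for f in scan.artefact_frames]}")

fd = compute_fd(scan.motion, head_radius=50.0)
dvars = compute_dvars(scan.volume, scan.mask)
print(f"mean FD    {fd.mean():.4f} mm  (spikes reach "
      f"{fd.values[scan.artefact_frames].max():.2f} mm)")
print(f"mean DVARS {dvars.mean():.2f} intensity units")

fd_flags = fd_outliers(fd)                 # fixed 0.25 mm rule
dvars_flags = dvars_outliers(dvars)        # adaptive P75 + 1.5 IQR rule
print(f"FD outlier frames:    {[int(f) for f in fd_flags.frames]}")
print(f"DVARS outlier frames: {[int(f) for f in dvars_flags.frames]} "
      f"(threshold {dvars_flags.threshold:.2f})")

covered = set(scan.artefact_frames) <= set(fd_flags.frames) | set(
    dvars_flags.frames
)
print(f"every injected spike caught by at least one rule: {covered}")
# The flagged sets include the frame after each spike too: both metrics
# are backward differences, so a one-frame displacement registers twice.
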