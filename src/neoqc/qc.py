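"""Automated cohort-level QC gating on robust z-scores.

Each scan contributes a handful of scalar metrics (mean denoised DVARS,
mean denoised tSNR and the NMI of each registration stage). Per metric,
the cohort is converted to z-scores using the median and the median
absolute deviation — robust to the very outliers the gate is looking
for — with the sign flipped where necessary so that more positive is
always better. A scan fails the gate if any gate metric scores below
the threshold (default −2.5), and a self-contained HTML report places
each scan inside its cohort distributions.
"""

from __future__ import annotations

import base64
import io as _io
import json
from dataclasses import dataclass, field
from pathlib import Path
from string import Template

import numpy as np
import pandas as pd

from .errors import DegenerateInputError

__all__ = [
    "GATE_METRICS",
    "METRIC_DIRECTIONS",
    "QCRecord",
    "QCGroupTable",
    "robust_z",
    "apply_gate",
    "render_report",
]

#: Consistency constant mapping MAD to the SD of a normal distribution,
#: so the −2.5 gate reads on a σ-like scale. Pinned, and surfaced in the
#: HTML report.
MAD_SCALE = 1.4826

GATE_THRESHOLD = -2.5

#: The gate metrics and whether larger raw values are better.
METRIC_DIRECTIONS = {
    "mean_dvars": "lower_better",
    "mean_tsnr": "higher_better",
    "func_to_sbref_nmi": "higher_better",
    "sbref_to_struct_nmi": "higher_better",
    "struct_to_template_nmi": "higher_better",
    "fieldmap_to_struct_nmi": "higher_better",
}
GATE_METRICS = tuple(METRIC_DIRECTIONS)


def robust_z(values: np.ndarray, direction: str = "higher_better") -> np.ndarray:
    """Median/MAD z-scores, sign-flipped so positive = better.

    z = (x − median) / (1.4826·MAD); if the MAD is zero (degenerate
    spread) every z is 0 rather than ±inf, so a constant cohort flags
    nobody.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        raise ValueError("values must be 1D")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 values for robust z")
    if not np.isfinite(x).all():
        raise ValueError("non-finite metric values")
    if direction not in ("higher_better", "lower_better"):
        raise ValueError(f"unknown direction {direction!r}")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.zeros_like(x)
    z = (x - med) / (MAD_SCALE * mad)
    return -z if direction == "lower_better" else z


@dataclass
class QCRecord:
    """Per-scan scalar QC metrics (native units)."""

    scan_id: str
    metrics: dict[str, float]

    def __post_init__(self) -> None:
        for m in GATE_METRICS:
            if m not in self.metrics:
                raise ValueError(f"scan {self.scan_id}: missing gate metric {m}")
            if not np.isfinite(self.metrics[m]):
                raise ValueError(f"scan {self.scan_id}: non-finite {m}")


@dataclass
class QCGroupTable:
    """A cohort of QC records plus (once gated) z-scores and flags."""

    records: list[QCRecord]
    z: pd.DataFrame | None = None
    failed_metrics: dict[str, set[str]] = field(default_factory=dict)
    threshold: float = GATE_THRESHOLD

    def __post_init__(self) -> None:
        ids = [r.scan_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate scan ids")

    @property
    def scan_ids(self) -> list[str]:
        return [r.scan_id for r in self.records]

    def metric_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [r.metrics for r in self.records], index=self.scan_ids
        )

    def failed_ids(self) -> list[str]:
        return [s for s in self.scan_ids if self.failed_metrics.get(s)]

    @property
    def n_failed(self) -> int:
        return len(self.failed_ids())


def apply_gate(table: QCGroupTable, threshold: float = GATE_THRESHOLD) -> QCGroupTable:
    """Compute robust z per gate metric and flag failing scans.

    A scan fails iff any gate metric's z is strictly below ``threshold``;
    the per-scan failed-metric set is the union over metrics, so a scan
    failing several metrics still counts once in the overall total.
    """
    df = table.metric_frame()
    z = pd.DataFrame(index=df.index, columns=list(GATE_METRICS), dtype=float)
    for metric in GATE_METRICS:
        z[metric] = robust_z(df[metric].to_numpy(), METRIC_DIRECTIONS[metric])
    failed: dict[str, set[str]] = {}
    for scan_id in df.index:
        bad = {m for m in GATE_METRICS if z.loc[scan_id, m] < threshold}
        failed[scan_id] = bad
    return QCGroupTable(table.records, z, failed, threshold)


# ---------------------------------------------------------------------------
# HTML reporting


_PAGE = Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>$title</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 60em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 0.3em 0.6em; text-align: right; }
.fail { background: #c0392b; color: white; padding: 0.5em 1em; }
.pass { background: #27ae60; color: white; padding: 0.5em 1em; }
.flagged { background: #f5b7b1; }
.note { color: #555; font-size: smaller; }
</style></head>
<body>
<h1>$title</h1>
$banner
$body
<p class="note">Robust z = (x − median) / (${mad_scale} · MAD), sign
flipped so positive is better; gate threshold z &lt; ${threshold}.
Generated by neoqc$timestamp.</p>
</body></html>
"""
)


def _fig_to_data_uri(fig) -> str:
    buf = _io.BytesIO()
    fig.savefig(buf, format="png", dpi=80, bbox_inches="tight",
                metadata={"Software": None})
    return "data:image/png;base64," + base64.b64encode(buf.getvalue()).decode()


def _distribution_figure(values: np.ndarray, own: float, metric: str):
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 2.2))
    ax.hist(values, bins=min(20, max(5, values.size // 2)), color="#85c1e9")
    ax.axvline(own, color="#c0392b", lw=2)
    ax.set_title(metric, fontsize=9)
    ax.tick_params(labelsize=7)
    fig.tight_layout()
    return fig


def render_report(
    table: QCGroupTable,
    out_dir: str | Path,
    scan_assets: dict[str, list[str]] | None = None,
    timestamp: str | None = None,
) -> list[Path]:
    """Write one self-contained HTML report per scan plus a cohort summary.

    ``scan_assets`` optionally maps scan id to image paths (voxplots,
    metric maps) to embed; missing paths are reported inline rather than
    raising. ``timestamp`` may be pinned (e.g. "") for byte-identical
    re-renders. Returns the written paths; a JSON sidecar with z-scores
    and flags is written alongside for programmatic use.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if table.z is None:
        raise ValueError("table has not been gated; call apply_gate first")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scan_assets = scan_assets or {}
    stamp = f" at {timestamp}" if timestamp else ""
    df = table.metric_frame()
    written: list[Path] = []

    for scan_id in table.scan_ids:
        bad = sorted(table.failed_metrics.get(scan_id, set()))
        if bad:
            banner = (
                f'<p class="fail">FAIL — metric(s) below threshold: '
                f'{", ".join(bad)}</p>'
            )
        else:
            banner = '<p class="pass">PASS — all gate metrics within range</p>'
        rows = []
        figs = []
        for metric in GATE_METRICS:
            zval = table.z.loc[scan_id, metric]
            cls = ' class="flagged"' if metric in bad else ""
            rows.append(
                f"<tr{cls}><td>{metric}</td>"
                f"<td>{df.loc[scan_id, metric]:.4g}</td>"
                f"<td>{zval:+.2f}</td></tr>"
            )
            fig = _distribution_figure(
                df[metric].to_numpy(), df.loc[scan_id, metric], metric
            )
            figs.append(f'<img src="{_fig_to_data_uri(fig)}"/>')
            plt.close(fig)
        assets = []
        for asset in scan_assets.get(scan_id, []):
            ap = Path(asset)
            if ap.exists():
                uri = "data:image/png;base64," + base64.b64encode(
                    ap.read_bytes()
                ).decode()
                assets.append(f'<img src="{uri}" style="max-width:100%"/>')
            else:
                assets.append(
                    f'<p class="note">missing asset: {ap}</p>'
                )
        body = (
            "<h2>Gate metrics</h2>"
            "<table><tr><th>metric</th><th>value</th><th>robust z</th></tr>"
            + "".join(rows)
            + "</table><h2>Cohort context</h2>"
            + "".join(figs)
            + ("<h2>Scan figures</h2>" + "".join(assets) if assets else "")
        )
        page = _PAGE.substitute(
            title=f"QC report — {scan_id}",
            banner=banner,
            body=body,
            mad_scale=MAD_SCALE,
            threshold=table.threshold,
            timestamp=stamp,
        )
        path = out / f"{scan_id}.html"
        path.write_text(page)
        written.append(path)

    failed = table.failed_ids()
    summary_rows = [
        f"<tr{' class=flagged' if s in failed else ''}><td>{s}</td>"
        + "".join(f"<td>{table.z.loc[s, m]:+.2f}</td>" for m in GATE_METRICS)
        + f"<td>{'FAIL' if s in failed else 'pass'}</td></tr>"
        for s in table.scan_ids
    ]
    summary = _PAGE.substitute(
        title="QC cohort summary",
        banner=(
            f"<p>{len(table.records) - len(failed)} of {len(table.records)} "
            f"scans pass; {len(failed)} flagged for inspection.</p>"
        ),
        body=(
            "<table><tr><th>scan</th>"
            + "".join(f"<th>{m}</th>" for m in GATE_METRICS)
            + "<th>status</th></tr>"
            + "".join(summary_rows)
            + "</table>"
        ),
        mad_scale=MAD_SCALE,
        threshold=table.threshold,
        timestamp=stamp,
    )
    summary_path = out / "summary.html"
    summary_path.write_text(summary)
    written.append(summary_path)

    sidecar = {
        "threshold": table.threshold,
        "mad_scale": MAD_SCALE,
        "z": {s: {m: table.z.loc[s, m] for m in GATE_METRICS}
              for s in table.scan_ids},
        "failed_metrics": {s: sorted(v) for s, v in table.failed_metrics.items()},
        "failed": failed,
    }
    (out / "qc.json").write_text(json.dumps(sidecar, indent=2))
    return written
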