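"""Rendering of average-profile plots and clustered heatmaps to PDF.

Each render also writes a small JSON manifest next to the PDF (row order,
color limits, axis limits) so that visual output can be verified without
image diffing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .cluster import ClusterResult
from .matrix import ProfileMatrix
from .stats import ProfileSummary, summarize

#: qualitative default palette for profile lines
DEFAULT_COLORS = [
    "#1f77b4", "#d62728", "#2ca02c", "#9467bd",
    "#ff7f0e", "#8c564b", "#e377c2", "#7f7f7f",
]
DEFAULT_GRADIENT = "Blues"  # white -> blue
MISSING_COLOR = "#d9d9d9"


@dataclass
class PlotSpec:
    """Appearance and output options shared by both plot kinds."""

    kind: str = "profile"
    title: str = ""
    x_label: str = "distance from anchor [bp]"
    y_label: str = "signal"
    y_min: float | None = None
    y_max: float | None = None
    color_map: list[str] | str | None = None
    error_band: str = "ci95"  # none | se | ci95
    heatmap_clip: tuple[float, float] = (0.01, 0.99)
    output: str = "plot.pdf"
    width: float = 6.0
    height: float = 4.5

    def __post_init__(self) -> None:
        if self.kind not in ("profile", "heatmap"):
            raise ValueError("kind must be 'profile' or 'heatmap'")
        if self.error_band not in ("none", "se", "ci95"):
            raise ValueError("error_band must be none, se or ci95")
        if self.y_min is not None and self.y_max is not None and not self.y_min < self.y_max:
            raise ValueError("require y_min < y_max")
        lo, hi = self.heatmap_clip
        if not 0 <= lo < hi <= 1:
            raise ValueError("heatmap_clip must satisfy 0 <= lo < hi <= 1")


def _write_manifest(pdf_path: Path, payload: dict) -> Path:
    man = pdf_path.with_suffix(pdf_path.suffix + ".manifest.json")
    with open(man, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
    return man


def pdf_page_count(path) -> int:
    """Page count of a PDF by object scan (enough for validity checks)."""
    data = Path(path).read_bytes()
    if not data.startswith(b"%PDF"):
        raise ValueError(f"{path} is not a PDF")
    return data.count(b"/Type /Page") - data.count(b"/Type /Pages")


def plot_profile(summaries: list[ProfileSummary], spec: PlotSpec) -> Path:
    """One line per summary, optional translucent error ribbon, PDF out."""
    if not summaries:
        raise ValueError("need at least one summary")
    offsets = summaries[0].bin_centers
    for s in summaries[1:]:
        if s.bin_centers.shape != offsets.shape or not np.allclose(
            s.bin_centers, offsets, equal_nan=True
        ):
            raise ValueError("summaries have mismatched bin offsets")
    colors = spec.color_map if isinstance(spec.color_map, list) else DEFAULT_COLORS
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    for i, s in enumerate(summaries):
        color = colors[i % len(colors)]
        ax.plot(s.bin_centers, s.mean, color=color, label=s.label, lw=1.5)
        if spec.error_band != "none":
            if spec.error_band == "ci95":
                lo, hi = s.ci_lo, s.ci_hi
            else:
                lo, hi = s.mean - s.se, s.mean + s.se
            ax.fill_between(s.bin_centers, lo, hi, color=color, alpha=0.25, lw=0)
    ax.axvline(0.0, color="0.4", ls="--", lw=0.8)
    ax.set_xlabel(spec.x_label)
    ax.set_ylabel(spec.y_label)
    if spec.title:
        ax.set_title(spec.title)
    ax.legend(frameon=False, fontsize=8)
    if spec.y_min is not None or spec.y_max is not None:
        ax.set_ylim(bottom=spec.y_min, top=spec.y_max)
    out = Path(spec.output)
    fig.savefig(out, format="pdf")
    payload = {
        "kind": "profile",
        "lines": [s.label for s in summaries],
        "error_band": spec.error_band,
        "xlim": list(ax.get_xlim()),
        "ylim": list(ax.get_ylim()),
    }
    plt.close(fig)
    _write_manifest(out, payload)
    return out


def plot_heatmap(
    matrices: list[ProfileMatrix],
    result: ClusterResult,
    spec: PlotSpec,
) -> Path:
    """One panel per matrix, rows in result.order for every panel.

    Horizontal separators mark cluster boundaries; each panel's color
    scale is clipped at the requested quantiles of that panel's
    non-missing values; missing cells render in a neutral grey.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    n_rows = matrices[0].n_features
    if result.order.shape[0] != n_rows:
        raise ValueError("cluster result rows do not match the matrices")
    for m in matrices:
        if m.n_features != n_rows:
            raise ValueError("matrices are not row-aligned")
    cmap_name = spec.color_map if isinstance(spec.color_map, str) else DEFAULT_GRADIENT
    cmap = plt.get_cmap(cmap_name).copy()
    cmap.set_bad(MISSING_COLOR)
    lo_q, hi_q = spec.heatmap_clip
    fig, axes = plt.subplots(
        1,
        len(matrices),
        figsize=(spec.width * len(matrices) / 2.0, spec.height),
        squeeze=False,
    )
    clims = []
    for ax, m in zip(axes[0], matrices):
        ordered = m.values[result.order]
        finite = ordered[~np.isnan(ordered)]
        if finite.size:
            vmin = float(np.quantile(finite, lo_q))
            vmax = float(np.quantile(finite, hi_q))
            if vmin == vmax:
                vmax = vmin + 1e-12
        else:
            vmin, vmax = 0.0, 1.0
        clims.append([vmin, vmax])
        masked = np.ma.masked_invalid(ordered)
        extent = [m.bin_centers[0], m.bin_centers[-1], n_rows, 0]
        im = ax.imshow(
            masked, aspect="auto", cmap=cmap, vmin=vmin, vmax=vmax,
            interpolation="nearest", extent=extent,
        )
        for b in result.boundaries:
            ax.axhline(b, color="black", lw=0.8)
        ax.set_title(m.signal_label, fontsize=9)
        ax.set_xlabel(spec.x_label, fontsize=8)
        fig.colorbar(im, ax=ax, shrink=0.7)
    # cluster id labels on the first panel
    ordered_labels = result.labels[result.order]
    starts = [0] + result.boundaries
    ends = result.boundaries + [n_rows]
    for s, e in zip(starts, ends):
        axes[0][0].text(
            -0.12,
            1 - (s + e) / (2 * n_rows),
            f"C{ordered_labels[s]}",
            transform=axes[0][0].transAxes,
            va="center",
            ha="right",
            fontsize=8,
        )
    if spec.title:
        fig.suptitle(spec.title)
    out = Path(spec.output)
    fig.savefig(out, format="pdf")
    plt.close(fig)
    row_ids = [matrices[0].feature_ids[int(i)] for i in result.order]
    _write_manifest(
        out,
        {
            "kind": "heatmap",
            "panels": [m.signal_label for m in matrices],
            "row_order": [int(i) for i in result.order],
            "row_ids": row_ids,
            "boundaries": [int(b) for b in result.boundaries],
            "clims": clims,
            "clip": list(spec.heatmap_clip),
        },
    )
    return out


def batch_render(
    pairs: list[tuple[str, str]],
    loader,
    out_dir,
    kind: str = "profile",
    spec: PlotSpec | None = None,
    cluster_result_for=None,
) -> list[Path]:
    """Render one PDF per (signal, feature) pair in the given order.

    `loader(signal, feature)` must return the cached ProfileMatrix and
    raise KeyError for an unknown pair (the error names the pair).
    Filenames follow "{signal}__{feature}__{kind}.pdf". For heatmaps an
    optional `cluster_result_for(matrix)` callback supplies the row order;
    by default rows are sorted by descending strength with no separators.
    """
    from .cluster import ClusterRequest, cluster_rows

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    template = spec or PlotSpec(kind=kind)
    produced = []
    for signal, feature in pairs:
        try:
            m = loader(signal, feature)
        except KeyError:
            raise KeyError(
                f"no cached matrix for pair ({signal!r}, {feature!r}); "
                "run precompute first"
            ) from None
        name = f"{signal}__{feature}__{kind}.pdf"
        pair_spec = PlotSpec(**{**template.__dict__, "kind": kind, "output": str(out_dir / name)})
        if kind == "profile":
            produced.append(plot_profile([summarize(m)], pair_spec))
        else:
            if cluster_result_for is not None:
                res = cluster_result_for(m)
            else:
                res = cluster_rows([m], ClusterRequest(method="none", sort_within=True))
            produced.append(plot_heatmap([m], res, pair_spec))
    return produced
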