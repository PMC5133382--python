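"""The matrix engine: feature-anchored binned signal matrices.

For every feature a window is laid out around an anchor point (the
feature's start, end or center, or stretched across the whole body), cut
into bins, and each bin filled with the length-weighted mean of the track's
per-base values. Minus-strand rows are computed over the mirrored genomic
window and reversed, so a given matrix column always means the same
biological offset: column order is 5'→3' with the anchor at offset 0
falling on the left edge of the first downstream bin.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import FeatureSet, GenomicInterval, SignalTrack

log = logging.getLogger("metaplots")

ANCHOR_MODES = ("start", "end", "center", "scaled")


@dataclass(frozen=True)
class AnchorSpec:
    """How per-feature windows are anchored and binned.

    mode
        ``start``/``end``/``center`` anchor at a single point;
        ``scaled`` stretches each feature body to ``body_bins``
        pseudo-bins with fixed-width flanks on both sides.
    upstream, downstream
        Flank lengths in bp (upstream is drawn at negative offsets).
    bin
        Bin width in bp for point windows and for scaled-mode flanks;
        fractional bins may occur at the outer window edges.
    body_bins
        Number of equal (possibly fractional-width) windows across the
        feature body in scaled mode.
    ignore_strand
        Treat every feature as plus-strand.
    """

    mode: str = "start"
    upstream: int = 1000
    downstream: int = 1500
    bin: int = 10
    body_bins: int = 100
    ignore_strand: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ANCHOR_MODES:
            raise ValueError(f"mode must be one of {ANCHOR_MODES}")
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("flank lengths must be >= 0")
        if self.bin < 1:
            raise ValueError("bin width must be >= 1")
        if self.mode == "scaled" and self.body_bins < 1:
            raise ValueError("body_bins must be >= 1")
        if self.mode != "scaled" and self.upstream + self.downstream <= 0:
            raise ValueError("point anchoring needs upstream + downstream > 0")

    @property
    def n_flank_bins(self) -> tuple[int, int]:
        return (
            math.ceil(self.upstream / self.bin),
            math.ceil(self.downstream / self.bin),
        )

    @property
    def n_bins(self) -> int:
        nu, nd = self.n_flank_bins
        return nu + nd + (self.body_bins if self.mode == "scaled" else 0)

    def fingerprint(self) -> str:
        """Stable hash of the anchoring parameters, for cache invalidation."""
        payload = json.dumps(
            {
                "mode": self.mode,
                "upstream": self.upstream,
                "downstream": self.downstream,
                "bin": self.bin,
                "body_bins": self.body_bins if self.mode == "scaled" else None,
                "ignore_strand": self.ignore_strand,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "upstream": self.upstream,
            "downstream": self.downstream,
            "bin": self.bin,
            "body_bins": self.body_bins,
            "ignore_strand": self.ignore_strand,
        }


@dataclass
class ProfileMatrix:
    """features x bins array of mean signal with anchoring metadata."""

    values: np.ndarray
    bin_centers: np.ndarray
    feature_ids: list[str]
    signal_label: str = ""
    feature_label: str = ""
    anchor: AnchorSpec = field(default_factory=AnchorSpec)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    def to_tsv(self, path) -> None:
        """Rows = features, columns = bin offsets."""
        df = pd.DataFrame(
            self.values,
            index=self.feature_ids,
            columns=[f"{c:g}" for c in self.bin_centers],
        )
        df.to_csv(path, sep="\t", index_label="feature")


def anchor_point(
    interval: GenomicInterval, mode: str, ignore_strand: bool = False
) -> int:
    """The genomic bp position of a feature's anchor.

    The biological start of a minus-strand feature is its right edge, so
    ``start`` and ``end`` reflect for strand '-' unless ignore_strand;
    ``center`` uses the floor midpoint (a deterministic tie-break for
    odd-length features) and never depends on strand.
    """
    if mode == "center":
        return (interval.start + interval.end) // 2
    flipped = interval.strand == "-" and not ignore_strand
    if mode == "start":
        return interval.end if flipped else interval.start
    if mode == "end":
        return interval.start if flipped else interval.end
    raise ValueError(f"anchor_point mode must be start/end/center, got {mode!r}")


def _flank_edges_left(anchor: float, flank: int, binw: int, n: int) -> list[float]:
    """Edges of `n` bins tiling [anchor-flank, anchor), outermost truncated."""
    return [anchor - min(flank, k * binw) for k in range(n, -1, -1)]


def _flank_edges_right(anchor: float, flank: int, binw: int, n: int) -> list[float]:
    """Edges of `n` bins tiling [anchor, anchor+flank), outermost truncated."""
    return [anchor + min(flank, k * binw) for k in range(0, n + 1)]


def _point_edges(anchor: int, anc: AnchorSpec, flipped: bool) -> np.ndarray:
    nu, nd = anc.n_flank_bins
    if flipped:
        left = _flank_edges_left(anchor, anc.downstream, anc.bin, nd)
        right = _flank_edges_right(anchor, anc.upstream, anc.bin, nu)
    else:
        left = _flank_edges_left(anchor, anc.upstream, anc.bin, nu)
        right = _flank_edges_right(anchor, anc.downstream, anc.bin, nd)
    return np.asarray(left[:-1] + right, dtype=float)


def _scaled_edges(iv: GenomicInterval, anc: AnchorSpec, flipped: bool) -> np.ndarray:
    nu, nd = anc.n_flank_bins
    length = iv.end - iv.start
    body = [iv.start + length * k / anc.body_bins for k in range(anc.body_bins + 1)]
    if flipped:
        left = _flank_edges_left(iv.start, anc.downstream, anc.bin, nd)
        right = _flank_edges_right(iv.end, anc.upstream, anc.bin, nu)
    else:
        left = _flank_edges_left(iv.start, anc.upstream, anc.bin, nu)
        right = _flank_edges_right(iv.end, anc.downstream, anc.bin, nd)
    return np.asarray(left[:-1] + body + right[1:], dtype=float)


def bin_centers_for(anchor: AnchorSpec) -> np.ndarray:
    """Biological bin-center offsets (bp; negative = upstream of the anchor).

    In scaled mode the body is drawn on a pseudo-axis where each body bin
    is `bin` bp wide: upstream flank at negative offsets, body spanning
    [0, body_bins*bin), downstream flank beyond.
    """
    nu, nd = anchor.n_flank_bins
    up_edges = np.asarray(_flank_edges_left(0.0, anchor.upstream, anchor.bin, nu))
    up_centers = (up_edges[:-1] + up_edges[1:]) / 2.0
    down_edges = np.asarray(
        _flank_edges_right(0.0, anchor.downstream, anchor.bin, nd)
    )
    down_centers = (down_edges[:-1] + down_edges[1:]) / 2.0
    if anchor.mode != "scaled":
        return np.concatenate([up_centers, down_centers])
    body_centers = (np.arange(anchor.body_bins) + 0.5) * anchor.bin
    return np.concatenate(
        [up_centers, body_centers, down_centers + anchor.body_bins * anchor.bin]
    )


def compute_matrix(
    features: FeatureSet,
    track: SignalTrack,
    anchor: AnchorSpec,
    signal_label: str = "",
    feature_label: str = "",
    use_summary: bool = True,
) -> ProfileMatrix:
    """The core computation: one row of binned mean signal per feature.

    Bins are filled with length-weighted per-base means; bases outside the
    chromosome or without data are missing (NaN, never zero — averages stay
    unbiased near chromosome ends), and a feature on a chromosome absent
    from the track yields a row of missing values plus a logged warning.
    """
    n_bins = anchor.n_bins
    out = np.full((len(features), n_bins), np.nan)
    for i, iv in enumerate(features):
        flipped = iv.strand == "-" and not anchor.ignore_strand
        if anchor.mode == "scaled":
            edges = _scaled_edges(iv, anchor, flipped)
        else:
            pt = anchor_point(iv, anchor.mode, anchor.ignore_strand)
            edges = _point_edges(pt, anchor, flipped)
        row = track.bin_means_edges(iv.chrom, edges, use_summary=use_summary)
        out[i] = row[::-1] if flipped else row
    return ProfileMatrix(
        values=out,
        bin_centers=bin_centers_for(anchor),
        feature_ids=features.ids(),
        signal_label=signal_label,
        feature_label=feature_label,
        anchor=anchor,
    )


def scale_body(per_base_values, body_bins: int) -> np.ndarray:
    """Compress/stretch a per-base vector to `body_bins` values.

    The index range [0, L) is cut into body_bins contiguous windows of
    (possibly fractional) width L/body_bins; each output is the
    length-weighted mean of the covered values, with missing bases excluded
    from numerator and denominator. A fully-missing window is NaN.
    """
    vals = np.asarray(per_base_values, dtype=float)
    if vals.ndim != 1 or vals.shape[0] < 1:
        raise ValueError("per_base_values must be a non-empty 1-D vector")
    if body_bins < 1:
        raise ValueError("body_bins must be >= 1")
    n = vals.shape[0]
    out = np.full(body_bins, np.nan)
    for k in range(body_bins):
        a = n * k / body_bins
        b = n * (k + 1) / body_bins
        i0 = int(math.floor(a))
        i1 = int(math.ceil(b))
        w = np.ones(i1 - i0)
        w[0] -= a - i0
        w[-1] -= i1 - b
        v = vals[i0:i1]
        ok = ~np.isnan(v)
        denom = w[ok].sum()
        if denom > 0:
            out[k] = float(np.dot(w[ok], v[ok])) / denom
    return out
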