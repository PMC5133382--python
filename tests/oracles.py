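"""Independent brute-force reference implementations used by the tests.

Everything here works directly on per-base value arrays with plain loops
and explicit window arithmetic — no summary levels, no shared code with
the package paths under test.
"""

from __future__ import annotations

import math

import numpy as np


def naive_range_mean(vals: np.ndarray, a: float, b: float) -> float:
    """Length-weighted mean of non-missing bases over [a, b), looped."""
    s = c = 0.0
    i0 = int(math.floor(max(a, 0.0)))
    i1 = int(math.ceil(min(b, float(len(vals)))))
    for i in range(i0, i1):
        w = min(b, i + 1) - max(a, i)
        if w > 0 and not math.isnan(vals[i]):
            s += w * vals[i]
            c += w
    return s / c if c > 0 else float("nan")


def naive_query_bins(vals: np.ndarray, start: float, end: float, nbins: int):
    out = []
    for i in range(nbins):
        a = start + (end - start) * i / nbins
        b = start + (end - start) * (i + 1) / nbins
        out.append(naive_range_mean(vals, a, b))
    return np.array(out)


def _point_bio_edges(up: int, down: int, binw: int) -> list[float]:
    """Biological-offset bin edges: anchor at 0 on a bin edge, bins of
    width binw tiling outward, outermost bins truncated at -up / +down."""
    nu = math.ceil(up / binw)
    nd = math.ceil(down / binw)
    edges = []
    for k in range(nu, 0, -1):
        edges.append(-float(min(up, k * binw)))
    edges.append(0.0)
    for k in range(1, nd + 1):
        edges.append(float(min(down, k * binw)))
    return edges


def naive_compute_matrix(features, track_values: dict, anchor) -> np.ndarray:
    """Per-base reference for compute_matrix, mapping each biological bin
    to its genomic range directly (no vector-reversal shortcut)."""
    rows = []
    for iv in features:
        flipped = iv.strand == "-" and not anchor.ignore_strand
        vals = track_values.get(iv.chrom)
        if anchor.mode == "scaled":
            row = _naive_scaled_row(iv, vals, anchor, flipped)
        else:
            if anchor.mode == "center":
                pt = (iv.start + iv.end) // 2
            elif anchor.mode == "start":
                pt = iv.end if flipped else iv.start
            else:
                pt = iv.start if flipped else iv.end
            edges = _point_bio_edges(anchor.upstream, anchor.downstream, anchor.bin)
            row = []
            for x0, x1 in zip(edges[:-1], edges[1:]):
                if vals is None:
                    row.append(float("nan"))
                elif flipped:
                    row.append(naive_range_mean(vals, pt - x1, pt - x0))
                else:
                    row.append(naive_range_mean(vals, pt + x0, pt + x1))
        rows.append(row)
    return np.array(rows, dtype=float)


def _naive_scaled_row(iv, vals, anchor, flipped):
    up_edges = _point_bio_edges(anchor.upstream, 0, anchor.bin) if anchor.upstream else [0.0]
    down_edges = _point_bio_edges(0, anchor.downstream, anchor.bin) if anchor.downstream else [0.0]
    length = iv.end - iv.start
    row = []
    if vals is None:
        n = (len(up_edges) - 1) + anchor.body_bins + (len(down_edges) - 1)
        return [float("nan")] * n
    # upstream flank: biological offsets relative to the 5' boundary
    for x0, x1 in zip(up_edges[:-1], up_edges[1:]):
        if flipped:  # 5' boundary of a minus feature is its genomic end
            row.append(naive_range_mean(vals, iv.end - x1, iv.end - x0))
        else:
            row.append(naive_range_mean(vals, iv.start + x0, iv.start + x1))
    # body: body_bins windows along the 5'->3' direction
    for k in range(anchor.body_bins):
        a = length * k / anchor.body_bins
        b = length * (k + 1) / anchor.body_bins
        if flipped:
            row.append(naive_range_mean(vals, iv.end - b, iv.end - a))
        else:
            row.append(naive_range_mean(vals, iv.start + a, iv.start + b))
    # downstream flank: offsets past the 3' boundary
    for x0, x1 in zip(down_edges[:-1], down_edges[1:]):
        if flipped:  # 3' boundary of a minus feature is its genomic start
            row.append(naive_range_mean(vals, iv.start - x1, iv.start - x0))
        else:
            row.append(naive_range_mean(vals, iv.end + x0, iv.end + x1))
    return row


# ---------------------------------------------------------------------------
# motifs

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "R": "Y", "Y": "R", "S": "S",
         "W": "W", "K": "M", "M": "K", "B": "V", "V": "B", "D": "H", "H": "D",
         "N": "N"}


def naive_scan(sequence: str, pattern: str, both_strands: bool) -> list[int]:
    """Positions where the pattern (or its reverse complement) matches,
    by direct character comparison at every offset."""

    def matches_at(seq, pat, i):
        if i + len(pat) > len(seq):
            return False
        return all(seq[i + j] in _IUPAC[pat[j]] for j in range(len(pat)))

    seq = sequence.upper()
    pats = [pattern.upper()]
    if both_strands:
        pats.append("".join(_COMP[c] for c in reversed(pattern.upper())))
    out = []
    for pat in pats:
        for i in range(len(seq)):
            if matches_at(seq, pat, i):
                out.append(i)
    return sorted(out)


def naive_density_at(starts: list[int], seq_len: int, pos: int, window: int,
                     per_kb: bool) -> float:
    """Match-start count in the (truncated) window centered on pos."""
    half = (window - 1) // 2
    lo = max(pos - half, 0)
    hi = min(pos + half + 1, seq_len)
    count = sum(1 for s in starts if lo <= s < hi)
    if per_kb:
        return count * 1000.0 / (hi - lo)
    return float(count)
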