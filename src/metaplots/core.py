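"""Core data model: genomic intervals, feature sets and queryable signal tracks.

Coordinates are uniformly 0-based half-open throughout the package; format
readers convert at parse time. Missing signal is an explicit marker (NaN),
distinct from a measured value of 0.0 — the two average differently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("metaplots")

VALID_STRANDS = frozenset({"+", "-", "."})

#: Explicit missing-data marker used in all value arrays.
MISSING = float("nan")


@dataclass(frozen=True)
class GenomicInterval:
    """A strand-aware interval in 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: str = ""
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of +, -, . (got {self.strand!r})")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class FeatureSet:
    """An ordered collection of genomic intervals.

    Row order is preserved exactly as read: heatmap rows are identified by
    their position in this list. Duplicate intervals are permitted.
    """

    intervals: list[GenomicInterval]
    source_path: str = ""
    genome_label: str = ""

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self):
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def subset(self, indices) -> "FeatureSet":
        return FeatureSet(
            [self.intervals[i] for i in indices],
            source_path=self.source_path,
            genome_label=self.genome_label,
        )

    def ids(self) -> list[str]:
        """Row labels: feature name if present, else chrom:start-end."""
        return [
            iv.name if iv.name else f"{iv.chrom}:{iv.start}-{iv.end}"
            for iv in self.intervals
        ]


def _block_reduce(values: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """NaN-aware (sum, count) of consecutive blocks of `width` bases."""
    n = values.shape[0]
    nblocks = -(-n // width)
    pad = nblocks * width - n
    v = values
    if pad:
        v = np.concatenate([values, np.full(pad, np.nan)])
    v = v.reshape(nblocks, width)
    ok = ~np.isnan(v)
    sums = np.where(ok, v, 0.0).sum(axis=1)
    counts = ok.sum(axis=1).astype(float)
    return sums, counts


class SignalTrack:
    """Per-base numeric coverage with multi-level binned summaries.

    Values are stored as one float64 array per chromosome; NaN marks bases
    with no data. Summary levels hold NaN-aware (sum, count) pairs for
    blocks at power-of-two zoom widths, mirroring the multi-resolution
    query strategy of indexed binary track formats: a windowed-mean query
    resolves full blocks from the coarsest usable level and only the
    fractional edges at base resolution, so zoomed-out queries stay cheap
    while agreeing with the base-level computation.
    """

    def __init__(self, values: dict[str, np.ndarray], source_format: str = "memory"):
        if not values:
            raise ValueError("track has no chromosomes")
        self.values: dict[str, np.ndarray] = {
            c: np.asarray(v, dtype=np.float64) for c, v in values.items()
        }
        self.chrom_sizes: dict[str, int] = {
            c: int(v.shape[0]) for c, v in self.values.items()
        }
        self.source_format = source_format
        self.summary_levels: dict[str, list[tuple[int, np.ndarray, np.ndarray]]] = {}
        self._build_summary_levels()
        self._warned_chroms: set[str] = set()

    def _build_summary_levels(self) -> None:
        for chrom, vals in self.values.items():
            levels = []
            width = 2
            while width < vals.shape[0]:
                sums, counts = _block_reduce(vals, width)
                levels.append((width, sums, counts))
                width *= 2
            self.summary_levels[chrom] = levels

    # -- queries ---------------------------------------------------------

    def per_base(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Raw per-base values over [start, end); out-of-bounds bases are NaN."""
        out = np.full(end - start, np.nan)
        if chrom not in self.values:
            self._warn_unknown(chrom)
            return out
        vals = self.values[chrom]
        lo = max(start, 0)
        hi = min(end, vals.shape[0])
        if hi > lo:
            out[lo - start : hi - start] = vals[lo:hi]
        return out

    def _warn_unknown(self, chrom: str) -> None:
        if chrom not in self._warned_chroms:
            self._warned_chroms.add(chrom)
            log.warning(
                "chromosome %r not in track (%s); returning missing values",
                chrom,
                ", ".join(sorted(self.chrom_sizes)),
            )

    def _pick_level(self, chrom: str, bin_width: float):
        """Coarsest level whose block width is <= half the bin width."""
        chosen = None
        for width, sums, counts in self.summary_levels.get(chrom, []):
            if width <= bin_width / 2.0:
                chosen = (width, sums, counts)
            else:
                break
        return chosen

    def _base_sum_count(self, vals: np.ndarray, a: float, b: float):
        """Length-weighted (sum, count) of non-missing bases over [a, b)."""
        a = max(a, 0.0)
        b = min(b, float(vals.shape[0]))
        if b <= a:
            return 0.0, 0.0
        i0 = int(math.floor(a))
        i1 = int(math.ceil(b))
        w = np.ones(i1 - i0)
        w[0] -= a - i0
        w[-1] -= i1 - b
        v = vals[i0:i1]
        ok = ~np.isnan(v)
        return float(np.dot(w[ok], v[ok])), float(w[ok].sum())

    def _range_sum_count(self, chrom: str, a: float, b: float, level):
        """(sum, count) over [a, b), using a summary level for full blocks."""
        vals = self.values[chrom]
        if level is None:
            return self._base_sum_count(vals, a, b)
        width, sums, counts = level
        lo = max(a, 0.0)
        hi = min(b, float(vals.shape[0]))
        if hi <= lo:
            return 0.0, 0.0
        j0 = int(math.ceil(lo / width))
        j1 = int(math.floor(hi / width))
        if j1 <= j0:
            return self._base_sum_count(vals, lo, hi)
        s_left, c_left = self._base_sum_count(vals, lo, j0 * width)
        s_right, c_right = self._base_sum_count(vals, j1 * width, hi)
        s_mid = float(sums[j0:j1].sum())
        c_mid = float(counts[j0:j1].sum())
        return s_left + s_mid + s_right, c_left + c_mid + c_right

    def bin_means_edges(
        self, chrom: str, edges, use_summary: bool = True
    ) -> np.ndarray:
        """Length-weighted mean per bin for consecutive edge pairs.

        Fractional edges are allowed; missing bases are excluded from both
        numerator and denominator, and a fully-missing bin is NaN.
        """
        edges = np.asarray(edges, dtype=float)
        nbins = edges.shape[0] - 1
        out = np.full(nbins, np.nan)
        if chrom not in self.values:
            self._warn_unknown(chrom)
            return out
        for i in range(nbins):
            a, b = edges[i], edges[i + 1]
            level = self._pick_level(chrom, b - a) if use_summary else None
            s, c = self._range_sum_count(chrom, a, b, level)
            if c > 0.0:
                out[i] = s / c
        return out


def query_bins(
    track: SignalTrack,
    chrom: str,
    start: float,
    end: float,
    nbins: int,
    use_summary: bool = True,
) -> np.ndarray:
    """Mean signal in `nbins` equal sub-ranges of [start, end).

    Bins partition the range as evenly as possible; fractional boundaries
    are resolved by length-weighted means. Bases outside the chromosome or
    without data count as missing; an entirely-missing bin is NaN. An
    unknown chromosome yields all-NaN bins plus a logged warning (feature
    files may reference scaffolds absent from a track).
    """
    if not end > start:
        raise ValueError("require start < end")
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    edges = start + (end - start) * np.arange(nbins + 1) / nbins
    return track.bin_means_edges(chrom, edges, use_summary=use_summary)
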