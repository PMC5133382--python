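"""Motif density tracks: scan a genome for an IUPAC pattern and turn the
occurrence counts into a coverage-like SignalTrack.

The value at base i is the number of match start positions inside a sliding
window centered on i, optionally normalized to occurrences per kb. Windows
truncated at chromosome ends use the truncated width as the per-kb
denominator. With both_strands, reverse-complement matches are reported at
their leftmost base and simply added — a palindromic pattern (e.g. CG)
therefore counts double, which is predictable and documented rather than
special-cased.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .core import SignalTrack

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(pattern: str) -> str:
    return pattern.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifSpec:
    """An IUPAC nucleotide pattern plus window/strand/normalization options.

    An even window width is rounded up to the next odd value so the window
    is symmetric around its center base.
    """

    pattern: str
    window: int = 200
    both_strands: bool = True
    per_kb: bool = True

    def __post_init__(self) -> None:
        pat = self.pattern.upper()
        object.__setattr__(self, "pattern", pat)
        if not pat:
            raise ValueError("motif pattern must be non-empty")
        bad = set(pat) - set(IUPAC)
        if bad:
            raise ValueError(
                f"invalid IUPAC letter(s) {sorted(bad)} in pattern {pat!r}"
            )
        w = int(self.window)
        if w % 2 == 0:
            w += 1
        object.__setattr__(self, "window", w)
        if w < len(pat):
            raise ValueError("window must be at least the pattern length")


def _pattern_regex(pattern: str) -> re.Pattern:
    # N in the sequence matches nothing: character classes only contain
    # ACGT, so assembly-gap Ns never create phantom matches.
    return re.compile("(?=" + "".join(f"[{IUPAC[c]}]" for c in pattern) + ")")


def scan_occurrences(sequence: str, spec: MotifSpec) -> list[int]:
    """All 0-based match start positions, overlapping matches included.

    With both_strands, positions where the reverse complement of the
    pattern matches are appended (at the match's leftmost base); the result
    is sorted and may contain duplicates for palindromic patterns.
    """
    seq = sequence.upper()
    positions = [m.start() for m in _pattern_regex(spec.pattern).finditer(seq)]
    if spec.both_strands:
        rc = reverse_complement(spec.pattern)
        positions += [m.start() for m in _pattern_regex(rc).finditer(seq)]
    positions.sort()
    return positions


def _density(counts: np.ndarray, spec: MotifSpec) -> np.ndarray:
    """Sliding-window sum of match-start counts, centered, edge-truncated."""
    n = counts.shape[0]
    half = (spec.window - 1) // 2
    csum = np.concatenate([[0.0], np.cumsum(counts)])
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    window_counts = csum[hi] - csum[lo]
    if spec.per_kb:
        return window_counts * (1000.0 / (hi - lo))
    return window_counts


def build_motif_track(genome, spec: MotifSpec) -> SignalTrack:
    """Genome-wide motif density from a FASTA file (path) or a dict of
    chromosome name -> sequence string."""
    if isinstance(genome, (str, Path)):
        sequences = {
            rec.id: str(rec.seq) for rec in SeqIO.parse(str(genome), "fasta")
        }
    else:
        sequences = dict(genome)
    if not sequences:
        raise ValueError("empty genome: no sequences found")
    values = {}
    for chrom, seq in sequences.items():
        counts = np.zeros(len(seq))
        starts = scan_occurrences(seq, spec)
        if starts:
            np.add.at(counts, np.asarray(starts), 1.0)
        values[chrom] = _density(counts, spec)
    return SignalTrack(values, source_format="motif")
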