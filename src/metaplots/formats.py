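"""Readers and writers for the accepted feature and signal track formats.

Feature formats: BED (0-based half-open, taken as-is) and GFF/GTF (1-based
inclusive, converted by start-1 at parse time). Signal formats: bigWig,
wiggle (fixedStep/variableStep), bedGraph and BAM/SAM alignments (converted
to coverage counting every aligned read's reference span). All formats land
on the same in-memory :class:`~metaplots.core.SignalTrack` model, and any
track can be written back out as an indexed bigWig.
"""

from __future__ import annotations

import logging
import math
import re
from pathlib import Path

import numpy as np
import pyBigWig
import pysam

from .core import FeatureSet, GenomicInterval, SignalTrack

log = logging.getLogger("metaplots")

FEATURE_EXTENSIONS = {".bed": "bed", ".gff": "gff", ".gff3": "gff", ".gtf": "gtf"}
SIGNAL_EXTENSIONS = {
    ".bw": "bigwig",
    ".bigwig": "bigwig",
    ".wig": "wig",
    ".bdg": "bedgraph",
    ".bedgraph": "bedgraph",
    ".bam": "bam",
    ".sam": "bam",
}


class ParseError(ValueError):
    """Malformed input file; message names the offending line."""


def _detect(path: Path, table: dict, what: str) -> str:
    fmt = table.get(path.suffix.lower())
    if fmt is None:
        accepted = ", ".join(sorted(table))
        raise ParseError(
            f"cannot infer {what} format from extension {path.suffix!r}; "
            f"accepted extensions: {accepted}"
        )
    return fmt


def _is_header(line: str) -> bool:
    s = line.strip()
    return (
        not s
        or s.startswith("#")
        or s.startswith("track")
        or s.startswith("browser")
    )


# ---------------------------------------------------------------------------
# feature files


_GFF_NAME_RE = re.compile(r'(?:ID=([^;]+)|gene_id\s+"([^"]+)")')


def read_features(path, format: str = "auto") -> FeatureSet:
    """Parse a BED/GFF/GTF file into a FeatureSet, preserving row order."""
    path = Path(path)
    fmt = format if format != "auto" else _detect(path, FEATURE_EXTENSIONS, "feature")
    if fmt not in ("bed", "gff", "gtf"):
        raise ParseError(f"unknown feature format {fmt!r}")
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_header(line):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if fmt == "bed":
                    iv = _parse_bed_fields(fields)
                else:
                    iv = _parse_gff_fields(fields)
            except (ValueError, IndexError) as exc:
                raise ParseError(f"{path.name}: malformed line {lineno}: {exc}") from exc
            intervals.append(iv)
    return FeatureSet(intervals, source_path=str(path))


def _parse_bed_fields(fields) -> GenomicInterval:
    if len(fields) < 3:
        raise ValueError("BED needs at least 3 tab-separated columns")
    chrom, start, end = fields[0], int(fields[1]), int(fields[2])
    name = fields[3] if len(fields) > 3 else ""
    if name == ".":  # conventional placeholder for "no name"
        name = ""
    strand = fields[5] if len(fields) > 5 else "."
    if strand not in ("+", "-"):
        strand = "."
    return GenomicInterval(chrom, start, end, name=name, strand=strand)


def _parse_gff_fields(fields) -> GenomicInterval:
    if len(fields) < 8:
        raise ValueError("GFF/GTF needs at least 8 tab-separated columns")
    chrom = fields[0]
    start = int(fields[3]) - 1  # 1-based inclusive -> 0-based half-open
    end = int(fields[4])
    strand = fields[6] if fields[6] in ("+", "-") else "."
    name = ""
    if len(fields) > 8:
        m = _GFF_NAME_RE.search(fields[8])
        if m:
            name = m.group(1) or m.group(2)
    return GenomicInterval(chrom, start, end, name=name, strand=strand)


def write_bed(features: FeatureSet, path) -> Path:
    """Write a 6-column BED file (score column fixed at 0)."""
    path = Path(path)
    with open(path, "w") as fh:
        for iv in features:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n"
            )
    return path


# ---------------------------------------------------------------------------
# signal files


def read_signal(path, format: str = "auto", chrom_sizes: dict | None = None) -> SignalTrack:
    """Read a signal track (bigWig / wiggle / bedGraph / BAM) into memory.

    `chrom_sizes` may extend chromosomes beyond the covered extent for text
    formats that do not declare sizes (wiggle, bedGraph); by default the
    size of each chromosome is the maximal covered end.
    """
    path = Path(path)
    fmt = format if format != "auto" else _detect(path, SIGNAL_EXTENSIONS, "signal")
    if fmt == "bigwig":
        return _read_bigwig(path)
    if fmt == "wig":
        return _read_wiggle(path, chrom_sizes)
    if fmt == "bedgraph":
        return _read_bedgraph(path, chrom_sizes)
    if fmt == "bam":
        return _read_bam(path)
    raise ParseError(f"unknown signal format {fmt!r}")


def _read_bigwig(path: Path) -> SignalTrack:
    bw = pyBigWig.open(str(path))
    try:
        values = {}
        for chrom, size in bw.chroms().items():
            values[chrom] = np.asarray(
                bw.values(chrom, 0, size, numpy=True), dtype=np.float64
            )
        return SignalTrack(values, source_format="bigwig")
    finally:
        bw.close()


def _alloc(values: dict, covered: dict, chrom: str, end: int, chrom_sizes: dict | None):
    """Buffer for writes up to `end`; grows geometrically (amortized O(n))."""
    covered[chrom] = max(covered.get(chrom, 0), end)
    size = end
    if chrom_sizes and chrom in chrom_sizes:
        size = max(size, chrom_sizes[chrom])
    if chrom not in values:
        values[chrom] = np.full(max(size, 1024), np.nan)
    elif values[chrom].shape[0] < size:
        old = values[chrom]
        values[chrom] = np.full(max(size, 2 * old.shape[0]), np.nan)
        values[chrom][: old.shape[0]] = old
    return values[chrom]


def _trim(values: dict, covered: dict, chrom_sizes: dict | None) -> dict:
    """Cut growth slack back to the covered extent / declared sizes."""
    out = {}
    for chrom, arr in values.items():
        size = covered.get(chrom, arr.shape[0])
        if chrom_sizes and chrom in chrom_sizes:
            size = max(size, chrom_sizes[chrom])
        out[chrom] = arr[:size] if arr.shape[0] > size else arr
    return out


def _read_wiggle(path: Path, chrom_sizes: dict | None) -> SignalTrack:
    values: dict[str, np.ndarray] = {}
    covered: dict[str, int] = {}
    mode = None  # ("fixed", chrom, next_start0, step, span) / ("variable", chrom, span)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("track") or s.startswith("browser"):
                continue
            if s.startswith("fixedStep") or s.startswith("variableStep"):
                try:
                    kv = dict(tok.split("=", 1) for tok in s.split()[1:])
                    chrom = kv["chrom"]
                    span = int(kv.get("span", 1))
                    if s.startswith("fixedStep"):
                        start0 = int(kv["start"]) - 1
                        step = int(kv.get("step", 1))
                        if start0 < 0 or step < 1 or span < 1 or span > step:
                            raise ValueError("inconsistent start/step/span")
                        mode = ["fixed", chrom, start0, step, span]
                    else:
                        if span < 1:
                            raise ValueError("span must be >= 1")
                        mode = ["variable", chrom, span]
                except (KeyError, ValueError) as exc:
                    raise ParseError(
                        f"{path.name}: bad wiggle declaration, line {lineno}: {exc}"
                    ) from exc
                continue
            if mode is None:
                raise ParseError(
                    f"{path.name}: data before any step declaration, line {lineno}"
                )
            try:
                if mode[0] == "fixed":
                    _, chrom, start0, step, span = mode
                    val = float(s)
                    arr = _alloc(values, covered, chrom, start0 + span, chrom_sizes)
                    arr[start0 : start0 + span] = val
                    mode[2] = start0 + step
                else:
                    _, chrom, span = mode
                    pos_s, val_s = s.split()
                    pos0 = int(pos_s) - 1
                    if pos0 < 0:
                        raise ValueError("position must be >= 1")
                    arr = _alloc(values, covered, chrom, pos0 + span, chrom_sizes)
                    arr[pos0 : pos0 + span] = float(val_s)
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}: malformed wiggle data, line {lineno}: {exc}"
                ) from exc
    if not values:
        raise ParseError(f"{path.name}: no data records")
    return SignalTrack(_trim(values, covered, chrom_sizes), source_format="wig")


def _read_bedgraph(path: Path, chrom_sizes: dict | None) -> SignalTrack:
    records: dict[str, list[tuple[int, int, float, int]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if _is_header(line):
                continue
            fields = line.split()
            try:
                if len(fields) < 4:
                    raise ValueError("bedGraph needs 4 columns")
                chrom, start, end, val = (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    float(fields[3]),
                )
                if not 0 <= start < end:
                    raise ValueError(f"bad interval [{start}, {end})")
            except ValueError as exc:
                raise ParseError(
                    f"{path.name}: malformed bedGraph line {lineno}: {exc}"
                ) from exc
            records.setdefault(chrom, []).append((start, end, val, lineno))
    if not records:
        raise ParseError(f"{path.name}: no data records")
    values: dict[str, np.ndarray] = {}
    covered: dict[str, int] = {}
    for chrom, recs in records.items():
        recs.sort(key=lambda r: (r[0], r[1]))
        prev_end, prev_line = -1, -1
        for start, end, _, lineno in recs:
            if start < prev_end:
                raise ParseError(
                    f"{path.name}: overlapping bedGraph intervals on {chrom} "
                    f"(lines {prev_line} and {lineno}): the value at a base "
                    "would be ambiguous"
                )
            prev_end, prev_line = end, lineno
        arr = _alloc(values, covered, chrom, max(r[1] for r in recs), chrom_sizes)
        for start, end, val, _ in recs:
            arr[start:end] = val
    return SignalTrack(_trim(values, covered, chrom_sizes), source_format="bedgraph")


def _read_bam(path: Path) -> SignalTrack:
    """Coverage from alignments: every aligned read's reference span counts.

    No MAPQ filter, no deduplication, no fragment extension; secondary and
    duplicate alignments are included. Uncovered bases on header-declared
    chromosomes are explicit zeros (coverage is defined genome-wide).
    An index is not required: the file is scanned sequentially.
    """
    mode = "r" if path.suffix.lower() == ".sam" else "rb"
    with pysam.AlignmentFile(str(path), mode) as af:
        values = {
            name: np.zeros(length)
            for name, length in zip(af.references, af.lengths)
        }
        for read in af.fetch(until_eof=True):
            if read.is_unmapped:
                continue
            arr = values[read.reference_name]
            start = max(read.reference_start, 0)
            end = min(read.reference_end, arr.shape[0])
            if end > start:
                arr[start:end] += 1.0
    if not values:
        raise ParseError(f"{path.name}: no reference sequences in header")
    return SignalTrack(values, source_format="bam")


# ---------------------------------------------------------------------------
# bigWig output


def _runs(vals: np.ndarray):
    """Yield (start, end, value) runs of equal, non-missing values."""
    n = vals.shape[0]
    ok = ~np.isnan(vals)
    if not ok.any():
        return
    # boundaries where the defined-ness or the value changes
    change = np.ones(n, dtype=bool)
    same = (vals[1:] == vals[:-1]) | (np.isnan(vals[1:]) & np.isnan(vals[:-1]))
    change[1:] = ~same
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        if ok[s]:
            yield int(s), int(e), float(vals[s])


def convert_to_indexed(track: SignalTrack, out_path) -> Path:
    """Write the track as a standard bigWig file.

    Missing (NaN) bases are written as gaps, so a round trip through
    :func:`read_signal` reproduces both the values and the missingness.
    """
    out_path = Path(out_path)
    header = sorted(track.chrom_sizes.items())
    for chrom in track.values:
        if chrom not in track.chrom_sizes:
            raise ValueError(f"chromosome {chrom!r} has data but no declared size")
    bw = pyBigWig.open(str(out_path), "w")
    try:
        bw.addHeader(header)
        for chrom, _ in header:
            starts, ends, vals = [], [], []
            for s, e, v in _runs(track.values[chrom]):
                starts.append(s)
                ends.append(e)
                vals.append(v)
            if starts:
                bw.addEntries(
                    [chrom] * len(starts), starts, ends=ends, values=vals
                )
    finally:
        bw.close()
    return out_path
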