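"""Deterministic synthetic genomes, tracks and feature files.

This module emulates the study conditions of a typical chromatin
metaplot analysis: protein-coding TSSs split into five expression classes,
a promoter-mark track peaking just downstream of the TSS (H3K4me3-like), a
variant-histone track flanking the TSS on both sides (H2A.Z-like), and a
gene-body elongation mark (H3K36me3-like) whose per-gene pattern is
planted as one of three hidden subtypes — bidirectional, unidirectional or
absent body signal — that clustering should recover. A random genome
sequence supplies material for dinucleotide-density tracks.

Everything is seeded: the same seed yields byte-identical files. Tracks
are written as fixedStep wiggle so the text-to-indexed conversion path is
exercised by every consumer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import FeatureSet, GenomicInterval

BODY_SUBTYPES = ("bidirectional", "unidirectional", "absent")

#: body-block height; bidirectional covers the whole window, so mean
#: strengths order bidirectional > unidirectional > absent.
BODY_HEIGHT = 3.0


@dataclass
class Scenario:
    """File paths and ground truth of one generated dataset."""

    root: Path
    seed: int
    genome_fasta: Path
    class_beds: dict[str, Path]
    all_bed: Path
    signal_wigs: dict[str, Path]
    features: FeatureSet
    class_labels: list[str]
    body_subtypes: list[str]
    chrom_sizes: dict[str, int]

    def subtype_indices(self, subtype: str) -> list[int]:
        return [i for i, s in enumerate(self.body_subtypes) if s == subtype]


def _write_fasta(path: Path, sequences: dict[str, str], width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _write_fixedstep_wig(path: Path, values: dict[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        for chrom, arr in values.items():
            fh.write(f"fixedStep chrom={chrom} start=1 step=1\n")
            fh.write("\n".join(f"{v:.6g}" for v in arr))
            fh.write("\n")


def _gaussian(offsets: np.ndarray, center: float, width: float, height: float):
    return height * np.exp(-((offsets - center) ** 2) / (2.0 * width**2))


def make_scenario(
    out_dir,
    seed: int = 0,
    n_per_class: int = 30,
    n_classes: int = 5,
    upstream: int = 1000,
    downstream: int = 1500,
    noise_sd: float = 0.5,
) -> Scenario:
    """Generate the full synthetic dataset under `out_dir`.

    Features are placed on one chromosome with 2x(upstream+downstream)
    padding between TSSs so windows never collide; strands are random.
    Expression class c scales the promoter/flank peak heights (class 1 is
    the top class); the body-signal subtype cycles through
    bidirectional/unidirectional/absent within each class. Gaussian noise
    of `noise_sd` per base is added to every track (0 gives the noise-free
    variant with analytically exact profiles).
    """
    if n_per_class < 1 or n_classes < 1:
        raise ValueError("need at least one feature per class")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    spacing = 2 * (upstream + downstream)
    n_features = n_per_class * n_classes
    chrom = "chrI"
    chrom_len = spacing * (n_features + 1)

    genome = {chrom: "".join(rng.choice(list("ACGT"), size=chrom_len))}
    genome_fasta = out_dir / "genome.fa"
    _write_fasta(genome_fasta, genome)

    # features: gene of seeded length with its TSS centered in its slot
    intervals: list[GenomicInterval] = []
    class_labels: list[str] = []
    body_subtypes: list[str] = []
    per_class: dict[str, list[GenomicInterval]] = {}
    for i in range(n_features):
        cls_i = i % n_classes
        cls = f"class{cls_i + 1}"
        tss = spacing * i + spacing // 2
        lo, hi = max(100, spacing // 4), max(200, min(2400, spacing - 100))
        gene_len = int(rng.integers(lo, hi))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_len = min(gene_len, tss - 1 if strand == "-" else chrom_len - tss - 1)
        if strand == "+":
            iv = GenomicInterval(chrom, tss, tss + gene_len, name=f"gene{i:04d}", strand=strand)
        else:
            iv = GenomicInterval(chrom, tss - gene_len, tss, name=f"gene{i:04d}", strand=strand)
        intervals.append(iv)
        class_labels.append(cls)
        body_subtypes.append(BODY_SUBTYPES[(i // n_classes) % len(BODY_SUBTYPES)])
        per_class.setdefault(cls, []).append(iv)

    class_beds = {}
    for cls, ivs in per_class.items():
        p = out_dir / f"tss_{cls}.bed"
        _write_bed_rows(p, ivs)
        class_beds[cls] = p
    all_bed = out_dir / "tss_all.bed"
    _write_bed_rows(all_bed, intervals)

    # signal tracks, placed in biological orientation around each TSS
    pad = max(upstream, downstream) + 500
    offsets = np.arange(-pad, pad + 1, dtype=float)
    tracks = {
        "tss_mark": np.zeros(chrom_len),
        "flank_mark": np.zeros(chrom_len),
        "body_mark": np.zeros(chrom_len),
    }
    for i, iv in enumerate(intervals):
        cls_i = int(class_labels[i][5:]) - 1
        scale = (n_classes - cls_i) / n_classes  # class1 strongest
        tss = anchor = iv.end if iv.strand == "-" else iv.start
        shape_tss = _gaussian(offsets, 150.0, 150.0, 4.0 * scale)
        shape_flank = _gaussian(offsets, -250.0, 100.0, 3.0 * scale) + _gaussian(
            offsets, 250.0, 100.0, 3.0 * scale
        )
        sub = body_subtypes[i]
        shape_body = np.zeros_like(offsets)
        if sub == "bidirectional":
            shape_body[(offsets >= -upstream) & (offsets < downstream)] = BODY_HEIGHT
        elif sub == "unidirectional":
            shape_body[(offsets >= 0) & (offsets < downstream)] = BODY_HEIGHT
        for name, shape in (
            ("tss_mark", shape_tss),
            ("flank_mark", shape_flank),
            ("body_mark", shape_body),
        ):
            if iv.strand == "+":
                g = (anchor + offsets).astype(int)
            else:
                g = (anchor - 1 - offsets).astype(int)
            ok = (g >= 0) & (g < chrom_len)
            tracks[name][g[ok]] += shape[ok]

    signal_wigs = {}
    for name, arr in tracks.items():
        if noise_sd > 0:
            arr = arr + rng.normal(0.0, noise_sd, size=arr.shape[0])
        p = out_dir / f"{name}.wig"
        _write_fixedstep_wig(p, {chrom: arr})
        signal_wigs[name] = p

    return Scenario(
        root=out_dir,
        seed=seed,
        genome_fasta=genome_fasta,
        class_beds=class_beds,
        all_bed=all_bed,
        signal_wigs=signal_wigs,
        features=FeatureSet(intervals, source_path=str(all_bed)),
        class_labels=class_labels,
        body_subtypes=body_subtypes,
        chrom_sizes={chrom: chrom_len},
    )


def _write_bed_rows(path: Path, ivs) -> None:
    with open(path, "w") as fh:
        for iv in ivs:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t0\t{iv.strand}\n")


def planted_matrix(seed: int, groups: list[tuple[int, np.ndarray, float]]):
    """Rows drawn Normal(center, sd * I) per group, then shuffled.

    Returns (array, labels): `labels[i]` is the 0-based group index of row
    i after the recorded shuffle, the ground truth for clustering checks.
    """
    if not groups:
        raise ValueError("need at least one group")
    rng = np.random.default_rng(seed)
    blocks, labels = [], []
    for g, (n_rows, center, sd) in enumerate(groups):
        center = np.asarray(center, dtype=float)
        blocks.append(center[None, :] + sd * rng.standard_normal((n_rows, center.shape[0])))
        labels += [g] * n_rows
    x = np.vstack(blocks)
    labels = np.asarray(labels)
    perm = rng.permutation(x.shape[0])
    return x[perm], labels[perm]
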