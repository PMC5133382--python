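"""CG dinucleotide density track from a genome sequence.

Scans both strands of a generated genome for the motif CG, counts match
starts in a 201 bp sliding window centered on every base, normalizes to
occurrences per kb, and writes the result as an indexed bigWig that can be
used anywhere a coverage track can. CG is palindromic, so both-strand
scanning doubles the density by design.
"""

from pathlib import Path

import numpy as np

from metaplots import MotifSpec, build_motif_track, convert_to_indexed
from metaplots.synth import make_scenario

out = Path("scratch/examples")
out.mkdir(parents=True, exist_ok=True)

sc = make_scenario(out / "data_motif", seed=0, n_per_class=4, n_classes=3,
                   upstream=200, downstream=300)

spec = MotifSpec("CG", window=201, both_strands=True, per_kb=True)
track = build_motif_track(sc.genome_fasta, spec)

chrom, size = next(iter(track.chrom_sizes.items()))
dens = track.values[chrom]
print(f"{chrom}: {size} bp, CG density mean {dens.mean():.1f} /kb "
      f"(min {dens.min():.1f}, max {dens.max():.1f})")
# a random ACGT genome has CG at ~1/16 of positions; both strands double it
print(f"expected for a uniform random genome: ~{2 * 1000 / 16:.0f} /kb")

bw = convert_to_indexed(track, out / "cg_density.bw")
print(f"wrote {bw}")
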