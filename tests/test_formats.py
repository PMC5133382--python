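import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaplots import (
    FeatureSet,
    GenomicInterval,
    ParseError,
    SignalTrack,
    convert_to_indexed,
    query_bins,
    read_features,
    read_signal,
    write_bed,
)

from oracles import naive_query_bins


# ---------------------------------------------------------------------------
# feature parsing


def test_bed_line_parses_as_half_open_interval(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chrI\t100\t200\tgeneA\t0\t+\n")
    fs = read_features(p)
    assert fs.intervals == [GenomicInterval("chrI", 100, 200, "geneA", "+")]


def test_gff_coordinates_converted_to_zero_based(tmp_path):
    p = tmp_path / "a.gff"
    p.write_text("chrI\tsrc\tgene\t101\t200\t.\t-\t.\tID=g1\n")
    (iv,) = read_features(p).intervals
    assert (iv.chrom, iv.start, iv.end, iv.strand, iv.name) == (
        "chrI", 100, 200, "-", "g1",
    )


def test_gtf_gene_id_attribute_becomes_name(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text('chrI\tsrc\texon\t1\t50\t.\t+\t.\tgene_id "abc"; tx "t1";\n')
    assert read_features(p).intervals[0].name == "abc"


def test_headers_and_comments_skipped(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text(
        "track name=test\n# comment\nbrowser position chrI\n"
        "chrI\t0\t10\nchrI\t20\t30\nchrI\t40\t50\n"
    )
    # independent count: non-header lines
    n_records = sum(
        1
        for line in p.read_text().splitlines()
        if line and not line.startswith(("track", "#", "browser"))
    )
    fs = read_features(p)
    assert len(fs) == n_records == 3


@pytest.mark.parametrize(
    "content",
    ["chrI\t-5\t10\n", "chrI\t20\t10\n", "chrI\tten\t20\n", "chrI\t5\n"],
)
def test_malformed_bed_errors_name_the_line(tmp_path, content):
    p = tmp_path / "bad.bed"
    p.write_text("chrI\t0\t10\n" + content)
    with pytest.raises(ParseError, match="line 2"):
        read_features(p)


def test_unknown_extension_lists_accepted(tmp_path):
    p = tmp_path / "a.xyz"
    p.write_text("chrI\t0\t10\n")
    with pytest.raises(ParseError, match="bed"):
        read_features(p)


@settings(max_examples=50, deadline=None, derandomize=True)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["chrI", "chrII", "scaffold_1"]),
            st.integers(0, 10_000),
            st.integers(1, 500),
            st.sampled_from(["", "x", "gene-1", "a.b"]),
            st.sampled_from(["+", "-", "."]),
        ),
        min_size=0,
        max_size=20,
    )
)
def test_bed_round_trip_preserves_features(tmp_path_factory, rows):
    """read_features(write_bed(F)) == F, including order and duplicates."""
    fs = FeatureSet(
        [
            GenomicInterval(c, s, s + ln, name=n, strand=st_)
            for c, s, ln, n, st_ in rows
        ]
    )
    p = tmp_path_factory.mktemp("rt") / "rt.bed"
    write_bed(fs, p)
    back = read_features(p)
    assert back.intervals == fs.intervals


# ---------------------------------------------------------------------------
# signal parsing


def test_fixedstep_wiggle_is_one_based(tmp_path):
    p = tmp_path / "a.wig"
    p.write_text("fixedStep chrom=chrI start=1 step=1\n1\n2\n3\n")
    track = read_signal(p)
    assert np.array_equal(track.per_base("chrI", 0, 3), [1, 2, 3])


def test_variablestep_wiggle_with_span(tmp_path):
    p = tmp_path / "a.wig"
    p.write_text("variableStep chrom=chrI span=2\n3\t5.0\n11\t7.0\n")
    track = read_signal(p)
    v = track.per_base("chrI", 0, 12)
    assert np.array_equal(v[2:4], [5.0, 5.0])
    assert np.array_equal(v[10:12], [7.0, 7.0])
    assert np.isnan(v[0]) and np.isnan(v[5])


def test_wiggle_span_exceeding_step_is_an_error(tmp_path):
    p = tmp_path / "a.wig"
    p.write_text("fixedStep chrom=chrI start=1 step=2 span=5\n1\n2\n")
    with pytest.raises(ParseError):
        read_signal(p)


def test_bedgraph_half_open_semantics(tmp_path):
    p = tmp_path / "a.bdg"
    p.write_text("chrI\t0\t10\t4.0\nchrI\t15\t20\t1.0\n")
    track = read_signal(p)
    assert np.all(track.per_base("chrI", 0, 10) == 4.0)
    assert np.isnan(track.per_base("chrI", 10, 11)[0])


def test_overlapping_bedgraph_intervals_rejected(tmp_path):
    p = tmp_path / "a.bdg"
    p.write_text("chrI\t0\t10\t4.0\nchrI\t5\t20\t1.0\n")
    with pytest.raises(ParseError, match="overlap"):
        read_signal(p)


def _write_sam(path, reads, chrom="chrI", length=1000):
    lines = [f"@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:{chrom}\tLN:{length}"]
    for i, (pos1, cigar_len) in enumerate(reads):
        seq = "A" * cigar_len
        lines.append(
            f"r{i}\t0\t{chrom}\t{pos1}\t30\t{cigar_len}M\t*\t0\t0\t{seq}\t*"
        )
    path.write_text("\n".join(lines) + "\n")


def test_sam_coverage_counts_all_aligned_reads(tmp_path):
    # two 50 bp reads whose spans both include 0-based position 120
    p = tmp_path / "a.sam"
    _write_sam(p, [(101, 50), (91, 50)])
    track = read_signal(p, format="bam")
    assert track.per_base("chrI", 120, 121)[0] == 2.0
    # uncovered bases are explicit zero coverage, not missing
    assert track.per_base("chrI", 500, 501)[0] == 0.0


def test_bam_without_index_full_scan(tmp_path):
    import pysam

    sam = tmp_path / "a.sam"
    _write_sam(sam, [(101, 50), (91, 50)])
    bam = tmp_path / "a.bam"
    with pysam.AlignmentFile(str(sam)) as fin:
        with pysam.AlignmentFile(str(bam), "wb", template=fin) as fout:
            for r in fin:
                fout.write(r)
    track = read_signal(bam)  # no .bai present
    assert track.per_base("chrI", 120, 121)[0] == 2.0


# ---------------------------------------------------------------------------
# bigWig round trips


def test_three_value_wiggle_round_trips_through_bigwig(tmp_path):
    p = tmp_path / "a.wig"
    p.write_text("fixedStep chrom=chrI start=1 step=1\n1\n2\n3\n")
    track = read_signal(p)
    bw = convert_to_indexed(track, tmp_path / "a.bw")
    back = read_signal(bw)
    assert np.array_equal(back.per_base("chrI", 0, 3), [1, 2, 3])


def test_random_track_round_trip_max_error_below_1e6(tmp_path, rng):
    vals = rng.normal(size=10_000)
    vals[2000:2500] = np.nan  # a no-data gap must survive the round trip
    track = SignalTrack({"chrI": vals})
    back = read_signal(convert_to_indexed(track, tmp_path / "t.bw"))
    got = back.per_base("chrI", 0, 10_000)
    assert np.array_equal(np.isnan(got), np.isnan(vals))
    assert np.nanmax(np.abs(got - vals)) < 1e-6


def test_round_trip_preserves_both_chromosomes(tmp_path, rng):
    track = SignalTrack(
        {"chrI": rng.normal(size=300), "chrII": rng.normal(size=450)}
    )
    back = read_signal(convert_to_indexed(track, tmp_path / "t.bw"))
    assert back.chrom_sizes == {"chrI": 300, "chrII": 450}


# ---------------------------------------------------------------------------
# query_bins


def test_constant_track_any_binning_is_constant():
    track = SignalTrack({"chrI": np.full(100, 5.0)})
    assert np.allclose(query_bins(track, "chrI", 3, 97, 7), 5.0, atol=1e-12)


def test_per_base_oracle_example():
    track = SignalTrack({"chrI": np.array([1.0, 2.0, 3.0, 4.0])})
    assert np.array_equal(query_bins(track, "chrI", 0, 4, 2), [1.5, 3.5])


def test_bins_past_chromosome_end_are_missing():
    track = SignalTrack({"chrI": np.ones(100)})
    out = query_bins(track, "chrI", 90, 160, 7)
    assert np.all(out[:1] == 1.0)
    assert np.all(np.isnan(out[2:]))  # bins fully beyond base 100


def test_unknown_chromosome_gives_missing_bins_and_warning(caplog):
    track = SignalTrack({"chrI": np.ones(10)})
    with caplog.at_level("WARNING", logger="metaplots"):
        out = query_bins(track, "chrXYZ", 0, 10, 3)
    assert np.all(np.isnan(out))
    assert any("chrXYZ" in r.message for r in caplog.records)


def test_nbins_equal_to_span_returns_raw_values(rng):
    vals = rng.normal(size=64)
    vals[10] = np.nan
    track = SignalTrack({"chrI": vals})
    out = query_bins(track, "chrI", 0, 64, 64)
    assert np.array_equal(np.isnan(out), np.isnan(vals))
    assert np.array_equal(out[~np.isnan(out)], vals[~np.isnan(vals)])


def test_query_bins_matches_naive_oracle_on_random_windows(rng):
    vals = rng.normal(size=2048)
    vals[rng.random(2048) < 0.05] = np.nan
    track = SignalTrack({"chrI": vals})
    for _ in range(100):
        start = int(rng.integers(-50, 2000))
        end = start + int(rng.integers(1, 400))
        nbins = int(rng.integers(1, 30))
        got = query_bins(track, "chrI", start, end, nbins)
        want = naive_query_bins(vals, start, end, nbins)
        assert np.allclose(got, want, atol=1e-9, equal_nan=True)


def test_summary_levels_agree_with_base_level(rng):
    """Zoomed queries must equal base-level computation within 1e-6."""
    vals = rng.normal(size=4096)
    vals[rng.random(4096) < 0.1] = np.nan
    track = SignalTrack({"chrI": vals})
    for _ in range(1000):
        start = int(rng.integers(0, 3000))
        end = start + int(rng.integers(2, 1000))
        nbins = int(rng.integers(1, 12))
        fast = query_bins(track, "chrI", start, end, nbins, use_summary=True)
        slow = query_bins(track, "chrI", start, end, nbins, use_summary=False)
        assert np.allclose(fast, slow, atol=1e-6, equal_nan=True)


def test_wiggle_bedgraph_bigwig_express_identical_coverage(tmp_path, rng):
    """The same coverage in all three text/binary formats binning identically."""
    n = 3000
    vals = np.full(n, np.nan)
    pos = 0
    segments = []
    while pos < n - 10:
        if rng.random() < 0.3:
            pos += int(rng.integers(5, 50))  # gap
            continue
        seg_len = int(rng.integers(5, 80))
        seg = np.round(rng.normal(size=seg_len), 4)
        seg_len = min(seg_len, n - pos)
        vals[pos : pos + seg_len] = seg[:seg_len]
        segments.append((pos, seg[:seg_len]))
        pos += seg_len
    wig = tmp_path / "t.wig"
    with open(wig, "w") as fh:
        for start, seg in segments:
            fh.write(f"fixedStep chrom=chrI start={start + 1} step=1\n")
            fh.write("\n".join(f"{v:.4f}" for v in seg) + "\n")
    bdg = tmp_path / "t.bdg"
    with open(bdg, "w") as fh:
        for start, seg in segments:
            for i, v in enumerate(seg):
                fh.write(f"chrI\t{start + i}\t{start + i + 1}\t{v:.4f}\n")
    t_wig = read_signal(wig, chrom_sizes={"chrI": n})
    t_bdg = read_signal(bdg, chrom_sizes={"chrI": n})
    t_bw = read_signal(convert_to_indexed(t_wig, tmp_path / "t.bw"))
    for _ in range(300):
        start = int(rng.integers(0, n - 1))
        end = start + int(rng.integers(1, 500))
        nbins = int(rng.integers(1, 20))
        a = query_bins(t_wig, "chrI", start, end, nbins)
        b = query_bins(t_bdg, "chrI", start, end, nbins)
        c = query_bins(t_bw, "chrI", start, end, nbins)
        assert np.allclose(a, b, atol=1e-6, equal_nan=True)
        assert np.allclose(a, c, atol=1e-6, equal_nan=True)
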