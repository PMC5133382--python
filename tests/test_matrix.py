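import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from metaplots import (
    AnchorSpec,
    FeatureSet,
    GenomicInterval,
    SignalTrack,
    anchor_point,
    compute_matrix,
    scale_body,
)

from oracles import naive_compute_matrix


def _fs(*ivs):
    return FeatureSet(list(ivs))


# ---------------------------------------------------------------------------
# anchor points


@pytest.mark.parametrize(
    "strand,mode,expected",
    [
        ("+", "start", 100),
        ("+", "end", 200),
        ("-", "start", 200),  # biological start of a minus feature: right edge
        ("-", "end", 100),
        ("+", "center", 150),
        ("-", "center", 150),
    ],
)
def test_anchor_point_strand_reflection(strand, mode, expected):
    iv = GenomicInterval("chrI", 100, 200, strand=strand)
    assert anchor_point(iv, mode) == expected


def test_center_uses_floor_midpoint_for_odd_lengths():
    iv = GenomicInterval("chrI", 100, 201, strand="+")
    assert anchor_point(iv, "center") == 150
    # brute force over parity cases
    for start, end in [(0, 1), (0, 2), (3, 8), (3, 9)]:
        iv = GenomicInterval("chrI", start, end)
        assert anchor_point(iv, "center") == math.floor((start + end) / 2)


def test_ignore_strand_suppresses_reflection():
    iv = GenomicInterval("chrI", 100, 200, strand="-")
    assert anchor_point(iv, "start", ignore_strand=True) == 100


# ---------------------------------------------------------------------------
# compute_matrix basics


def test_tss_window_has_250_bins_with_expected_centers():
    """1 kb upstream / 1.5 kb downstream at 10 bp: 250 bins, -995..+1495."""
    anc = AnchorSpec(mode="start", upstream=1000, downstream=1500, bin=10)
    track = SignalTrack({"chrI": np.zeros(10_000)})
    m = compute_matrix(_fs(GenomicInterval("chrI", 5000, 6000, strand="+")), track, anc)
    assert m.values.shape == (1, 250)
    assert m.bin_centers[0] == -995 and m.bin_centers[-1] == 1495
    assert np.all(np.diff(m.bin_centers) == 10)


def test_constant_track_fills_matrix_regardless_of_mode_and_strand():
    track = SignalTrack({"chrI": np.ones(20_000)})
    fs = _fs(
        GenomicInterval("chrI", 5000, 6001, strand="+"),
        GenomicInterval("chrI", 9000, 10_500, strand="-"),
    )
    for mode in ("start", "end", "center", "scaled"):
        anc = AnchorSpec(mode=mode, upstream=95, downstream=130, bin=7, body_bins=13)
        m = compute_matrix(fs, track, anc)
        assert np.allclose(m.values, 1.0, atol=1e-12)


def test_mirrored_ramp_rows_are_exact_reverses():
    """A + and a - feature at mirrored positions on a left-right ramp give
    exactly reversed rows."""
    n = 4000
    ramp = np.arange(n, dtype=float)
    track_f = SignalTrack({"chrI": ramp})
    track_r = SignalTrack({"chrI": ramp[::-1].copy()})
    anc = AnchorSpec(mode="start", upstream=100, downstream=150, bin=10)
    plus = compute_matrix(
        _fs(GenomicInterval("chrI", 1000, 1500, strand="+")), track_f, anc
    )
    minus = compute_matrix(
        _fs(GenomicInterval("chrI", n - 1500, n - 1000, strand="-")), track_r, anc
    )
    assert np.array_equal(plus.values[0], minus.values[0])


def test_feature_on_unknown_chromosome_gives_missing_row(caplog):
    track = SignalTrack({"chrI": np.ones(1000)})
    fs = _fs(
        GenomicInterval("chrI", 400, 500, strand="+"),
        GenomicInterval("scaffold_9", 400, 500, strand="+"),
    )
    anc = AnchorSpec(upstream=50, downstream=50, bin=10)
    with caplog.at_level("WARNING", logger="metaplots"):
        m = compute_matrix(fs, track, anc)
    assert np.all(np.isnan(m.values[1])) and not np.any(np.isnan(m.values[0]))
    assert any("scaffold_9" in r.message for r in caplog.records)


def test_window_past_chromosome_edge_is_missing_not_zero():
    track = SignalTrack({"chrI": np.full(200, 2.0)})
    anc = AnchorSpec(mode="start", upstream=100, downstream=100, bin=10)
    m = compute_matrix(_fs(GenomicInterval("chrI", 50, 150, strand="+")), track, anc)
    assert np.all(np.isnan(m.values[0][:5]))  # bins fully before base 0
    assert np.all(m.values[0][5:] == 2.0)


# ---------------------------------------------------------------------------
# scale_body


@pytest.mark.parametrize(
    "values,body_bins,expected",
    [
        ([1, 2, 3, 4], 2, [1.5, 3.5]),
        ([7], 3, [7, 7, 7]),
        ([1, 2, 3], 2, [4 / 3, 8 / 3]),  # 1.5-base windows, middle base split
    ],
)
def test_scale_body_weighted_mean_oracle(values, body_bins, expected):
    assert np.allclose(scale_body(values, body_bins), expected, atol=1e-12)


def test_scale_body_excludes_missing_from_both_sides():
    got = scale_body([1.0, np.nan, 3.0, np.nan], 2)
    assert got[0] == 1.0 and got[1] == 3.0


def test_scale_body_fully_missing_window_is_missing():
    got = scale_body([np.nan, np.nan, 1.0, 1.0], 2)
    assert np.isnan(got[0]) and got[1] == 1.0


# ---------------------------------------------------------------------------
# oracle equivalence and strand properties


def _random_instance(rng):
    n = int(rng.integers(150, 400))
    vals = rng.normal(size=n)
    vals[rng.random(n) < 0.08] = np.nan
    track = SignalTrack({"chrI": vals})
    mode = ["start", "end", "center", "scaled"][int(rng.integers(4))]
    anc = AnchorSpec(
        mode=mode,
        upstream=int(rng.integers(0, 60)) if mode == "scaled" else int(rng.integers(1, 60)),
        downstream=int(rng.integers(1, 80)),
        bin=int(rng.integers(1, 13)),
        body_bins=int(rng.integers(1, 15)),
        ignore_strand=bool(rng.integers(2)),
    )
    ivs = []
    for _ in range(int(rng.integers(1, 5))):
        start = int(rng.integers(0, n - 30))
        end = start + int(rng.integers(1, 25))
        strand = "+-."[int(rng.integers(3))]
        ivs.append(GenomicInterval("chrI", start, end, strand=strand))
    return _fs(*ivs), track, anc


def test_compute_matrix_equals_naive_per_base_reference(rng):
    """200 seeded random (feature, track, anchor) instances across all four
    anchor modes agree with a direct per-base implementation to 1e-9."""
    for _ in range(200):
        fs, track, anc = _random_instance(rng)
        got = compute_matrix(fs, track, anc).values
        want = naive_compute_matrix(fs, track.values, anc)
        assert got.shape == want.shape
        assert np.allclose(got, want, atol=1e-9, equal_nan=True)


def test_genome_mirror_reverses_every_row_bitwise(rng):
    """Mirroring the track and flipping all strands reverses each matrix
    row exactly (integer-valued track, so no float-order effects)."""
    n = 3000
    vals = rng.integers(0, 7, size=n).astype(float)
    vals[rng.random(n) < 0.05] = np.nan
    fwd = SignalTrack({"chrI": vals})
    rev = SignalTrack({"chrI": vals[::-1].copy()})
    ivs, mirrored = [], []
    body_bins = 10
    for _ in range(20):
        start = int(rng.integers(500, 2000))
        # lengths divisible by 2*body_bins keep scaled-mode weights integral
        # (order-independent arithmetic) and the floor center midpoint
        # mirror-symmetric
        end = start + 2 * body_bins * int(rng.integers(2, 15))
        strand = "+" if rng.random() < 0.5 else "-"
        flip = "-" if strand == "+" else "+"
        ivs.append(GenomicInterval("chrI", start, end, strand=strand))
        mirrored.append(GenomicInterval("chrI", n - end, n - start, strand=flip))
    for mode in ("start", "end", "center", "scaled"):
        anc = AnchorSpec(mode=mode, upstream=120, downstream=80, bin=10, body_bins=body_bins)
        a = compute_matrix(_fs(*ivs), fwd, anc).values
        b = compute_matrix(_fs(*mirrored), rev, anc).values
        assert np.array_equal(a, b, equal_nan=True)


def test_ignore_strand_makes_strands_identical(rng):
    vals = rng.normal(size=1000)
    track = SignalTrack({"chrI": vals})
    anc = AnchorSpec(mode="start", upstream=50, downstream=70, bin=10, ignore_strand=True)
    plus = compute_matrix(_fs(GenomicInterval("chrI", 400, 500, strand="+")), track, anc)
    minus = compute_matrix(_fs(GenomicInterval("chrI", 400, 500, strand="-")), track, anc)
    assert np.array_equal(plus.values, minus.values, equal_nan=True)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    mode=st.sampled_from(["start", "end", "center", "scaled"]),
    upstream=st.integers(0, 500),
    downstream=st.integers(0, 500),
    binw=st.integers(1, 50),
    body_bins=st.integers(1, 40),
)
def test_column_count_formula(mode, upstream, downstream, binw, body_bins):
    """n_bins = ceil(up/bin) + ceil(down/bin) (+ body_bins when scaled)."""
    if mode != "scaled" and upstream + downstream == 0:
        upstream = 1
    anc = AnchorSpec(
        mode=mode, upstream=upstream, downstream=downstream, bin=binw,
        body_bins=body_bins,
    )
    expected = math.ceil(upstream / binw) + math.ceil(downstream / binw)
    if mode == "scaled":
        expected += body_bins
    track = SignalTrack({"chrI": np.zeros(3000)})
    m = compute_matrix(_fs(GenomicInterval("chrI", 1000, 1100)), track, anc)
    assert m.n_bins == expected == anc.n_bins
    assert m.bin_centers.shape == (expected,)


def test_matrix_tsv_round_trip(tmp_path, rng):
    import pandas as pd

    track = SignalTrack({"chrI": rng.normal(size=500)})
    anc = AnchorSpec(upstream=50, downstream=50, bin=10)
    m = compute_matrix(
        _fs(GenomicInterval("chrI", 200, 300, name="g1", strand="+")), track, anc,
        signal_label="sig", feature_label="feat",
    )
    p = tmp_path / "m.tsv"
    m.to_tsv(p)
    df = pd.read_csv(p, sep="\t", index_col=0)
    assert df.shape == (1, 10)
    assert np.allclose(df.values, m.values)
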