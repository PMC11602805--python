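"""Interval engine: unit examples, per-base-oracle fuzzing, set-theory laws."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from teatlas.intervals import (
    GenomeLayout,
    IntervalSet,
    LayoutMismatchError,
    presence_mask,
    window_around,
)

from conftest import BaseOracle, random_pairs


class TSS:
    def __init__(self, gene_id, chrom, position):
        self.gene_id, self.chrom, self.position = gene_id, chrom, position


def test_layout_rejects_duplicates_and_bad_lengths():
    with pytest.raises(ValueError):
        GenomeLayout([("chr1", 100), ("chr1", 200)])
    with pytest.raises(ValueError):
        GenomeLayout([("chr1", 0)])


@pytest.mark.parametrize(
    "raw, expected, bp",
    [
        ([("chr1", 10, 20), ("chr1", 15, 30), ("chr1", 40, 50)],
         [("chr1", 10, 30), ("chr1", 40, 50)], 30),
        ([("chr1", 10, 20), ("chr1", 20, 30)], [("chr1", 10, 30)], 20),
        ([], [], 0),
        ([("chr1", 5, 6)], [("chr1", 5, 6)], 1),
    ],
)
def test_normalize_coalesces_overlapping_and_abutting(small_layout, raw, expected, bp):
    s = IntervalSet.from_pairs(small_layout, raw)
    assert s.to_pairs() == expected
    assert s.total_bp == bp


def test_basic_overlap_and_disjoint(small_layout):
    a = IntervalSet.from_pairs(small_layout, [("chr1", 0, 100)])
    b = IntervalSet.from_pairs(small_layout, [("chr1", 50, 150)])
    assert a.overlap_bp(b) == 50
    c = IntervalSet.from_pairs(small_layout, [("chr2", 0, 10)])
    assert a.overlap_bp(c) == 0
    assert a.intersect(c).total_bp == 0


def test_layout_mismatch_raises(small_layout):
    other = GenomeLayout([("chr1", 10_000)])
    a = IntervalSet.from_pairs(small_layout, [("chr1", 0, 10)])
    b = IntervalSet.from_pairs(other, [("chr1", 0, 10)])
    with pytest.raises(LayoutMismatchError):
        a.intersect(b)


def test_fuzzed_ops_equal_per_base_oracle(small_layout):
    """normalize/intersect/subtract/union/overlap match the boolean-array oracle."""
    rng = np.random.default_rng(2024)
    for _ in range(350):
        pa = random_pairs(rng, small_layout, int(rng.integers(0, 200)))
        pb = random_pairs(rng, small_layout, int(rng.integers(0, 200)))
        a = IntervalSet.from_pairs(small_layout, pa)
        b = IntervalSet.from_pairs(small_layout, pb)
        oa = BaseOracle(small_layout, pa)
        ob = BaseOracle(small_layout, pb)
        assert a.to_pairs() == oa.to_pairs()  # normalization
        assert a.intersect(b).to_pairs() == oa.intersect(ob).to_pairs()
        assert a.subtract(b).to_pairs() == oa.subtract(ob).to_pairs()
        assert a.union(b).to_pairs() == oa.union(ob).to_pairs()
        assert a.overlap_bp(b) == oa.intersect(ob).total_bp


def test_conservation_and_idempotence_fuzzed(small_layout):
    rng = np.random.default_rng(7)
    for _ in range(200):
        a = IntervalSet.from_pairs(
            small_layout, random_pairs(rng, small_layout, int(rng.integers(0, 80)))
        )
        b = IntervalSet.from_pairs(
            small_layout, random_pairs(rng, small_layout, int(rng.integers(0, 80)))
        )
        # conservation: intersect + subtract partition a
        assert a.intersect(b).total_bp + a.subtract(b).total_bp == a.total_bp
        assert a.intersect(a) == a
        assert a.subtract(a).total_bp == 0
        assert a.union(a) == a


@settings(derandomize=True, max_examples=60, deadline=None)
@given(
    st.lists(
        st.tuples(st.integers(0, 9_900), st.integers(1, 400)), max_size=40
    ),
)
def test_complement_involution_property(pairs):
    layout = GenomeLayout([("chr1", 10_000)])
    s = IntervalSet.from_pairs(
        layout, [("chr1", a, min(10_000, a + w)) for a, w in pairs]
    )
    assert s.complement().complement() == s
    assert s.total_bp + s.complement().total_bp == 10_000


def test_overlap_bp_ranges_matches_set_intersection(small_layout):
    rng = np.random.default_rng(11)
    s = IntervalSet.from_pairs(small_layout, random_pairs(rng, small_layout, 120))
    qs = np.array([0, 100, 5000, 9000])
    qe = np.array([50, 4000, 9999, 10_000])
    got = s.overlap_bp_ranges("chr1", qs, qe)
    for i in range(len(qs)):
        w = IntervalSet.from_pairs(small_layout, [("chr1", int(qs[i]), int(qe[i]))])
        assert got[i] == s.overlap_bp(w)


def test_window_around_examples():
    layout = GenomeLayout([("chr1", 1_000_000)])
    per_gene, union = window_around([TSS("g1", "chr1", 7_000)], 5_000, layout)
    assert per_gene["g1"] == ("chr1", 2_000, 12_000)
    assert union.total_bp == 10_000
    # boundary clip
    per_gene, union = window_around([TSS("g1", "chr1", 1_000)], 5_000, layout)
    assert per_gene["g1"] == ("chr1", 0, 6_000)
    # two TSSs 3 kb apart merge into one 13 kb window
    _, union = window_around(
        [TSS("g1", "chr1", 50_000), TSS("g2", "chr1", 53_000)], 5_000, layout
    )
    assert union.total_bp == 13_000 and union.region_count == 1


def test_presence_mask_examples_and_fuzz(small_layout):
    a = IntervalSet.from_pairs(small_layout, [("chr1", 100, 200)])
    b = IntervalSet.from_pairs(small_layout, [("chr1", 100, 200)])
    c = IntervalSet.from_pairs(small_layout, [("chr1", 100, 200), ("chr1", 300, 400)])
    union = a.union(b).union(c)
    intervals, mask = presence_mask(union, {"a": a, "b": b, "c": c})
    assert intervals == [("chr1", 100, 200), ("chr1", 300, 400)]
    assert mask.tolist() == [[True, True, True], [False, False, True]]

    # sample outside the union is rejected
    with pytest.raises(ValueError, match="outside the union"):
        presence_mask(a, {"c": c})

    # fuzz against per-base recomputation
    rng = np.random.default_rng(5)
    for _ in range(30):
        samples = {
            f"s{i}": IntervalSet.from_pairs(
                small_layout, random_pairs(rng, small_layout, 50)
            )
            for i in range(4)
        }
        union = IntervalSet.empty(small_layout)
        for s in samples.values():
            union = union.union(s)
        intervals, mask = presence_mask(union, samples)
        for i, (chrom, s0, e0) in enumerate(intervals):
            w = IntervalSet.from_pairs(small_layout, [(chrom, s0, e0)])
            for j, s in enumerate(samples.values()):
                assert mask[i, j] == (w.overlap_bp(s) >= 1)


def test_merge_and_intersect_agree_with_bedtools(small_layout, tmp_path):
    """Cross-check against bedtools, the standard interval-arithmetic tool."""
    import subprocess

    rng = np.random.default_rng(99)
    pa = sorted(random_pairs(rng, small_layout, 150))
    pb = sorted(random_pairs(rng, small_layout, 150))
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    fa.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in pa))
    fb.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in pb))

    def run(cmd):
        out = subprocess.run(cmd, capture_output=True, text=True, check=True).stdout
        return [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.splitlines())
        ]

    a = IntervalSet.from_pairs(small_layout, pa)
    b = IntervalSet.from_pairs(small_layout, pb)
    merged = run(["bedtools", "merge", "-i", str(fa)])
    assert a.to_pairs() == merged
    fm_a, fm_b = tmp_path / "ma.bed", tmp_path / "mb.bed"
    fm_a.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in a.to_pairs()))
    fm_b.write_text("".join(f"{c}\t{s}\t{e}\n" for c, s, e in b.to_pairs()))
    inter = run(["bedtools", "intersect", "-a", str(fm_a), "-b", str(fm_b)])
    assert a.intersect(b).to_pairs() == inter
    sub = run(["bedtools", "subtract", "-a", str(fm_a), "-b", str(fm_b)])
    assert a.subtract(b).to_pairs() == sub


def test_min_overlap_threshold(small_layout):
    big = IntervalSet.from_pairs(small_layout, [("chr1", 0, 1000)])
    graze = IntervalSet.from_pairs(small_layout, [("chr1", 0, 5)])
    union = big.union(graze)
    _, mask = presence_mask(union, {"big": big, "graze": graze}, min_overlap_bp=10)
    assert mask.tolist() == [[True, False]]
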