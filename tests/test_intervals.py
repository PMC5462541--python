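"""Interval algebra vs a per-basepair bitmap oracle, plus stated examples."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methbin import (
    GenomicInterval,
    chop,
    converge_to_loci,
    intersect_direct,
    merge_within,
    overlap_annotation,
    overlap_depth_counts,
    read_bed,
    union_across_contexts,
    write_bed,
)
from oracles import (
    bitmap_to_regions,
    bitmap_union,
    loci_union_find,
    merge_bitmap,
    overlap_bp_bitmap,
)

GI = GenomicInterval
CHROM_LEN = 10_000


def random_intervals(rng, n, length=CHROM_LEN, max_width=400, context=None):
    starts = rng.integers(0, length - max_width, size=n)
    widths = rng.integers(1, max_width, size=n)
    return [GI("chr1", int(s), int(s + w), context=context) for s, w in zip(starts, widths)]


def disjoint_intervals(rng, n, **kw):
    out = []
    for iv in sorted(random_intervals(rng, n, **kw), key=lambda i: i.start):
        if not out or iv.start >= out[-1].end:
            out.append(iv)
    return out


class TestChopAndIntersect:
    def test_pairwise_intersection_and_chop(self):
        got = intersect_direct([[GI("chr1", 0, 100)], [GI("chr1", 50, 150)]])
        assert [(g.start, g.end) for g in got] == [(50, 100)]

    def test_chop_decomposition_with_remainder(self):
        got = chop([GI("chr1", 40, 290)], window=100)
        assert [(g.start, g.end) for g in got] == [(40, 140), (140, 240), (240, 290)]

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            intersect_direct([])

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        sets = [disjoint_intervals(rng, 15) for _ in range(4)]
        ref = [(g.start, g.end) for g in intersect_direct(sets)]
        for perm in ([3, 1, 0, 2], [2, 3, 1, 0]):
            got = [(g.start, g.end) for g in intersect_direct([sets[i] for i in perm])]
            assert got == ref

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bitmap_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = [disjoint_intervals(rng, 20) for _ in range(3)]
        bm = bitmap_union(sets[0], CHROM_LEN)
        for s in sets[1:]:
            bm &= bitmap_union(s, CHROM_LEN)
        expected_regions = bitmap_to_regions(bm)
        got = intersect_direct(sets, window=100)
        # windows reassemble exactly the bitmap regions
        assert bitmap_to_regions(bitmap_union(got, CHROM_LEN)) == expected_regions
        # chop restarts at each region start
        for s, e in expected_regions:
            pieces = [(g.start, g.end) for g in got if s <= g.start < e]
            assert pieces[0][0] == s and pieces[-1][1] == e
            assert all(p[1] - p[0] == 100 for p in pieces[:-1])

    def test_depth_counts_monotone(self):
        rng = np.random.default_rng(5)
        sets = [disjoint_intervals(rng, 25) for _ in range(6)]
        counts = overlap_depth_counts(sets)
        ks = sorted(counts)
        assert all(counts[a] >= counts[b] for a, b in zip(ks, ks[1:]))


class TestMerge:
    def test_gap_at_distance_merges(self):
        got = merge_within([GI("chr1", 0, 100), GI("chr1", 350, 450)], distance=300)
        assert [(g.start, g.end) for g in got] == [(0, 450)]

    def test_gap_beyond_distance_does_not(self):
        got = merge_within([GI("chr1", 0, 100), GI("chr1", 401, 501)], distance=300)
        assert len(got) == 2

    def test_context_restriction(self):
        ivs = [GI("chr1", 0, 100, context="CG"), GI("chr1", 150, 250, context="CHH")]
        assert len(merge_within(ivs, distance=300, same_context=True)) == 2
        assert len(merge_within(ivs, distance=300, same_context=False)) == 1

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_idempotent_and_separated(self, seed):
        rng = np.random.default_rng(seed)
        ivs = random_intervals(rng, 30, context="CG")
        merged = merge_within(ivs, distance=300)
        again = merge_within(merged, distance=300)
        assert [(g.start, g.end) for g in merged] == [(g.start, g.end) for g in again]
        for a, b in zip(merged, merged[1:]):
            assert b.start - a.end > 300
        covered = bitmap_union(ivs, CHROM_LEN).sum()
        assert bitmap_union(merged, CHROM_LEN).sum() >= covered

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_mergebed_bitmap_oracle(self, seed):
        rng = np.random.default_rng(100 + seed)
        ivs = random_intervals(rng, 40, context="CG")
        got = [(g.start, g.end) for g in merge_within(ivs, distance=300)]
        assert got == merge_bitmap(ivs, 300, CHROM_LEN)


class TestUnionAcrossContexts:
    def test_adjacent_regions_join(self):
        got = union_across_contexts(
            {"CG": [GI("chr1", 0, 100)], "CHH": [GI("chr1", 100, 200)]}
        )
        assert [(g.start, g.end) for g in got] == [(0, 200)]

    def test_gap_keeps_regions_apart(self):
        got = union_across_contexts(
            {"CG": [GI("chr1", 0, 100)], "CHH": [GI("chr1", 150, 250)]}
        )
        assert len(got) == 2


class TestOverlapAnnotation:
    def test_single_bp_overlap_kept(self):
        q = [GI("chr1", 0, 100)]
        f = [GI("chr1", 99, 200)]
        assert len(overlap_annotation(q, f, "element_of")) == 1
        assert len(overlap_annotation([GI("chr1", 0, 99)], f, "element_of")) == 0

    def test_empty_features(self):
        q = [GI("chr1", 0, 100)]
        assert overlap_annotation(q, [], "element_of") == []
        assert len(overlap_annotation(q, [], "not_element_of")) == 1

    @pytest.mark.parametrize("seed", range(8))
    def test_partition_property_vs_bitmap(self, seed):
        rng = np.random.default_rng(200 + seed)
        q = disjoint_intervals(rng, 30)
        f = random_intervals(rng, 20)
        inside = overlap_annotation(q, f, "element_of")
        outside = overlap_annotation(q, f, "not_element_of")
        assert sorted(i.key for i in inside + outside) == sorted(i.key for i in q)
        for iv in q:
            bp = overlap_bp_bitmap(iv, f, CHROM_LEN)
            assert (iv.key in {i.key for i in inside}) == (bp >= 1)


class TestLoci:
    def test_overlapping_contexts_one_locus(self):
        loci = converge_to_loci(
            [GI("chr1", 0, 100, context="CG", direction="hyper"),
             GI("chr1", 50, 150, context="CHG", direction="hyper"),
             GI("chr1", 100, 200, context="CHH", direction="hyper")]
        )
        assert len(loci) == 1
        assert loci[0].contexts == ("CG", "CHG", "CHH")
        assert loci[0].direction == "hyper"

    @pytest.mark.parametrize("seed", range(6))
    def test_locus_count_equals_connected_components(self, seed):
        rng = np.random.default_rng(300 + seed)
        windows = random_intervals(rng, 34, max_width=120)
        loci = converge_to_loci(windows, merge_distance=300)
        assert len(loci) == loci_union_find(windows, 300)
        assert sum(len(l.members) for l in loci) == len(windows)

    def test_direction_summary(self):
        loci = converge_to_loci(
            [GI("chr1", 0, 100, direction="hyper"),
             GI("chr1", 50, 150, direction="hyper"),
             GI("chr1", 120, 220, direction="hypo")]
        )
        assert loci[0].direction_counts == {"hyper": 2, "hypo": 1}


class TestBedIO:
    def test_round_trip(self, tmp_path):
        ivs = [GI("chr1", 0, 100, context="CG", direction="hyper", score=12.5),
               GI("chr2", 50, 150)]
        path = tmp_path / "x.bed"
        write_bed(ivs, path)
        back = read_bed(path)
        assert [b.key for b in back] == [i.key for i in ivs]
        assert back[0].context == "CG" and back[0].direction == "hyper"
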