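"""Interval arithmetic: 1-based inclusive overlap, reciprocal overlap, sizes."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvscreen import GenomicInterval, overlap_bp, reciprocal_overlap, size_mb
from cnvscreen.intervals import AnnotationTrack, chrom_sort_key, normalize_chrom

from .oracles import overlap_by_enumeration

intervals_st = st.builds(
    lambda chrom, start, length: GenomicInterval(chrom, start, start + length),
    chrom=st.sampled_from(["1", "2", "X"]),
    start=st.integers(min_value=1, max_value=500),
    length=st.integers(min_value=0, max_value=500),
)


class TestOverlap:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("1", 1, 10), ("1", 5, 20), 6),
            (("1", 1, 10), ("2", 1, 10), 0),
            (("1", 1, 10), ("1", 11, 20), 0),
            (("1", 5, 5), ("1", 5, 5), 1),
        ],
    )
    def test_overlap_examples(self, a, b, expected):
        assert overlap_bp(GenomicInterval(*a), GenomicInterval(*b)) == expected

    def test_printed_span_self_overlap(self):
        """The 22q11.1 printed span overlaps itself over its full 1,180,008 bp."""
        span = GenomicInterval("22", 16_114_244, 17_294_251)
        assert overlap_bp(span, span) == 1_180_008 == span.size
        # same arithmetic validated by base enumeration on a scaled copy
        scaled = GenomicInterval("22", 1_244, 2_251)
        assert overlap_bp(scaled, scaled) == overlap_by_enumeration(scaled, scaled) == 1_008

    @settings(max_examples=60, derandomize=True)
    @given(a=intervals_st, b=intervals_st)
    def test_overlap_symmetric_and_bounded(self, a, b):
        ov = overlap_bp(a, b)
        assert ov == overlap_bp(b, a)
        assert 0 <= ov <= min(a.size, b.size)
        assert ov == overlap_by_enumeration(a, b)


class TestReciprocalOverlap:
    def test_identity_disjoint_and_half(self):
        a = GenomicInterval("1", 1, 100)
        assert reciprocal_overlap(a, a) == 1.0
        assert reciprocal_overlap(a, GenomicInterval("1", 200, 300)) == 0.0
        b = GenomicInterval("1", 51, 150)
        assert reciprocal_overlap(a, b) == pytest.approx(0.5)
        assert overlap_by_enumeration(a, b) == 50

    @settings(max_examples=60, derandomize=True)
    @given(a=intervals_st, b=intervals_st)
    def test_symmetric_and_one_iff_same_span(self, a, b):
        r = reciprocal_overlap(a, b)
        assert r == reciprocal_overlap(b, a)
        assert 0.0 <= r <= 1.0
        assert (r == 1.0) == a.same_span(b)


class TestSizeMb:
    @pytest.mark.parametrize(
        "chrom, start, end, printed",
        [
            ("X", 62_038_249, 68_117_977, 6.08),
            ("22", 16_114_244, 17_294_251, 1.18),
            ("13", 104_746_408, 106_422_213, 1.68),
            ("5", 111_778_778, 112_842_992, 1.06),
            ("X", 6_430_651, 8_135_053, 1.70),
            ("X", 6_436_087, 8_135_053, 1.70),
            ("4", 117_047_226, 118_043_617, 1.00),
            ("1", 1_385_211, 1_425_700, 0.04),
            ("1", 1_415_012, 1_447_325, 0.03),
            ("19", 53_932_295, 54_010_277, 0.08),
        ],
    )
    def test_printed_sizes_reproduced(self, chrom, start, end, printed):
        assert size_mb(GenomicInterval(chrom, start, end)) == pytest.approx(printed)

    def test_single_base_and_rounding_half_up(self):
        assert size_mb(GenomicInterval("1", 5, 5)) == 0.0
        # 1,005,000 bp sits exactly on the .005 boundary -> away from zero
        assert size_mb(GenomicInterval("1", 1, 1_005_000)) == 1.01


class TestValidationAndNormalisation:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            GenomicInterval("1", 0, 10)
        with pytest.raises(ValueError):
            GenomicInterval("1", 10, 9)
        with pytest.raises(ValueError):
            GenomicInterval("", 1, 10)

    def test_chr_prefix_stripped(self):
        assert normalize_chrom("chr22") == "22"
        assert GenomicInterval("chrX", 1, 2).chrom == "X"

    def test_chrom_sort_order(self):
        labels = ["X", "2", "10", "1", "Y"]
        assert sorted(labels, key=chrom_sort_key) == ["1", "2", "10", "X", "Y"]


class TestAnnotationTrack:
    def test_sorted_and_queryable(self):
        track = AnnotationTrack(
            "t",
            [
                GenomicInterval("2", 10, 20, "b"),
                GenomicInterval("1", 5, 15, "a"),
                GenomicInterval("1", 1, 4, "c"),
            ],
        )
        assert [iv.label for iv in track] == ["c", "a", "b"]
        hits = track.overlapping(GenomicInterval("1", 4, 6))
        assert [iv.label for iv in hits] == ["c", "a"]
        assert track.count_overlapping(GenomicInterval("3", 1, 100)) == 0

    def test_union_coverage_merges_overlaps(self):
        track = AnnotationTrack(
            "t", [GenomicInterval("1", 10, 30), GenomicInterval("1", 25, 40)]
        )
        region = GenomicInterval("1", 1, 100)
        assert track.coverage_bp(region) == 31  # union 10..40
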