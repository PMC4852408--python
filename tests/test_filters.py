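"""Annotation operations and the five-criterion cascade with size gate."""

import pytest

from cnvscreen import (
    AnnotationTrack,
    CnvCall,
    ConfigurationError,
    DgvRecord,
    FilterParams,
    GenomicInterval,
    control_frequency,
    dgv_entries,
    gene_count,
    genomewide_filter,
    regional_filter,
    segdup_relation,
    survivors,
)
from cnvscreen.intervals import round_half_away

from .oracles import overlap_by_enumeration


def _call(chrom, start, end, state=1, sample="s", label=""):
    return CnvCall(sample, GenomicInterval(chrom, start, end, label), state, 50.0, 30)


class TestGeneCount:
    def test_counts_and_desert(self, bundle):
        genes = bundle.tracks["genes"]
        assert gene_count(_call("4", 117_047_226, 118_043_617, 3), genes) == 2
        assert gene_count(_call("4", 1_000, 2_000), genes) == 0

    def test_printed_gene_counts_reproduced(self, fixture, bundle):
        genes = bundle.tracks["genes"]
        expected = {"Pat17": 43, "Pat14": 10, "Pat15": 7, "Pat16": 7, "Pat21": 1, "Pat19": 2}
        for call in fixture.calls:
            if call.sample_id in expected:
                assert gene_count(call, genes) == expected[call.sample_id]


class TestSegdupRelation:
    def test_three_relations_on_1kb_toy(self):
        segdups = AnnotationTrack("segdups", [GenomicInterval("1", 401, 900)])
        assert segdup_relation(_call("1", 1, 300), segdups) == "none"
        assert segdup_relation(_call("1", 500, 800), segdups) == "contained"
        # 30% of the call covered -> partial; cross-check by base enumeration
        call = _call("1", 251, 550)
        covered = overlap_by_enumeration(call.region, GenomicInterval("1", 401, 900))
        assert covered == 150 and covered < call.region.size
        assert segdup_relation(call, segdups) == "partial"

    def test_containment_via_union_of_pieces(self):
        segdups = AnnotationTrack(
            "segdups", [GenomicInterval("1", 100, 200), GenomicInterval("1", 201, 300)]
        )
        assert segdup_relation(_call("1", 150, 250), segdups) == "contained"


class TestControlFrequency:
    def test_carrier_counting_and_rounding(self):
        call = _call("1", 100_000, 200_000, state=3)
        carriers = [_call("1", 100_000, 200_000, state=3, sample=f"c{i}") for i in range(2)]
        assert control_frequency(call, [], 1307) == 0.0
        one = control_frequency(call, carriers[:1], 1307)
        assert round_half_away(one, 4) == 0.0008 and one < 0.0008
        assert round_half_away(control_frequency(call, carriers, 1307), 4) == 0.0015

    def test_type_and_reciprocal_overlap_matching(self):
        call = _call("1", 1, 1000, state=3)
        wrong_type = _call("1", 1, 1000, state=1, sample="c1")
        small = _call("1", 1, 400, state=3, sample="c2")
        assert control_frequency(call, [wrong_type, small], 100) == 0.0
        assert control_frequency(call, [_call("1", 251, 1000, state=3, sample="c3")], 100) == 0.01

    def test_duplicate_calls_from_one_carrier_counted_once(self):
        call = _call("1", 1, 1000, state=3)
        twice = [_call("1", 1, 1000, state=3, sample="c1")] * 2
        assert control_frequency(call, twice, 100) == 0.01

    def test_zero_controls_rejected(self):
        with pytest.raises(ValueError):
            control_frequency(_call("1", 1, 10), [], 0)


class TestDgvEntries:
    def test_counting_and_type_matching(self):
        call = _call("6", 70_000_000, 71_150_000, state=1)
        records = [DgvRecord(GenomicInterval("6", 70_000_000, 71_150_000), "deletion")] * 11
        assert dgv_entries(call, []) == 0
        assert dgv_entries(call, records) == 11
        dups = [DgvRecord(GenomicInterval("6", 70_000_000, 71_150_000), "duplication")] * 11
        assert dgv_entries(call, dups) == 0


class TestCascade:
    def test_fixture_reproduces_survivor_counts(self, fixture, bundle, decoys):
        calls = fixture.calls + decoys
        verdicts = regional_filter(
            calls, bundle.beec_regions, bundle.tracks, bundle.control_calls, bundle.dgv, bundle.params
        )
        gw = survivors(verdicts, "genomewide")
        reg = survivors(verdicts, "regional")
        assert len(gw) == 7
        assert len(reg) == 6
        assert sum(1 for v in gw if v.control_frequency == 0.0) == 4
        assert {v.call.sample_id for v in gw} == {
            "Pat5", "Pat6", "Pat11", "Pat14", "Pat15", "Pat16", "Pat17"
        }
        assert {v.call.sample_id for v in reg} == {
            "Pat2", "Pat9", "Pat19", "Pat20", "Pat21", "Pat22"
        }
        # survivor sets disjoint
        assert not {id(v) for v in gw} & {id(v) for v in reg}

    def test_each_decoy_fails_exactly_its_criterion(self, bundle, decoys):
        verdicts = regional_filter(
            decoys, bundle.beec_regions, bundle.tracks, bundle.control_calls, bundle.dgv, bundle.params
        )
        by_sample = {v.call.sample_id: v for v in verdicts}
        for v in verdicts:
            assert not v.pass_genomewide and not v.pass_regional
        v = by_sample["DEC_TEL"]
        assert v.excluded_telomere_hla and v.gene_count >= 1 and v.segdup_relation == "none"
        assert v.control_frequency == 0 and v.dgv_entries == 0 and v.size_mb >= 1
        v = by_sample["DEC_NOGENE"]
        assert v.gene_count == 0 and not v.excluded_telomere_hla and v.size_mb >= 1
        v = by_sample["DEC_SEGDUP"]
        assert v.segdup_relation == "contained" and v.gene_count >= 1
        v = by_sample["DEC_FREQ"]
        assert v.control_frequency > 0.01 and v.gene_count >= 1 and v.dgv_entries <= 10
        v = by_sample["DEC_DGV"]
        assert v.dgv_entries == 11 and v.control_frequency == 0 and v.gene_count >= 1
        v = by_sample["DEC_SIZE"]
        assert v.size_mb < 1 and v.gene_count >= 1 and not v.excluded_telomere_hla
        assert v.segdup_relation == "none" and v.control_frequency == 0 and v.dgv_entries == 0

    def test_decoys_do_not_change_survivors(self, fixture, bundle, decoys):
        def run(calls):
            verdicts = regional_filter(
                calls, bundle.beec_regions, bundle.tracks, bundle.control_calls, bundle.dgv, bundle.params
            )
            return (
                {v.call.sample_id for v in survivors(verdicts, "genomewide")},
                {v.call.sample_id for v in survivors(verdicts, "regional")},
            )

        assert run(fixture.calls) == run(fixture.calls + decoys)

    def test_exactly_one_percent_frequency_survives(self, bundle):
        """The exclusion rule is strict (>1 %), so exactly 1 % passes."""
        call = _call("6", 70_000_000, 71_150_000, state=3, sample="case")
        carriers = [
            _call("6", 70_000_000, 71_150_000, state=3, sample=f"c{i}") for i in range(13)
        ]
        params = FilterParams(n_controls=1300)
        (v,) = genomewide_filter([call], bundle.tracks, carriers, bundle.dgv, params)
        assert v.control_frequency == pytest.approx(0.01)
        assert v.dgv_entries == 0  # the catalogued records there are deletions
        assert v.pass_genomewide
        fourteen = carriers + [_call("6", 70_000_000, 71_150_000, state=3, sample="c13")]
        (v2,) = genomewide_filter([call], bundle.tracks, fourteen, bundle.dgv, params)
        assert not v2.pass_genomewide

    def test_tightening_thresholds_never_adds_survivors(self, fixture, bundle, decoys):
        calls = fixture.calls + decoys
        base_params = bundle.params
        base = genomewide_filter(calls, bundle.tracks, bundle.control_calls, bundle.dgv, base_params)
        n_base = len(survivors(base, "genomewide"))
        for tighter in [
            FilterParams(max_control_freq=0.0005, n_controls=1307),
            FilterParams(max_dgv_entries=1, n_controls=1307),
            FilterParams(min_size_mb=2.0, n_controls=1307),
            FilterParams(min_recip_overlap=0.1, n_controls=1307),
        ]:
            v = genomewide_filter(calls, bundle.tracks, bundle.control_calls, bundle.dgv, tighter)
            assert len(survivors(v, "genomewide")) <= n_base

    def test_regional_gating(self, bundle):
        params = bundle.params
        outside = _call("2", 100_000_000, 100_500_000, state=3, sample="a")  # rare but no region
        inside_common = _call("1", 1_390_000, 1_430_000, state=1, sample="b")
        carriers = [
            CnvCall(f"c{i}", inside_common.region, 1, 50.0, 30) for i in range(27)
        ]
        verdicts = regional_filter(
            [outside, inside_common],
            bundle.beec_regions,
            bundle.tracks,
            bundle.control_calls + carriers,
            bundle.dgv,
            params,
        )
        by = {v.call.sample_id: v for v in verdicts}
        assert by["a"].matched_region is None and not by["a"].pass_regional
        assert by["b"].matched_region is not None
        assert by["b"].control_frequency > 0.01 and not by["b"].pass_regional

    def test_missing_track_and_empty_region_track_rejected(self, fixture, bundle):
        with pytest.raises(ConfigurationError, match="genes"):
            genomewide_filter(fixture.calls, {"segdups": bundle.tracks["segdups"]}, [], [])
        with pytest.raises(ConfigurationError):
            regional_filter(
                fixture.calls, AnnotationTrack("beec_regions", []), bundle.tracks, [], []
            )

    def test_empty_call_set(self, bundle):
        assert genomewide_filter([], bundle.tracks, [], []) == []
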