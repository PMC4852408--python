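"""Segmentation into candidate calls, call-level QC and sample-level QC."""

import numpy as np
import pandas as pd
import pytest

from cnvscreen import GenomicInterval, MarkerSignalTable, call_cnvs, sample_qc
from cnvscreen.caller import segments_from_path
from cnvscreen.simulate import SimConfig, TruthEvent, simulate_cohort


def _table(lrr, baf, positions=None, sample="s"):
    n = len(lrr)
    positions = positions if positions is not None else np.arange(1, n + 1) * 1000
    return MarkerSignalTable(
        sample, pd.DataFrame({"chrom": "1", "position": positions, "lrr": lrr, "baf": baf})
    )


class TestSegments:
    def test_all_diploid_no_candidates(self):
        assert segments_from_path(np.full(10, 2), np.arange(10) * 100 + 1, "1") == []

    def test_run_of_seven_cn3(self):
        path = np.array([2, 2, 3, 3, 3, 3, 3, 3, 3, 2])
        pos = np.arange(10) * 1000 + 1
        (cand,) = segments_from_path(path, pos, "1", "s")
        assert cand.n_markers == 7
        assert cand.cn_state == 3
        assert (cand.region.start, cand.region.end) == (pos[2], pos[8])

    def test_runs_split_by_diploid_marker(self):
        # run-length encoding oracle: two CN1 runs separated by one CN2 marker
        path = np.array([1, 1, 1, 2, 1, 1])
        cands = segments_from_path(path, np.arange(6) * 10 + 1, "1")
        assert [c.n_markers for c in cands] == [3, 2]

    def test_run_at_end_of_chromosome_kept(self):
        path = np.array([2, 2, 4, 4])
        cands = segments_from_path(path, np.arange(4) * 10 + 1, "1")
        assert [c.cn_state for c in cands] == [4]


class TestCallCnvs:
    def test_short_strong_deletion_dropped_by_marker_rule(self, model):
        """4 aberrant markers fail the >=5 consecutive-marker criterion."""
        lrr = [0.0] * 5 + [-0.45] * 4 + [0.0] * 5
        baf = [0.5] * 5 + [0.0, 1.0, 0.0, 1.0] + [0.5] * 5
        assert call_cnvs(_table(lrr, baf)) == []

    def test_clean_diploid_sample_yields_no_calls(self, model):
        rng = np.random.default_rng(0)
        n = 400
        lrr = rng.normal(0.0, 0.15, n)
        baf = np.clip(rng.choice([0.0, 0.5, 1.0], n, p=[0.25, 0.5, 0.25]) + rng.normal(0, 0.03, n), 0, 1)
        assert call_cnvs(_table(lrr, baf)) == []

    def test_simulated_deletion_recovered_within_two_markers(self, model):
        sim = simulate_cohort(
            SimConfig(
                genome_layout=(("1", 2_000_000),),
                n_controls=0,
                events=(TruthEvent("case", GenomicInterval("1", 500_000, 565_000), 1),),
                seed=42,
            )
        )
        table = sim.samples["case"]
        event = sim.truth[0]
        pos = sim.positions["1"]
        in_event = (pos >= event.region.start) & (pos <= event.region.end)
        assert in_event.sum() >= 20
        (call,) = call_cnvs(table, model)
        assert call.cnv_type == "deletion"
        i_truth = np.flatnonzero(in_event)
        i_call0 = int(np.searchsorted(pos, call.region.start))
        i_call1 = int(np.searchsorted(pos, call.region.end, side="right")) - 1
        assert abs(i_call0 - i_truth[0]) <= 2
        assert abs(i_call1 - i_truth[-1]) <= 2

    def test_deterministic_and_monotone_in_thresholds(self, model):
        sim = simulate_cohort(
            SimConfig(
                genome_layout=(("1", 2_000_000),),
                n_controls=0,
                events=(
                    TruthEvent("case", GenomicInterval("1", 300_000, 365_000), 1),
                    TruthEvent("case", GenomicInterval("1", 1_200_000, 1_265_000), 3),
                ),
                seed=7,
            )
        )
        table = sim.samples["case"]
        base = call_cnvs(table, model)
        assert call_cnvs(table, model) == base  # deterministic
        for min_markers, min_lbf in [(5, 60), (10, 30), (40, 30), (5, 10_000)]:
            tightened = call_cnvs(table, model, min_markers=min_markers, min_lbf=min_lbf)
            assert len(tightened) <= len(base)
            assert set(tightened) <= set(base)


class TestSampleQc:
    def test_quiet_sample_passes(self):
        table = _table([0.0] * 50, [0.5] * 50)
        qc = sample_qc(table, [])
        assert qc.passed and qc.lrr_sd == 0.0 and qc.n_calls == 0

    def test_more_than_ten_calls_fails(self, fixture):
        table = _table([0.0] * 10, [0.5] * 10)
        eleven = [fixture.calls[0]] * 11
        assert not sample_qc(table, eleven).passed
        assert sample_qc(table, eleven[:10]).passed

    def test_noisy_lrr_fails(self):
        rng = np.random.default_rng(5)
        table = _table(rng.normal(0.0, 0.4, 500), np.full(500, 0.5))
        qc = sample_qc(table, [])
        assert qc.lrr_sd > 0.3 and not qc.passed
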