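"""Synthetic SNP-array cohorts with embedded ground-truth CNVs.

The generator emulates a HumanOmniExpress-like array: marker gaps are drawn
from an exponential distribution calibrated so the *median* spacing is
2.1 kb (only the median of the real platform is known; the exponential is
the maximum-entropy choice given that), positions are drawn once per genome
and shared across all samples, and each sample's LRR/BAF are drawn from the
state-conditional emission model used by the caller: Gaussian LRR around
the per-state mean, BAF from genotype clusters (binomial allele weights at
allele frequency 0.5) with Gaussian scatter clipped to [0, 1].

It does not model GC waves, batch effects, sex chromosomes or partial
marker call rates — every synthetic sample has a complete, clean marker
grid, so recovery results here bound what the caller can do on real data
from above.

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calls import CnvCall, MarkerSignalTable
from .hmm import HmmModel
from .intervals import GenomicInterval, overlap_bp

__all__ = [
    "SimConfig",
    "TruthEvent",
    "CohortSim",
    "TruthMatch",
    "simulate_cohort",
    "match_calls_to_truth",
]

# genotype-cluster means and binomial weights per copy-number state
_CLUSTER_WEIGHTS: dict[int, tuple[np.ndarray, np.ndarray]] = {
    1: (np.array([0.0, 1.0]), np.array([0.5, 0.5])),
    2: (np.array([0.0, 0.5, 1.0]), np.array([0.25, 0.5, 0.25])),
    3: (np.array([0.0, 1 / 3, 2 / 3, 1.0]), np.array([1, 3, 3, 1]) / 8.0),
    4: (np.array([0.0, 0.25, 0.5, 0.75, 1.0]), np.array([1, 4, 6, 4, 1]) / 16.0),
}


@dataclass(frozen=True)
class TruthEvent:
    """A planned (ground-truth) copy-number event in one synthetic sample."""

    sample_id: str
    region: GenomicInterval
    cn_state: int

    def __post_init__(self) -> None:
        if self.cn_state not in (0, 1, 3, 4):
            raise ValueError("truth events must be non-diploid (cn_state in {0,1,3,4})")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated platform and study: 2,100 bp median marker
    spacing, LRR noise sd 0.15, BAF cluster sd 0.03, and a desk-scale
    control cohort of 100 (the study's was 1,307; frequency denominators are
    overridable downstream so printed frequencies remain reproducible).
    """

    genome_layout: tuple[tuple[str, int], ...] = (("1", 4_000_000),)
    marker_spacing_median: float = 2_100.0
    lrr_noise_sd: float = 0.15
    baf_sd: float = 0.03
    n_controls: int = 100
    events: tuple[TruthEvent, ...] = ()
    trio_flags: tuple[tuple[str, bool, bool], ...] = ()  # (child, mother_carrier, father_carrier)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_spacing_median <= 0:
            raise ValueError("marker spacing must be positive")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        by_sample: dict[str, list[TruthEvent]] = {}
        for ev in self.events:
            by_sample.setdefault(ev.sample_id, []).append(ev)
        for sample, evs in by_sample.items():
            evs = sorted(evs, key=lambda e: e.region.sort_key())
            for a, b in zip(evs, evs[1:]):
                if overlap_bp(a.region, b.region) > 0:
                    raise ValueError(f"overlapping planned events in sample {sample!r}")


@dataclass
class CohortSim:
    """Simulated cohort: signal tables, truth manifest and the shared marker grid."""

    samples: dict[str, MarkerSignalTable]
    truth: list[TruthEvent]
    positions: dict[str, np.ndarray]

    @property
    def case_ids(self) -> list[str]:
        return sorted({ev.sample_id for ev in self.truth})


def _draw_positions(rng: np.random.Generator, layout, median_spacing: float) -> dict[str, np.ndarray]:
    # exponential gaps: median = scale * ln 2
    scale = median_spacing / math.log(2.0)
    positions = {}
    for chrom, length in layout:
        n_expected = int(length / median_spacing * 1.5) + 10
        gaps = rng.exponential(scale, size=n_expected)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        while pos[-1] < length:  # rare undershoot
            extra = np.cumsum(rng.exponential(scale, size=n_expected)).astype(np.int64) + pos[-1]
            pos = np.concatenate([pos, extra])
        pos = pos[pos <= length]
        pos = np.unique(pos)
        positions[chrom] = pos
    return positions


def _sample_signals(
    rng: np.random.Generator,
    sample_id: str,
    positions: dict[str, np.ndarray],
    events: Sequence[TruthEvent],
    model: HmmModel,
    lrr_noise_sd: float,
    baf_sd: float,
) -> MarkerSignalTable:
    frames = []
    for chrom, pos in positions.items():
        states = np.full(pos.size, 2, dtype=int)
        for ev in events:
            if ev.region.chrom == chrom:
                mask = (pos >= ev.region.start) & (pos <= ev.region.end)
                states[mask] = ev.cn_state
        lrr = rng.normal(model.lrr_means[states], lrr_noise_sd)
        baf = np.empty(pos.size)
        for state in np.unique(states):
            mask = states == state
            n = int(mask.sum())
            if state == 0:
                baf[mask] = rng.uniform(0.0, 1.0, size=n)
                continue
            means, weights = _CLUSTER_WEIGHTS[int(state)]
            cluster = rng.choice(means, size=n, p=weights)
            baf[mask] = np.clip(cluster + rng.normal(0.0, baf_sd, size=n), 0.0, 1.0)
        frames.append(pd.DataFrame({"chrom": chrom, "position": pos, "lrr": lrr, "baf": baf}))
    return MarkerSignalTable(sample_id, pd.concat(frames, ignore_index=True))


def simulate_cohort(config: SimConfig, model: HmmModel | None = None) -> CohortSim:
    """Generate the cohort described by ``config``.

    Marker positions are drawn once and shared by all samples. Samples are
    generated in a fixed order (cases in plan order, then trio parents, then
    controls), so identical configs give identical outputs.
    """
    model = model or HmmModel()
    rng = np.random.default_rng(config.seed)
    positions = _draw_positions(rng, config.genome_layout, config.marker_spacing_median)

    by_sample: dict[str, list[TruthEvent]] = {}
    for ev in config.events:
        by_sample.setdefault(ev.sample_id, []).append(ev)

    samples: dict[str, MarkerSignalTable] = {}
    truth: list[TruthEvent] = list(config.events)

    for sample_id in by_sample:
        samples[sample_id] = _sample_signals(
            rng, sample_id, positions, by_sample[sample_id], model, config.lrr_noise_sd, config.baf_sd
        )
    for child, mother_carrier, father_carrier in config.trio_flags:
        child_events = by_sample.get(child, [])
        for parent_suffix, carrier in (("_M", mother_carrier), ("_F", father_carrier)):
            parent_id = child + parent_suffix
            parent_events = (
                [TruthEvent(parent_id, ev.region, ev.cn_state) for ev in child_events]
                if carrier
                else []
            )
            truth.extend(parent_events)
            samples[parent_id] = _sample_signals(
                rng, parent_id, positions, parent_events, model, config.lrr_noise_sd, config.baf_sd
            )
    for i in range(config.n_controls):
        sample_id = f"CTRL_{i + 1:04d}"
        samples[sample_id] = _sample_signals(
            rng, sample_id, positions, [], model, config.lrr_noise_sd, config.baf_sd
        )
    return CohortSim(samples=samples, truth=truth, positions=positions)


@dataclass(frozen=True)
class TruthMatch:
    """Best-matching call (if any) for one embedded event."""

    event: TruthEvent
    call: Optional[CnvCall]
    type_match: bool
    breakpoint_error: Optional[int]  # max marker-index error over both ends

    def recovered(self, max_breakpoint_error: int = 2) -> bool:
        return (
            self.call is not None
            and self.type_match
            and self.breakpoint_error is not None
            and self.breakpoint_error <= max_breakpoint_error
        )


def match_calls_to_truth(
    calls: Sequence[CnvCall],
    truth: Sequence[TruthEvent],
    positions: dict[str, np.ndarray],
) -> list[TruthMatch]:
    """Match each truth event to its best-overlapping call from the same sample.

    Breakpoint error is measured in marker indices on the shared grid: the
    larger of the start- and end-index differences between the call span and
    the truth span.
    """
    matches = []
    for ev in truth:
        pos = positions[ev.region.chrom]
        candidates = [
            c
            for c in calls
            if c.sample_id == ev.sample_id and overlap_bp(c.region, ev.region) > 0
        ]
        if not candidates:
            matches.append(TruthMatch(ev, None, False, None))
            continue
        best = max(candidates, key=lambda c: overlap_bp(c.region, ev.region))
        truth_i0 = int(np.searchsorted(pos, ev.region.start, side="left"))
        truth_i1 = int(np.searchsorted(pos, ev.region.end, side="right")) - 1
        call_i0 = int(np.searchsorted(pos, best.region.start, side="left"))
        call_i1 = int(np.searchsorted(pos, best.region.end, side="right")) - 1
        err = max(abs(call_i0 - truth_i0), abs(call_i1 - truth_i1))
        matches.append(TruthMatch(ev, best, best.cnv_type == (
            "deletion" if ev.cn_state < 2 else "duplication"
        ), err))
    return matches
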