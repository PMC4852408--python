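"""CNV calling: segmentation of Viterbi paths, call-level QC and sample-level QC.

Call-level QC drops candidate events with a log10 Bayes factor below 30 or
fewer than 5 consecutive aberrant markers. Sample-level QC excludes samples
with more than 10 surviving calls or an LRR standard deviation above 0.3.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np

from .calls import CnvCall, MarkerSignalTable
from .hmm import HmmModel, log_bayes_factor, log_emission_matrix, _viterbi
from .intervals import GenomicInterval

__all__ = ["SampleQcResult", "segments_from_path", "call_cnvs", "sample_qc"]

DEFAULT_MIN_MARKERS = 5
DEFAULT_MIN_LBF = 30.0
DEFAULT_MAX_CALLS = 10
DEFAULT_MAX_LRR_SD = 0.3


@dataclass(frozen=True)
class SampleQcResult:
    sample_id: str
    n_calls: int
    lrr_sd: float
    max_calls: int = DEFAULT_MAX_CALLS
    max_lrr_sd: float = DEFAULT_MAX_LRR_SD

    @property
    def passed(self) -> bool:
        return self.n_calls <= self.max_calls and self.lrr_sd <= self.max_lrr_sd


def segments_from_path(
    path: np.ndarray,
    positions: np.ndarray,
    chrom: str,
    sample_id: str = "",
) -> list[CnvCall]:
    """Turn a per-marker state path into unscored candidate calls.

    Maximal runs of identical non-diploid states become candidates whose
    region spans the first to last marker of the run; ``lbf`` is left at 0.0
    until scored (see :func:`call_cnvs`).
    """
    path = np.asarray(path)
    positions = np.asarray(positions)
    if path.shape != positions.shape:
        raise ValueError("path and positions must be aligned")
    candidates: list[CnvCall] = []
    n = path.size
    i = 0
    while i < n:
        state = int(path[i])
        j = i
        while j + 1 < n and path[j + 1] == state:
            j += 1
        if state != 2:
            candidates.append(
                CnvCall(
                    sample_id=sample_id,
                    region=GenomicInterval(chrom, int(positions[i]), int(positions[j])),
                    cn_state=state,
                    lbf=0.0,
                    n_markers=j - i + 1,
                )
            )
        i = j + 1
    return candidates


def call_cnvs(
    signals: MarkerSignalTable,
    model: HmmModel | None = None,
    min_markers: int = DEFAULT_MIN_MARKERS,
    min_lbf: float = DEFAULT_MIN_LBF,
) -> list[CnvCall]:
    """Call CNVs for one sample: Viterbi segmentation plus call-level QC.

    Candidates with ``n_markers >= min_markers`` and ``lbf >= min_lbf`` are
    retained, sorted by (sample, chromosome, start). Deterministic given
    (signals, model, thresholds).
    """
    model = model or HmmModel()
    log_prior = np.log(model.state_priors)
    log_trans = model.log_transition
    calls: list[CnvCall] = []
    for chrom, positions, lrr, baf in signals.iter_chromosomes():
        log_em = log_emission_matrix(lrr, baf, model)
        path, _ = _viterbi(log_em, log_prior, log_trans)
        for cand in segments_from_path(path, positions, chrom, signals.sample_id):
            mask = (positions >= cand.region.start) & (positions <= cand.region.end)
            lbf = log_bayes_factor(lrr[mask], baf[mask], cand.cn_state, model)
            if cand.n_markers >= min_markers and lbf >= min_lbf:
                calls.append(replace(cand, lbf=lbf))
    return sorted(calls, key=CnvCall.sort_key)


def sample_qc(
    signals: MarkerSignalTable,
    calls: Iterable[CnvCall],
    max_calls: int = DEFAULT_MAX_CALLS,
    max_lrr_sd: float = DEFAULT_MAX_LRR_SD,
) -> SampleQcResult:
    """Sample-level QC on call count and LRR noise."""
    n_calls = sum(1 for _ in calls)
    return SampleQcResult(
        sample_id=signals.sample_id,
        n_calls=n_calls,
        lrr_sd=signals.lrr_sd(),
        max_calls=max_calls,
        max_lrr_sd=max_lrr_sd,
    )
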