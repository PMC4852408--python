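"""Rare-CNV prioritisation: annotation against tracks and the filter cascade.

A call survives the genome-wide pass when it simultaneously

* does not touch the telomeric/HLA exclusion track        (criterion I),
* overlaps at least one gene                              (criterion II),
* is not wholly contained in segmental duplications       (criterion III),
* has a control-cohort carrier frequency of at most 1 %   (criterion IV),
* has at most 10 matching DGV-like entries                (criterion V),
* and is at least 1.00 Mb after rounding (the size gate).

The region-targeted ("regional") pass re-evaluates calls that overlap a
track of disease-associated regions under the same five criteria with the
size gate lifted; calls already surviving genome-wide are reported only in
the genome-wide block, so the two survivor sets are disjoint.

The criteria are evaluated as a conjunction, so the outcome is independent
of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .calls import CnvCall, DgvRecord
from .intervals import AnnotationTrack, overlap_bp, reciprocal_overlap, size_mb

__all__ = [
    "ConfigurationError",
    "FilterParams",
    "FilterVerdict",
    "gene_count",
    "segdup_relation",
    "control_frequency",
    "dgv_entries",
    "genomewide_filter",
    "regional_filter",
    "survivors",
]

REQUIRED_TRACKS = ("genes", "segdups", "telomere_hla_exclusion")


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class FilterParams:
    """Cascade thresholds with the reference study's defaults.

    ``max_control_freq`` is the strict-exclusion boundary (">1 %" excludes, so
    exactly 1 % survives); ``min_size_mb`` applies to the genome-wide pass only
    and compares the *rounded* 2-decimal size, so a 996,392 bp call printed as
    1.00 Mb passes.
    """

    max_control_freq: float = 0.01
    max_dgv_entries: int = 10
    min_size_mb: float = 1.00
    min_recip_overlap: float = 0.5
    n_controls: int = 1307

    def __post_init__(self) -> None:
        if min(self.max_control_freq, self.max_dgv_entries, self.min_size_mb, self.min_recip_overlap) < 0:
            raise ValueError("thresholds must be >= 0")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")


@dataclass
class FilterVerdict:
    """Per-call annotation and cascade outcome."""

    call: CnvCall
    excluded_telomere_hla: bool
    gene_count: int
    segdup_relation: str  # none | partial | contained
    control_frequency: float
    dgv_entries: int
    size_mb: float
    pass_genomewide: bool = False
    matched_region: Optional[str] = None
    pass_regional: bool = False


def gene_count(call: CnvCall, genes: AnnotationTrack) -> int:
    """Number of gene intervals sharing >= 1 bp with the call."""
    return genes.count_overlapping(call.region)


def segdup_relation(call: CnvCall, segdups: AnnotationTrack) -> str:
    """Relation of the call to segmental duplications.

    ``contained`` - every base of the call lies in the union of segdups
    (unreliable call, excluded); ``partial`` - some but not all bases overlap
    (call kept, but qPCR confirmation is infeasible); ``none`` otherwise.
    """
    covered = segdups.coverage_bp(call.region)
    if covered == 0:
        return "none"
    return "contained" if covered == call.region.size else "partial"


def control_frequency(
    call: CnvCall,
    control_calls: Sequence[CnvCall],
    n_controls: int,
    min_recip: float = 0.5,
) -> float:
    """Fraction of control samples carrying a matching same-type call.

    A control call matches when it has the same CNV type and a reciprocal
    overlap of at least ``min_recip`` with the query.
    """
    if n_controls < 1:
        raise ValueError("n_controls must be >= 1")
    carriers = {
        c.sample_id
        for c in control_calls
        if c.cnv_type == call.cnv_type
        and reciprocal_overlap(c.region, call.region) >= min_recip
    }
    return len(carriers) / n_controls


def dgv_entries(call: CnvCall, dgv_records: Sequence[DgvRecord], min_recip: float = 0.5) -> int:
    """Count of same-type DGV-like records at >= ``min_recip`` reciprocal overlap."""
    return sum(
        1
        for rec in dgv_records
        if rec.cnv_type == call.cnv_type
        and reciprocal_overlap(rec.region, call.region) >= min_recip
    )


def _check_tracks(tracks: Mapping[str, AnnotationTrack]) -> None:
    for name in REQUIRED_TRACKS:
        if name not in tracks:
            raise ConfigurationError(f"missing annotation track: {name!r}")


def _annotate(
    call: CnvCall,
    tracks: Mapping[str, AnnotationTrack],
    control_calls: Sequence[CnvCall],
    dgv: Sequence[DgvRecord],
    params: FilterParams,
) -> FilterVerdict:
    verdict = FilterVerdict(
        call=call,
        excluded_telomere_hla=tracks["telomere_hla_exclusion"].count_overlapping(call.region) > 0,
        gene_count=gene_count(call, tracks["genes"]),
        segdup_relation=segdup_relation(call, tracks["segdups"]),
        control_frequency=control_frequency(
            call, control_calls, params.n_controls, params.min_recip_overlap
        ),
        dgv_entries=dgv_entries(call, dgv, params.min_recip_overlap),
        size_mb=size_mb(call.region),
    )
    criteria = (
        not verdict.excluded_telomere_hla
        and verdict.gene_count >= 1
        and verdict.segdup_relation != "contained"
        and verdict.control_frequency <= params.max_control_freq
        and verdict.dgv_entries <= params.max_dgv_entries
    )
    verdict.pass_genomewide = criteria and verdict.size_mb >= params.min_size_mb
    return verdict


def genomewide_filter(
    calls: Iterable[CnvCall],
    tracks: Mapping[str, AnnotationTrack],
    control_calls: Sequence[CnvCall],
    dgv: Sequence[DgvRecord],
    params: FilterParams | None = None,
) -> list[FilterVerdict]:
    """Annotate every call and apply criteria I-V plus the size gate.

    Returns one verdict per input call, sorted by (chromosome, start).
    """
    params = params or FilterParams()
    _check_tracks(tracks)
    verdicts = [_annotate(c, tracks, control_calls, dgv, params) for c in calls]
    return sorted(verdicts, key=lambda v: v.call.region.sort_key())


def regional_filter(
    calls: Iterable[CnvCall],
    beec_regions: AnnotationTrack,
    tracks: Mapping[str, AnnotationTrack],
    control_calls: Sequence[CnvCall],
    dgv: Sequence[DgvRecord],
    params: FilterParams | None = None,
) -> list[FilterVerdict]:
    """Region-targeted pass: criteria I-V with the size gate lifted.

    Only calls overlapping a disease-associated region by >= 1 bp are
    eligible; calls that already survive the genome-wide pass stay in that
    block (``pass_regional`` false), keeping the survivor sets disjoint.
    """
    params = params or FilterParams()
    _check_tracks(tracks)
    if len(beec_regions) == 0:
        raise ConfigurationError("disease-associated region track is empty")
    verdicts = []
    for call in calls:
        verdict = _annotate(call, tracks, control_calls, dgv, params)
        hits = beec_regions.overlapping(call.region)
        if hits:
            verdict.matched_region = hits[0].label or str(hits[0])
        criteria = (
            not verdict.excluded_telomere_hla
            and verdict.gene_count >= 1
            and verdict.segdup_relation != "contained"
            and verdict.control_frequency <= params.max_control_freq
            and verdict.dgv_entries <= params.max_dgv_entries
        )
        verdict.pass_regional = bool(hits) and criteria and not verdict.pass_genomewide
        verdicts.append(verdict)
    return sorted(verdicts, key=lambda v: v.call.region.sort_key())


def survivors(verdicts: Iterable[FilterVerdict], which: str = "genomewide") -> list[FilterVerdict]:
    """Convenience selector for surviving verdicts (``genomewide`` or ``regional``)."""
    if which == "genomewide":
        return [v for v in verdicts if v.pass_genomewide]
    if which == "regional":
        return [v for v in verdicts if v.pass_regional]
    raise ValueError(f"unknown survivor class {which!r}")
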