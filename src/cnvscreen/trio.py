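"""Trio segregation: confirmability flagging and inheritance classification.

A call is confirmable by qPCR unless it partially overlaps segmental
duplications (primer placement is then unreliable). For confirmable calls,
parental carrier status — from parental qPCR copy numbers or from parental
CNV calls — classifies the event as maternal, paternal or de novo; any
unknown parent leaves the call not confirmed. Both parents carrying the
event has no obvious single-parent label and is reported distinctly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .calls import CnvCall
from .filters import segdup_relation
from .intervals import AnnotationTrack, reciprocal_overlap

__all__ = [
    "TrioResult",
    "confirmable",
    "classify_inheritance",
    "carrier_from_calls",
    "segregate",
]

MATERNAL = "maternal"
PATERNAL = "paternal"
DE_NOVO = "de_novo"
NOT_CONFIRMED = "not_confirmed"
BIPARENTAL = "biparental_ambiguous"


@dataclass(frozen=True)
class TrioResult:
    call: CnvCall
    confirmable: bool
    inheritance: str

    def __post_init__(self) -> None:
        if not self.confirmable and self.inheritance != NOT_CONFIRMED:
            raise ValueError("non-confirmable calls must be labelled not_confirmed")


def confirmable(call: CnvCall, segdups: AnnotationTrack) -> bool:
    """False iff the call partially overlaps segmental duplications.

    Calls lying wholly inside segdups are assumed to have been excluded
    upstream (cascade criterion III), so containment is treated as
    confirmable here.
    """
    return segdup_relation(call, segdups) != "partial"


def classify_inheritance(
    call: CnvCall,
    mother_carrier: Optional[bool],
    father_carrier: Optional[bool],
) -> str:
    """Label the parental origin of a confirmable call.

    Symmetric: swapping the parents swaps maternal and paternal.
    """
    if mother_carrier is None or father_carrier is None:
        return NOT_CONFIRMED
    if mother_carrier and father_carrier:
        return BIPARENTAL
    if mother_carrier:
        return MATERNAL
    if father_carrier:
        return PATERNAL
    return DE_NOVO


def carrier_from_calls(
    call: CnvCall,
    parental_calls: Sequence[CnvCall],
    min_recip: float = 0.5,
) -> bool:
    """Carrier status inferred from a parent's own CNV calls.

    The parent carries the event when any of their same-type calls has at
    least ``min_recip`` reciprocal overlap with the child call.
    """
    return any(
        pc.cnv_type == call.cnv_type
        and reciprocal_overlap(pc.region, call.region) >= min_recip
        for pc in parental_calls
    )


def segregate(
    calls: Iterable[CnvCall],
    segdups: AnnotationTrack,
    parental_status: Mapping[str, tuple[Optional[bool], Optional[bool]]],
) -> list[TrioResult]:
    """Confirmability plus inheritance for a collection of calls.

    ``parental_status`` maps a child sample id to
    ``(mother_carrier, father_carrier)`` flags (``None`` = unknown/untested).
    """
    results = []
    for call in calls:
        ok = confirmable(call, segdups)
        if not ok:
            results.append(TrioResult(call, False, NOT_CONFIRMED))
            continue
        mother, father = parental_status.get(call.sample_id, (None, None))
        results.append(TrioResult(call, True, classify_inheritance(call, mother, father)))
    return results
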