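"""Genomic interval primitives and arithmetic.

Coordinates are 1-based and inclusive at both ends throughout the package,
which matches how CNV tables print positions (``22:16,114,244-17,294,251``).
BED files, which are 0-based half-open, are converted at the I/O boundary
(:mod:`cnvscreen.io`).

Chromosome labels are normalised by stripping a leading ``chr`` prefix;
``X``/``Y``/``MT`` are kept as letters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "AnnotationTrack",
    "normalize_chrom",
    "chrom_sort_key",
    "overlap_bp",
    "reciprocal_overlap",
    "size_mb",
    "round_half_away",
]


def normalize_chrom(chrom: str) -> str:
    """Strip a ``chr`` prefix and surrounding whitespace from a chromosome label."""
    chrom = str(chrom).strip()
    if chrom.lower().startswith("chr"):
        chrom = chrom[3:]
    if not chrom:
        raise ValueError("chromosome label must be non-empty")
    return chrom


def chrom_sort_key(chrom: str) -> tuple[int, int, str]:
    """Sort key placing autosomes numerically, then X, Y, MT, then other labels."""
    c = normalize_chrom(chrom)
    if c.isdigit():
        return (0, int(c), "")
    special = {"X": 23, "Y": 24, "MT": 25, "M": 25}
    if c.upper() in special:
        return (0, special[c.upper()], "")
    return (1, 0, c)


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round with ties going away from zero (unlike banker's rounding)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class GenomicInterval:
    """A 1-based, fully inclusive genomic span.

    ``start`` and ``end`` are both part of the interval, so a single base is
    represented as ``start == end`` and the size is ``end - start + 1``.
    """

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chrom", normalize_chrom(self.chrom))
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) must be >= start ({self.start})")

    @property
    def size(self) -> int:
        return self.end - self.start + 1

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.start, self.end, self.label)

    def same_span(self, other: "GenomicInterval") -> bool:
        return (self.chrom, self.start, self.end) == (other.chrom, other.start, other.end)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.chrom}:{self.start}-{self.end}"


def overlap_bp(a: GenomicInterval, b: GenomicInterval) -> int:
    """Number of bases shared by two intervals (0 on different chromosomes)."""
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start) + 1)


def reciprocal_overlap(a: GenomicInterval, b: GenomicInterval) -> float:
    """Fraction of the *smaller-covered* interval shared: min(ov/|a|, ov/|b|).

    Equals 1.0 iff the two spans are identical, and 0.0 iff they are disjoint.
    """
    ov = overlap_bp(a, b)
    if ov == 0:
        return 0.0
    return min(ov / a.size, ov / b.size)


def size_mb(a: GenomicInterval) -> float:
    """Interval size in megabases, rounded half-away-from-zero to 2 decimals.

    Uses integer arithmetic so printed-table sizes reproduce exactly
    (e.g. a 996,392 bp span rounds to 1.00 Mb).
    """
    return ((a.size + 5000) // 10000) / 100.0


class AnnotationTrack:
    """A named, sorted collection of intervals (genes, segdups, regions...).

    Intervals may overlap within a track. Overlap queries are served by a
    per-chromosome :class:`intervaltree.IntervalTree`.
    """

    def __init__(self, name: str, intervals: Iterable[GenomicInterval] = ()):
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(intervals, key=GenomicInterval.sort_key)
        self._trees: dict[str, IntervalTree] = {}
        for iv in self.intervals:
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            # intervaltree is half-open; store end+1 to keep inclusive semantics
            tree.addi(iv.start, iv.end + 1, iv)

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def overlapping(self, region: GenomicInterval) -> list[GenomicInterval]:
        """All track intervals sharing >= 1 bp with ``region``, in sorted order."""
        tree = self._trees.get(region.chrom)
        if tree is None:
            return []
        hits = [hit.data for hit in tree.overlap(region.start, region.end + 1)]
        return sorted(hits, key=GenomicInterval.sort_key)

    def count_overlapping(self, region: GenomicInterval) -> int:
        return len(self.overlapping(region))

    def coverage_bp(self, region: GenomicInterval) -> int:
        """Bases of ``region`` covered by the union of the track's intervals."""
        hits = self.overlapping(region)
        if not hits:
            return 0
        clipped = sorted(
            (max(h.start, region.start), min(h.end, region.end)) for h in hits
        )
        covered = 0
        cur_start, cur_end = clipped[0]
        for s, e in clipped[1:]:
            if s > cur_end + 1:
                covered += cur_end - cur_start + 1
                cur_start, cur_end = s, e
            else:
                cur_end = max(cur_end, e)
        covered += cur_end - cur_start + 1
        return covered
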