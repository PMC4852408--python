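"""Core record types: marker signal tables, CNV calls and DGV-like records."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, chrom_sort_key, normalize_chrom

__all__ = ["CnvCall", "DgvRecord", "MarkerSignalTable", "ValidationError"]

SIGNAL_COLUMNS = ["sample_id", "chrom", "position", "lrr", "baf"]


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class CnvCall:
    """A called copy-number event.

    ``cn_state`` is the integer copy number (0, 1, 3 or 4 — never the diploid
    2); ``lbf`` is the log10 Bayes factor of the called state against the
    diploid null summed over the segment; ``n_markers`` the number of
    consecutive aberrant markers supporting the call.
    """

    sample_id: str
    region: GenomicInterval
    cn_state: int
    lbf: float
    n_markers: int

    def __post_init__(self) -> None:
        if self.cn_state not in (0, 1, 3, 4):
            raise ValueError(f"cn_state must be in {{0,1,3,4}}, got {self.cn_state}")
        if self.n_markers < 1:
            raise ValueError("n_markers must be >= 1")

    @property
    def cnv_type(self) -> str:
        return "deletion" if self.cn_state < 2 else "duplication"

    def sort_key(self) -> tuple:
        return (self.sample_id, *self.region.sort_key())


@dataclass(frozen=True)
class DgvRecord:
    """A catalogued structural variant with a span and a type (DGV-like)."""

    region: GenomicInterval
    cnv_type: str  # "deletion" | "duplication"

    def __post_init__(self) -> None:
        if self.cnv_type not in ("deletion", "duplication"):
            raise ValueError(f"unknown cnv_type {self.cnv_type!r}")


class MarkerSignalTable:
    """Per-sample marker-level array signals: position, LRR and BAF.

    Positions must be strictly increasing within each chromosome, BAF must lie
    in [0, 1], and LRR must be finite; violations raise
    :class:`ValidationError`.
    """

    def __init__(self, sample_id: str, markers: pd.DataFrame):
        self.sample_id = str(sample_id)
        df = markers.copy()
        missing = [c for c in ("chrom", "position", "lrr", "baf") if c not in df.columns]
        if missing:
            raise ValidationError(f"signal table missing column(s): {', '.join(missing)}")
        df["chrom"] = df["chrom"].map(normalize_chrom)
        df["position"] = df["position"].astype(np.int64)
        df["lrr"] = df["lrr"].astype(float)
        df["baf"] = df["baf"].astype(float)
        if not np.isfinite(df["lrr"].to_numpy()).all():
            raise ValidationError(f"non-finite LRR values in sample {self.sample_id}")
        baf = df["baf"].to_numpy()
        if ((baf < 0) | (baf > 1)).any() or not np.isfinite(baf).all():
            raise ValidationError(f"BAF outside [0, 1] in sample {self.sample_id}")
        for chrom, grp in df.groupby("chrom", sort=False):
            pos = grp["position"].to_numpy()
            if (np.diff(pos) <= 0).any():
                raise ValidationError(
                    f"positions not strictly increasing on chromosome {chrom} "
                    f"(sample {self.sample_id})"
                )
        self.markers = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.markers)

    @property
    def chromosomes(self) -> list[str]:
        seen = dict.fromkeys(self.markers["chrom"])
        return sorted(seen, key=chrom_sort_key)

    def iter_chromosomes(self) -> Iterator[tuple[str, np.ndarray, np.ndarray, np.ndarray]]:
        """Yield ``(chrom, positions, lrr, baf)`` arrays, one chromosome at a time."""
        for chrom in self.chromosomes:
            grp = self.markers[self.markers["chrom"] == chrom]
            yield (
                chrom,
                grp["position"].to_numpy(),
                grp["lrr"].to_numpy(),
                grp["baf"].to_numpy(),
            )

    def lrr_sd(self) -> float:
        """Sample standard deviation (ddof=1) of LRR across all markers."""
        if len(self.markers) < 2:
            return 0.0
        return float(np.std(self.markers["lrr"].to_numpy(), ddof=1))
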