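"""Readers and writers for the plain-text formats the pipeline consumes.

All tabular formats are tab-separated with a header row; annotation tracks
are BED (0-based half-open, converted to the package's 1-based inclusive
convention on read and back on write).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .calls import CnvCall, DgvRecord, MarkerSignalTable, ValidationError
from .intervals import AnnotationTrack, GenomicInterval, round_half_away, size_mb

__all__ = [
    "BedParseError",
    "SchemaError",
    "read_bed",
    "write_bed",
    "read_signal_table",
    "read_signal_tables",
    "write_signal_table",
    "read_calls",
    "write_calls",
    "read_dgv",
    "read_pedigree",
    "read_qpcr",
    "write_report",
]

CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cn_state", "cnv_type", "lbf", "n_markers"]
REPORT_COLUMNS = [
    "block",
    "band",
    "position",
    "size_mb",
    "sample",
    "sex",
    "phenotype",
    "type",
    "genes",
    "inheritance",
    "control_frequency",
]


class BedParseError(ValueError):
    pass


class SchemaError(ValueError):
    pass


def read_bed(path: str | Path, name: str = "") -> AnnotationTrack:
    """Read a BED3+ file into an :class:`AnnotationTrack`.

    BED is 0-based half-open; records become 1-based inclusive intervals
    (``start + 1``, ``end`` unchanged). An optional 4th column is kept as the
    interval label. Records with ``end <= start`` are rejected.
    """
    path = Path(path)
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path.name}:{lineno}: expected >= 3 BED columns")
            chrom, raw_start, raw_end = fields[0], fields[1], fields[2]
            try:
                bed_start, bed_end = int(raw_start), int(raw_end)
            except ValueError as exc:
                raise BedParseError(f"{path.name}:{lineno}: non-integer coordinates") from exc
            if bed_end <= bed_start or bed_start < 0:
                raise BedParseError(
                    f"{path.name}:{lineno}: BED end must be > start (got {bed_start}, {bed_end})"
                )
            label = fields[3] if len(fields) > 3 else ""
            intervals.append(GenomicInterval(chrom, bed_start + 1, bed_end, label))
    return AnnotationTrack(name or path.stem, intervals)


def write_bed(track: AnnotationTrack, path: str | Path) -> None:
    """Write a track as BED; inverse of :func:`read_bed` (round-trip identity
    for canonical tab-separated BED with bare chromosome labels)."""
    with open(path, "w") as fh:
        for iv in track:
            fields = [iv.chrom, str(iv.start - 1), str(iv.end)]
            if iv.label:
                fields.append(iv.label)
            fh.write("\t".join(fields) + "\n")


def _read_tsv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{Path(path).name}: missing column(s): {', '.join(missing)}")
    return df


def read_signal_tables(path: str | Path) -> list[MarkerSignalTable]:
    """Read a signal TSV (sample_id, chrom, position, lrr, baf), one table per sample."""
    df = _read_tsv(path, ["sample_id", "chrom", "position", "lrr", "baf"])
    return [
        MarkerSignalTable(sample_id, grp.drop(columns="sample_id"))
        for sample_id, grp in df.groupby("sample_id", sort=False)
    ]


def read_signal_table(path: str | Path) -> MarkerSignalTable:
    """Like :func:`read_signal_tables` but requires exactly one sample."""
    tables = read_signal_tables(path)
    if len(tables) != 1:
        raise ValidationError(f"expected exactly one sample in {path}, found {len(tables)}")
    return tables[0]


def write_signal_table(tables: Iterable[MarkerSignalTable], path: str | Path) -> None:
    frames = []
    for table in tables:
        df = table.markers.copy()
        df.insert(0, "sample_id", table.sample_id)
        frames.append(df)
    out = pd.concat(frames) if frames else pd.DataFrame(columns=["sample_id", "chrom", "position", "lrr", "baf"])
    out.to_csv(path, sep="\t", index=False)


def read_calls(path: str | Path) -> list[CnvCall]:
    """Read a CNV call TSV into :class:`CnvCall` records (band kept as label)."""
    df = _read_tsv(path, ["sample_id", "chrom", "start", "end", "cn_state", "lbf", "n_markers"])
    calls = []
    for row in df.itertuples(index=False):
        label = str(getattr(row, "band", "") or "")
        call = CnvCall(
            sample_id=str(row.sample_id),
            region=GenomicInterval(row.chrom, int(row.start), int(row.end), label),
            cn_state=int(row.cn_state),
            lbf=float(row.lbf),
            n_markers=int(row.n_markers),
        )
        declared = str(getattr(row, "cnv_type", call.cnv_type))
        if declared != call.cnv_type:
            raise ValidationError(
                f"call {call.region}: cnv_type {declared!r} inconsistent with cn_state {call.cn_state}"
            )
        calls.append(call)
    return calls


def write_calls(calls: Iterable[CnvCall], path: str | Path) -> None:
    rows = [
        {
            "sample_id": c.sample_id,
            "chrom": c.region.chrom,
            "start": c.region.start,
            "end": c.region.end,
            "cn_state": c.cn_state,
            "cnv_type": c.cnv_type,
            "lbf": round(c.lbf, 3),
            "n_markers": c.n_markers,
            "band": c.region.label,
        }
        for c in calls
    ]
    pd.DataFrame(rows, columns=CALL_COLUMNS + ["band"]).to_csv(path, sep="\t", index=False)


def read_dgv(path: str | Path) -> list[DgvRecord]:
    """Read DGV-like records: chrom, start, end, cnv_type."""
    df = _read_tsv(path, ["chrom", "start", "end", "cnv_type"])
    return [
        DgvRecord(GenomicInterval(r.chrom, int(r.start), int(r.end)), str(r.cnv_type))
        for r in df.itertuples(index=False)
    ]


def read_pedigree(path: str | Path) -> pd.DataFrame:
    """Read a trio pedigree TSV: child, mother, father, sex, phenotype."""
    return _read_tsv(path, ["child", "mother", "father", "sex", "phenotype"])


def read_qpcr(path: str | Path) -> pd.DataFrame:
    """Read a qPCR Ct table: sample_id, assay (target|reference), replicate, ct."""
    df = _read_tsv(path, ["sample_id", "assay", "replicate", "ct"])
    bad = set(df["assay"]) - {"target", "reference"}
    if bad:
        raise SchemaError(f"unknown assay label(s): {sorted(bad)}")
    if (df["ct"] <= 0).any():
        raise ValidationError("Ct values must be positive")
    return df


def write_report(
    verdicts: Iterable,
    path: str | Path,
    *,
    trio_results: Optional[Iterable] = None,
    case_info: Optional[Mapping[str, Mapping[str, str]]] = None,
    seed: Optional[int] = None,
) -> None:
    """Write the survivor report, one row per surviving call.

    Genome-wide survivors come first (sorted by chromosome and start), then
    regional survivors, mirroring a two-block CNV table: band, position,
    size in Mb, carrier sample with sex/phenotype, aberration type, gene
    count, inheritance and control frequency.

    ``trio_results`` supplies inheritance labels; ``case_info`` supplies
    per-sample sex/phenotype. ``seed`` is recorded in a header comment.
    """
    inheritance: dict[tuple[str, str, int, int], str] = {}
    if trio_results is not None:
        for tr in trio_results:
            key = (tr.call.sample_id, tr.call.region.chrom, tr.call.region.start, tr.call.region.end)
            inheritance[key] = tr.inheritance
    case_info = case_info or {}

    def row(v, block: str) -> dict:
        c = v.call
        info = case_info.get(c.sample_id, {})
        key = (c.sample_id, c.region.chrom, c.region.start, c.region.end)
        return {
            "block": block,
            "band": c.region.label or v.matched_region or "",
            "position": f"{c.region.chrom}:{c.region.start}-{c.region.end}",
            "size_mb": f"{size_mb(c.region):.2f}",
            "sample": c.sample_id,
            "sex": info.get("sex", ""),
            "phenotype": info.get("phenotype", ""),
            "type": c.cnv_type,
            "genes": v.gene_count,
            "inheritance": inheritance.get(key, ""),
            "control_frequency": f"{round_half_away(v.control_frequency, 4):.4f}",
        }

    verdicts = list(verdicts)
    gw = sorted((v for v in verdicts if v.pass_genomewide), key=lambda v: v.call.region.sort_key())
    reg = sorted((v for v in verdicts if v.pass_regional), key=lambda v: v.call.region.sort_key())
    rows = [row(v, "genomewide") for v in gw] + [row(v, "regional") for v in reg]
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(fh, sep="\t", index=False)
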