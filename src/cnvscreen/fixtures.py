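"""Packaged worked-example fixture: 13 rare CNVs plus synthetic annotation.

The fixture bundles a published-style table of 13 rare CNVs found in a
cohort of 169 patients with the bladder exstrophy-epispadias complex
(7 from the genome-wide pass, 6 from the region-targeted pass), together
with *synthetic* gene, segmental-duplication, telomere/HLA-exclusion and
disease-region tracks, DGV-like records, control-cohort calls (denominator
1307) and decoy calls.

The tracks are synthetic stand-ins, not real RefSeq/segdup/DGV content:
they are constructed so that running the filter cascade on the fixture
reproduces the table's annotation pattern exactly — per-call gene counts,
partial segdup overlap for the three unconfirmable calls, and carrier
counts yielding the printed control frequencies at n = 1307.

Two rows carry documented size discrepancies between printed size and
coordinate-derived size (1q41: 0.16 vs 0.15; 9q34.2: 0.01 vs 0.00); both
printed and derived values are retained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import pandas as pd

from .calls import CnvCall, DgvRecord
from .filters import FilterParams
from .intervals import AnnotationTrack, GenomicInterval

__all__ = [
    "CaseInfo",
    "Table2Fixture",
    "FixtureBundle",
    "table2_fixture",
    "fixture_tracks",
    "decoy_calls",
    "fixture_trios",
    "fixture_pedigree",
]

N_CONTROLS = 1307

# hg19 chromosome lengths for the chromosomes the fixture touches
CHROM_LENGTHS: dict[str, int] = {
    "1": 249_250_621,
    "2": 243_199_373,
    "3": 198_022_430,
    "4": 191_154_276,
    "5": 180_915_260,
    "6": 171_115_067,
    "7": 159_138_663,
    "9": 141_213_431,
    "13": 115_169_878,
    "19": 59_128_983,
    "22": 51_304_566,
    "X": 155_270_560,
}

# band, chrom, start, end, printed Mb, patient, sex, phenotype, type,
# printed gene count, inheritance, printed control frequency, block
_ROWS = [
    ("4q26", "4", 117_047_226, 118_043_617, 1.00, "Pat5", "male", "E", "duplication", 2, "paternal", 0.0, "genomewide"),
    ("5q22.2", "5", 111_778_778, 112_842_992, 1.06, "Pat6", "female", "CBE", "duplication", 7, "paternal", 0.0, "genomewide"),
    ("13q33.1-q33.2", "13", 104_746_408, 106_422_213, 1.68, "Pat11", "male", "CBE", "deletion", 3, "maternal", 0.0, "genomewide"),
    ("Xq11.1-q13.1", "X", 62_038_249, 68_117_977, 6.08, "Pat17", "female", "CBE", "duplication", 43, "paternal", 0.0, "genomewide"),
    ("22q11.1", "22", 16_114_244, 17_294_251, 1.18, "Pat14", "female", "CBE", "duplication", 10, "n.c.", 0.0022, "genomewide"),
    ("Xp22.31", "X", 6_430_651, 8_135_053, 1.70, "Pat15", "female", "CBE", "duplication", 7, "maternal", 0.0008, "genomewide"),
    ("Xp22.31", "X", 6_436_087, 8_135_053, 1.70, "Pat16", "female", "CBE", "duplication", 7, "paternal", 0.0008, "genomewide"),
    ("1p36.33", "1", 1_385_211, 1_425_700, 0.04, "Pat19", "male", "CBE", "deletion", 2, "paternal", 0.0, "regional"),
    ("1p36.33", "1", 1_385_211, 1_425_700, 0.04, "Pat20", "female", "CBE", "deletion", 2, "maternal", 0.0, "regional"),
    ("1p36.33", "1", 1_415_012, 1_447_325, 0.03, "Pat21", "male", "E", "deletion", 1, "n.c.", 0.0008, "regional"),
    ("1q41", "1", 216_277_327, 216_431_962, 0.16, "Pat2", "male", "CBE", "deletion", 1, "maternal", 0.0, "regional"),
    ("9q34.2", "9", 136_128_546, 136_133_506, 0.01, "Pat9", "female", "CBE", "deletion", 1, "maternal", 0.0, "regional"),
    ("19q13.42", "19", 53_932_295, 54_010_277, 0.08, "Pat22", "female", "CBE", "deletion", 3, "n.c.", 0.0015, "regional"),
]

# calls whose qPCR confirmation is defeated by partial segdup overlap
SEGDUP_PARTIAL_SAMPLES = ("Pat14", "Pat21", "Pat22")

# parental carrier plan: child -> (mother_carrier, father_carrier); None = untestable
_TRIO_PLAN: dict[str, tuple[Optional[bool], Optional[bool]]] = {
    "Pat5": (False, True),
    "Pat6": (False, True),
    "Pat11": (True, False),
    "Pat17": (False, True),
    "Pat15": (True, False),
    "Pat16": (False, True),
    "Pat19": (False, True),
    "Pat20": (True, False),
    "Pat2": (True, False),
    "Pat9": (True, False),
    "Pat14": (None, None),
    "Pat21": (None, None),
    "Pat22": (None, None),
}

_XQ_GENES = [
    "SPIN4", "ARHGEF9", "AMER1", "ASB12", "MTMR8", "ZC4H2", "LAS1L", "MSN",
    "VSIG4", "HEPH", "GPR174", "ITM2A", "TBX22", "EDA", "AWAT2", "OTUD6A",
    "IGBP1", "DGAT2L6", "AWAT1", "P2RY4", "ARR3", "PDZD11", "KIF4A", "GDPD2",
    "RAB41", "NLGN3", "GJB1", "ZMYM3", "NONO", "ITGB1BP2", "TAF1", "OGT",
    "CXCR3", "NHSL2", "RGAG4", "PIN4", "ERCC6L", "EFNB1", "PJA1", "FAM155B",
    "EDA2R", "AR", "OPHN1",
]
_22Q_GENES = [
    "POTEH", "OR11H1", "CCT8L2", "XKR3", "GAB4", "BMS1P17", "BMS1P18",
    "POTEH-AS1", "DUXAP8", "CECR7",
]
_5Q_GENES = ["APC", "SRP19", "ZRSR1", "REEP5", "DCP2", "MCC", "TSSK1B"]
_XP_GENES = ["HDHD1", "STS", "VCX", "PNPLA4", "VCX2", "VCX3A", "VCX3B"]


@dataclass(frozen=True)
class CaseInfo:
    sample_id: str
    band: str
    sex: str
    phenotype: str
    inheritance_printed: str  # maternal | paternal | n.c.
    control_freq_printed: float
    size_mb_printed: float
    block: str  # genomewide | regional


@dataclass
class Table2Fixture:
    calls: list[CnvCall]
    info: dict[str, CaseInfo]

    @property
    def genomewide_calls(self) -> list[CnvCall]:
        return [c for c in self.calls if self.info[c.sample_id].block == "genomewide"]

    @property
    def regional_calls(self) -> list[CnvCall]:
        return [c for c in self.calls if self.info[c.sample_id].block == "regional"]


@dataclass
class FixtureBundle:
    tracks: dict[str, AnnotationTrack]
    beec_regions: AnnotationTrack
    dgv: list[DgvRecord]
    control_calls: list[CnvCall]
    params: FilterParams = field(default_factory=lambda: FilterParams(n_controls=N_CONTROLS))


def table2_fixture() -> Table2Fixture:
    """The packaged 13-call fixture with carrier metadata.

    Copy-number states are 3 for duplications and 1 for deletions; marker
    counts are derived from size at the platform's 2.1 kb median spacing.
    """
    calls = []
    info = {}
    for band, chrom, start, end, mb, pat, sex, pheno, cnv_type, _genes, inher, freq, block in _ROWS:
        region = GenomicInterval(chrom, start, end, label=band)
        n_markers = max(5, region.size // 2100)
        calls.append(
            CnvCall(
                sample_id=pat,
                region=region,
                cn_state=3 if cnv_type == "duplication" else 1,
                lbf=round(max(30.0, n_markers * 0.8), 1),
                n_markers=n_markers,
            )
        )
        info[pat] = CaseInfo(pat, band, sex, pheno, inher, freq, mb, block)
    return Table2Fixture(calls=calls, info=info)


def _tile(chrom: str, names: list[str], first_start: int, step: int, length: int) -> list[GenomicInterval]:
    return [
        GenomicInterval(chrom, first_start + i * step, first_start + i * step + length - 1, name)
        for i, name in enumerate(names)
    ]


def _gene_track() -> AnnotationTrack:
    genes: list[GenomicInterval] = [
        GenomicInterval("4", 117_500_000, 117_520_000, "TRAM1L1"),
        GenomicInterval("4", 117_700_000, 117_700_100, "MIR1973"),
        GenomicInterval("1", 1_390_000, 1_401_000, "ATAD3C"),
        GenomicInterval("1", 1_418_000, 1_431_000, "ATAD3B"),
        GenomicInterval("1", 216_200_000, 216_600_000, "USH2A"),
        GenomicInterval("9", 136_125_000, 136_150_300, "ABO"),
        GenomicInterval("19", 53_921_000, 53_957_000, "ZNF761"),
        GenomicInterval("19", 53_970_000, 53_998_000, "ZNF813"),
        GenomicInterval("19", 54_002_000, 54_009_000, "TPM3P9"),
        # genes inside decoy spans so each decoy fails exactly one criterion
        GenomicInterval("5", 200_000, 290_000, "TELG1"),
        GenomicInterval("7", 50_500_000, 50_600_000, "SDUPG1"),
        GenomicInterval("3", 60_400_000, 60_500_000, "FRQG1"),
        GenomicInterval("6", 70_400_000, 70_500_000, "DGVG1"),
        GenomicInterval("2", 100_200_000, 100_260_000, "SZG1"),
    ]
    genes += _tile("5", _5Q_GENES, 111_800_000, 140_000, 60_000)
    genes += _tile("13", ["DAOA", "DAOA-AS1", "LINC00343"], 104_900_000, 400_000, 100_000)
    genes += _tile("X", _XQ_GENES, 62_100_000, 130_000, 60_000)
    genes += _tile("22", _22Q_GENES, 16_450_000, 80_000, 30_000)
    # the two Xp22.31 duplications share these 7 genes (placed in their intersection)
    genes += _tile("X", _XP_GENES, 6_500_000, 220_000, 80_000)
    return AnnotationTrack("genes", genes)


def _segdup_track() -> AnnotationTrack:
    return AnnotationTrack(
        "segdups",
        [
            GenomicInterval("22", 16_000_000, 16_400_000, "SD_22q11"),
            GenomicInterval("1", 1_440_000, 1_470_000, "SD_1p36"),
            GenomicInterval("19", 53_900_000, 53_940_000, "SD_19q13"),
            GenomicInterval("7", 50_000_000, 52_000_000, "SD_decoy"),
        ],
    )


def _exclusion_track() -> AnnotationTrack:
    """Equivocal telomeric windows (100 kb per chromosome end) plus the HLA region."""
    intervals = [GenomicInterval("6", 28_477_797, 33_448_354, "HLA")]
    for chrom, length in CHROM_LENGTHS.items():
        intervals.append(GenomicInterval(chrom, 1, 100_000, f"tel_{chrom}p"))
        intervals.append(GenomicInterval(chrom, length - 99_999, length, f"tel_{chrom}q"))
    return AnnotationTrack("telomere_hla_exclusion", intervals)


def _beec_region_track() -> AnnotationTrack:
    """Previously disease-associated bands as nominal windows.

    Bands hosting a fixture regional CNV get a window guaranteed to contain
    it; the remainder are nominal ~2 Mb windows (band boundaries beyond
    containment affect nothing downstream).
    """
    windows = [
        ("1p36.33", "1", 1_000_000, 3_500_000),
        ("1q41", "1", 215_000_000, 217_500_000),
        ("2p15", "2", 61_000_000, 63_000_000),
        ("3q12.2-q13.2", "3", 100_000_000, 113_000_000),
        ("4p16.3", "4", 1, 2_000_000),
        ("5q21.1", "5", 92_000_000, 94_000_000),
        ("6q21", "6", 105_000_000, 107_000_000),
        ("7p15.1", "7", 28_000_000, 30_000_000),
        ("7p21.3", "7", 8_000_000, 10_000_000),
        ("9p24", "9", 1, 2_000_000),
        ("9q34.1-qter", "9", 131_000_000, 141_213_431),
        ("19p13.12", "19", 14_000_000, 16_000_000),
        ("19q13.42", "19", 53_500_000, 54_500_000),
        ("22q11.1", "22", 16_000_000, 18_000_000),
        ("22q11.21", "22", 18_650_000, 21_500_000),
        ("Xp22.12-pter", "X", 1, 21_000_000),
        ("Xp22.31", "X", 6_000_000, 8_500_000),
        ("Xq26.3-qter", "X", 133_000_000, 155_270_560),
    ]
    return AnnotationTrack(
        "beec_regions",
        [GenomicInterval(chrom, start, end, band) for band, chrom, start, end in windows],
    )


def _dgv_records() -> list[DgvRecord]:
    records = [
        # common-benign decoy: 11 matching deletion records
        DgvRecord(GenomicInterval("6", 70_000_000 + 2_000 * i, 71_150_000 - 1_000 * i), "deletion")
        for i in range(11)
    ]
    records += [
        DgvRecord(GenomicInterval("X", 62_038_249, 68_117_977), "duplication"),
        DgvRecord(GenomicInterval("X", 62_100_000, 68_000_000), "duplication"),
        DgvRecord(GenomicInterval("X", 62_000_000, 68_200_000), "duplication"),
        DgvRecord(GenomicInterval("22", 16_114_244, 17_294_251), "duplication"),
        DgvRecord(GenomicInterval("22", 16_100_000, 17_300_000), "duplication"),
    ]
    return records


def _control_calls() -> list[CnvCall]:
    """Control-cohort carriers yielding the printed frequencies at n = 1307.

    1 carrier of the Xp22.31 duplication (1/1307 -> 0.0008), 3 of the 22q11.1
    duplication (3/1307 -> 0.0023; printed as 0.0022), 1 of the small 1p36.33
    deletion, 2 of the 19q13.42 deletion, and 27 of the common decoy
    duplication (27/1307 ~ 2.1 % > 1 %).
    """

    def ctrl(sample: str, chrom: str, start: int, end: int, state: int) -> CnvCall:
        return CnvCall(sample, GenomicInterval(chrom, start, end), state, lbf=50.0, n_markers=50)

    calls = [ctrl("CTRL_X_01", "X", 6_430_651, 8_135_053, 3)]
    calls += [ctrl(f"CTRL_22_{i:02d}", "22", 16_114_244, 17_294_251, 3) for i in range(1, 4)]
    calls += [ctrl("CTRL_1P_01", "1", 1_415_012, 1_447_325, 1)]
    calls += [ctrl(f"CTRL_19_{i:02d}", "19", 53_932_295, 54_010_277, 1) for i in range(1, 3)]
    calls += [ctrl(f"CTRL_FRQ_{i:02d}", "3", 60_000_000, 61_200_000, 3) for i in range(1, 28)]
    return calls


def fixture_tracks(seed: int = 0) -> FixtureBundle:
    """Annotation tracks, DGV-like records and control calls for the fixture.

    Construction is fully deterministic; ``seed`` is accepted for interface
    symmetry with the simulators and does not alter the output.
    """
    del seed
    tracks = {
        "genes": _gene_track(),
        "segdups": _segdup_track(),
        "telomere_hla_exclusion": _exclusion_track(),
    }
    return FixtureBundle(
        tracks=tracks,
        beec_regions=_beec_region_track(),
        dgv=_dgv_records(),
        control_calls=_control_calls(),
    )


def decoy_calls() -> list[CnvCall]:
    """Negative controls: six calls, each violating exactly one cascade rule.

    In order: telomere/HLA overlap, no gene content, contained in segmental
    duplications, control frequency > 1 %, > 10 DGV entries, and below the
    1 Mb size gate while outside all disease-associated regions. None
    survives either pass.
    """

    def decoy(sample: str, chrom: str, start: int, end: int, state: int, tag: str) -> CnvCall:
        region = GenomicInterval(chrom, start, end, label=tag)
        return CnvCall(sample, region, state, lbf=60.0, n_markers=max(5, region.size // 2100))

    return [
        decoy("DEC_TEL", "5", 1, 1_210_000, 3, "decoy_telomere"),
        decoy("DEC_NOGENE", "2", 40_000_000, 41_100_000, 3, "decoy_geneless"),
        decoy("DEC_SEGDUP", "7", 50_200_000, 51_400_000, 1, "decoy_segdup_only"),
        decoy("DEC_FREQ", "3", 60_000_000, 61_200_000, 3, "decoy_common_in_controls"),
        decoy("DEC_DGV", "6", 70_000_000, 71_150_000, 1, "decoy_common_in_dgv"),
        decoy("DEC_SIZE", "2", 100_000_000, 100_500_000, 3, "decoy_sub_1mb"),
    ]


def fixture_trios() -> dict[str, tuple[Optional[bool], Optional[bool]]]:
    """Parental carrier plan per patient: (mother_carrier, father_carrier)."""
    return dict(_TRIO_PLAN)


def fixture_pedigree() -> pd.DataFrame:
    """Trio pedigree table for the fixture patients."""
    fixture = table2_fixture()
    rows = [
        {
            "child": pat,
            "mother": f"{pat}_M",
            "father": f"{pat}_F",
            "sex": info.sex,
            "phenotype": info.phenotype,
        }
        for pat, info in fixture.info.items()
    ]
    return pd.DataFrame(rows)
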