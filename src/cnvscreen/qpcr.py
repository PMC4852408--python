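"""Relative quantification of copy number from qPCR cycle thresholds (ΔΔCt).

For each sample, ΔCt = mean Ct(target) − mean Ct(reference); subtracting the
diploid calibrator's ΔCt gives ΔΔCt, and copy number follows as
CN = 2 · 2^(−ΔΔCt) — one cycle earlier at the target locus doubles its
dosage. Replicates are aggregated by arithmetic mean of Ct, with no outlier
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .intervals import round_half_away

__all__ = ["CopyNumberEstimate", "delta_delta_ct", "copy_number"]


@dataclass(frozen=True)
class CopyNumberEstimate:
    sample_id: str
    ddct: float
    cn_continuous: float
    cn_integer: int


def _delta_ct(measurements: pd.DataFrame, sample_id: str) -> float:
    sample = measurements[measurements["sample_id"] == sample_id]
    means = {}
    for assay in ("target", "reference"):
        ct = sample.loc[sample["assay"] == assay, "ct"]
        if ct.empty:
            raise ValueError(f"no {assay} replicates for sample {sample_id!r}")
        means[assay] = ct.mean()
    return float(means["target"] - means["reference"])


def delta_delta_ct(measurements: pd.DataFrame, calibrator_id: str) -> dict[str, float]:
    """ΔΔCt per sample against a diploid calibrator.

    ``measurements`` needs columns sample_id, assay (target|reference),
    replicate, ct (see :func:`cnvscreen.io.read_qpcr`). The calibrator itself
    is included in the output with ΔΔCt = 0 by construction.
    """
    calibrator_dct = _delta_ct(measurements, calibrator_id)
    return {
        str(sample_id): _delta_ct(measurements, sample_id) - calibrator_dct
        for sample_id in measurements["sample_id"].unique()
    }


def copy_number(ddct: float, sample_id: str = "") -> CopyNumberEstimate:
    """Copy number from ΔΔCt: CN = 2·2^(−ΔΔCt), integerised half-away-from-zero."""
    cn = 2.0 * 2.0 ** (-ddct)
    return CopyNumberEstimate(
        sample_id=sample_id,
        ddct=float(ddct),
        cn_continuous=cn,
        cn_integer=int(round_half_away(cn)),
    )
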