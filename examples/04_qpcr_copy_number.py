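"""Copy-number estimation from qPCR cycle thresholds via the ΔΔCt method.

Builds a small Ct table for a diploid calibrator, a deletion carrier and a
duplication carrier, computes ΔΔCt per sample against the calibrator and
converts to copy number (CN = 2·2^(−ΔΔCt)).
"""

import pandas as pd

from cnvscreen import copy_number, delta_delta_ct

rows = [
    # sample, assay, replicate, ct
    ("calibrator", "target", 1, 25.02), ("calibrator", "target", 2, 24.98),
    ("calibrator", "reference", 1, 20.01), ("calibrator", "reference", 2, 19.99),
    # deletion carrier: target amplifies one cycle late (half the template)
    ("del_carrier", "target", 1, 26.03), ("del_carrier", "target", 2, 25.97),
    ("del_carrier", "reference", 1, 20.00), ("del_carrier", "reference", 2, 20.00),
    # duplication carrier: target ~0.585 cycles early (1.5x the template)
    ("dup_carrier", "target", 1, 24.40), ("dup_carrier", "target", 2, 24.43),
    ("dup_carrier", "reference", 1, 20.00), ("dup_carrier", "reference", 2, 20.01),
]
measurements = pd.DataFrame(rows, columns=["sample_id", "assay", "replicate", "ct"])

for sample, ddct in delta_delta_ct(measurements, "calibrator").items():
    est = copy_number(ddct, sample)
    print(f"{sample:<11} ddct={est.ddct:+.3f}  CN={est.cn_continuous:.2f}  integer CN={est.cn_integer}")

print(
    "\nΔΔCt 0 -> CN 2 (diploid), +1 -> CN 1 (heterozygous deletion),"
    "\n-0.585 -> CN 3 (one extra copy); each qPCR cycle is a factor of two."
)
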