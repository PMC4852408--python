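"""Run the rare-CNV filter cascade on the packaged 13-CNV worked example.

Loads the packaged CNV table (13 calls from a bladder exstrophy-epispadias
cohort) plus six decoys that each violate one cascade rule, applies the
genome-wide five-criterion cascade with its 1 Mb size gate and the relaxed
region-targeted pass, and prints the survivor table.
"""

from cnvscreen import (
    decoy_calls,
    fixture_tracks,
    regional_filter,
    size_mb,
    survivors,
    table2_fixture,
)

fixture = table2_fixture()
bundle = fixture_tracks()
calls = fixture.calls + decoy_calls()

verdicts = regional_filter(
    calls, bundle.beec_regions, bundle.tracks, bundle.control_calls, bundle.dgv, bundle.params
)

for which in ("genomewide", "regional"):
    block = survivors(verdicts, which)
    print(f"\n{which} survivors ({len(block)}):")
    for v in block:
        c = v.call
        print(
            f"  {c.region.label:<14} {c.region!s:>28}  {size_mb(c.region):.2f} Mb  "
            f"{c.cnv_type:<11} genes={v.gene_count:<2} ctrl_freq={v.control_frequency:.4f}"
        )

print(
    "\nExpected: 7 genome-wide survivors (>1 Mb, rare, genic) and 6 regional"
    "\nsurvivors (<1 Mb deletions inside previously disease-associated bands);"
    "\nall 6 decoys are excluded, 4 of the 7 genome-wide calls are absent from"
    "\nthe 1,307-sample control cohort."
)
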