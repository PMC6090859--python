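"""Partition ortholog groups into photosynthesis-type clades; screen for
conserved CAM-specific genes.

Builds a synthetic ortholog table with a prescribed clade composition,
recovers that composition with the partitioner, then screens two candidate
genes against a homolog-presence panel of three independent CAM lineages
and three non-CAM species.
"""

import pandas as pd

from camrewire.clades import cam_specific_screen, partition_groups
from camrewire.simulate import CladeSpec, simulate_ortholog_table

roster = {
    "aam": "CAM", "ade": "CAM", "ate": "CAM",
    "ath": "C3", "osa": "C3",
    "zma": "C4",
    "ppa": "NVP",
}
spec = CladeSpec(roster, {"NVP:C3:CAM:C4": 6, "C3:CAM:C4": 5, "CAM-only": 4, "C3:C4": 3})
groups = simulate_ortholog_table(spec, seed=2)

by_clade, fractions = partition_groups(groups, roster)
for label in sorted(by_clade):
    print(f"{label:>15}: {len(by_clade[label])} groups")
print("\nper-species clade fractions (rows sum to 1):")
print(fractions.round(3).to_string())

presence = pd.DataFrame(
    [[True, True, True, False, False, False],
     [True, True, False, False, False, False]],
    index=["Aam048341", "Aam020007"],
    columns=["kfe", "aco", "peq", "ath", "osa", "zma"],
)
kept = cam_specific_screen(
    ["Aam048341", "Aam020007"],
    presence,
    cam_lineages=[["kfe"], ["aco"], ["peq"]],
    non_cam=["ath", "osa", "zma"],
)
print(f"\nconserved CAM-specific candidates kept: {kept}")

# Only the gene with homologs in all three independent CAM lineages and in
# none of the non-CAM panel species survives the screen.
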