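"""Profile the bundled secondary-screen EC50 panel.

Loads the 17-compound x 8-cell-line EC50 matrix (uM), applies the
broad-potency rule (<1 uM in every line), orders cell lines by clustering
their log10 potency profiles, ranks compounds by AMKL selectivity, and runs
the advancement gate (potent everywhere + FDA-approved + pediatric dose +
not already an AML drug).
"""

import screenkit as sk
from screenkit.datasets import (
    cell_line_subtypes,
    secondary_screen_annotations,
    secondary_screen_ec50,
)

panel = secondary_screen_ec50()
subtypes = cell_line_subtypes()
_, annotations = secondary_screen_annotations()

flagged = sk.flag_broad_potency(panel, cut=1.0)
print(f"broadly potent (<1 uM in all {panel.shape[1]} lines): "
      f"{len(flagged)} of {len(panel)} compounds")

order, _ = sk.cluster_cell_lines(panel)
print("cell lines ordered by potency-profile clustering:")
print("  " + "  ".join(f"{line}[{subtypes[line]}]" for line in order))

ranking = sk.subtype_selectivity(panel, subtypes, "AMKL")
top = ranking.index[0]
print(f"\nmost AMKL-selective compound: {top} "
      f"(non-AMKL/AMKL median EC50 ratio = {ranking.iloc[0].selectivity_ratio:.1f})")

print("\nadvancement decisions (ratio >1 favors AMKL; gate needs potency + clinical flags):")
for ann in annotations:
    decision = sk.advancement_flags(panel.loc[ann.compound_id], ann)
    if decision.advance:
        print(f"  ADVANCE {ann.compound_id}")
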