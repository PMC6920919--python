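"""Abundance classes, occupancy, and Levins niche breadth.

Classifies every OTU as abundant (>1% of all reads) / rare (<0.1%), counts
habitat occupancy, computes Levins' B_j = 1 / sum_i p_ij^2 (generalist if
B_j > 10, specialist if B_j < 5), prints the summary table, and scores the
calls against the generator's planted roles.
"""

from phyllonet import (
    classification_summary,
    generate_community,
    levins_index,
    occupancy,
    recovery_report,
)

table, metadata, truth = generate_community(seed=42)

niche = levins_index(table)
occ = occupancy(table, metadata)
print(classification_summary(table, metadata, niche=niche, occ=occ))

rep = recovery_report(truth, niche, occ)
print(f"\ngeneralist recovery: precision={rep.generalist_precision:.2f} "
      f"recall={rep.generalist_recall:.2f}")
print(f"specialist recovery: precision={rep.specialist_precision:.2f} "
      f"recall={rep.specialist_recall:.2f}")
print("(1.0 = every planted generalist/specialist is recovered exactly)")
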