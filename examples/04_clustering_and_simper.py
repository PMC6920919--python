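"""Bray-Curtis clustering and SIMPER decomposition.

Builds the sample dissimilarity matrix, the group-average (UPGMA)
dendrogram, cuts it at a 20% similarity level, and decomposes each
cluster's average within-group similarity into per-OTU contributions.
Air samples separate from leaf samples; the discriminating OTU set is the
smallest set accumulating 90% of the similarity.
"""

from phyllonet import (
    bray_curtis,
    cut_clusters,
    generate_community,
    simper,
    upgma_cluster,
)

table, metadata, _ = generate_community(seed=42)

d = bray_curtis(table)
tree = upgma_cluster(d)
clusters = cut_clusters(tree, similarity_percent=20)

for label in sorted(clusters.unique()):
    members = clusters.index[clusters == label]
    kinds = metadata.loc[members, "source"].value_counts().to_dict()
    print(f"cluster {label}: {len(members)} samples {kinds}")

res = simper(table, clusters)
for label, sim in res.average_similarity.items():
    disc = res.discriminating[label]
    print(f"\ncluster {label}: average within-group similarity {sim:.1f}%")
    print(f"  {len(disc)} OTUs reach the 90% cumulative cutoff; top 5:")
    print(res.contributions[label].head(5).round(2))
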