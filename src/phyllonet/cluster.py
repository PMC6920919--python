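"""Bray–Curtis dissimilarity, group-average clustering and SIMPER.

Samples are compared with the Bray–Curtis dissimilarity
:math:`d(x, y) = \\sum_k |x_k - y_k| / \\sum_k (x_k + y_k)` on (rarefied)
counts, clustered by group-average (UPGMA) agglomeration, and cut at a
percent-similarity level (similarity = 100·(1 − d)).  SIMPER decomposes
each cluster's average within-group percent similarity into additive
per-OTU contributions: for a sample pair (x, y), OTU k contributes
:math:`100 \\cdot 2\\min(x_k, y_k) / \\sum_m (x_m + y_m)`, and contributions
are averaged over all within-cluster pairs.  The OTUs "responsible for"
a cluster are those accumulating a cumulative-contribution cutoff
(default 90%).

UPGMA is implemented directly so the agglomeration order is fully
deterministic: at each step the pair at minimal distance merges, ties
broken by the lexicographically smallest member label.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .community import CommunityError, OtuTable


def bray_curtis(table: OtuTable) -> pd.DataFrame:
    """Pairwise Bray–Curtis dissimilarity matrix over samples."""
    if table.n_samples < 2:
        raise CommunityError("need at least 2 samples")
    x = table.counts.to_numpy(dtype=float).T
    zero = table.sample_sums() == 0
    if zero.any():
        raise CommunityError(
            f"all-zero sample(s): {list(table.sample_sums().index[zero])}"
        )
    d = squareform(pdist(x, metric="braycurtis"))
    return pd.DataFrame(d, index=table.sample_ids, columns=table.sample_ids)


@dataclass(frozen=True)
class Merge:
    height: float
    left: tuple[str, ...]   # leaf labels of each child, sorted
    right: tuple[str, ...]

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(sorted(self.left + self.right))


@dataclass(frozen=True)
class Dendrogram:
    """Binary merge tree; heights in dissimilarity units, non-decreasing."""

    leaves: tuple[str, ...]
    merges: tuple[Merge, ...]

    def __post_init__(self) -> None:
        heights = [m.height for m in self.merges]
        if any(b < a - 1e-12 for a, b in zip(heights, heights[1:])):
            raise CommunityError("merge heights must be non-decreasing")

    def to_newick(self) -> str:
        """Newick with ultrametric branch lengths (leaf depth = height/2)."""
        node = {(leaf,): (leaf, 0.0) for leaf in self.leaves}
        for m in self.merges:
            parts = []
            for child in (m.left, m.right):
                rep, h = node[child]
                parts.append(f"{rep}:{(m.height - h) / 2:.6g}")
            node[m.members] = (f"({parts[0]},{parts[1]})", m.height)
        root = node[self.merges[-1].members][0] if self.merges else self.leaves[0]
        return root + ";"


def upgma_cluster(d: pd.DataFrame) -> Dendrogram:
    """Group-average (UPGMA) agglomerative clustering of a dissimilarity matrix.

    Average linkage over all inter-cluster sample pairs; deterministic
    tie-break (smallest distance, then lexicographically smallest member
    label of the candidate pair).
    """
    arr = d.to_numpy(dtype=float)
    if arr.shape[0] != arr.shape[1] or not np.allclose(arr, arr.T, atol=1e-12):
        raise CommunityError("dissimilarity matrix must be square and symmetric")
    labels = [str(c) for c in d.columns]
    clusters: dict[tuple[str, ...], dict] = {
        (lab,): {"size": 1} for lab in labels
    }
    dist = {}
    for i, a in enumerate(labels):
        for j, b in enumerate(labels):
            if i < j:
                dist[frozenset([(a,), (b,)])] = arr[i, j]
    merges = []
    while len(clusters) > 1:
        best = min(
            (
                (dist[frozenset([a, b])], tuple(sorted(min(a, b) + max(a, b))), a, b)
                for a in clusters
                for b in clusters
                if a < b
            ),
            key=lambda t: (t[0], t[1]),
        )
        h, _, a, b = best
        left, right = sorted((a, b))
        merged = tuple(sorted(left + right))
        size_a, size_b = clusters[a]["size"], clusters[b]["size"]
        for other in list(clusters):
            if other in (a, b):
                continue
            dnew = (
                size_a * dist[frozenset([a, other])]
                + size_b * dist[frozenset([b, other])]
            ) / (size_a + size_b)
            dist[frozenset([merged, other])] = dnew
        del clusters[a], clusters[b]
        clusters[merged] = {"size": size_a + size_b}
        merges.append(Merge(height=float(h), left=left, right=right))
    return Dendrogram(leaves=tuple(labels), merges=tuple(merges))


def cut_clusters(tree: Dendrogram, similarity_percent: float) -> pd.Series:
    """Cluster assignment at a percent-similarity cut.

    Samples merging at heights strictly below ``1 - s/100`` share a
    cluster.  Labels are A, B, C, ... ordered by each cluster's first leaf
    in the tree's leaf order.
    """
    if not 0 < similarity_percent < 100:
        raise CommunityError("similarity_percent must be in (0, 100)")
    cutoff = 1.0 - similarity_percent / 100.0
    parent = {leaf: leaf for leaf in tree.leaves}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for m in tree.merges:
        if m.height < cutoff:
            ra, rb = find(m.left[0]), find(m.right[0])
            if ra != rb:
                parent[rb] = ra
    order, labels = {}, {}
    for leaf in tree.leaves:
        root = find(leaf)
        if root not in order:
            order[root] = chr(ord("A") + len(order))
        labels[leaf] = order[root]
    return pd.Series(labels, name="cluster").rename_axis("sample_id")


@dataclass(frozen=True)
class SimperResult:
    """Per-cluster SIMPER decomposition.

    ``average_similarity`` maps cluster label -> average within-group percent
    similarity; ``contributions`` maps label -> DataFrame (index otu_id,
    columns ``contribution, pct_of_total, cumulative_pct``, sorted by
    decreasing contribution); ``discriminating`` maps label -> the ordered
    OTU list reaching the cumulative cutoff.
    """

    average_similarity: dict
    contributions: dict
    discriminating: dict
    cutoff: float

    def solely_responsible(self, label: str) -> list[str]:
        """Discriminating OTUs of ``label`` not discriminating for any other
        cluster (an interpretation of cluster-exclusive drivers)."""
        others = {
            o for lab, otus in self.discriminating.items() if lab != label for o in otus
        }
        return [o for o in self.discriminating[label] if o not in others]


def simper(
    table: OtuTable, clusters: pd.Series, cutoff: float = 0.90
) -> SimperResult:
    """Within-cluster SIMPER on counts.

    Clusters with fewer than two samples are skipped with a warning.  The
    per-OTU contributions sum exactly to the cluster's average within-group
    similarity (0–100 scale).
    """
    avg, contrib, disc = {}, {}, {}
    for label in sorted(clusters.unique()):
        members = clusters.index[clusters == label].tolist()
        if len(members) < 2:
            warnings.warn(f"cluster {label!r} has < 2 samples; skipped in SIMPER")
            continue
        sub = table.counts[members].to_numpy(dtype=float)
        parts = []
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                x, y = sub[:, i], sub[:, j]
                denom = (x + y).sum()
                if denom == 0:
                    raise CommunityError(
                        f"pair of all-zero samples in cluster {label!r}"
                    )
                parts.append(100.0 * 2.0 * np.minimum(x, y) / denom)
        per_otu = np.mean(parts, axis=0)
        total = float(per_otu.sum())
        frame = (
            pd.DataFrame(
                {"contribution": per_otu}, index=table.counts.index
            )
            .rename_axis("otu_id")
            .sort_values("contribution", ascending=False, kind="mergesort")
        )
        frame["pct_of_total"] = (
            100.0 * frame["contribution"] / total if total > 0 else 0.0
        )
        frame["cumulative_pct"] = frame["pct_of_total"].cumsum()
        avg[label] = total
        contrib[label] = frame
        keep = frame[frame["contribution"] > 0]
        cum = 0.0
        chosen = []
        for otu, row in keep.iterrows():
            chosen.append(otu)
            cum += row["pct_of_total"]
            if cum >= 100.0 * cutoff:
                break
        disc[label] = chosen
    return SimperResult(avg, contrib, disc, cutoff)


def between_group_simper(
    table: OtuTable, clusters: pd.Series, label_a: str, label_b: str
) -> tuple[float, pd.DataFrame]:
    """Decompose the average between-group Bray–Curtis dissimilarity
    (0–100 scale) of two clusters into per-OTU |x_k − y_k| contributions."""
    a = clusters.index[clusters == label_a].tolist()
    b = clusters.index[clusters == label_b].tolist()
    if not a or not b:
        raise CommunityError("both clusters must be non-empty")
    sub = table.counts
    parts = []
    for sa in a:
        for sb in b:
            x = sub[sa].to_numpy(dtype=float)
            y = sub[sb].to_numpy(dtype=float)
            denom = (x + y).sum()
            parts.append(100.0 * np.abs(x - y) / denom)
    per_otu = np.mean(parts, axis=0)
    frame = (
        pd.DataFrame({"contribution": per_otu}, index=sub.index)
        .rename_axis("otu_id")
        .sort_values("contribution", ascending=False, kind="mergesort")
    )
    total = float(per_otu.sum())
    frame["pct_of_total"] = 100.0 * frame["contribution"] / total if total else 0.0
    frame["cumulative_pct"] = frame["pct_of_total"].cumsum()
    return total, frame
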