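"""Abundance classes, habitat occupancy and Levins niche-breadth classification.

Dataset-level abundance classes use strict thresholds on an OTU's share of
all reads: abundant (> 1%), rare (< 0.1%), everything else intermediate;
"local" variants apply the same cuts within each sample.

Niche breadth is Levins' index

.. math:: B_j = 1 / \\sum_{i=1}^{N} p_{ij}^2

where :math:`p_{ij}` is the share of OTU *j*'s reads found in sample *i*
and *N* the number of samples, so :math:`B_j` ranges from 1 (all reads in
one sample) to *N* (perfectly uniform).  OTUs with :math:`B_j > 10` are
called generalists and :math:`B_j < 5` specialists; the unnamed middle band
is labelled intermediate.  On a rarefied table the read-share
normalisation coincides with abundance-share normalisation.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
import pandas as pd

from .community import CommunityError, OtuTable

ABUNDANT_THRESHOLD = 0.01
RARE_THRESHOLD = 0.001
GENERALIST_THRESHOLD = 10.0
SPECIALIST_THRESHOLD = 5.0


def _abundance_category(frac: float, abundant: float, rare: float) -> str:
    if frac > abundant:
        return "abundant"
    if frac < rare:
        return "rare"
    return "intermediate"


def classify_abundance(
    table: OtuTable,
    abundant_threshold: float = ABUNDANT_THRESHOLD,
    rare_threshold: float = RARE_THRESHOLD,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overall and local (per-sample) abundance classes.

    Returns ``(overall, local)``: ``overall`` indexed by OTU with columns
    ``fraction`` (share of all reads in the dataset) and ``category``;
    ``local`` an OTU x sample frame of local categories from within-sample
    fractions.  Thresholds are strict, so an OTU at exactly 1% or 0.1% is
    intermediate.
    """
    total = table.counts.to_numpy().sum()
    if table.n_otus == 0 or total == 0:
        raise CommunityError("empty table")
    frac = table.otu_sums() / total
    overall = pd.DataFrame(
        {
            "fraction": frac,
            "category": [
                _abundance_category(f, abundant_threshold, rare_threshold)
                for f in frac
            ],
        }
    ).rename_axis("otu_id")
    local_frac = table.counts / table.sample_sums()
    local = local_frac.map(
        lambda f: "locally_" + _abundance_category(f, abundant_threshold, rare_threshold)
    )
    return overall, local


def occupancy(table: OtuTable, metadata: pd.DataFrame) -> pd.DataFrame:
    """Per-OTU habitat occupancy (seasons pooled) and air presence.

    Occupancy counts the plant-species habitats where the OTU has at least
    one read in either season; ``universal`` flags presence in every
    habitat, ``single_habitat`` presence in exactly one.  OTUs found only
    in air have occupancy 0 with ``present_in_air`` true.
    """
    leaf = metadata[metadata["source"] == "leaf"]
    habitats = leaf["habitat"].unique()
    occ = pd.DataFrame(0, index=table.counts.index, columns=habitats)
    for hab in habitats:
        cols = leaf.index[leaf["habitat"] == hab]
        occ[hab] = (table.counts[list(cols)].sum(axis=1) > 0).astype(int)
    air_cols = metadata.index[metadata["source"] == "air"]
    in_air = table.counts[list(air_cols)].sum(axis=1) > 0 if len(air_cols) else pd.Series(False, index=table.counts.index)
    n_occ = occ.sum(axis=1)
    return pd.DataFrame(
        {
            "n_habitats_occupied": n_occ,
            "present_in_air": in_air,
            "universal": n_occ == len(habitats),
            "single_habitat": n_occ == 1,
        }
    ).rename_axis("otu_id")


def occupancy_histogram(occ: pd.DataFrame) -> pd.DataFrame:
    """Occupancy distribution: OTU counts per habitat-occupancy level,
    split by air co-occurrence, plus the air-only level (occupancy 0)."""
    rows = []
    for k in range(int(occ["n_habitats_occupied"].max()) + 1):
        sub = occ[occ["n_habitats_occupied"] == k]
        rows.append(
            {
                "n_habitats": k,
                "n_otus": len(sub),
                "n_also_in_air": int(sub["present_in_air"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("n_habitats")


def levins_index(
    table: OtuTable,
    samples=None,
    generalist_threshold: float = GENERALIST_THRESHOLD,
    specialist_threshold: float = SPECIALIST_THRESHOLD,
) -> pd.DataFrame:
    """Levins niche breadth B_j per OTU with generalist/specialist calls.

    ``samples`` restricts the resource states considered (e.g. leaf-only);
    default is every sample in the table.  OTUs with no reads over the
    chosen samples are dropped.  Unequal sample depths trigger a warning —
    proportions are computed on read shares regardless.
    """
    sub = table.counts if samples is None else table.counts[list(samples)]
    sums = sub.sum(axis=0)
    if sums.nunique() > 1:
        warnings.warn(
            "samples have unequal depths; B_j computed on raw read shares"
        )
    totals = sub.sum(axis=1)
    keep = totals > 0
    if not keep.all():
        sub, totals = sub.loc[keep], totals[keep]
    p = sub.div(totals, axis=0)
    b = 1.0 / (p**2).sum(axis=1)
    # strict thresholds compare on a rounded value so that exact-boundary
    # compositions (e.g. uniform over 5 samples) are not misclassified by
    # floating-point noise
    b_cmp = b.round(9)
    category = pd.Series("intermediate", index=b.index)
    category[b_cmp > generalist_threshold] = "generalist"
    category[b_cmp < specialist_threshold] = "specialist"
    out = p.copy()
    out.columns = [f"p_{c}" for c in out.columns]
    out.insert(0, "B", b)
    out.insert(1, "category", category)
    return out.rename_axis("otu_id")


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero (the convention that
    reproduces the reported summary percentages)."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


def percentage(count: int, denominator: int) -> int | None:
    if denominator == 0:
        return None
    return round_half_away(100.0 * count / denominator)


def classification_summary(
    table: OtuTable,
    metadata: pd.DataFrame,
    abundance: pd.DataFrame | None = None,
    occ: pd.DataFrame | None = None,
    niche: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Dataset summary: named OTU counts with overall and within-group %.

    Overall percentages use the total OTU count as denominator; within-group
    percentages use the phyllosphere OTU count for leaf rows and the air OTU
    count for air rows.  Percentages are integers (half away from zero).
    Classifications are computed on the fly when not supplied.
    """
    if abundance is None:
        abundance, _ = classify_abundance(table)
    if occ is None:
        occ = occupancy(table, metadata)
    if niche is None:
        niche = levins_index(table)

    counts = table.counts
    leaf_cols = metadata.index[metadata["source"] == "leaf"]
    air_cols = metadata.index[metadata["source"] == "air"]

    def present(cols) -> pd.Series:
        return counts[list(cols)].sum(axis=1) > 0

    in_leaf, in_air = present(leaf_cols), present(air_cols)
    total = table.n_otus
    n_leaf, n_air = int(in_leaf.sum()), int(in_air.sum())

    def season_cols(cols, season):
        return [c for c in cols if metadata.loc[c, "season"] == season]

    cat = abundance["category"]
    niche_cat = niche["category"].reindex(counts.index)
    rows = [
        ("OTUs in the dataset", total, None, None),
        ("OTUs in the phyllosphere", n_leaf, total, None),
        ("OTUs in the air", n_air, total, None),
        ("Abundant OTUs (>1% of all reads)", int((cat == "abundant").sum()), total, None),
        ("Rare OTUs (<0.1% of all reads)", int((cat == "rare").sum()), total, None),
        ("Generalist OTUs (Levins B > 10)", int((niche_cat == "generalist").sum()), total, None),
        ("Specialist OTUs (Levins B < 5)", int((niche_cat == "specialist").sum()), total, None),
        ("OTUs on leaves in summer", int(present(season_cols(leaf_cols, "summer")).sum()), total, n_leaf),
        ("OTUs on leaves in winter", int(present(season_cols(leaf_cols, "winter")).sum()), total, n_leaf),
        ("OTUs in the air in summer", int(present(season_cols(air_cols, "summer")).sum()), total, n_air),
        ("OTUs in the air in winter", int(present(season_cols(air_cols, "winter")).sum()), total, n_air),
        ("Abundant OTUs on leaves", int(((cat == "abundant") & in_leaf).sum()), total, n_leaf),
        ("Rare OTUs on leaves", int(((cat == "rare") & in_leaf).sum()), total, n_leaf),
        ("Universal OTUs (all habitats)", int(occ["universal"].sum()), total, n_leaf),
        ("OTUs on only one habitat", int(occ["single_habitat"].sum()), total, n_leaf),
    ]
    out = pd.DataFrame(
        [
            {
                "count": n,
                "overall_pct": percentage(n, d_all) if d_all else None,
                "within_group_pct": percentage(n, d_grp) if d_grp else None,
            }
            for _, n, d_all, d_grp in rows
        ],
        index=pd.Index([r[0] for r in rows], name="otu_class"),
    )
    return out


def summary_percentages(count: int, overall_denominator: int, group_denominator: int | None = None):
    """Summary-table arithmetic for one row: (overall %, within-group %)."""
    return (
        percentage(count, overall_denominator),
        percentage(count, group_denominator) if group_denominator else None,
    )
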