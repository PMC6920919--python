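"""OTU count tables: data model, TSV I/O, filtering and rarefaction.

The analysis-ready object is an :class:`OtuTable` — a non-negative integer
read-count matrix (rows = OTUs, columns = samples) with optional taxonomy —
paired with a sample metadata frame mapping each sample to its source
(``leaf`` or ``air``), habitat (plant species, or ``"air"``) and season
(``summer`` or ``winter``).

Normalisation follows the conventional amplicon workflow: OTUs with a single
read in the entire dataset are removed first (suspected sequencing errors),
every sample is then rarefied (subsampled without replacement) to a common
depth, and finally OTUs whose lineage is chloroplast-derived or unclassified
at the domain level are dropped.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SOURCES = ("leaf", "air")
SEASONS = ("summer", "winter")

#: taxonomy substrings excluded after normalisation (case-insensitive);
#: chloroplast reads at any rank, plus domain-level unclassified OTUs.
DEFAULT_EXCLUDED_LABELS = ("chloroplast",)
DEFAULT_UNCLASSIFIED_LABELS = ("unclassified", "unknown")

TAXONOMY_RANKS = ("domain", "phylum", "class", "order", "closest_relative")


class CommunityError(ValueError):
    """Raised for invalid tables, metadata or infeasible operations."""


@dataclass(frozen=True)
class OtuTable:
    """Integer read-count matrix indexed by (otu_id, sample_id).

    Parameters
    ----------
    counts
        DataFrame of non-negative integers; index = OTU ids, columns =
        sample ids, both unique.
    taxonomy
        Optional DataFrame indexed by OTU id with columns
        ``domain, phylum, class, order, closest_relative`` (missing columns
        tolerated).
    provenance
        Free-form record of the filtering steps applied (depth, seed,
        removed-OTU counts); serialised alongside outputs.
    """

    counts: pd.DataFrame
    taxonomy: pd.DataFrame | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "counts", self.counts.rename_axis(index="otu_id", columns=None)
        )
        c = self.counts
        if c.index.has_duplicates:
            raise CommunityError("duplicate OTU ids in table")
        if c.columns.has_duplicates:
            raise CommunityError("duplicate sample ids in table")
        arr = c.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.allclose(arr, np.round(arr)):
                bad = np.argwhere(arr != np.round(arr))[0]
                raise CommunityError(
                    f"non-integer count at OTU {c.index[bad[0]]!r}, "
                    f"sample {c.columns[bad[1]]!r}"
                )
            object.__setattr__(self, "counts", c.astype(np.int64))
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            bad = np.argwhere(arr < 0)[0]
            raise CommunityError(
                f"negative count at OTU {c.index[bad[0]]!r}, "
                f"sample {c.columns[bad[1]]!r}"
            )

    # -- conveniences -------------------------------------------------
    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_otus(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def otu_sums(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def select_samples(self, sample_ids) -> "OtuTable":
        """Restrict to the given samples, keeping OTU rows (zeros retained)."""
        return replace(self, counts=self.counts.loc[:, list(sample_ids)])

    def select_otus(self, otu_ids) -> "OtuTable":
        return replace(self, counts=self.counts.loc[list(otu_ids)])

    def drop_empty_otus(self) -> "OtuTable":
        keep = self.counts.sum(axis=1) > 0
        return replace(self, counts=self.counts.loc[keep])


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample metadata frame (index sample_id; columns source,
    habitat, season) and return it with categorical checks applied.

    Habitat must be ``"air"`` exactly for air samples and a plant species
    name otherwise.
    """
    required = {"source", "habitat", "season"}
    missing = required - set(metadata.columns)
    if missing:
        raise CommunityError(f"metadata missing columns: {sorted(missing)}")
    if metadata.index.has_duplicates:
        dupes = metadata.index[metadata.index.duplicated()].tolist()
        raise CommunityError(f"duplicate sample ids in metadata: {dupes}")
    bad_source = set(metadata["source"]) - set(SOURCES)
    if bad_source:
        raise CommunityError(f"unknown source values: {sorted(bad_source)}")
    bad_season = set(metadata["season"]) - set(SEASONS)
    if bad_season:
        raise CommunityError(f"unknown season values: {sorted(bad_season)}")
    is_air = metadata["source"] == "air"
    if not (is_air == (metadata["habitat"] == "air")).all():
        bad = metadata.index[(is_air != (metadata["habitat"] == "air"))][0]
        raise CommunityError(
            f"sample {bad!r}: habitat must be 'air' iff source is 'air'"
        )
    return metadata


def _align_metadata(counts: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    absent = [s for s in counts.columns if s not in metadata.index]
    if absent:
        raise CommunityError(f"missing metadata for sample(s): {absent}")
    extra = [s for s in metadata.index if s not in counts.columns]
    if extra:
        logger.warning("metadata rows for unknown samples ignored: %s", extra)
    return metadata.loc[list(counts.columns)]


def read_otu_table(
    table_path,
    metadata_path,
    taxonomy_path=None,
) -> tuple[OtuTable, pd.DataFrame]:
    """Read an OTU table, its sample metadata and optional taxonomy.

    The table is tab-separated with OTU ids in the first column and sample
    ids in the header; metadata has columns
    ``sample_id, source, habitat, season``.  Metadata rows for samples not
    present in the table are ignored with a warning; a table sample with no
    metadata is a hard error.
    """
    counts = pd.read_csv(table_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    metadata = pd.read_csv(metadata_path, sep="\t", index_col="sample_id")
    metadata.index = metadata.index.astype(str)
    metadata = _align_metadata(counts, validate_metadata(metadata))
    taxonomy = None
    if taxonomy_path is not None:
        taxonomy = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
        taxonomy.index = taxonomy.index.astype(str)
    table = OtuTable(counts=counts, taxonomy=taxonomy)
    return table, metadata


def write_otu_table(
    table: OtuTable,
    table_path,
    metadata: pd.DataFrame | None = None,
    metadata_path=None,
    taxonomy_path=None,
    provenance_path=None,
) -> None:
    """Write table/metadata/taxonomy as TSV plus a JSON provenance sidecar."""
    table.counts.to_csv(table_path, sep="\t", index_label="otu_id")
    if metadata is not None and metadata_path is not None:
        metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")
    if table.taxonomy is not None and taxonomy_path is not None:
        table.taxonomy.to_csv(taxonomy_path, sep="\t", index_label="otu_id")
    if provenance_path is not None:
        with open(provenance_path, "w") as fh:
            json.dump(table.provenance, fh, indent=2, default=str)
            fh.write("\n")


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop OTUs with a single read in the entire dataset.

    Applied to the raw table before rarefaction; retained OTUs have total
    reads >= 2.  Removed ids are recorded in the provenance.
    """
    totals = table.otu_sums()
    keep = totals >= 2
    removed = totals.index[~keep].tolist()
    if not keep.any():
        warnings.warn("all OTUs are singletons; result is empty")
    prov = dict(table.provenance)
    prov["singletons_removed"] = len(removed)
    logger.info("remove_singletons: %d OTUs in, %d removed", len(totals), len(removed))
    return replace(table, counts=table.counts.loc[keep], provenance=prov)


def remove_excluded_taxa(
    table: OtuTable,
    excluded_labels=DEFAULT_EXCLUDED_LABELS,
    unclassified_labels=DEFAULT_UNCLASSIFIED_LABELS,
) -> OtuTable:
    """Drop chloroplast-annotated OTUs and OTUs unclassified at domain level.

    Matching is case-insensitive substring on the lineage for
    ``excluded_labels`` and on the ``domain`` column for
    ``unclassified_labels``; both lists are configurable.  Without taxonomy
    the call is a no-op with a warning.
    """
    if table.taxonomy is None:
        warnings.warn("no taxonomy available; remove_excluded_taxa is a no-op")
        return table
    tax = table.taxonomy.reindex(table.counts.index)
    lineage = tax.astype(str).agg(";".join, axis=1).str.lower()
    drop = pd.Series(False, index=table.counts.index)
    for label in excluded_labels:
        drop |= lineage.str.contains(label.lower(), regex=False)
    if "domain" in tax.columns:
        dom = tax["domain"].astype(str).str.lower()
        for label in unclassified_labels:
            drop |= dom.str.contains(label.lower(), regex=False) | (dom == "nan")
    prov = dict(table.provenance)
    prov["excluded_taxa_removed"] = int(drop.sum())
    logger.info("remove_excluded_taxa: %d OTUs dropped", int(drop.sum()))
    return replace(table, counts=table.counts.loc[~drop], provenance=prov)


def rarefy(table: OtuTable, depth: int | None = None, seed: int = 0) -> OtuTable:
    """Subsample every sample without replacement to a common depth.

    ``depth`` defaults to the minimum sample sum.  Sampling is a single
    multivariate-hypergeometric draw per sample (one draw per seed, not an
    average over draws); OTUs left with zero reads everywhere are dropped.
    Deterministic for a fixed seed.
    """
    sums = table.sample_sums()
    if depth is None:
        depth = int(sums.min())
    if depth <= 0:
        raise CommunityError("rarefaction depth must be positive")
    shallow = sums.index[sums < depth].tolist()
    if shallow:
        raise CommunityError(
            f"sample(s) {shallow} have fewer than {depth} reads; cannot rarefy"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy()
        if col.sum() == depth:
            out[sample] = col
        else:
            out[sample] = rng.multivariate_hypergeometric(col, depth)
    counts = pd.DataFrame(out, index=table.counts.index)
    prov = dict(table.provenance)
    prov.update(rarefaction_depth=depth, rarefaction_seed=seed)
    n_before = counts.shape[0]
    result = replace(table, counts=counts, provenance=prov).drop_empty_otus()
    prov["otus_lost_in_rarefaction"] = n_before - result.n_otus
    logger.info(
        "rarefy: depth=%d seed=%d, %d -> %d OTUs", depth, seed, n_before, result.n_otus
    )
    return result


def normalize_pipeline(
    table: OtuTable,
    metadata: pd.DataFrame,
    depth: int | None = None,
    seed: int = 0,
) -> tuple[OtuTable, pd.DataFrame]:
    """Full normalisation: singleton removal, rarefaction, taxon exclusion.

    Singletons go before rarefaction; chloroplast/domain-unclassified OTUs
    are excluded after, matching the order stated for the source workflow.
    """
    table = remove_singletons(table)
    table = rarefy(table, depth=depth, seed=seed)
    if table.taxonomy is not None:
        table = remove_excluded_taxa(table)
    metadata = _align_metadata(table.counts, metadata)
    return table, metadata


def leaf_samples(metadata: pd.DataFrame) -> list[str]:
    return metadata.index[metadata["source"] == "leaf"].tolist()


def air_samples(metadata: pd.DataFrame) -> list[str]:
    return metadata.index[metadata["source"] == "air"].tolist()
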