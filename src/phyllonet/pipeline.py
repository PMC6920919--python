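"""End-to-end orchestration: normalise → diversity → classify → cluster →
SIMPER → MIC networks → random-graph nulls, from one config, into a report
bundle of TSV/JSON/Newick/GraphML files with a run manifest.

Also hosts the air-load unit conversion: airborne gene-copy concentrations
measured per cubic metre are re-expressed per gram of air using the density
of air at sea level (1250 g m⁻³), making air and leaf community sizes
comparable on a per-weight basis.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from . import __version__
from .cluster import bray_curtis, cut_clusters, simper, upgma_cluster
from .community import (
    CommunityError,
    OtuTable,
    normalize_pipeline,
    read_otu_table,
    write_otu_table,
)
from .diversity import diversity_profile, seasonal_diversity_comparison
from .network import build_network, random_topology, topology
from .niche import classification_summary, classify_abundance, levins_index, occupancy, occupancy_histogram
from .simulate import SyntheticConfig, generate_community

logger = logging.getLogger(__name__)

AIR_DENSITY_G_PER_M3 = 1250.0


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))


def air_copies_per_gram(
    copies_per_m3: float, air_density_g_per_m3: float = AIR_DENSITY_G_PER_M3
) -> float:
    """Convert an airborne gene-copy concentration from per-m³ to per-gram
    of air, reported to 3 significant figures.

    Uses the density of air at sea level, ~1/800 that of water
    (1.25 kg m⁻³ = 1250 g m⁻³) by default.
    """
    if copies_per_m3 < 0 or air_density_g_per_m3 <= 0:
        raise CommunityError("concentration must be >= 0 and density > 0")
    return round_sig(copies_per_m3 / air_density_g_per_m3, 3)


@dataclass(frozen=True)
class PipelineConfig:
    """Full-run configuration; defaults mirror the package-wide conventions
    (strict 1%/0.1% abundance cuts, Levins 5/10, similarity cuts at 20% and
    35%, SIMPER cumulative 90%, MIC > 0.5)."""

    table_path: str | None = None
    metadata_path: str | None = None
    taxonomy_path: str | None = None
    simulate: SyntheticConfig | None = None
    rarefaction_depth: int | None = None
    rarefaction_seed: int = 0
    abundant_threshold: float = 0.01
    rare_threshold: float = 0.001
    specialist_threshold: float = 5.0
    generalist_threshold: float = 10.0
    cut_similarities: tuple[float, ...] = (20.0, 35.0)
    simper_cutoff: float = 0.90
    mic_threshold: float = 0.5
    mic_alpha: float = 0.6
    mic_clumps: int = 15
    network_min_samples: int = 5
    null_replicates: int = 20
    null_seed: int = 0
    output_dir: str = "phyllonet_out"

    def __post_init__(self) -> None:
        if self.simulate is None and (self.table_path is None or self.metadata_path is None):
            raise CommunityError("provide input paths or a simulate block")
        for s in self.cut_similarities:
            if not 0 < s < 100:
                raise CommunityError("cut similarities must be in (0, 100)")


@dataclass
class PipelineResult:
    table: OtuTable
    metadata: pd.DataFrame
    diversity: pd.DataFrame
    seasonal: pd.DataFrame
    summary: pd.DataFrame
    clusters: dict = field(default_factory=dict)
    simper: dict = field(default_factory=dict)
    networks: dict = field(default_factory=dict)
    topologies: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write the report bundle.

    Outputs under ``config.output_dir``: normalised table + provenance,
    per-sample diversity and seasonal comparisons, per-OTU classification,
    summary table, occupancy histogram, dissimilarity matrix, Newick
    dendrogram, cluster assignments, SIMPER reports, per-cluster edge lists,
    GraphML networks, a topology table with G(n, m) null columns, and a
    ``manifest.json`` recording seeds, thresholds and input checksums.
    Deterministic (byte-identical bundle) for a fixed config.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "phyllonet_version": __version__,
        "config": _config_dict(config),
        "stages": [],
    }

    # ---- input / simulation ------------------------------------------
    if config.simulate is not None:
        table, metadata, truth = generate_community(config.simulate)
        truth.to_json(out / "truth.json")
        raw_depths = None
    else:
        table, metadata = read_otu_table(
            config.table_path, config.metadata_path, config.taxonomy_path
        )
        manifest["inputs"] = {
            p: _sha256(Path(p))
            for p in (config.table_path, config.metadata_path, config.taxonomy_path)
            if p
        }
        raw_depths = table.sample_sums().to_dict()
        table, metadata = normalize_pipeline(
            table, metadata, depth=config.rarefaction_depth, seed=config.rarefaction_seed
        )
    manifest["stages"].append(
        {"stage": "input", "n_otus": table.n_otus, "n_samples": table.n_samples,
         "raw_depths": raw_depths, "provenance": table.provenance}
    )
    write_otu_table(
        table,
        out / "table.tsv",
        metadata,
        out / "metadata.tsv",
        taxonomy_path=(out / "taxonomy.tsv") if table.taxonomy is not None else None,
        provenance_path=out / "provenance.json",
    )

    # ---- diversity ---------------------------------------------------
    div = diversity_profile(table)
    div.to_csv(out / "diversity.tsv", sep="\t", float_format="%.6g")
    seasonal = seasonal_diversity_comparison(table, metadata)
    seasonal.to_csv(out / "seasonal_comparisons.tsv", sep="\t", float_format="%.6g")
    manifest["stages"].append({"stage": "diversity", "n_samples": len(div)})

    # ---- classification ----------------------------------------------
    abundance, _local = classify_abundance(
        table, config.abundant_threshold, config.rare_threshold
    )
    occ = occupancy(table, metadata)
    niche = levins_index(
        table,
        generalist_threshold=config.generalist_threshold,
        specialist_threshold=config.specialist_threshold,
    )
    per_otu = abundance.join(occ).join(niche[["B", "category"]].rename(columns={"category": "niche_category"}))
    per_otu.to_csv(out / "otu_classification.tsv", sep="\t", float_format="%.6g")
    occupancy_histogram(occ).to_csv(out / "occupancy_histogram.tsv", sep="\t")
    summary = classification_summary(table, metadata, abundance, occ, niche)
    summary.to_csv(out / "summary.tsv", sep="\t")
    manifest["stages"].append(
        {"stage": "classify",
         "abundant": int((abundance["category"] == "abundant").sum()),
         "rare": int((abundance["category"] == "rare").sum()),
         "generalists": int((niche["category"] == "generalist").sum()),
         "specialists": int((niche["category"] == "specialist").sum())}
    )

    # ---- clustering + SIMPER -----------------------------------------
    d = bray_curtis(table)
    d.to_csv(out / "bray_curtis.tsv", sep="\t", float_format="%.6g")
    tree = upgma_cluster(d)
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    clusters, simper_results = {}, {}
    for s in config.cut_similarities:
        assign = cut_clusters(tree, s)
        assign.to_csv(out / f"clusters_at_{s:g}pct.tsv", sep="\t")
        clusters[s] = assign
        res = simper(table, assign, cutoff=config.simper_cutoff)
        simper_results[s] = res
        for label, frame in res.contributions.items():
            frame.to_csv(
                out / f"simper_{s:g}pct_cluster_{label}.tsv",
                sep="\t", float_format="%.6g",
            )
    manifest["stages"].append(
        {"stage": "cluster",
         "cuts": {str(s): clusters[s].to_dict() for s in config.cut_similarities}}
    )

    # ---- networks + nulls --------------------------------------------
    primary_cut = config.cut_similarities[0]
    assign = clusters[primary_cut]
    res = simper_results[primary_cut]
    networks, topo_rows = {}, {}
    for label in sorted(assign.unique()):
        members = assign.index[assign == label].tolist()
        otus = res.discriminating.get(label, [])
        if len(members) < config.network_min_samples or len(otus) < 2:
            logger.warning(
                "cluster %s: %d samples / %d OTUs; network skipped",
                label, len(members), len(otus),
            )
            continue
        g = build_network(
            table, samples=members, otus=otus,
            mic_threshold=config.mic_threshold, alpha=config.mic_alpha,
            c=config.mic_clumps, min_samples=config.network_min_samples,
        )
        networks[label] = g
        nx.write_graphml(g, out / f"network_cluster_{label}.graphml")
        pd.DataFrame(
            [(u, v, d["mic"], d["rho"]) for u, v, d in g.edges(data=True)],
            columns=["otu_a", "otu_b", "mic", "rho"],
        ).to_csv(out / f"edges_cluster_{label}.tsv", sep="\t", index=False,
                 float_format="%.6g")
        if g.number_of_nodes() == 0:
            logger.warning("cluster %s: empty network; topology skipped", label)
            continue
        obs = topology(g).to_series()
        null = random_topology(
            g.number_of_nodes(), g.number_of_edges(),
            n_replicates=config.null_replicates, seed=config.null_seed,
        )
        topo_rows[f"cluster_{label}"] = obs
        topo_rows[f"random_{label}_mean"] = null["mean"].round(3)
        topo_rows[f"random_{label}_sd"] = null["sd"].round(3)
    topologies = pd.DataFrame(topo_rows) if topo_rows else None
    if topologies is not None:
        topologies.to_csv(out / "topology.tsv", sep="\t")
    manifest["stages"].append(
        {"stage": "network", "clusters_with_networks": sorted(networks)}
    )

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return PipelineResult(
        table=table, metadata=metadata, diversity=div, seasonal=seasonal,
        summary=summary, clusters=clusters, simper=simper_results,
        networks=networks, topologies=topologies, manifest=manifest,
    )


def _config_dict(config: PipelineConfig) -> dict:
    d = asdict(config)
    return d


def verify_bundle(result: PipelineResult, n_checks: int = 20, seed: int = 0) -> None:
    """Audit mode: re-derive a sample of report cells from their inputs.

    Recomputes summary percentages from counts and topology identities
    (density, average neighbours) from node/edge counts; raises on any
    mismatch.
    """
    from .niche import percentage

    rng = np.random.default_rng(seed)
    summary = result.summary
    total = int(summary.loc["OTUs in the dataset", "count"])
    rows = rng.choice(summary.index, size=min(n_checks, len(summary)), replace=False)
    for row in rows:
        n = int(summary.loc[row, "count"])
        pct = summary.loc[row, "overall_pct"]
        if pd.notna(pct) and row != "OTUs in the dataset":
            if int(pct) != percentage(n, total):
                raise CommunityError(f"summary row {row!r}: percentage mismatch")
    if result.topologies is not None:
        for col in result.topologies.columns:
            if col.startswith("cluster_"):
                t = result.topologies[col]
                n, m = int(t["nodes"]), int(t["edges"])
                if n > 1 and abs(t["density"] - round(2 * m / (n * (n - 1)), 3)) > 1e-9:
                    raise CommunityError(f"{col}: density does not recompute")
                if abs(t["avg_neighbors"] - round(2 * m / n, 3)) > 1e-9:
                    raise CommunityError(f"{col}: avg_neighbors does not recompute")
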