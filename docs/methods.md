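# Methods

This note documents the models and procedures phyllonet implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical choices made where the design was open.

## Data model and normalisation

The central object is an integer OTU-by-sample read-count matrix with a
metadata record per sample (source ∈ {leaf, air}; habitat = plant species
or "air"; season ∈ {summer, winter}). Normalisation follows the
conventional amplicon order:

1. OTUs with a single read in the whole dataset are removed *before*
   rarefaction (singletons are likely sequencing artefacts, and removing
   them first means they cannot consume rarefaction draws);
2. every sample is rarefied — subsampled **without replacement** (one
   multivariate-hypergeometric draw per sample) — to a common depth,
   defaulting to the minimum sample sum. A single draw is used per seed,
   not an average over draws; the seed defaults to 0 and is recorded in
   the output provenance. Replicated draws can be obtained by calling
   `rarefy` with different seeds;
3. chloroplast-annotated OTUs and OTUs unclassified at the domain level
   are dropped *after* rarefaction (so column sums may fall slightly below
   the depth in the final table; all downstream proportions are computed
   from the actual column sums).

## Alpha diversity and seasonal tests

Shannon entropy uses the natural logarithm (configurable base); Pielou's
J = H/ln S is undefined (NaN) for single-OTU samples; Simpson is reported
as 1−D. Seasonal contrasts are two-sided paired t-tests across habitat
(summer, winter) value pairs — d.f. = pairs − 1, so 8 for nine habitats.
Two degenerate inputs are handled explicitly: when one season is
identically zero for every pair the test degrades to a one-sample t-test
of the other season against 0; when the paired differences have zero
variance the result is flagged as a tie (t = 0, p = 1 if all differences
are zero, otherwise t undefined). No multiple-testing correction is
applied across attributes or taxa; users comparing many taxa should
adjust externally.

## Niche structure

Abundance classes use strict thresholds on the OTU's share of all reads
in the dataset: abundant > 1%, rare < 0.1%; an OTU at exactly a boundary
is "intermediate" (the class the thresholds leave unnamed). Local
variants use within-sample shares.

Levins' niche breadth for OTU j is B_j = 1/Σ_i p_ij², with p_ij the share
of OTU j's reads in sample i (row normalisation — identical to
abundance-share normalisation on an equal-depth table; a warning is
emitted for unequal depths). Generalist means B_j > 10, specialist
B_j < 5, both strict; the comparison is made on B rounded to 9 decimals
so exact-boundary compositions (e.g. uniform over 5 samples) are not
misclassified by floating-point noise. All samples (leaf and air) enter N
by default; a `samples=` argument restricts the resource states (e.g.
leaf-only) for sensitivity analysis.

Summary-table percentages are integers, rounded half away from zero;
overall percentages divide by the total OTU count, within-group
percentages by the phyllosphere or air OTU count.

## Clustering and SIMPER

Bray–Curtis dissimilarities are computed on rarefied counts without
transformation. The dendrogram is group-average (UPGMA) agglomeration —
ties broken by smallest distance, then lexicographically smallest member
label, making the merge order fully deterministic. Cutting at s%
similarity groups samples whose merge height is strictly below 1 − s/100.
Newick export places leaves at depth height/2 (ultrametric branch
lengths in dissimilarity units).

SIMPER: for each within-cluster sample pair, similarity is
100·(1 − Bray–Curtis), and OTU k contributes 100·2·min(x_k, y_k)/Σ(x+y);
per-OTU contributions are means over pairs, and they sum *exactly* to the
cluster's average within-group similarity (tested to 1e-9). The
"discriminating" set of a cluster collects OTUs in decreasing
contribution order until 90% cumulative contribution (configurable). The
OTUs "solely responsible" for a cluster are interpreted as the set
difference of its discriminating set against all other clusters'. A
between-group decomposition (mean |x_k − y_k| terms) is also provided.

## MIC and co-occurrence networks

MIC(x, y) is the maximum over grids (a columns × b rows, a·b ≤ B(n),
a, b ≥ 2) of the grid's mutual information divided by log₂ min(a, b).
The grid budget is B(n) = max(⌊n^0.6⌋, 4); the floor of 4 keeps the 2×2
grid admissible for short vectors (the raw n^0.6 bound would exclude
every grid for n ≤ 10). Grid lines never split tied values.

The search holds one axis fixed and optimises the other *exactly* by
dynamic programming over clumps (runs of tied values); the fixed axis is
itself searched exhaustively whenever its partitions number ≤ 200 —
always the case at the 9–20-sample scale this package targets, making
the score exact (verified against a brute-force enumeration of all
admissible grids) — and falls back to the near-equal equipartition
heuristic with superclump coarsening (clump factor c = 15) for longer
vectors. Both axis orientations are tried and the maximum taken.
Constant vectors score 0 with a warning. Permutation p-values use the
add-one estimator p = (1 + #{MIC_perm ≥ MIC_obs})/(1 + n_perm); at small
n the MIC null is discrete, so these p-values are valid (super-uniform)
but conservative.

An edge joins two OTUs when MIC > 0.5 **and** their Spearman rank
correlation is positive — MIC is sign-blind, so positivity of the
monotone trend is imposed separately to capture "strong positive
correlations". Network construction refuses groups of fewer than 5
samples by default (MIC on 2 points is degenerate); the minimum is an
explicit argument.

Topology follows the Cytoscape-style definitions: clustering coefficient
averages 2t/(k(k−1)) over all nodes with degree-<2 nodes contributing 0
(an exclude mode is not needed for the identities tested); diameter and
radius are the max/min eccentricity in the largest component; shortest
paths counts ordered reachable pairs; characteristic path length is the
mean distance over those pairs; centralization is
(N/(N−2))·(k_max/(N−1) − density), undefined for N < 3; heterogeneity is
the coefficient of variation of the degrees (population sd). Values are
presented to 3 decimals.

The null model is uniform G(n, m) at the observed node and edge counts
(disconnected outcomes allowed), summarised as mean ± sd over replicate
seeds; a degree-preserving double-edge-swap null (`rewired_null`) is
provided as an alternative.

## The synthetic community generator

The generator emulates a two-season survey of nine perennial plant
species plus one air sample per season, 5038 reads per sample. What it
produces, per OTU:

* a lognormal(0, 2) base abundance — a few dominant and many rare taxa;
* a planted role: **generalists** (default 1.5% of 1350 OTUs) occupy all
  habitats in both seasons with base abundances from a shifted lognormal
  (μ+4, 0.6σ) — real-world generalists are typically universal, abundant
  taxa; **specialists** (75%) have expected reads in exactly one habitat
  (air-only OTUs, 5%, are specialists with home habitat "air");
  **background** OTUs (the remainder) occupy exactly 4 habitats with a
  moderate abundance boost and narrower spread (μ+1.5, 0.5σ), reflecting
  the positive abundance–occupancy relationship. The 4-habitat cap bounds
  background niche breadth at 10 (8 leaf + 2 air samples), so only
  planted generalists can exceed the generalist threshold — mirroring
  communities where generalists are a qualitatively distinct handful;
* seasonal structure: specialists drop out of winter with the probability
  that makes the *expected per-sample richness ratio* equal
  `summer_richness_factor` (default 1.6); generalists and background
  carry coherent multiplicative seasonal abundance factors
  (lognormal, σ = 0.8) shared across habitats — these community-wide
  shifts, not the specialist turnover, are what give samples a seasonal
  Bray–Curtis signal;
* mild per-(OTU, habitat) abundance variation (lognormal, σ = 0.35).

Air samples are a thinned image of the pooled leaf community plus an
air-only block: each leaf OTU enters the air with probability
1 − exp(−pool_i/τ), with τ solved so the expected air support is
`air_thinning` (default 0.10) of the season's pooled richness — abundant
taxa almost surely reach the air, rare ones rarely — then distorted by a
per-OTU airborne propensity (lognormal, σ = 2), with the air-only block
weighted equal to the included leaf mass. Counts are one multinomial draw
of the depth per sample, so column sums equal the depth exactly and the
empirical proportions converge to the expected ones as depth grows.

At the defaults this yields ≈1000 observed OTUs, mean leaf richness
≈200 (summer) / ≈140 (winter), and air richness ≈120–160 (summer) /
≈90 (winter) — the qualitative profile of a Mediterranean-type
phyllosphere survey: summer-enriched richness, species-poor air, heavy
specialist occupancy. Air samples separate from leaf samples in the
UPGMA tree at the 20% similarity cut; seasonal leaf blocks appear at
higher similarity cuts (≈50%) rather than at 35%, a known difference
between the simplified generator and field data.

What the generator does **not** emulate: sequence-level error and
chimeras, phylogenetic correlation among OTUs, spatial or interannual
structure, taxon-specific interactions beyond shared habitat masks, and
any calibrated air-community abundance model (the thinning and propensity
parameters are free choices, not estimates). Passing recovery tests on
this generator therefore show that the classification chain is correct
and well-calibrated *under the planted model*, not that real communities
satisfy its assumptions.

## Recovery scoring

`recovery_report` scores Levins-category calls one-vs-rest against
planted roles over the OTUs retained in the observed table: precision and
recall for generalists and for specialists, plus an occupancy confusion
table. Rare background OTUs observed in only 1–2 samples are genuine
confounders (they look like specialists at any finite depth) and are
counted as errors; classes with no planted members report
not-applicable (None). On the noise-free expected-proportion table the
recovery is exact.

## Problem sizes and determinism

The test suite and the acceptance script run the stochastic checks over
50 generator seeds at the default design (20 samples × ~1350 planted
OTUs, depth 5038), networks over the 40 most abundant summer OTUs, and
nulls over 20 G(n, m) replicates — sizes chosen so a full run completes
in minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins. All randomness flows from explicit integer seeds
(numpy `default_rng`); identical config + seed reproduces every table,
tree, network and report byte for byte.

## Known limitations

* MIC falls back to the equipartition heuristic for long vectors
  (> ~20 observations with distinct values), where the score is a lower
  bound on the exact grid maximum — the standard behaviour of MINE-style
  estimators.
* SIMPER contributions are computed on counts; no standardisation or
  transformation options are provided.
* The paired t-tests assume approximately normal habitat differences;
  with nine pairs the tests are robust but not assumption-free.
* `classification_summary` mirrors a fixed report layout; bespoke
  summaries should be assembled from the per-OTU frames.
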