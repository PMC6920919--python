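"""Synthetic seasonal phyllosphere/air communities with planted ground truth.

The generator emulates the sampling design the downstream analysis assumes:
nine plant-species habitats sampled in summer and winter (one pooled leaf
sample per habitat and season) plus one air sample per season, every sample
carrying the same fixed read depth.  OTU base abundances are lognormal (a
few dominant taxa, a long rare tail); each OTU is planted as a

* **generalist** — present in all habitats and both seasons with near-uniform
  expected abundance, drawn from the upper abundance range (real-world
  generalists are typically universal, abundant taxa);
* **specialist** — expected reads in exactly one home habitat (air-only
  OTUs are specialists with home habitat ``"air"``); or
* **background** — present in a middling number of habitats (3–4) with a
  positive abundance–occupancy boost (widespread taxa tend to be more
  abundant).  Capping background occupancy at four habitats (eight leaf
  samples plus at most two air samples) bounds their attainable niche
  breadth at 10, so only planted generalists can exceed the generalist
  threshold.

Winter samples lose a random subset of specialists (dropout probability
1 − 1/``summer_richness_factor``) and attenuate background OTUs, so
expected summer richness exceeds winter richness.  Air communities are a
thinned draw of the pooled leaf community plus an air-only OTU block,
giving species-poor air samples.

Counts are one multinomial draw of ``depth`` reads per sample from the
sample's expected relative abundances, so column sums equal the depth by
construction.  Everything is deterministic per seed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .community import SEASONS, CommunityError, OtuTable, validate_metadata

HABITAT_NAMES = (
    "Quercus_coccifera",
    "Pistacia_lentiscus",
    "Phillyrea_latifolia",
    "Arbutus_unedo",
    "Myrtus_communis",
    "Olea_europaea",
    "Ceratonia_siliqua",
    "Cistus_creticus",
    "Sarcopoterium_spinosum",
)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic community design.

    Defaults reproduce the study design emulated throughout the package:
    9 habitats x 2 seasons + 1 air sample per season at depth 5038, 1350
    planted OTUs with lognormal(0, 2) base abundances, ~1.5% planted
    generalists, 75% single-habitat specialists, a 1.6-fold summer
    richness excess, coherent seasonal abundance shifts in the persistent
    taxa, and species-poor, compositionally distinct air communities.
    """

    n_habitats: int = 9
    n_air_samples_per_season: int = 1
    depth: int = 5038
    n_otus: int = 1350
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    frac_generalists: float = 0.015
    frac_single_habitat: float = 0.75
    background_min_habitats: int = 4
    background_max_habitats: int = 4
    background_mu_shift: float = 1.5
    summer_richness_factor: float = 1.6
    seasonal_sigma: float = 0.8
    air_thinning: float = 0.10
    frac_air_only: float = 0.05
    air_only_weight: float = 1.0
    air_distortion_sigma: float = 2.0
    generalist_mu_shift: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frac_generalists + self.frac_single_habitat > 1:
            raise CommunityError(
                "frac_generalists + frac_single_habitat must be <= 1"
            )
        if self.summer_richness_factor < 1:
            raise CommunityError("summer_richness_factor must be >= 1")
        if self.depth <= 0 or self.n_otus <= 0 or self.n_habitats <= 0:
            raise CommunityError("depth, n_otus and n_habitats must be positive")

    def habitat_names(self) -> list[str]:
        base = list(HABITAT_NAMES)
        while len(base) < self.n_habitats:
            base.append(f"Habitat_{len(base) + 1}")
        return base[: self.n_habitats]


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted per-OTU roles plus the expected-abundance matrix.

    ``roles`` maps otu_id -> {generalist, specialist, background};
    ``home_habitat`` is set for specialists (``"air"`` for air-only ones);
    ``seasonal_bias`` is the multiplicative winter factor (0 = summer-only,
    1 = aseasonal).
    ``expected`` holds each sample's expected relative-abundance vector —
    the noise-free community the multinomial draws converge to.
    """

    roles: pd.Series
    home_habitat: pd.Series
    seasonal_bias: pd.Series
    expected: pd.DataFrame
    config: SyntheticConfig
    seed: int

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "config": asdict(self.config),
            "roles": self.roles.to_dict(),
            "home_habitat": {
                k: (None if pd.isna(v) else v) for k, v in self.home_habitat.items()
            },
            "seasonal_bias": self.seasonal_bias.to_dict(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")


def _expected_matrix(config: SyntheticConfig, rng: np.random.Generator):
    """Build per-sample expected relative abundances and the truth labels."""
    n = config.n_otus
    habitats = config.habitat_names()
    n_gen = max(1, round(config.frac_generalists * n)) if config.frac_generalists else 0
    n_spec = round(config.frac_single_habitat * n)
    n_air_only = round(config.frac_air_only * n)
    n_bg = n - n_gen - n_spec - n_air_only
    if n_bg < 0:
        raise CommunityError("role fractions exceed the OTU budget")

    otu_ids = [f"OTU{i + 1:04d}" for i in range(n)]
    # air-only OTUs are specialists whose home habitat is the air
    roles = np.array(
        ["generalist"] * n_gen
        + ["specialist"] * n_spec
        + ["background"] * n_bg
        + ["specialist"] * n_air_only
    )

    base = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, size=n)
    # generalists sit in the upper abundance range, moderately even;
    # background taxa get an abundance-occupancy boost (widespread taxa
    # tend to be more abundant than narrow-range ones)
    base[:n_gen] = rng.lognormal(
        config.lognormal_mu + config.generalist_mu_shift,
        config.lognormal_sigma * 0.3,
        size=n_gen,
    )
    bg_slice = slice(n_gen + n_spec, n_gen + n_spec + n_bg)
    base[bg_slice] = rng.lognormal(
        config.lognormal_mu + config.background_mu_shift,
        config.lognormal_sigma * 0.5,
        size=n_bg,
    )

    # habitat occupancy mask (leaf habitats only)
    mask = np.zeros((n, config.n_habitats), dtype=float)
    mask[:n_gen, :] = 1.0
    home = np.full(n, None, dtype=object)
    spec_idx = np.arange(n_gen, n_gen + n_spec)
    spec_home = rng.integers(0, config.n_habitats, size=n_spec)
    mask[spec_idx, spec_home] = 1.0
    home[spec_idx] = [habitats[h] for h in spec_home]
    bg_idx = np.arange(n_gen + n_spec, n_gen + n_spec + n_bg)
    for i in bg_idx:
        k = rng.integers(
            config.background_min_habitats, config.background_max_habitats + 1
        )
        occ = rng.choice(config.n_habitats, size=k, replace=False)
        mask[i, occ] = 1.0
    home[n - n_air_only:] = "air"
    # air-only OTUs never occupy a leaf habitat (mask row stays zero)

    # mild per-(OTU, habitat) abundance variation so generalists are not
    # perfectly uniform across habitats
    hab_noise = rng.lognormal(0.0, 0.35, size=(n, config.n_habitats))

    # winter retention: specialists drop out of winter at the rate that
    # makes the expected per-sample richness ratio equal the configured
    # summer_richness_factor (generalists and background stay, the latter
    # attenuated), i.e. q = S_summer (1 - 1/f) / A with S_summer the
    # expected per-habitat support and A its specialist part
    winter = np.ones(n)
    k_mean = 0.5 * (config.background_min_habitats + config.background_max_habitats)
    per_habitat = (
        n_gen
        + n_spec / config.n_habitats
        + n_bg * k_mean / config.n_habitats
    )
    spec_per_habitat = n_spec / config.n_habitats
    f = config.summer_richness_factor
    q = 0.0
    if f > 1 and spec_per_habitat > 0:
        q = min(0.95, per_habitat * (1.0 - 1.0 / f) / spec_per_habitat)
    dropout = rng.random(n) < q
    winter[spec_idx] = np.where(dropout[spec_idx], 0.0, 1.0)
    # community-wide seasonal abundance shifts: persistent taxa wax or wane
    # between seasons coherently across habitats, which is what makes
    # samples cluster by season rather than by habitat
    winter[:n_gen] = np.exp(rng.normal(0.0, config.seasonal_sigma, size=n_gen))
    winter[bg_slice] = np.exp(rng.normal(0.0, config.seasonal_sigma, size=n_bg))

    samples, meta_rows, cols = [], [], []
    for season in SEASONS:
        sfac = winter if season == "winter" else np.ones(n)
        for h, hab in enumerate(habitats):
            expected = base * mask[:, h] * hab_noise[:, h] * sfac
            if expected.sum() <= 0:
                raise CommunityError(
                    f"no OTUs eligible for habitat {hab!r} in {season}"
                )
            sid = f"{hab}_{season[0].upper()}"
            samples.append(expected / expected.sum())
            meta_rows.append(("leaf", hab, season))
            cols.append(sid)

    # air: thinned pooled leaf community + air-only block
    leaf_pool = {
        s: np.mean(
            [v for v, (src, _, se) in zip(samples, meta_rows) if se == s], axis=0
        )
        for s in SEASONS
    }
    air_only_idx = np.arange(n - n_air_only, n)
    air_base = np.zeros(n)
    air_base[air_only_idx] = rng.lognormal(
        config.lognormal_mu, config.lognormal_sigma, size=n_air_only
    )
    if air_base.sum() > 0:
        air_base = air_base / air_base.sum()
    # airborne propensity: how well a leaf taxon aerosolises is only loosely
    # related to its leaf abundance, so air composition is a strongly
    # distorted image of the pooled phyllosphere
    propensity = np.exp(rng.normal(0.0, config.air_distortion_sigma, size=n))
    for season in SEASONS:
        # abundance-dependent inclusion: abundant leaf taxa almost surely
        # reach the air, rare ones rarely do; tau is solved so the expected
        # air support is air_thinning * n_otus
        pool = leaf_pool[season]
        target = config.air_thinning * (pool > 0).sum()
        lo, hi = 1e-12, 1.0
        for _ in range(80):
            tau = (lo + hi) / 2
            if (1.0 - np.exp(-pool / tau)).sum() > target:
                lo = tau
            else:
                hi = tau
        p_incl = 1.0 - np.exp(-pool / tau)
        include = rng.random(n) < p_incl
        for a in range(config.n_air_samples_per_season):
            leaf_part = pool * include * propensity
            expected = leaf_part + config.air_only_weight * leaf_part.sum() * air_base
            if expected.sum() <= 0:
                raise CommunityError(f"no OTUs eligible for air in {season}")
            suffix = f"_{a + 1}" if config.n_air_samples_per_season > 1 else ""
            samples.append(expected / expected.sum())
            meta_rows.append(("air", "air", season))
            cols.append(f"Air_{season[0].upper()}{suffix}")

    expected = pd.DataFrame(np.column_stack(samples), index=otu_ids, columns=cols)
    metadata = pd.DataFrame(
        meta_rows, columns=["source", "habitat", "season"], index=pd.Index(cols, name="sample_id")
    )
    truth_frames = (
        pd.Series(roles, index=otu_ids, name="role"),
        pd.Series(home, index=otu_ids, name="home_habitat"),
        pd.Series(winter, index=otu_ids, name="seasonal_bias"),
    )
    return expected, metadata, truth_frames


def generate_community(
    config: SyntheticConfig | None = None, seed: int | None = None
) -> tuple[OtuTable, pd.DataFrame, SyntheticTruth]:
    """Draw one synthetic dataset: counts, sample metadata, planted truth.

    ``seed`` overrides ``config.seed``.  Each sample is one multinomial draw
    of ``config.depth`` reads from its expected relative abundances; OTUs
    with zero reads everywhere are dropped from the table (the truth keeps
    all planted OTUs).
    """
    config = config or SyntheticConfig()
    if seed is not None:
        config = SyntheticConfig(**{**asdict(config), "seed": seed})
    rng = np.random.default_rng(config.seed)
    expected, metadata, (roles, home, bias) = _expected_matrix(config, rng)
    counts = pd.DataFrame(
        {
            sid: rng.multinomial(config.depth, expected[sid].to_numpy())
            for sid in expected.columns
        },
        index=expected.index,
    )
    table = OtuTable(
        counts=counts,
        provenance={"synthetic_seed": config.seed, "depth": config.depth},
    ).drop_empty_otus()
    truth = SyntheticTruth(
        roles=roles, home_habitat=home, seasonal_bias=bias,
        expected=expected, config=config, seed=config.seed,
    )
    validate_metadata(metadata)
    return table, metadata, truth


def expected_table(truth: SyntheticTruth, scale: int = 10**6) -> OtuTable:
    """The noise-free community as integer-scaled counts (sampling-free limit)."""
    counts = (truth.expected * scale).round().astype(np.int64)
    return OtuTable(counts=counts, provenance={"noise_free": True}).drop_empty_otus()


@dataclass(frozen=True)
class RecoveryReport:
    """Precision/recall of niche-role recovery against the planted truth."""

    generalist_precision: float | None
    generalist_recall: float | None
    specialist_precision: float | None
    specialist_recall: float | None
    occupancy_confusion: pd.DataFrame = field(repr=False, default=None)


def recovery_report(truth: SyntheticTruth, niche, occupancy=None) -> RecoveryReport:
    """Score Levins-category calls against planted roles.

    ``niche`` is the per-OTU niche-breadth frame from
    :func:`phyllonet.niche.levins_index` (columns include ``category``);
    ``occupancy`` optionally the occupancy frame for the habitat-count
    confusion table.  Classes with no planted members yield ``None``
    (not-applicable) precision/recall.
    """
    pred = niche["category"]
    unknown = set(pred.index) - set(truth.roles.index)
    if unknown:
        raise CommunityError(f"OTUs absent from truth: {sorted(unknown)[:5]}")
    true = truth.roles.loc[pred.index]

    def _pr(label: str):
        tp = int(((pred == label) & (true == label)).sum())
        n_pred = int((pred == label).sum())
        n_true = int((true == label).sum())
        if n_true == 0:
            return None, None
        precision = tp / n_pred if n_pred else None
        recall = tp / n_true
        return precision, recall

    gp, gr = _pr("generalist")
    sp, sr = _pr("specialist")

    confusion = None
    if occupancy is not None:
        planted = truth.roles.loc[occupancy.index].rename("planted_role")
        confusion = (
            pd.crosstab(planted, occupancy["n_habitats_occupied"])
            .rename_axis(columns="observed_habitats")
        )
    return RecoveryReport(gp, gr, sp, sr, confusion)
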