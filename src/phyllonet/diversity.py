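"""Alpha diversity (richness, Shannon, Simpson, Pielou) and paired seasonal tests.

Per sample, with :math:`p_k` the within-sample relative abundance of OTU
:math:`k` (positive counts only):

* richness :math:`S` — number of OTUs with reads;
* Shannon :math:`H = -\\sum_k p_k \\ln p_k` (natural log by default);
* Simpson :math:`1 - D = 1 - \\sum_k p_k^2`;
* Pielou evenness :math:`J = H / \\ln S` (undefined for :math:`S = 1`).

Seasonal contrasts are paired t-tests across habitats (summer vs winter
value per habitat).  When one season is identically zero across all pairs,
the test degrades to a one-sample t-test of the other season against zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityError, OtuTable


def diversity_profile(table: OtuTable, base: float | None = None) -> pd.DataFrame:
    """Per-sample diversity profile.

    Returns a DataFrame indexed by sample id with columns
    ``richness, shannon, simpson, pielou``; ``pielou`` is NaN when S = 1.
    ``base`` switches the Shannon logarithm (default natural log; Pielou is
    base-invariant).
    """
    rows = {}
    log = math.log if base is None else (lambda v: math.log(v, base))
    for sample in table.sample_ids:
        col = table.counts[sample].to_numpy(dtype=float)
        total = col.sum()
        if total == 0:
            raise CommunityError(f"sample {sample!r} has no reads")
        p = col[col > 0] / total
        s = int(p.size)
        h = float(-(p * np.array([log(v) for v in p])).sum())
        simpson = float(1.0 - (p**2).sum())
        pielou = h / log(s) if s > 1 else float("nan")
        rows[sample] = dict(richness=s, shannon=h, simpson=simpson, pielou=pielou)
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis("sample_id")


@dataclass(frozen=True)
class SeasonalComparison:
    """One paired summer-vs-winter contrast (one attribute or taxon)."""

    attribute: str
    summer_mean: float
    summer_se: float
    winter_mean: float
    winter_se: float
    df: int
    t: float
    p: float
    mode: str  # "paired" | "one_sample_vs_zero" | "tie"

    @property
    def significant(self) -> bool:
        return bool(self.p < 0.05) if np.isfinite(self.p) else False


def paired_season_test(
    summer, winter, attribute: str = "value"
) -> SeasonalComparison:
    """Two-sided paired t-test of summer vs winter values across habitats.

    ``summer`` and ``winter`` are equal-length sequences, one value per
    habitat pair.  With all-winter (or all-summer) values identically zero
    the comparison becomes a one-sample t-test of the non-zero season
    against 0.  Zero variance of the differences is reported as an exact
    tie (t = 0, p = 1 if all differences are zero; t undefined otherwise).
    """
    summer = np.asarray(summer, dtype=float)
    winter = np.asarray(winter, dtype=float)
    if summer.shape != winter.shape:
        raise CommunityError("summer and winter must pair one value per habitat")
    n = summer.size
    if n < 2:
        raise CommunityError("need at least 2 habitat pairs")

    def _se(v):
        return float(np.std(v, ddof=1) / math.sqrt(n))

    means = (float(summer.mean()), _se(summer), float(winter.mean()), _se(winter))
    if np.all(winter == 0) and not np.all(summer == 0):
        t, p = stats.ttest_1samp(summer, 0.0)
        return SeasonalComparison(attribute, *means, n - 1, float(t), float(p), "one_sample_vs_zero")
    if np.all(summer == 0) and not np.all(winter == 0):
        t, p = stats.ttest_1samp(winter, 0.0)
        return SeasonalComparison(attribute, *means, n - 1, float(t), float(p), "one_sample_vs_zero")
    diffs = summer - winter
    if np.std(diffs) == 0:
        if np.all(diffs == 0):
            return SeasonalComparison(attribute, *means, n - 1, 0.0, 1.0, "tie")
        return SeasonalComparison(
            attribute, *means, n - 1, float("nan"), float("nan"), "tie"
        )
    t, p = stats.ttest_rel(summer, winter)
    return SeasonalComparison(attribute, *means, n - 1, float(t), float(p), "paired")


def seasonal_diversity_comparison(
    table: OtuTable, metadata: pd.DataFrame
) -> pd.DataFrame:
    """Habitat-paired seasonal contrasts of richness and diversity indices.

    Leaf samples are paired by habitat (summer vs winter); air samples are
    excluded.  Returns one row per attribute with means ± SE, d.f., t and p.
    """
    leaf = metadata[metadata["source"] == "leaf"]
    prof = diversity_profile(table.select_samples(leaf.index))
    prof = prof.join(leaf[["habitat", "season"]])
    wide = {
        attr: prof.pivot_table(index="habitat", columns="season", values=attr)
        for attr in ("richness", "shannon", "simpson", "pielou")
    }
    rows = []
    for attr, tab in wide.items():
        tab = tab.dropna()
        res = paired_season_test(tab["summer"], tab["winter"], attribute=attr)
        rows.append(res.__dict__ | {"significant": res.significant})
    return pd.DataFrame(rows).set_index("attribute")
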