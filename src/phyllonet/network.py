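"""MIC co-occurrence networks and their topological characterisation.

The Maximal Information Coefficient (MIC) between two abundance vectors is
the maximum, over all two-dimensional grids with at most B(n) cells, of the
grid's mutual information normalised by ``log2`` of the smaller grid
dimension.  Following the MINE heuristic, one axis is equipartitioned and
the other optimised exactly by dynamic programming over "clumps" (runs of
tied values that no grid line may split), in both orientations.  The grid
budget is :math:`B(n) = \\max(\\lfloor n^{\\alpha} \\rfloor, 4)` with
``alpha = 0.6``, so the 2x2 grid is always admissible.

Pairs with MIC above a threshold (default 0.5) and positive Spearman rank
correlation become edges of an undirected co-occurrence network, whose
topology (density, clustering coefficient, centralization, characteristic
path length, heterogeneity, ...) is compared against uniform G(n, m)
random graphs with the same node and edge counts.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityError, OtuTable

DEFAULT_ALPHA = 0.6
DEFAULT_CLUMPS = 15
MIC_THRESHOLD = 0.5
MIN_GROUP_SAMPLES = 5


# ---------------------------------------------------------------------------
# MIC core
# ---------------------------------------------------------------------------

def grid_budget(n: int, alpha: float = DEFAULT_ALPHA) -> int:
    """Maximal number of grid cells B(n); floored at 4 so the 2x2 grid
    always competes even for very short vectors."""
    return max(int(math.floor(n**alpha)), 4)


def _equipartition(vals: np.ndarray, b: int) -> np.ndarray:
    """Assign points to ``b`` (or fewer) rows, near-equal sizes, never
    splitting tied values across a boundary."""
    order = np.argsort(vals, kind="mergesort")
    n = len(vals)
    assign = np.empty(n, dtype=np.int64)
    i, row = 0, 0
    while i < n and row < b:
        target = (n - i) / (b - row)
        j, size = i, 0
        while j < n:
            k = j
            while k < n and vals[order[k]] == vals[order[j]]:
                k += 1
            run = k - j
            if size > 0 and abs(size + run - target) >= abs(size - target):
                break
            size += run
            j = k
        assign[order[i:j]] = row
        i, row = j, row + 1
    if i < n:
        assign[order[i:]] = b - 1
    return assign


def _clumps(x: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Cumulative per-row counts after each clump of x-tied points.

    Points are sorted by x; a clump is a maximal run of equal x values
    (grid lines cannot separate ties).  Returns an array of shape
    (n_clumps + 1, n_rows) of cumulative row counts.
    """
    order = np.argsort(x, kind="mergesort")
    xs, qs = x[order], q[order]
    n_rows = int(q.max()) + 1
    cums = [np.zeros(n_rows, dtype=np.int64)]
    i = 0
    while i < len(xs):
        j = i
        while j < len(xs) and xs[j] == xs[i]:
            j += 1
        row_counts = np.bincount(qs[i:j], minlength=n_rows)
        cums.append(cums[-1] + row_counts)
        i = j
    return np.asarray(cums)


def _optimize_axis(cum: np.ndarray, max_cols: int, n: int) -> np.ndarray:
    """Best mutual information partitioning the clumped axis into 2..max_cols
    columns against the fixed row partition (dynamic programme).

    ``cum[t]`` holds cumulative row counts over the first t clumps.  The
    objective I = H(cols) + H(rows) − H(cols, rows) is additive over
    columns once H(rows) is set aside, enabling the DP.  Returns best I
    (bits) indexed by column count (index 0, 1 unused).
    """
    k = cum.shape[0] - 1  # number of clumps
    row_tot = cum[-1]
    p_rows = row_tot[row_tot > 0] / n
    h_rows = float(-(p_rows * np.log2(p_rows)).sum())

    # phi[s, t] = column-additive part of I for a column spanning clumps
    # (s, t]: -(m/n)log2(m/n) + sum_r (m_r/n)log2(m_r/n)
    seg = (cum[None, :, :] - cum[:, None, :]) / n  # (s, t, row)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = seg.sum(axis=2)
        t1 = np.where(m > 0, -m * np.log2(np.where(m > 0, m, 1.0)), 0.0)
        t2 = np.where(seg > 0, seg * np.log2(np.where(seg > 0, seg, 1.0)), 0.0).sum(axis=2)
    phi = t1 + t2

    max_cols = min(max_cols, k)
    neg = -math.inf
    f = np.full((k + 1, max_cols + 1), neg)
    f[0, 0] = 0.0
    for t in range(1, k + 1):
        for l in range(1, min(t, max_cols) + 1):
            prev = f[l - 1 : t, l - 1]
            cand = prev + phi[l - 1 : t, t]
            f[t, l] = cand.max()
    best = np.full(max_cols + 1, neg)
    for l in range(2, max_cols + 1):
        best[l] = h_rows + f[k, l]
    return best


def _row_partitions(vals: np.ndarray, b: int, limit: int):
    """Partitions of ``vals`` into exactly ``b`` ordered groups respecting
    ties.  All such partitions are enumerated when their number is at most
    ``limit`` (the fixed axis is then searched exactly); otherwise only the
    near-equal equipartition is yielded, as in the MINE heuristic."""
    order = np.argsort(vals, kind="mergesort")
    vs = vals[order]
    n = len(vs)
    boundaries = [i for i in range(1, n) if vs[i] != vs[i - 1]]
    if math.comb(len(boundaries), b - 1) <= limit and len(boundaries) >= b - 1:
        for cuts in combinations(boundaries, b - 1):
            assign = np.empty(n, dtype=np.int64)
            assign[order] = np.searchsorted(np.asarray(cuts), np.arange(n), side="right")
            yield assign
    else:
        yield _equipartition(vals, b)


def mic(
    x,
    y,
    alpha: float = DEFAULT_ALPHA,
    c: int = DEFAULT_CLUMPS,
    exact_limit: int = 200,
) -> float:
    """Maximal Information Coefficient of two equal-length vectors.

    ``alpha`` sets the grid budget exponent and ``c`` the superclump
    factor of the MINE-style search.  One axis is held to a fixed
    partition while the other is optimised exactly by dynamic programming;
    the fixed axis is searched exhaustively whenever its partitions number
    at most ``exact_limit`` (always the case for the short vectors of
    sample-wise abundance profiles, making the score exact), and falls
    back to the equipartition heuristic otherwise.  Constant vectors score
    0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise CommunityError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 5:
        raise CommunityError("MIC requires at least 5 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("constant vector; MIC set to 0")
        return 0.0
    b_max = grid_budget(n, alpha)
    best = 0.0
    for xv, yv in ((x, y), (y, x)):
        for b in range(2, b_max // 2 + 1):
            max_cols = b_max // b
            for q in _row_partitions(yv, b, exact_limit):
                n_rows = int(q.max()) + 1
                if n_rows < 2:
                    continue
                cum = _clumps(xv, q)
                if cum.shape[0] - 1 > c * max_cols:
                    cum = _superclumps(cum, c * max_cols)
                scores = _optimize_axis(cum, max_cols, n)
                for cols in range(2, len(scores)):
                    if scores[cols] == -math.inf:
                        continue
                    norm = math.log2(min(cols, n_rows))
                    best = max(best, scores[cols] / norm)
    return float(min(best, 1.0))


def _superclumps(cum: np.ndarray, limit: int) -> np.ndarray:
    """Coalesce clump boundaries down to ``limit`` near-equal superclumps."""
    k = cum.shape[0] - 1
    if k <= limit:
        return cum
    sizes = cum[1:].sum(axis=1) - cum[:-1].sum(axis=1)
    # greedy equipartition of clumps by point count
    n = cum[-1].sum()
    target = n / limit
    keep = [0]
    acc = 0
    for t in range(1, k + 1):
        acc += sizes[t - 1]
        if acc >= target * len(keep) or t == k:
            keep.append(t)
    return cum[np.asarray(keep)]


def mic_brute_force(x, y, alpha: float = DEFAULT_ALPHA) -> float:
    """Exhaustive-grid MIC: enumerate every admissible grid (cut positions
    respecting ties on each axis), used as an independent oracle for short
    vectors.  Exponential in n; intended for n <= 10."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return 0.0
    b_max = grid_budget(n, alpha)

    def cut_positions(v):
        order = np.argsort(v, kind="mergesort")
        vs = v[order]
        return [i for i in range(1, n) if vs[i] != vs[i - 1]], order

    px, ox = cut_positions(x)
    py, oy = cut_positions(y)
    rank_x = np.empty(n, dtype=int)
    rank_x[ox] = np.arange(n)
    rank_y = np.empty(n, dtype=int)
    rank_y[oy] = np.arange(n)

    def partitions(positions, parts):
        def rec(start, left):
            if left == 1:
                yield []
                return
            for i, pos in enumerate(positions):
                if pos <= start:
                    continue
                for rest in rec(pos, left - 1):
                    yield [pos] + rest

        yield from rec(0, parts)

    best = 0.0
    for a in range(2, b_max // 2 + 1):
        for b in range(2, b_max // a + 1):
            for cx in partitions(px, a):
                col = np.searchsorted(cx, rank_x, side="right")
                for cy in partitions(py, b):
                    row = np.searchsorted(cy, rank_y, side="right")
                    joint = np.zeros((a, b))
                    for ci, ri in zip(col, row):
                        joint[ci, ri] += 1
                    joint /= n
                    pi, pj = joint.sum(axis=1), joint.sum(axis=0)
                    nzi = joint > 0
                    info = float(
                        (joint[nzi] * np.log2(joint[nzi] / np.outer(pi, pj)[nzi])).sum()
                    )
                    best = max(best, info / math.log2(min(a, b)))
    return float(min(best, 1.0))


def mic_pvalue(x, y, n_perm: int = 999, seed: int = 0, **mic_kwargs) -> float:
    """Permutation p-value for MIC: p = (1 + #{MIC_perm >= MIC_obs}) / (1 + n_perm)."""
    if n_perm < 99:
        raise CommunityError("use at least 99 permutations")
    observed = mic(x, y, **mic_kwargs)
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    exceed = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_perm):
            if mic(x, rng.permutation(y), **mic_kwargs) >= observed:
                exceed += 1
    return (1 + exceed) / (1 + n_perm)


# ---------------------------------------------------------------------------
# Network construction and topology
# ---------------------------------------------------------------------------

def mic_edges(
    table: OtuTable,
    samples=None,
    alpha: float = DEFAULT_ALPHA,
    c: int = DEFAULT_CLUMPS,
) -> pd.DataFrame:
    """All-pairs MIC and Spearman rho over the given samples.

    Returns a DataFrame with columns ``otu_a, otu_b, mic, rho``.
    """
    sub = table.counts if samples is None else table.counts[list(samples)]
    mat = sub.to_numpy(dtype=float)
    ids = list(sub.index)
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, j in combinations(range(len(ids)), 2):
            score = mic(mat[i], mat[j], alpha=alpha, c=c)
            if np.all(mat[i] == mat[i][0]) or np.all(mat[j] == mat[j][0]):
                rho = 0.0
            else:
                rho = float(stats.spearmanr(mat[i], mat[j]).statistic)
            rows.append((ids[i], ids[j], score, rho))
    return pd.DataFrame(rows, columns=["otu_a", "otu_b", "mic", "rho"])


def build_network(
    table: OtuTable,
    samples=None,
    otus=None,
    mic_threshold: float = MIC_THRESHOLD,
    alpha: float = DEFAULT_ALPHA,
    c: int = DEFAULT_CLUMPS,
    min_samples: int = MIN_GROUP_SAMPLES,
    keep_isolated: bool = False,
    taxonomy_group: pd.Series | None = None,
) -> nx.Graph:
    """Thresholded co-occurrence network over a sample group.

    An edge joins two OTUs when MIC exceeds ``mic_threshold`` and their
    Spearman rank correlation is positive ("strong positive correlation").
    Groups smaller than ``min_samples`` are refused (lower ``min_samples``
    explicitly to override); isolated nodes are dropped unless
    ``keep_isolated``.  ``taxonomy_group`` (otu_id -> label) annotates nodes.
    """
    sub = table if samples is None else table.select_samples(samples)
    if otus is not None:
        sub = sub.select_otus([o for o in otus if o in sub.counts.index])
    sub = sub.drop_empty_otus()
    if sub.n_samples < min_samples:
        raise CommunityError(
            f"group has {sub.n_samples} samples; at least {min_samples} "
            "required (pass min_samples to override)"
        )
    if sub.n_otus < 2:
        raise CommunityError("need at least 2 OTUs")
    edges = mic_edges(sub, alpha=alpha, c=c)
    g = nx.Graph()
    if keep_isolated:
        g.add_nodes_from(sub.counts.index)
    hits = edges[(edges["mic"] > mic_threshold) & (edges["rho"] > 0)]
    for _, row in hits.iterrows():
        g.add_edge(row["otu_a"], row["otu_b"], mic=row["mic"], rho=row["rho"])
    if taxonomy_group is not None:
        for node in g.nodes:
            g.nodes[node]["group"] = str(taxonomy_group.get(node, "unknown"))
    return g


@dataclass(frozen=True)
class TopologyReport:
    """The twelve topological parameters reported per network (3-decimal
    presentation is applied by :meth:`to_series`)."""

    nodes: int
    edges: int
    clustering_coefficient: float
    connected_components: int
    diameter: float
    radius: float
    centralization: float | None
    shortest_paths: int
    characteristic_path_length: float
    avg_neighbors: float
    density: float
    heterogeneity: float

    def to_series(self, decimals: int = 3) -> pd.Series:
        s = pd.Series(self.__dict__)
        return s.map(lambda v: round(v, decimals) if isinstance(v, float) else v)


def topology(g: nx.Graph) -> TopologyReport:
    """Cytoscape-style topological parameters of an undirected simple graph.

    Clustering coefficient averages 2t/(k(k-1)) over all nodes, degree-<2
    nodes contributing 0.  Diameter and radius are max/min eccentricity in
    the largest connected component; shortest paths counts ordered
    reachable pairs (all components) and the characteristic path length is
    the mean distance over those pairs.  Centralization is
    (N/(N−2))·(k_max/(N−1) − density); heterogeneity the coefficient of
    variation of the degrees.  Centralization needs N ≥ 3 (else None).
    """
    n = g.number_of_nodes()
    if n < 1:
        raise CommunityError("empty graph")
    m = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)
    density = 2 * m / (n * (n - 1)) if n > 1 else 0.0
    clustering = float(nx.average_clustering(g, count_zeros=True)) if n > 0 else 0.0
    components = list(nx.connected_components(g))
    largest = max(components, key=len)
    if len(largest) > 1:
        ecc = nx.eccentricity(g.subgraph(largest))
        diameter = float(max(ecc.values()))
        radius = float(min(ecc.values()))
    else:
        diameter = radius = 0.0
    n_paths = 0
    total_len = 0.0
    for comp in components:
        k = len(comp)
        if k < 2:
            continue
        for _, dists in nx.shortest_path_length(g.subgraph(comp)):
            for target, dist in dists.items():
                if dist > 0:
                    n_paths += 1
                    total_len += dist
    cpl = total_len / n_paths if n_paths else 0.0
    centralization = (
        (n / (n - 2)) * (degrees.max() / (n - 1) - density) if n >= 3 else None
    )
    mean_deg = degrees.mean() if n else 0.0
    heterogeneity = float(degrees.std() / mean_deg) if mean_deg > 0 else 0.0
    return TopologyReport(
        nodes=n,
        edges=m,
        clustering_coefficient=clustering,
        connected_components=len(components),
        diameter=diameter,
        radius=radius,
        centralization=float(centralization) if centralization is not None else None,
        shortest_paths=n_paths,
        characteristic_path_length=cpl,
        avg_neighbors=float(2 * m / n),
        density=float(density),
        heterogeneity=heterogeneity,
    )


def random_network(n_nodes: int, n_edges: int, seed: int = 0) -> nx.Graph:
    """Uniform simple graph with exactly the requested node and edge counts
    (Erdős–Rényi G(n, m))."""
    max_edges = n_nodes * (n_nodes - 1) // 2
    if n_edges > max_edges:
        raise CommunityError(
            f"{n_edges} edges infeasible for {n_nodes} nodes (max {max_edges})"
        )
    return nx.gnm_random_graph(n_nodes, n_edges, seed=int(seed))


def random_topology(
    n_nodes: int, n_edges: int, n_replicates: int = 1, seed: int = 0
) -> pd.DataFrame:
    """Topology of G(n, m) null draws: mean ± sd over replicates.

    Returns a DataFrame with columns ``mean`` and ``sd`` over the numeric
    topological parameters.
    """
    rows = []
    for r in range(n_replicates):
        rep = topology(random_network(n_nodes, n_edges, seed=seed + r))
        rows.append(rep.to_series(decimals=12))
    frame = pd.DataFrame(rows).drop(columns=["centralization"]).astype(float)
    cent = [r["centralization"] for r in rows if r["centralization"] is not None]
    out = pd.DataFrame({"mean": frame.mean(), "sd": frame.std(ddof=0)})
    if cent:
        out.loc["centralization"] = (float(np.mean(cent)), float(np.std(cent)))
    return out


def rewired_null(g: nx.Graph, seed: int = 0, n_swaps: int | None = None) -> nx.Graph:
    """Degree-preserving null: double-edge swaps of a copy of ``g``."""
    h = g.copy()
    m = h.number_of_edges()
    if m < 2:
        return h
    nx.double_edge_swap(
        h, nswap=n_swaps or 10 * m, max_tries=1000 * m, seed=int(seed)
    )
    return h
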