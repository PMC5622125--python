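"""Per-locus differentiation tests and clustering of significant loci.

Each polymorphic MSL is tested for unequal methylated/unmethylated
proportions across groups with a Fisher exact test on its 2 x G count
table, and the p-values are adjusted jointly by Benjamini-Hochberg.  For
visualisation, the significant loci are clustered by UPGMA on Gower
distances of their categorical (Type I-IV) profiles across samples.

For G > 2 the exact test enumerates every table with the observed margins
and sums the multivariate-hypergeometric probabilities of tables no more
probable than the observed one (the classical exact-test rule).  When the
enumeration would exceed a budget, a seeded Monte-Carlo estimate over
random margin-preserving tables is used instead and logged.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, UndefinedValueError
from .differentiation import DistanceMatrix
from .methylation import MethylationTypeMatrix, MslBinaryMatrix

logger = logging.getLogger(__name__)

#: above this many candidate tables, fall back to Monte Carlo
ENUMERATION_BUDGET = 2_000_000
MONTE_CARLO_DRAWS = 100_000
_REL_TOL = 1 + 1e-7  # probability-comparison slack, matches R's fisher.test


@dataclass
class LocusTestTable:
    locus_ids: list[str]
    contingency: dict[str, pd.DataFrame]  # locus -> 2 x G counts
    p_raw: pd.Series
    p_adj: pd.Series
    significant: pd.Series
    alpha: float

    @property
    def significant_loci(self) -> list[str]:
        return [l for l in self.locus_ids if bool(self.significant[l])]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p_raw": self.p_raw, "p_adj": self.p_adj, "significant": self.significant}
        ).rename_axis("locus")


@dataclass
class LinkageTree:
    """UPGMA dendrogram: merge list plus heights, Newick-serialisable."""

    leaf_ids: list[str]
    # each merge: (left node id, right node id, height); leaves are 0..n-1,
    # internal nodes n, n+1, ... in merge order
    merges: list[tuple[int, int, float]]

    def to_newick(self) -> str:
        n = len(self.leaf_ids)
        height: dict[int, float] = {i: 0.0 for i in range(n)}
        node: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        min_leaf: dict[int, str] = {i: self.leaf_ids[i] for i in range(n)}
        for k, (a, b, h) in enumerate(self.merges):
            # children ordered by smallest leaf label for a canonical string
            if min_leaf[b] < min_leaf[a]:
                a, b = b, a
            node[n + k] = (
                f"({node[a]}:{h - height[a]:.10g},{node[b]}:{h - height[b]:.10g})"
            )
            height[n + k] = h
            min_leaf[n + k] = min(min_leaf[a], min_leaf[b])
        root = n + len(self.merges) - 1 if self.merges else 0
        return node[root] + ";"


def adjust_bh(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, original order."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigurationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _exact_2xg_p(table: np.ndarray) -> float:
    """Exact p for a 2 x G table: sum of P(T) over margin-matched tables
    with P(T) <= P(observed), multivariate hypergeometric under fixed
    margins."""
    meth = table[0]
    col = table.sum(axis=0)
    r1 = int(meth.sum())
    N = int(col.sum())
    logC = [np.array([math.lgamma(c + 1) - math.lgamma(k + 1) - math.lgamma(c - k + 1)
                      for k in range(c + 1)]) for c in col.astype(int)]
    log_denom = math.lgamma(N + 1) - math.lgamma(r1 + 1) - math.lgamma(N - r1 + 1)
    obs_logp = sum(lc[k] for lc, k in zip(logC, meth.astype(int))) - log_denom
    cutoff = obs_logp + math.log(_REL_TOL)
    G = len(col)
    total = 0.0
    # depth-first over compositions of r1 into the G columns
    stack = [(0, r1, 0.0)]
    suffix_cap = np.concatenate([np.cumsum(col[::-1])[::-1][1:], [0]])
    while stack:
        g, rem, acc = stack.pop()
        if g == G - 1:
            if rem <= col[g]:
                lp = acc + logC[g][rem] - log_denom
                if lp <= cutoff:
                    total += math.exp(lp)
            continue
        lo = max(0, rem - int(suffix_cap[g]))
        hi = min(int(col[g]), rem)
        for k in range(lo, hi + 1):
            stack.append((g + 1, rem - k, acc + logC[g][k]))
    return min(1.0, total)


def _enumeration_size(col: np.ndarray) -> int:
    size = 1
    for c in col:
        size *= int(c) + 1
        if size > ENUMERATION_BUDGET:
            return size
    return size


def _montecarlo_2xg_p(table: np.ndarray, rng: np.random.Generator,
                      draws: int = MONTE_CARLO_DRAWS) -> float:
    meth = table[0].astype(int)
    col = table.sum(axis=0).astype(int)
    r1 = int(meth.sum())
    N = int(col.sum())
    # draw margin-preserving tables by permuting the pooled 0/1 labels
    pool = np.zeros(N, dtype=np.int8)
    pool[:r1] = 1
    edges = np.concatenate([[0], np.cumsum(col)])
    logC = [np.array([math.lgamma(c + 1) - math.lgamma(k + 1) - math.lgamma(c - k + 1)
                      for k in range(c + 1)]) for c in col]
    log_denom = math.lgamma(N + 1) - math.lgamma(r1 + 1) - math.lgamma(N - r1 + 1)
    obs_logp = sum(lc[k] for lc, k in zip(logC, meth)) - log_denom
    cutoff = obs_logp + math.log(_REL_TOL)
    hits = 0
    for _ in range(draws):
        perm = rng.permutation(pool)
        lp = -log_denom
        for g in range(len(col)):
            k = int(perm[edges[g]:edges[g + 1]].sum())
            lp += logC[g][k]
        if lp <= cutoff:
            hits += 1
    return (1 + hits) / (1 + draws)


def fisher_exact_2xg(table, seed: int | None = None) -> float:
    """Two-sided Fisher exact p-value for a 2 x G count table.

    G = 2 delegates to scipy's fisher_exact; larger G enumerates all
    margin-matched tables (Monte Carlo above the enumeration budget).
    A table with an all-zero row or column margin carries no information
    and returns p = 1.
    """
    t = np.asarray(table, dtype=float)
    if t.shape[0] != 2 or t.ndim != 2:
        raise ConfigurationError("table must be 2 x G")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ConfigurationError("table must hold non-negative integer counts")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        logger.info("degenerate margin in contingency table; p = 1")
        return 1.0
    if t.shape[1] == 2:
        return float(stats.fisher_exact(t, alternative="two-sided")[1])
    if _enumeration_size(t.sum(axis=0)) <= ENUMERATION_BUDGET:
        return _exact_2xg_p(t)
    logger.info("enumeration budget exceeded; Monte-Carlo Fisher p (%d draws)",
                MONTE_CARLO_DRAWS)
    return _montecarlo_2xg_p(t, np.random.default_rng(seed))


def locus_fisher_tests(
    matrix: MslBinaryMatrix, alpha: float = 0.05, seed: int | None = None
) -> LocusTestTable:
    """Per-locus Fisher exact tests with joint Benjamini-Hochberg control.

    For every locus, the 2 x G table of methylated vs unmethylated counts
    per group (missing cells excluded) is tested two-sided; adjusted
    p-values are compared against ``alpha`` (FDR level).
    """
    if not 0 < alpha < 1:
        raise ConfigurationError(f"alpha must be in (0, 1), got {alpha}")
    groups = np.array(matrix.group_labels)
    uniq = pd.unique(groups)
    if len(uniq) < 2:
        raise ConfigurationError("need >= 2 groups")
    x = matrix.states.to_numpy(dtype=float)
    tables: dict[str, pd.DataFrame] = {}
    p_raw = []
    for j, locus in enumerate(matrix.locus_ids):
        col = x[:, j]
        counts = np.zeros((2, len(uniq)))
        for gi, g in enumerate(uniq):
            sel = (groups == g) & ~np.isnan(col)
            counts[0, gi] = np.sum(col[sel] == 1)  # methylated
            counts[1, gi] = np.sum(col[sel] == 0)
        tables[locus] = pd.DataFrame(
            counts.astype(int), index=["methylated", "unmethylated"], columns=list(uniq)
        )
        p_raw.append(fisher_exact_2xg(counts, seed=seed))
    p_raw = pd.Series(p_raw, index=matrix.locus_ids, name="p_raw")
    p_adj = pd.Series(adjust_bh(p_raw.to_numpy()), index=matrix.locus_ids, name="p_adj")
    return LocusTestTable(
        locus_ids=list(matrix.locus_ids),
        contingency=tables,
        p_raw=p_raw,
        p_adj=p_adj,
        significant=(p_adj < alpha).rename("significant"),
        alpha=alpha,
    )


def intersect_significant(table_a: LocusTestTable, table_b: LocusTestTable) -> set[str]:
    """Loci significant in both tables (shared locus namespace assumed)."""
    if not set(table_a.locus_ids) & set(table_b.locus_ids):
        logger.warning("intersect_significant: locus namespaces are disjoint")
        return set()
    return set(table_a.significant_loci) & set(table_b.significant_loci)


def gower_distance(types: MethylationTypeMatrix) -> DistanceMatrix:
    """Gower distance between loci over their categorical type profiles.

    For a locus pair, the distance is the fraction of samples (both cells
    non-missing) whose Type I-IV categories differ — Gower's coefficient
    for purely categorical variables.  Lives in [0, 1].  Indexed by locus,
    not sample; stored in the d2 slot unsquared, as UPGMA consumes raw
    dissimilarities.
    """
    t = types.types.to_numpy(dtype=float).T  # loci x samples
    L = t.shape[0]
    if L < 2:
        raise ConfigurationError("gower_distance requires >= 2 loci")
    obs = ~np.isnan(t)
    both = obs.astype(float) @ obs.astype(float).T
    same = np.zeros((L, L))
    for k in (1, 2, 3, 4):
        ind = (np.nan_to_num(t) == k) & obs
        same += ind.astype(float) @ ind.astype(float).T
    no_overlap = (both == 0) & ~np.eye(L, dtype=bool)
    if no_overlap.any():
        i, j = np.argwhere(no_overlap)[0]
        raise UndefinedValueError(
            f"loci {types.locus_ids[i]} and {types.locus_ids[j]} share no "
            "jointly non-missing sample"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(both > 0, (both - same) / both, 0.0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(types.locus_ids), (d + d.T) / 2)


def upgma_cluster(dist: DistanceMatrix) -> LinkageTree:
    """UPGMA (average-linkage) clustering with deterministic tie-breaking.

    Repeatedly merges the closest pair of clusters; the distance between
    clusters is the arithmetic mean of all cross-pair leaf distances
    (unweighted on leaves), and a merge at distance d places the new node
    at height d/2 (ultrametric).  Ties are broken by the lexicographically
    smallest leaf label in each cluster, so output is independent of input
    order.
    """
    d = np.asarray(dist.d2, dtype=float)
    if not np.all(np.isfinite(d)):
        raise ConfigurationError("distances must be finite")
    n = len(dist.sample_ids)
    if n < 2:
        raise ConfigurationError("upgma_cluster requires >= 2 leaves")
    # active clusters: node id -> (min leaf label, leaf count)
    active: dict[int, tuple[str, int]] = {
        i: (dist.sample_ids[i], 1) for i in range(n)
    }
    dd: dict[tuple[int, int], float] = {
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float]] = []
    next_id = n
    while len(active) > 1:
        best = None
        for (i, j), val in dd.items():
            key = (val, min(active[i][0], active[j][0]),
                   max(active[i][0], active[j][0]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        dij = dd[(i, j)]
        si, sj = active[i][1], active[j][1]
        new_min = min(active[i][0], active[j][0])
        merges.append((i, j, dij / 2.0))
        del dd[(i, j)]
        others = [k for k in active if k not in (i, j)]
        for k in others:
            dik = dd[(min(i, k), max(i, k))]
            djk = dd[(min(j, k), max(j, k))]
            del dd[(min(i, k), max(i, k))]
            del dd[(min(j, k), max(j, k))]
            dd[(min(next_id, k), max(next_id, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[next_id] = (new_min, si + sj)
        next_id += 1
    return LinkageTree(list(dist.sample_ids), merges)
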