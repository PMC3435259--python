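"""Descriptive statistics: pairwise correlation, site clustering, group tests.

Three analyses complement the model-based scoring:

* the phi-coefficient (Pearson correlation of two binary site columns) per
  individual, aggregated across individuals with a z-test and
  Benjamini-Hochberg FDR across pairs;
* Jaccard / Dice distances between sites with single-linkage hierarchical
  clustering, where each internal cluster's confidence is the fraction of
  individuals whose own dendrogram contains the identical site set;
* a two-group comparison by a permutation G-test: the likelihood-ratio (G)
  statistic over the 2^S pattern categories, with subjects (not reads)
  randomly reassigned to groups, group sizes fixed.  P-values count random
  statistics >= the observed one, a deliberately conservative convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.special import xlogy
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .core import Cohort, PatternCounts
from .scoring import _site_bits

__all__ = [
    "PairTable",
    "PhiResult",
    "Dendrogram",
    "GroupComparison",
    "pair_table",
    "phi",
    "phi_inference",
    "all_pairs",
    "jaccard_distance",
    "dice_distance",
    "cluster_sites",
    "g_statistic",
    "permutation_group_test",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairTable:
    """2x2 contingency table of two sites over one individual's reads."""

    sites: tuple[int, int]
    n11: int
    n10: int
    n01: int
    n00: int

    @property
    def N(self) -> int:
        return self.n11 + self.n10 + self.n01 + self.n00


def pair_table(counts: PatternCounts, i: int, j: int) -> PairTable:
    """Marginalise the pattern histogram onto sites i and j."""
    if i == j:
        raise ValueError("pair requires two distinct sites")
    bits = _site_bits(counts.S)
    bi, bj = bits[:, i], bits[:, j]
    c = counts.counts
    return PairTable(
        (i, j),
        n11=int(c[(bi == 1) & (bj == 1)].sum()),
        n10=int(c[(bi == 1) & (bj == 0)].sum()),
        n01=int(c[(bi == 0) & (bj == 1)].sum()),
        n00=int(c[(bi == 0) & (bj == 0)].sum()),
    )


def phi(table: PairTable) -> float:
    """phi-coefficient: for binary data, the Pearson correlation.

    Undefined (NaN) when any marginal of the 2x2 table is zero.
    """
    n11, n10, n01, n00 = table.n11, table.n10, table.n01, table.n00
    r1, r0 = n11 + n10, n01 + n00
    c1, c0 = n11 + n01, n10 + n00
    denom = float(r1) * r0 * c1 * c0
    if denom == 0:
        return float("nan")
    return (n11 * n00 - n10 * n01) / np.sqrt(denom)


def _pair_margins(M: np.ndarray, S: int, i: int, j: int) -> np.ndarray:
    """(n_individuals, 4) columns n11, n10, n01, n00 for a site pair."""
    bits = _site_bits(S)
    bi, bj = bits[:, i], bits[:, j]
    masks = np.stack(
        [
            (bi == 1) & (bj == 1),
            (bi == 1) & (bj == 0),
            (bi == 0) & (bj == 1),
            (bi == 0) & (bj == 0),
        ]
    ).T.astype(np.int64)
    return M @ masks


def _phi_vector(M: np.ndarray, S: int, i: int, j: int) -> np.ndarray:
    """Per-individual phi for one pair; NaN where a margin is zero."""
    m = _pair_margins(M, S, i, j).astype(float)
    n11, n10, n01, n00 = m.T
    denom = (n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(
            denom > 0, (n11 * n00 - n10 * n01) / np.sqrt(np.maximum(denom, 1)),
            np.nan,
        )
    return out


@dataclass
class PhiResult:
    pair: tuple[int, int]
    phis: np.ndarray  # per-individual values, NaN where undefined
    mean: float
    sd: float
    m: int  # number of individuals with a defined phi
    z: float
    p: float
    q: float | None = None
    degenerate: bool = False


def phi_inference(cohort: Cohort, pair: tuple[int, int]) -> PhiResult:
    """Across-individual z-test on the per-individual phi values.

    z = mean / (sd / sqrt(m)) over the m individuals with a defined phi;
    two-sided normal p-value.  Individuals with a zero margin are excluded
    with a warning.  sd = 0 is flagged degenerate (p = 0 if mean != 0 else 1).
    """
    i, j = pair
    M = cohort.count_matrix()
    phis = _phi_vector(M, cohort.sites.S, i, j)
    defined = ~np.isnan(phis)
    m = int(defined.sum())
    if m < len(phis):
        excl = [cohort.ids[k] for k in np.flatnonzero(~defined)]
        logger.warning(
            "pair (%d,%d): phi undefined (zero margin) for %d individual(s): %s",
            i, j, len(excl), excl,
        )
    if m < 2:
        raise ValueError(
            f"pair {pair}: need >= 2 individuals with defined phi, got {m}"
        )
    vals = phis[defined]
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0.0:
        z = float("inf") if mean > 0 else float("-inf") if mean < 0 else 0.0
        p = 0.0 if mean != 0 else 1.0
        return PhiResult(pair, phis, mean, sd, m, z, p, degenerate=True)
    z = mean / (sd / np.sqrt(m))
    p = float(2 * norm.sf(abs(z)))
    return PhiResult(pair, phis, mean, sd, m, z, p)


def all_pairs(cohort: Cohort) -> list[PhiResult]:
    """phi inference for every site pair, Benjamini-Hochberg FDR across pairs."""
    results = [phi_inference(cohort, pr) for pr in cohort.sites.pairs()]
    pvals = [r.p for r in results]
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    for r, q in zip(results, qvals):
        r.q = float(q)
    return results


def phi_table(cohort: Cohort) -> pd.DataFrame:
    labels = cohort.sites.labels
    rows = []
    for r in all_pairs(cohort):
        a, b = r.pair
        rows.append(
            {
                "pair": f"({labels[a]},{labels[b]})",
                "mean_phi": r.mean,
                "sd_phi": r.sd,
                "n_individuals": r.m,
                "z": r.z,
                "p": r.p,
                "q": r.q,
                "degenerate": r.degenerate,
            }
        )
    return pd.DataFrame(rows)


def _distance(counts: PatternCounts, i: int, j: int, metric: str) -> float:
    t = pair_table(counts, i, j)
    union = t.n11 + t.n10 + t.n01
    if union == 0:
        logger.warning(
            "sites (%d,%d): no reads edited at either site; distance set to 1",
            i, j,
        )
        return 1.0
    if metric == "jaccard":
        return 1.0 - t.n11 / union
    if metric == "dice":
        return 1.0 - 2 * t.n11 / (t.n11 + union)
    raise ValueError(f"unknown metric {metric!r}")


def jaccard_distance(counts: PatternCounts, i: int, j: int) -> float:
    """1 - n11/(n11+n10+n01): co-editing dissimilarity of two sites."""
    return _distance(counts, i, j, "jaccard")


def dice_distance(counts: PatternCounts, i: int, j: int) -> float:
    """1 - 2 n11/(2 n11+n10+n01); always <= the Jaccard distance."""
    return _distance(counts, i, j, "dice")


@dataclass
class Dendrogram:
    """Single-linkage dendrogram over sites with per-cluster support."""

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray  # scipy (S-1, 4) merge table
    node_sets: list[frozenset[int]]  # site-index set per internal node
    supports: list[float]  # fraction of individuals reproducing the set
    metric: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (row, s, sup) in zip(self.linkage_matrix, self.node_sets,
                                 self.supports):
            rows.append(
                {
                    "height": float(row[2]),
                    "sites": ",".join(self.labels[k] for k in sorted(s)),
                    "support": sup,
                }
            )
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick string with supports as internal node labels and merge
        heights as branch lengths."""
        S = len(self.labels)
        heights = {k: 0.0 for k in range(S)}
        texts = {k: self.labels[k] for k in range(S)}
        for m, row in enumerate(self.linkage_matrix):
            a, b, h = int(row[0]), int(row[1]), float(row[2])
            node = S + m
            la = h - heights[a]
            lb = h - heights[b]
            sup = self.supports[m]
            texts[node] = f"({texts[a]}:{la:g},{texts[b]}:{lb:g}){sup:g}"
            heights[node] = h
        return texts[S + len(self.linkage_matrix) - 1] + ";"


def _merge_sets(Z: np.ndarray, S: int) -> list[frozenset[int]]:
    sets: dict[int, frozenset[int]] = {k: frozenset([k]) for k in range(S)}
    out = []
    for m, row in enumerate(Z):
        merged = sets[int(row[0])] | sets[int(row[1])]
        sets[S + m] = merged
        out.append(merged)
    return out


def _condensed_distances(counts: PatternCounts, S: int, metric: str) -> np.ndarray:
    return np.array(
        [_distance(counts, i, j, metric) for i in range(S)
         for j in range(i + 1, S)]
    )


def cluster_sites(cohort: Cohort, metric: str = "jaccard",
                  pooled: bool = True) -> Dendrogram:
    """Single-linkage clustering of the sites with per-individual support.

    With ``pooled`` (default) the distance matrix comes from the pooled
    cohort counts; otherwise from the mean of per-individual distance
    matrices.  The support of each internal node is the fraction of
    individuals whose own dendrogram contains an internal node with the
    identical site set.
    """
    from .core import pool

    S = cohort.sites.S
    if pooled:
        dists = _condensed_distances(pool(cohort), S, metric)
    else:
        per_ind = [
            _condensed_distances(pc, S, metric)
            for pc in cohort.individuals if pc.N > 0
        ]
        dists = np.mean(per_ind, axis=0)
    Z = linkage(dists, method="single")
    node_sets = _merge_sets(Z, S)

    ind_sets: list[set[frozenset[int]]] = []
    for pc in cohort.individuals:
        if pc.N == 0:
            logger.warning("skipping individual %r in cluster support: no reads",
                           pc.individual_id)
            continue
        Zi = linkage(_condensed_distances(pc, S, metric), method="single")
        ind_sets.append(set(_merge_sets(Zi, S)))
    n_ind = len(ind_sets)
    supports = [
        sum(s in clusters for clusters in ind_sets) / n_ind if n_ind else
        float("nan")
        for s in node_sets
    ]
    return Dendrogram(cohort.sites.labels, Z, node_sets, supports, metric)


def g_statistic(a: PatternCounts | np.ndarray, b: PatternCounts | np.ndarray
                ) -> float:
    """Two-sample likelihood-ratio (G) statistic over pattern categories.

    G = 2 sum_c [ n_ac ln(n_ac/e_ac) + n_bc ln(n_bc/e_bc) ] with pooled
    expectations e_gc = N_g (n_ac + n_bc) / (N_a + N_b); zero-count terms
    contribute 0, so G >= 0 with equality iff the proportions coincide.
    """
    na = np.asarray(a.counts if isinstance(a, PatternCounts) else a, dtype=float)
    nb = np.asarray(b.counts if isinstance(b, PatternCounts) else b, dtype=float)
    Na, Nb = na.sum(), nb.sum()
    if Na < 1 or Nb < 1:
        raise ValueError("both samples need at least one read")
    tot = na + nb
    keep = tot > 0
    ea = Na * tot[keep] / (Na + Nb)
    eb = Nb * tot[keep] / (Na + Nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        g = 2.0 * (
            xlogy(na[keep], na[keep] / ea).sum()
            + xlogy(nb[keep], nb[keep] / eb).sum()
        )
    return float(max(g, 0.0))


@dataclass(frozen=True)
class GroupComparison:
    statistic: float
    reps: int
    n_greater_equal: int
    p_value: float
    seed: int | None
    groups: tuple[str, str]
    group_sizes: tuple[int, int]


def permutation_group_test(cohort: Cohort, reps: int = 1_000_000,
                           seed: int | None = None,
                           estimator: str = "count",
                           chunk: int = 20_000) -> GroupComparison:
    """Subject-label randomisation test on the G statistic.

    Subjects (not reads) are reassigned to the two groups, keeping the group
    sizes fixed; the pooled pattern counts of each randomised group are
    recomputed each repetition.  ``estimator="count"`` returns
    #(G_rand >= G_obs)/reps (ties favour the null); ``"plus-one"`` returns
    (#+1)/(reps+1).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    labels = cohort.group_labels()
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, got {labels}")
    ga, gb = labels
    ids_a = cohort.members_of(ga)
    ids_b = cohort.members_of(gb)
    if not ids_a or not ids_b:
        raise ValueError("both groups must be non-empty")
    M = cohort.count_matrix().astype(float)
    lab = np.array([cohort.group[i] for i in cohort.ids])
    A_obs = M[lab == ga].sum(axis=0)
    B_obs = M[lab == gb].sum(axis=0)
    g_obs = g_statistic(A_obs, B_obs)

    n_ind = len(cohort)
    n_a = len(ids_a)
    tot = M.sum(axis=0)
    keep = tot > 0
    Mk = M[:, keep]
    totk = tot[keep]
    N_tot = totk.sum()
    rng = np.random.default_rng(seed)
    n_ge = 0
    done = 0
    while done < reps:
        m = min(chunk, reps - done)
        u = rng.random((m, n_ind))
        sel_idx = np.argpartition(u, n_a - 1, axis=1)[:, :n_a]
        sel = np.zeros((m, n_ind), dtype=float)
        np.put_along_axis(sel, sel_idx, 1.0, axis=1)
        A = sel @ Mk
        B = totk[None, :] - A
        NA = A.sum(axis=1, keepdims=True)
        NB = N_tot - NA
        eA = NA * totk[None, :] / N_tot
        eB = NB * totk[None, :] / N_tot
        with np.errstate(invalid="ignore", divide="ignore"):
            g_rand = 2.0 * (xlogy(A, A / eA).sum(axis=1)
                            + xlogy(B, B / eB).sum(axis=1))
        n_ge += int((g_rand >= g_obs).sum())
        done += m
    if estimator == "count":
        p = n_ge / reps
    elif estimator == "plus-one":
        p = (n_ge + 1) / (reps + 1)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return GroupComparison(
        g_obs, reps, n_ge, float(p), seed, (ga, gb), (n_a, len(ids_b))
    )
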