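"""Model selection: best-model-per-edge-count sequences and edge statistics.

The 8,782 five-site equivalence classes are grouped by pDAG edge count
e = 0..10 and the best-scoring class M_e is found within each group.  Edges
are then characterised by

* rank: the smallest e for which M_e contains the edge, and
* support: the fraction of the models M_r..M_Emax containing it,

and, across individuals, by per-individual best-model tallies with
Bonferroni-corrected one-sided proportion tests (equally-supported model
sets, basic edge sets).  Edge identity is always the unordered site pair;
tie-breaks are deterministic (smaller canonical_id, lexicographic pair) and
logged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import Cohort, PatternCounts
from .enumeration import (
    Cpdag,
    EquivalenceClass,
    cpdag,
    enumerate_classes,
    group_by_edge_count,
    parent_mask_matrix,
)
from .scoring import SCORE_SIGN, ScoreCache

__all__ = [
    "SequenceEntry",
    "BestModelSequence",
    "EdgeRanking",
    "EquallySupported",
    "ModelSelector",
    "best_in_group",
    "best_sequence",
    "individual_sequences",
    "edge_rank_and_support",
    "equally_supported_set",
    "edge_appearance_stats",
    "basic_edge_set",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SequenceEntry:
    """Best model within the e-edge group."""

    n_edges: int
    cls: EquivalenceClass
    cpdag: Cpdag
    score: float
    loglik: float | None
    K: int

    @property
    def class_id(self) -> int:
        return self.cls.canonical_id


@dataclass(frozen=True)
class BestModelSequence:
    """M_0..M_Emax for one data source under one score type."""

    score_type: str
    source: str
    models: tuple[SequenceEntry, ...]

    @property
    def e_max(self) -> int:
        return len(self.models) - 1

    def skeleton(self, e: int) -> frozenset[tuple[int, int]]:
        return self.models[e].cls.skeleton

    def to_frame(self, labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        rows = []
        for m in self.models:
            pd_json = m.cpdag.to_json_dict(labels)
            rows.append(
                {
                    "n_edges": m.n_edges,
                    "class_id": m.class_id,
                    "K": m.K,
                    "loglik": m.loglik,
                    "score": m.score,
                    "directed": ";".join("->".join(e) for e in pd_json["directed"]),
                    "undirected": ";".join("--".join(e) for e in pd_json["undirected"]),
                }
            )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class EdgeRank:
    pair: tuple[int, int]
    rank: int | None
    support: float | None
    supporting_models: tuple[int, ...]


@dataclass(frozen=True)
class EdgeRanking:
    edges: dict[tuple[int, int], EdgeRank]
    e_max: int

    def to_frame(self, labels: tuple[str, ...] | None = None) -> pd.DataFrame:
        rows = []
        for (a, b), er in sorted(self.edges.items()):
            la, lb = (labels[a], labels[b]) if labels else (str(a), str(b))
            n_sup = len(er.supporting_models)
            rows.append(
                {
                    "edge": f"({la},{lb})",
                    "rank": er.rank,
                    "support": er.support,
                    "support_str": ""
                    if er.rank is None
                    else f"{n_sup}/{self.e_max - er.rank + 1}",
                    "models_supporting": ",".join(map(str, er.supporting_models)),
                }
            )
        return pd.DataFrame(rows)


class ModelSelector:
    """Cached enumeration + vectorised scoring machinery for n sites.

    Scoring all classes for one dataset costs one :class:`ScoreCache`
    (S 2^(S-1) family terms) plus a gather-sum over the class list.
    """

    def __init__(self, n: int):
        self.n = n
        self.classes = enumerate_classes(n)
        self.by_edge = group_by_edge_count(self.classes)
        self.pmat = parent_mask_matrix(self.classes, n)
        self.class_index = {c.canonical_id: k for k, c in enumerate(self.classes)}
        self.k_vec = np.array(
            [sum(1 << bin(m).count("1") for m in c.representative.parent_masks)
             for c in self.classes]
        )
        self._group_idx = {
            e: np.array([self.class_index[c.canonical_id] for c in cls_list])
            for e, cls_list in self.by_edge.items()
        }
        self._cpdag_cache: dict[int, Cpdag] = {}
        self.e_max = n * (n - 1) // 2

    def cpdag_of(self, cls: EquivalenceClass) -> Cpdag:
        if cls.canonical_id not in self._cpdag_cache:
            self._cpdag_cache[cls.canonical_id] = cpdag(cls)
        return self._cpdag_cache[cls.canonical_id]

    def score_all(self, counts: PatternCounts, score_type: str,
                  cache: ScoreCache | None = None) -> np.ndarray:
        cache = cache or ScoreCache(counts)
        return cache.scores_of(self.pmat, score_type)

    def _best_index(self, values: np.ndarray, idx: np.ndarray,
                    score_type: str) -> int:
        vals = values[idx] * -SCORE_SIGN[score_type]  # make "smaller is better"
        best = np.flatnonzero(vals == vals.min())
        if best.size > 1:
            ids = [self.classes[idx[b]].canonical_id for b in best]
            logger.info(
                "score tie among classes %s; choosing smallest canonical_id", ids
            )
        return int(idx[min(best, key=lambda b: self.classes[idx[b]].canonical_id)])

    def best_in_group(self, e: int, counts: PatternCounts, score_type: str,
                      cache: ScoreCache | None = None) -> SequenceEntry:
        cache = cache or ScoreCache(counts)
        values = self.score_all(counts, score_type, cache)
        return self._entry(e, values, cache, score_type)

    def _entry(self, e: int, values: np.ndarray, cache: ScoreCache,
               score_type: str) -> SequenceEntry:
        k = self._best_index(values, self._group_idx[e], score_type)
        cls = self.classes[k]
        ll = (
            float(cache.loglik_of(self.pmat[k:k + 1])[0])
            if cache.N >= 1
            else None
        )
        return SequenceEntry(
            n_edges=e,
            cls=cls,
            cpdag=self.cpdag_of(cls),
            score=float(values[k]),
            loglik=ll,
            K=int(self.k_vec[k]),
        )

    def best_sequence(self, counts: PatternCounts, score_type: str,
                      source: str = "pooled") -> BestModelSequence:
        if counts.N < 1:
            raise ValueError(f"source {source!r} has no reads (N=0)")
        cache = ScoreCache(counts)
        values = cache.scores_of(self.pmat, score_type)
        entries = tuple(
            self._entry(e, values, cache, score_type)
            for e in range(self.e_max + 1)
        )
        return BestModelSequence(score_type, source, entries)

    def individual_sequences(self, cohort: Cohort,
                             score_type: str) -> list[BestModelSequence]:
        out = []
        for pc in cohort.individuals:
            if pc.N == 0:
                logger.warning(
                    "skipping individual %r: no reads", pc.individual_id
                )
                continue
            out.append(self.best_sequence(pc, score_type, source=pc.individual_id))
        return out


_SELECTORS: dict[int, ModelSelector] = {}


def get_selector(n: int) -> ModelSelector:
    if n not in _SELECTORS:
        _SELECTORS[n] = ModelSelector(n)
    return _SELECTORS[n]


def best_in_group(classes_e: Sequence[EquivalenceClass], counts: PatternCounts,
                  score_type: str) -> tuple[EquivalenceClass, float]:
    """Best-scoring class within one edge-count group (module-level form)."""
    if not classes_e:
        raise ValueError("empty class group")
    cache = ScoreCache(counts)
    n = classes_e[0].n_nodes
    pmat = parent_mask_matrix(list(classes_e), n)
    values = cache.scores_of(pmat, score_type)
    order = sorted(
        range(len(classes_e)),
        key=lambda k: (-SCORE_SIGN[score_type] * values[k],
                       classes_e[k].canonical_id),
    )
    k = order[0]
    return classes_e[k], float(values[k])


def best_sequence(counts: PatternCounts, score_type: str,
                  source: str = "pooled") -> BestModelSequence:
    return get_selector(counts.S).best_sequence(counts, score_type, source)


def individual_sequences(cohort: Cohort, score_type: str) -> list[BestModelSequence]:
    return get_selector(cohort.sites.S).individual_sequences(cohort, score_type)


def edge_rank_and_support(seq: BestModelSequence) -> EdgeRanking:
    """Rank (first e containing the edge) and support (fraction of M_r..M_Emax
    containing it) for every edge appearing anywhere in the sequence."""
    e_max = seq.e_max
    all_pairs: set[tuple[int, int]] = set()
    for m in seq.models:
        all_pairs |= m.cls.skeleton
    edges = {}
    for pair in sorted(all_pairs):
        present = [e for e in range(e_max + 1) if pair in seq.skeleton(e)]
        rank = present[0]
        support = len(present) / (e_max - rank + 1)
        edges[pair] = EdgeRank(pair, rank, support, tuple(present))
    return EdgeRanking(edges, e_max)


def _one_sided_proportion_p(k1: int, k2: int, n: int) -> float:
    """One-sided two-sample z-test (pooled variance) that proportion k1/n
    exceeds k2/n; marginal-binomial treatment of the supporter counts."""
    p1, p2 = k1 / n, k2 / n
    pbar = (k1 + k2) / (2 * n)
    if pbar in (0.0, 1.0):
        return 1.0
    se = np.sqrt(pbar * (1 - pbar) * (2 / n))
    z = (p1 - p2) / se
    return float(norm.sf(z))


@dataclass(frozen=True)
class EquallySupported:
    """Result of the Bonferroni proportion-test series at one edge count."""

    retained: tuple
    p_values: tuple[float, ...]
    n_comparisons: int
    alpha: float


def equally_supported_set(tally: Sequence[tuple[object, int]], n_individuals: int,
                          alpha: float = 0.05) -> EquallySupported:
    """Prefix of the descending support tally not significantly below the top.

    ``tally`` lists (model, supporter count) sorted by count descending.  The
    top model is compared against each other model with a one-sided
    proportion test; the Bonferroni divisor is the number of comparisons in
    the series.  The set ends just before the first significantly lower
    model; if none is significant, every tallied model is retained.
    """
    ks = [k for _, k in tally]
    if ks != sorted(ks, reverse=True):
        raise ValueError("tally must be sorted by supporter count, descending")
    if len(tally) == 1:
        return EquallySupported((tally[0][0],), (), 0, alpha)
    k1 = tally[0][1]
    n_comp = len(tally) - 1
    pvals = tuple(
        _one_sided_proportion_p(k1, kj, n_individuals) for _, kj in tally[1:]
    )
    cutoff = len(tally)
    for j, p in enumerate(pvals, start=1):
        if p < alpha / n_comp:
            cutoff = j
            break
    return EquallySupported(
        tuple(m for m, _ in tally[:cutoff]), pvals, n_comp, alpha
    )


def model_tally(sequences: Sequence[BestModelSequence], e: int
                ) -> list[tuple[int, int]]:
    """Descending tally of distinct best classes at edge count e.

    Count ties are broken by smaller canonical_id for determinism.
    """
    counts: dict[int, int] = {}
    for seq in sequences:
        cid = seq.models[e].class_id
        counts[cid] = counts.get(cid, 0) + 1
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


@dataclass(frozen=True)
class EdgeStat:
    pair: tuple[int, int]
    k: int
    n: int

    @property
    def proportion(self) -> float:
        return self.k / self.n

    @property
    def variance(self) -> float:
        """Binomial proportion variance p(1-p)/n."""
        p = self.proportion
        return p * (1 - p) / self.n

    @property
    def count_variance(self) -> float:
        """Binomial count variance n p(1-p)."""
        p = self.proportion
        return self.n * p * (1 - p)


def edge_appearance_stats(sequences: Sequence[BestModelSequence], e: int
                          ) -> dict[tuple[int, int], EdgeStat]:
    """Per-edge appearance counts across individual best models M_e^(i)."""
    if not sequences:
        raise ValueError("no sequences given")
    n_nodes = sequences[0].models[0].cpdag.n_nodes
    n = len(sequences)
    stats = {}
    for a in range(n_nodes):
        for b in range(a + 1, n_nodes):
            k = sum((a, b) in seq.skeleton(e) for seq in sequences)
            stats[(a, b)] = EdgeStat((a, b), k, n)
    return stats


@dataclass(frozen=True)
class BasicEdgeSet:
    e: int
    basic: tuple[tuple[int, int], ...]
    additional: tuple[tuple[int, int], ...]
    n_unique_models: int
    stats: dict[tuple[int, int], EdgeStat] = field(hash=False, default_factory=dict)


def basic_edge_set(sequences: Sequence[BestModelSequence], e: int,
                   alpha: float = 0.05) -> BasicEdgeSet:
    """The e most-supported edges at edge count e, plus "additional" edges
    whose support is not significantly below the e-th under Bonferroni."""
    if e < 1:
        raise ValueError("basic edge set requires e >= 1")
    stats = edge_appearance_stats(sequences, e)
    n = len(sequences)
    ordered = sorted(stats.values(), key=lambda s: (-s.k, s.pair))
    basic = tuple(s.pair for s in ordered[:e])
    k_ref = ordered[e - 1].k
    rest = [s for s in ordered[e:] if s.k > 0]
    additional = []
    if rest:
        n_comp = len(rest)
        for s in rest:
            p = _one_sided_proportion_p(k_ref, s.k, n)
            if p >= alpha / n_comp:
                additional.append(s.pair)
    n_unique = len({seq.models[e].class_id for seq in sequences})
    return BasicEdgeSet(e, basic, tuple(additional), n_unique, stats)
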