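"""Scoring of Bayesian-network models against pattern counts.

For binary sites the sufficient statistics of a model are per-family counts
N(x_i, pa_i) obtained by marginalising the 2^S pattern histogram onto each
node and its parent set.  From these we compute:

* maximum-likelihood CPT estimates theta(x_i=1 | pa) = N(1, pa) / N(pa),
* the maximised log-likelihood sum_i sum_pa sum_x N(x, pa) ln theta(x | pa)
  (0 ln 0 = 0; parent configurations never observed contribute nothing),
* BIC = -2 lnL + K ln N and AIC = -2 lnL + 2K with K = sum_i 2^{|Pa_i|}
  (both minimised),
* a Bayesian score: the log marginal likelihood under Dirichlet priors
  equivalent to one pseudo-measurement per possible S-site pattern, i.e.
  alpha(x, pa) = 2^{S-1-|Pa_i|} and alpha(pa) = 2^{S-|Pa_i|} (maximised).

All four quantities depend on a DAG only through its parent sets and are
identical for every member of a Markov equivalence class (score
equivalence); the uniform pseudo-sample prior preserves this for the
Bayesian score as well.  Scores are evaluated from a per-(node, parent-set)
table so that scoring all 8,782 five-site classes is a cheap gather-sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlogy

from .core import PatternCounts
from .enumeration import Dag, EquivalenceClass, parent_mask_matrix

__all__ = [
    "FamilyCounts",
    "ModelScore",
    "ScoreCache",
    "family_counts",
    "ml_estimate",
    "log_likelihood",
    "n_params",
    "bic_score",
    "aic_score",
    "bayes_score",
    "better",
    "SCORE_TYPES",
]

SCORE_TYPES = ("BIC", "AIC", "BAYES")

#: +1 if larger values are better for the score type, -1 if smaller.
SCORE_SIGN = {"BIC": -1, "AIC": -1, "BAYES": +1, "LOGLIK": +1}


def better(value_a: float, value_b: float, score_type: str) -> bool:
    """True if value_a is a strictly better score than value_b."""
    return SCORE_SIGN[score_type] * (value_a - value_b) > 0


@dataclass(frozen=True)
class FamilyCounts:
    """Sufficient statistics for one node given an ordered parent list.

    ``n1[pa]`` / ``n0[pa]`` count reads with the node edited / unedited in
    parent configuration ``pa`` (first listed parent = MSB of the config).
    """

    node: int
    parents: tuple[int, ...]
    n1: np.ndarray
    n0: np.ndarray

    @property
    def n_pa(self) -> np.ndarray:
        return self.n1 + self.n0

    @property
    def N(self) -> int:
        return int(self.n1.sum() + self.n0.sum())


@dataclass(frozen=True)
class ModelScore:
    class_id: int | None
    score_type: str
    value: float
    K: int
    loglik: float | None = None


def _site_bits(S: int) -> np.ndarray:
    """(2^S, S) matrix of pattern bits, MSB-first site order."""
    pats = np.arange(1 << S)
    return ((pats[:, None] >> (S - 1 - np.arange(S))) & 1).astype(np.int64)


def family_counts(
    counts: PatternCounts, node: int, parents: tuple[int, ...] | list[int]
) -> FamilyCounts:
    """Marginalise the pattern histogram onto (node, parents)."""
    parents = tuple(parents)
    S = counts.S
    if node in parents:
        raise ValueError(f"node {node} cannot be its own parent")
    if not 0 <= node < S or any(not 0 <= p < S for p in parents):
        raise ValueError(f"site indices must be < {S}")
    if len(set(parents)) != len(parents):
        raise ValueError(f"duplicate parents {parents}")
    bits = _site_bits(S)
    npa = len(parents)
    if npa:
        weights = 1 << np.arange(npa - 1, -1, -1)
        cfg = bits[:, list(parents)] @ weights
    else:
        cfg = np.zeros(1 << S, dtype=np.int64)
    x = bits[:, node]
    n1 = np.bincount(cfg, weights=counts.counts * x, minlength=1 << npa)
    n0 = np.bincount(cfg, weights=counts.counts * (1 - x), minlength=1 << npa)
    return FamilyCounts(node, parents, n1.astype(np.int64), n0.astype(np.int64))


def ml_estimate(fc: FamilyCounts) -> np.ndarray:
    """theta-hat(x=1 | pa) = N(1,pa)/N(pa); NaN where N(pa)=0 (undefined)."""
    n = fc.n_pa
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.where(n > 0, fc.n1 / np.maximum(n, 1), np.nan)
    return theta


def _family_loglik(n1: np.ndarray, n0: np.ndarray) -> float:
    """Maximised log-likelihood contribution of one family (0 ln 0 = 0)."""
    n = n1 + n0
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = xlogy(n1, np.where(n > 0, n1 / np.maximum(n, 1), 1.0))
        t0 = xlogy(n0, np.where(n > 0, n0 / np.maximum(n, 1), 1.0))
    return float(t1.sum() + t0.sum())


def _family_bayes(n1: np.ndarray, n0: np.ndarray, S: int, n_parents: int,
                  pseudo_multiplier: float = 1.0) -> float:
    """Log marginal-likelihood contribution of one family under the
    one-pseudo-measurement-per-pattern Dirichlet prior."""
    a_x = pseudo_multiplier * float(1 << (S - 1 - n_parents))
    a_pa = 2.0 * a_x
    n = n1 + n0
    term = (
        gammaln(a_pa) - gammaln(a_pa + n)
        + gammaln(a_x + n1) - gammaln(a_x)
        + gammaln(a_x + n0) - gammaln(a_x)
    )
    return float(term.sum())


class ScoreCache:
    """Per-dataset score tables over all (node, parent-set) families.

    There are only S * 2^(S-1) distinct families, so precomputing their
    log-likelihood and Bayesian contributions makes scoring any number of
    DAGs or classes a constant-time gather.  Index convention:
    ``node * 2^S + parent_bitmask``.
    """

    def __init__(self, counts: PatternCounts, pseudo_multiplier: float = 1.0):
        self.counts = counts
        self.S = S = counts.S
        self.N = counts.N
        self.pseudo_multiplier = pseudo_multiplier
        size = S << S
        self.loglik_fam = np.full(size, np.nan)
        self.bayes_fam = np.full(size, np.nan)
        self.k_fam = np.zeros(size, dtype=np.int64)
        bits = _site_bits(S)
        vec = counts.counts
        for node in range(S):
            x = bits[:, node]
            for mask in range(1 << S):
                if (mask >> node) & 1:
                    continue  # node cannot be its own parent
                parents = [p for p in range(S) if (mask >> p) & 1]
                npa = len(parents)
                if npa:
                    weights = 1 << np.arange(npa - 1, -1, -1)
                    cfg = bits[:, parents] @ weights
                else:
                    cfg = np.zeros(1 << S, dtype=np.int64)
                n1 = np.bincount(cfg, weights=vec * x, minlength=1 << npa)
                n0 = np.bincount(cfg, weights=vec * (1 - x), minlength=1 << npa)
                idx = (node << S) | mask
                self.loglik_fam[idx] = _family_loglik(n1, n0)
                self.bayes_fam[idx] = _family_bayes(
                    n1, n0, S, npa, pseudo_multiplier
                )
                self.k_fam[idx] = 1 << npa

    def _fam_indices(self, pmat: np.ndarray) -> np.ndarray:
        nodes = np.arange(self.S, dtype=np.int64)
        return (nodes << self.S) + pmat

    def loglik_of(self, pmat: np.ndarray) -> np.ndarray:
        """Log-likelihood for each row of a parent-mask matrix."""
        return self.loglik_fam[self._fam_indices(pmat)].sum(axis=1)

    def k_of(self, pmat: np.ndarray) -> np.ndarray:
        return self.k_fam[self._fam_indices(pmat)].sum(axis=1)

    def scores_of(self, pmat: np.ndarray, score_type: str) -> np.ndarray:
        """Score vector for the models described by a parent-mask matrix."""
        if score_type == "BAYES":
            return self.bayes_fam[self._fam_indices(pmat)].sum(axis=1)
        if self.N < 1:
            raise ValueError("ML-based scores require at least one read")
        ll = self.loglik_of(pmat)
        k = self.k_of(pmat)
        if score_type == "BIC":
            return -2.0 * ll + k * np.log(self.N)
        if score_type == "AIC":
            return -2.0 * ll + 2.0 * k
        if score_type == "LOGLIK":
            return ll
        raise ValueError(f"unknown score type {score_type!r}")


def _as_pmat(model: Dag | EquivalenceClass) -> tuple[np.ndarray, int, int | None]:
    if isinstance(model, EquivalenceClass):
        dag = model.representative
        cid = model.canonical_id
    else:
        dag, cid = model, None
    pmat = parent_mask_matrix([dag], dag.n_nodes)
    return pmat, dag.n_nodes, cid


def log_likelihood(model: Dag | EquivalenceClass, counts: PatternCounts,
                   cache: ScoreCache | None = None) -> float:
    """Maximised log-likelihood of a DAG or class (class-invariant)."""
    if counts.N < 1:
        raise ValueError("log-likelihood requires at least one read")
    pmat, _, _ = _as_pmat(model)
    cache = cache or ScoreCache(counts)
    return float(cache.loglik_of(pmat)[0])


def n_params(model: Dag | EquivalenceClass) -> int:
    """K = sum_i 2^{|Pa_i|}, identical for all members of a class."""
    dag = model.representative if isinstance(model, EquivalenceClass) else model
    return sum(1 << bin(m).count("1") for m in dag.parent_masks)


def _ml_penalised(model, counts, cache, score_type) -> ModelScore:
    pmat, _, cid = _as_pmat(model)
    cache = cache or ScoreCache(counts)
    ll = float(cache.loglik_of(pmat)[0])
    k = int(cache.k_of(pmat)[0])
    value = float(cache.scores_of(pmat, score_type)[0])
    return ModelScore(cid, score_type, value, k, loglik=ll)


def bic_score(model: Dag | EquivalenceClass, counts: PatternCounts,
              cache: ScoreCache | None = None) -> ModelScore:
    """BIC = -2 lnL + K ln N (minimised)."""
    return _ml_penalised(model, counts, cache, "BIC")


def aic_score(model: Dag | EquivalenceClass, counts: PatternCounts,
              cache: ScoreCache | None = None) -> ModelScore:
    """AIC = -2 lnL + 2K (minimised)."""
    return _ml_penalised(model, counts, cache, "AIC")


def bayes_score(model: Dag | EquivalenceClass, counts: PatternCounts,
                cache: ScoreCache | None = None,
                pseudo_multiplier: float = 1.0) -> ModelScore:
    """Log marginal likelihood under the uniform pseudo-sample prior
    (maximised).  Defined for N = 0, where it is 0 for every model."""
    pmat, _, cid = _as_pmat(model)
    if cache is None:
        cache = ScoreCache(counts, pseudo_multiplier=pseudo_multiplier)
    value = float(cache.scores_of(pmat, "BAYES")[0])
    return ModelScore(cid, "BAYES", value, n_params(model))
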