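"""Exhaustive enumeration of DAGs and their Markov equivalence classes.

Every factorisation of a joint distribution over S binary sites corresponds
to a labeled DAG; DAGs sharing skeleton and v-structures encode the same
conditional-independence model (Markov equivalence) and receive identical
likelihood-based scores.  At S = 5 there are 29,281 DAGs partitioning into
8,782 equivalence classes, each visualised by its CPDAG (pDAG): an edge is
drawn directed only when every member of the class orients it the same way.

The approach is exponential in S and intended for small site sets; the
enumeration is capped (default S <= 6) and results are cached per S.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import cached_property
from math import comb

import numpy as np

__all__ = [
    "Dag",
    "EquivalenceClass",
    "Cpdag",
    "count_dags",
    "enumerate_dags",
    "equivalence_signature",
    "partition_into_classes",
    "enumerate_classes",
    "cpdag",
    "group_by_edge_count",
    "parent_mask_matrix",
]

#: Default cap on exhaustive enumeration (3,781,503 DAGs at n=6).
ENUMERATION_CAP = 6


@dataclass(frozen=True)
class Dag:
    """Directed acyclic graph on nodes 0..n_nodes-1."""

    n_nodes: int
    edges: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        object.__setattr__(self, "edges", frozenset(self.edges))
        for p, c in self.edges:
            if p == c:
                raise ValueError(f"self-loop at node {p}")
            if not (0 <= p < self.n_nodes and 0 <= c < self.n_nodes):
                raise ValueError(f"edge ({p},{c}) outside 0..{self.n_nodes - 1}")
        if not self._is_acyclic():
            raise ValueError(f"graph with edges {sorted(self.edges)} has a cycle")

    def _is_acyclic(self) -> bool:
        indeg = [0] * self.n_nodes
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for p, c in self.edges:
            indeg[c] += 1
            children[p].append(c)
        stack = [v for v in range(self.n_nodes) if indeg[v] == 0]
        seen = 0
        while stack:
            v = stack.pop()
            seen += 1
            for c in children[v]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    stack.append(c)
        return seen == self.n_nodes

    @cached_property
    def parent_masks(self) -> tuple[int, ...]:
        """Per-node bitmask of parent node indices."""
        masks = [0] * self.n_nodes
        for p, c in self.edges:
            masks[c] |= 1 << p
        return tuple(masks)

    def parents(self, node: int) -> tuple[int, ...]:
        m = self.parent_masks[node]
        return tuple(v for v in range(self.n_nodes) if (m >> v) & 1)

    @property
    def n_edges(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class EquivalenceClass:
    """A Markov equivalence class: all DAGs sharing skeleton and v-structures.

    ``canonical_id`` is the smallest enumeration rank (lexicographic by
    adjacency bits) among the members, which makes ids deterministic and
    reproducible across runs; members are kept in enumeration order so
    ``members[0]`` is the canonical representative.
    """

    canonical_id: int
    members: tuple[Dag, ...]
    skeleton: frozenset[tuple[int, int]]
    v_structures: frozenset[tuple[int, int, int]]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("equivalence class must have at least one member")

    @property
    def n_edges(self) -> int:
        return len(self.skeleton)

    @property
    def n_nodes(self) -> int:
        return self.members[0].n_nodes

    @property
    def representative(self) -> Dag:
        return self.members[0]


@dataclass(frozen=True)
class Cpdag:
    """Partially directed graph (pDAG) representing an equivalence class."""

    n_nodes: int
    directed: frozenset[tuple[int, int]]
    undirected: frozenset[tuple[int, int]]

    def __post_init__(self) -> None:
        und = frozenset((min(a, b), max(a, b)) for a, b in self.undirected)
        object.__setattr__(self, "undirected", und)
        dir_pairs = {(min(a, b), max(a, b)) for a, b in self.directed}
        if dir_pairs & und:
            raise ValueError("a pair cannot be both directed and undirected")

    @property
    def skeleton(self) -> frozenset[tuple[int, int]]:
        return frozenset(
            {(min(a, b), max(a, b)) for a, b in self.directed} | self.undirected
        )

    def to_json_dict(self, labels: tuple[str, ...] | None = None) -> dict:
        lab = labels or tuple(str(v) for v in range(self.n_nodes))
        return {
            "directed": sorted([lab[a], lab[b]] for a, b in self.directed),
            "undirected": sorted([lab[a], lab[b]] for a, b in self.undirected),
        }

    def to_dot(self, labels: tuple[str, ...] | None = None,
               name: str = "pdag") -> str:
        lab = labels or tuple(str(v) for v in range(self.n_nodes))
        lines = [f"digraph {name} {{"]
        for v in range(self.n_nodes):
            lines.append(f'  "{lab[v]}";')
        for a, b in sorted(self.directed):
            lines.append(f'  "{lab[a]}" -> "{lab[b]}";')
        for a, b in sorted(self.undirected):
            lines.append(f'  "{lab[a]}" -> "{lab[b]}" [dir=none];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def count_dags(n: int) -> int:
    """Number of labeled DAGs on n nodes by the standard inclusion-exclusion
    recursion a(n) = sum_k (-1)^(k+1) C(n,k) 2^(k(n-k)) a(n-k)."""
    if not 1 <= n <= 8:
        raise ValueError(f"n must be in 1..8, got {n}")
    a = [1]
    for m in range(1, n + 1):
        a.append(
            sum(
                (-1) ** (k + 1) * comb(m, k) * 2 ** (k * (m - k)) * a[m - k]
                for k in range(1, m + 1)
            )
        )
    return a[n]


_DAG_CACHE: dict[int, list[Dag]] = {}
_CLASS_CACHE: dict[int, list[EquivalenceClass]] = {}


def _edge_slots(n: int) -> list[tuple[int, int]]:
    """Row-major ordered pairs (i, j), i != j: the adjacency-bit order."""
    return [(i, j) for i in range(n) for j in range(n) if i != j]


def enumerate_dags(n: int, cap: int = ENUMERATION_CAP) -> list[Dag]:
    """All labeled DAGs on n nodes, in lexicographic adjacency-bit order.

    Enumerated by deciding each ordered pair (row-major, absent before
    present) with incremental transitive-closure pruning, so only acyclic
    graphs are ever visited.
    """
    if n > cap:
        raise ValueError(
            f"enumeration of DAGs on {n} nodes refused (cap={cap}): "
            f"{count_dags(n)} graphs is combinatorially infeasible here"
        )
    if n in _DAG_CACHE:
        return _DAG_CACHE[n]
    slots = _edge_slots(n)
    results: list[Dag] = []
    edges: list[tuple[int, int]] = []
    reach = [1 << v for v in range(n)]  # reach[v]: nodes reachable from v

    def rec(k: int) -> None:
        if k == len(slots):
            results.append(Dag(n, frozenset(edges)))
            return
        rec(k + 1)  # slot absent first: lexicographic order
        i, j = slots[k]
        if not (reach[j] >> i) & 1:  # adding i->j keeps the graph acyclic
            saved = reach.copy()
            rj = reach[j]
            for v in range(n):
                if (reach[v] >> i) & 1:
                    reach[v] |= rj
            edges.append((i, j))
            rec(k + 1)
            edges.pop()
            reach[:] = saved

    rec(0)
    _DAG_CACHE[n] = results
    return results


def equivalence_signature(
    dag: Dag,
) -> tuple[frozenset[tuple[int, int]], frozenset[tuple[int, int, int]]]:
    """(skeleton, v-structures) — equal iff two DAGs are Markov equivalent.

    A v-structure is an unshielded collider a->c<-b with a, b non-adjacent;
    triples are stored as (min(a,b), max(a,b), c).
    """
    skeleton = frozenset((min(p, c), max(p, c)) for p, c in dag.edges)
    vs = set()
    for c in range(dag.n_nodes):
        ps = dag.parents(c)
        for a, b in itertools.combinations(ps, 2):
            if (min(a, b), max(a, b)) not in skeleton:
                vs.add((min(a, b), max(a, b), c))
    return skeleton, frozenset(vs)


def partition_into_classes(dags: list[Dag]) -> list[EquivalenceClass]:
    """Partition an exhaustive DAG list into Markov equivalence classes,
    ordered by canonical_id (= smallest member enumeration rank)."""
    groups: dict[tuple, tuple[int, list[Dag]]] = {}
    for rank, dag in enumerate(dags):
        sig = equivalence_signature(dag)
        if sig in groups:
            groups[sig][1].append(dag)
        else:
            groups[sig] = (rank, [dag])
    classes = [
        EquivalenceClass(
            canonical_id=rank,
            members=tuple(members),
            skeleton=sig[0],
            v_structures=sig[1],
        )
        for sig, (rank, members) in groups.items()
    ]
    classes.sort(key=lambda c: c.canonical_id)
    return classes


def enumerate_classes(n: int, cap: int = ENUMERATION_CAP) -> list[EquivalenceClass]:
    """All Markov equivalence classes on n nodes (cached per n)."""
    if n not in _CLASS_CACHE:
        _CLASS_CACHE[n] = partition_into_classes(enumerate_dags(n, cap=cap))
    return _CLASS_CACHE[n]


def cpdag(cls: EquivalenceClass) -> Cpdag:
    """CPDAG by member census: an edge is directed iff every member of the
    class orients it identically, otherwise it is undirected.

    Exact at this scale; no rule-based compelled-edge algorithm is needed.
    """
    directed = set()
    undirected = set()
    for a, b in cls.skeleton:
        forward = [(a, b) in m.edges for m in cls.members]
        if all(forward):
            directed.add((a, b))
        elif not any(forward):
            directed.add((b, a))
        else:
            undirected.add((a, b))
    return Cpdag(cls.n_nodes, frozenset(directed), frozenset(undirected))


def group_by_edge_count(
    classes: list[EquivalenceClass],
) -> dict[int, list[EquivalenceClass]]:
    """Group classes by skeleton size; keys are exactly 0..n(n-1)/2."""
    n = classes[0].n_nodes
    e_max = n * (n - 1) // 2
    out: dict[int, list[EquivalenceClass]] = {e: [] for e in range(e_max + 1)}
    for c in classes:
        out[c.n_edges].append(c)
    return out


def parent_mask_matrix(models: list[EquivalenceClass] | list[Dag], n: int) -> np.ndarray:
    """(n_models, n) matrix of per-node parent bitmasks of each model's
    representative DAG — the gather index used for vectorised scoring."""
    rows = np.empty((len(models), n), dtype=np.int64)
    for k, m in enumerate(models):
        dag = m.representative if isinstance(m, EquivalenceClass) else m
        rows[k] = dag.parent_masks
    return rows
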