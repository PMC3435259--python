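"""Core data model: editing sites, per-individual pattern counts, cohorts, and TSV/JSON I/O.

A single transcript read is summarised as a binary vector over the S editing
sites (1 = edited).  Per individual we keep only the histogram of these
vectors: a length-2^S integer count vector indexed by the decimal value of
the pattern, with the FIRST listed site as the most-significant bit, so for
the default site order (A, B, E, C, D) the pattern "11001" (A, B, D edited)
has index 25.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_SITE_LABELS",
    "SiteSet",
    "PatternCounts",
    "Cohort",
    "pattern_index",
    "pattern_string",
    "from_read_matrix",
    "pool",
    "read_pattern_counts",
    "write_pattern_counts",
    "read_site_config",
]

#: Genomic (5'->3') order of the five serotonin-receptor editing sites.
DEFAULT_SITE_LABELS = ("A", "B", "E", "C", "D")

#: Exhaustive enumeration downstream is exponential in S; refuse beyond this.
MAX_SITES = 6


class FormatError(ValueError):
    """Malformed pattern string or input table."""


@dataclass(frozen=True)
class SiteSet:
    """Ordered collection of site names defining the pattern bit order."""

    labels: tuple[str, ...] = DEFAULT_SITE_LABELS

    def __post_init__(self) -> None:
        labels = tuple(self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 2:
            raise ValueError("need at least two sites")
        if len(set(labels)) != len(labels):
            raise ValueError(f"site labels must be unique, got {labels!r}")

    @property
    def S(self) -> int:
        return len(self.labels)

    @property
    def n_patterns(self) -> int:
        return 1 << self.S

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"unknown site {label!r}") from None

    def pairs(self) -> list[tuple[int, int]]:
        """All unordered site-index pairs (i < j)."""
        return [(i, j) for i in range(self.S) for j in range(i + 1, self.S)]


def pattern_index(pattern: str, sites: SiteSet) -> int:
    """Decimal index of a binary pattern string (first site = MSB)."""
    if len(pattern) != sites.S:
        raise FormatError(
            f"pattern {pattern!r} has length {len(pattern)}, expected {sites.S}"
        )
    if set(pattern) - {"0", "1"}:
        raise FormatError(f"pattern {pattern!r} contains characters other than 0/1")
    return int(pattern, 2)


def pattern_string(index: int, sites: SiteSet) -> str:
    """Inverse of :func:`pattern_index`."""
    if not 0 <= index < sites.n_patterns:
        raise FormatError(f"pattern index {index} out of range for S={sites.S}")
    return format(index, f"0{sites.S}b")


class PatternCounts:
    """One individual's read counts over all 2^S editing patterns."""

    __slots__ = ("individual_id", "counts")

    def __init__(self, individual_id: str, counts: Sequence[int] | np.ndarray):
        arr = np.asarray(counts, dtype=np.int64)
        if arr.ndim != 1 or (arr.size & (arr.size - 1)) or arr.size < 4:
            raise ValueError(
                f"counts must be a vector of length 2^S (S>=2), got shape {arr.shape}"
            )
        if (arr < 0).any():
            raise ValueError(f"negative counts for individual {individual_id!r}")
        self.individual_id = individual_id
        self.counts = arr

    @property
    def N(self) -> int:
        """Total number of reads."""
        return int(self.counts.sum())

    @property
    def S(self) -> int:
        return self.counts.size.bit_length() - 1

    def frequencies(self) -> np.ndarray:
        if self.N == 0:
            raise ValueError(
                f"individual {self.individual_id!r} has no reads (N=0)"
            )
        return self.counts / self.N

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PatternCounts):
            return NotImplemented
        return self.individual_id == other.individual_id and np.array_equal(
            self.counts, other.counts
        )

    def __repr__(self) -> str:
        return f"PatternCounts({self.individual_id!r}, S={self.S}, N={self.N})"


@dataclass
class Cohort:
    """A set of individuals with group labels sharing one site ordering."""

    sites: SiteSet
    individuals: list[PatternCounts]
    group: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [pc.individual_id for pc in self.individuals]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dup}")
        n = self.sites.n_patterns
        for pc in self.individuals:
            if pc.counts.size != n:
                raise ValueError(
                    f"individual {pc.individual_id!r} has {pc.counts.size} patterns, "
                    f"expected {n}"
                )
        if not self.group:
            self.group = {i: "all" for i in ids}
        missing = set(ids) - set(self.group)
        if missing:
            raise ValueError(f"individuals without group label: {sorted(missing)}")
        if any(not g for g in self.group.values()):
            raise ValueError("empty group labels are not allowed")

    @property
    def ids(self) -> list[str]:
        return [pc.individual_id for pc in self.individuals]

    def __len__(self) -> int:
        return len(self.individuals)

    def __getitem__(self, individual_id: str) -> PatternCounts:
        for pc in self.individuals:
            if pc.individual_id == individual_id:
                return pc
        raise KeyError(f"unknown individual {individual_id!r}")

    def count_matrix(self) -> np.ndarray:
        """(n_individuals, 2^S) integer matrix in cohort order."""
        return np.stack([pc.counts for pc in self.individuals])

    def group_labels(self) -> list[str]:
        return sorted(set(self.group.values()))

    def members_of(self, label: str) -> list[str]:
        return [i for i in self.ids if self.group[i] == label]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Cohort):
            return NotImplemented
        return (
            self.sites == other.sites
            and self.individuals == other.individuals
            and self.group == other.group
        )


def from_read_matrix(
    rows: Iterable[str | Sequence[int]],
    individual_id: str,
    sites: SiteSet,
) -> PatternCounts:
    """Aggregate per-read binary vectors into a pattern histogram.

    ``rows`` may contain pattern strings ("11001") or 0/1 sequences.  An
    empty row list yields an all-zero histogram (N=0), which is accepted at
    construction but rejected by analysis stages.
    """
    counts = np.zeros(sites.n_patterns, dtype=np.int64)
    for row in rows:
        if isinstance(row, str):
            idx = pattern_index(row, sites)
        else:
            if len(row) != sites.S:
                raise FormatError(
                    f"read vector of length {len(row)}, expected {sites.S}"
                )
            idx = 0
            for b in row:
                if b not in (0, 1):
                    raise FormatError(f"read vector entries must be 0/1, got {b!r}")
                idx = (idx << 1) | b
        counts[idx] += 1
    return PatternCounts(individual_id, counts)


def pool(cohort: Cohort, ids: Sequence[str] | None = None,
         individual_id: str = "pooled") -> PatternCounts:
    """Element-wise sum of the pattern counts of a subset of individuals."""
    if ids is None:
        ids = cohort.ids
    ids = list(ids)
    if not ids:
        raise ValueError("cannot pool an empty set of individuals")
    total = np.zeros(cohort.sites.n_patterns, dtype=np.int64)
    for i in ids:
        total += cohort[i].counts
    return PatternCounts(individual_id, total)


# ---------------------------------------------------------------------------
# File formats
# ---------------------------------------------------------------------------
#
# Pattern-count TSV: UTF-8, '#' comment lines permitted, header
#   individual_id <TAB> group <TAB> pattern <TAB> count
# Site config JSON: {"sites": ["A", "B", "E", "C", "D"]}

_COLUMNS = ["individual_id", "group", "pattern", "count"]


def read_site_config(path: str | Path) -> SiteSet:
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if not isinstance(data, dict) or "sites" not in data:
        raise FormatError(f"{path}: site config must be a JSON object with 'sites'")
    return SiteSet(tuple(data["sites"]))


def read_pattern_counts(path: str | Path, sites: SiteSet | None = None) -> Cohort:
    """Read a pattern-count TSV into a validated :class:`Cohort`.

    Patterns missing for an individual are filled with count 0; duplicate
    (individual, pattern) rows and negative counts are errors reported with
    the offending data-row number.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"individual_id": str, "group": str, "pattern": str},
    )
    if list(df.columns) != _COLUMNS:
        raise FormatError(
            f"{path}: expected columns {_COLUMNS}, got {list(df.columns)}"
        )
    lengths = df["pattern"].str.len().unique()
    if len(lengths) > 1:
        raise FormatError(
            f"{path}: inconsistent pattern lengths {sorted(int(x) for x in lengths)}"
        )
    if sites is None:
        if len(df) == 0:
            raise FormatError(f"{path}: empty table and no site config given")
        s = int(lengths[0])
        if s == len(DEFAULT_SITE_LABELS):
            sites = SiteSet()
        else:
            sites = SiteSet(tuple(f"S{k}" for k in range(s)))
    if len(df) and int(lengths[0]) != sites.S:
        raise FormatError(
            f"{path}: patterns of length {int(lengths[0])} but {sites.S} sites configured"
        )

    counts_col = pd.to_numeric(df["count"], errors="raise")
    bad = counts_col < 0
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(f"{path}: negative count at data row {row + 1}")

    dup = df.duplicated(subset=["individual_id", "pattern"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise FormatError(
            f"{path}: duplicate (individual, pattern) entry at data row {row + 1}"
        )

    individuals: list[PatternCounts] = []
    group: dict[str, str] = {}
    for ind, sub in df.groupby("individual_id", sort=False):
        glabels = set(sub["group"])
        if len(glabels) > 1:
            raise FormatError(
                f"{path}: individual {ind!r} appears with several group labels "
                f"{sorted(glabels)}"
            )
        vec = np.zeros(sites.n_patterns, dtype=np.int64)
        for pat, cnt in zip(sub["pattern"], counts_col[sub.index]):
            vec[pattern_index(pat, sites)] = int(cnt)
        individuals.append(PatternCounts(str(ind), vec))
        group[str(ind)] = str(next(iter(glabels)))
    return Cohort(sites=sites, individuals=individuals, group=group)


def write_pattern_counts(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort in canonical form (zero-count rows omitted).

    An individual with no reads at all is represented by a single explicit
    zero-count row so that the round-trip preserves cohort membership.
    """
    rows = []
    for pc in cohort.individuals:
        g = cohort.group[pc.individual_id]
        nz = np.flatnonzero(pc.counts)
        if nz.size == 0:
            rows.append((pc.individual_id, g, pattern_string(0, cohort.sites), 0))
            continue
        for idx in nz:
            rows.append(
                (pc.individual_id, g, pattern_string(int(idx), cohort.sites),
                 int(pc.counts[idx]))
            )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, sep="\t", index=False)
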