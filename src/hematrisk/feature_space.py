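"""Cluster-constrained biomarker tuple space.

Grouping the p = 29 biomarkers into m = 7 correlation clusters and taking
exactly one representative per cluster reduces the classifier search space
from the unconstrained sum of binomial coefficients
N_T = sum_{k=1..k_max} C(p, k) (over 2.1 million for p = 29, k_max = 7)
to the product N_C = prod_i N_b(i) of the cluster sizes — 10,080 for the
published cluster sizes (2, 2, 6, 5, 4, 3, 7) — making an exhaustive
search feasible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterator, Sequence

from .errors import ConfigError, ParameterError
from .clustering import ClusterAssignment


@dataclass(frozen=True)
class FeatureTuple:
    """One biomarker per biomarker cluster, in cluster order."""

    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ConfigError(f"duplicate members in tuple {self.members}")

    def __iter__(self):
        return iter(self.members)

    def __len__(self):
        return len(self.members)


@dataclass
class BiomarkerClustering:
    """A partition of the biomarker panel into named clusters."""

    clusters: list[list[str]]

    def __post_init__(self) -> None:
        flat = [b for group in self.clusters for b in group]
        if len(set(flat)) != len(flat):
            raise ConfigError("biomarker clusters are not disjoint")
        if any(len(group) == 0 for group in self.clusters):
            raise ConfigError("empty biomarker cluster")

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(group) for group in self.clusters)

    @property
    def biomarkers(self) -> list[str]:
        return [b for group in self.clusters for b in group]

    @classmethod
    def from_assignment(cls, assignment: ClusterAssignment) -> "BiomarkerClustering":
        groups = [sorted(assignment.members(lab)) for lab in range(1, assignment.k + 1)]
        return cls(clusters=groups)

    @classmethod
    def from_blocks(cls, blocks: dict[str, Sequence[str]]) -> "BiomarkerClustering":
        return cls(clusters=[list(members) for members in blocks.values()])


def count_constrained(sizes: Sequence[int]) -> int:
    """Number of one-per-cluster tuples: the exact product of cluster sizes."""
    if len(sizes) == 0:
        raise ParameterError("empty size list")
    if any(int(s) < 1 for s in sizes):
        raise ParameterError(f"cluster sizes must be >= 1, got {list(sizes)}")
    return math.prod(int(s) for s in sizes)


def count_unconstrained(p: int, k_max: int) -> int:
    """Number of non-empty biomarker subsets of size at most k_max out of p.

    Exact integer sum of binomial coefficients C(p, k) for k = 1..k_max.
    """
    if not 1 <= k_max <= p:
        raise ParameterError(f"require 1 <= k_max <= p, got k_max={k_max}, p={p}")
    return sum(math.comb(p, k) for k in range(1, k_max + 1))


def enumerate_tuples(clustering: BiomarkerClustering) -> Iterator[FeatureTuple]:
    """Yield every one-per-cluster tuple exactly once.

    Deterministic lexicographic order over (cluster index, member name);
    the sequence length equals ``count_constrained(clustering.sizes)``.
    """
    pools = [sorted(group) for group in clustering.clusters]
    for combo in itertools.product(*pools):
        yield FeatureTuple(members=tuple(combo))
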