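"""Consensus community detection and partition comparison.

The Louvain method is a greedy stochastic modularity maximizer, so a
single run is one local optimum among many.  Following standard
consensus-clustering practice, the method is re-run many times; the
*co-assignment matrix* records, for every node pair, the fraction of
runs placing them in the same community; thresholding that matrix gives
a weighted agreement graph which is itself re-clustered, iterating until
all runs agree.  Partitions are compared with the Rand index (fraction
of node pairs treated the same way — together in both or apart in both)
and summarized against the cue categories with a dispersion statistic:
the sample SD of a category's member counts over the communities it
occupies (low = spread out, high = concentrated).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score, rand_score

from .cueset import CueSet
from .metrics import modularity


class CommunityError(ValueError):
    pass


class ConsensusError(RuntimeError):
    """Consensus iteration failed to converge; carries the last matrix."""

    def __init__(self, message: str, coassignment: pd.DataFrame):
        super().__init__(message)
        self.coassignment = coassignment


@dataclass(frozen=True)
class Partition:
    """A node -> community assignment with contiguous ids from 1."""

    assignment: dict[str, int] = field(hash=False)

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def nodes(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    def community(self, cid: int) -> set[str]:
        return {n for n, c in self.assignment.items() if c == cid}

    def as_sets(self) -> list[set[str]]:
        return [self.community(c) for c in sorted(set(self.assignment.values()))]

    @classmethod
    def from_sets(
        cls, communities: list[set[str]], node_order: list[str] | None = None
    ) -> "Partition":
        """Canonicalize: ids 1.. assigned by smallest-member node order."""
        order = node_order or sorted(set().union(*communities))
        pos = {n: i for i, n in enumerate(order)}
        ranked = sorted(communities, key=lambda s: min(pos[n] for n in s))
        assignment = {n: cid for cid, s in enumerate(ranked, start=1) for n in s}
        return cls({n: assignment[n] for n in order if n in assignment})

    @classmethod
    def from_labels(cls, labels: dict[str, object]) -> "Partition":
        """From arbitrary node -> label maps (e.g. cue categories)."""
        by_label: dict[object, set[str]] = {}
        for node, lab in labels.items():
            by_label.setdefault(lab, set()).add(node)
        return cls.from_sets(list(by_label.values()), node_order=list(labels))


@dataclass(frozen=True)
class ConsensusConfig:
    n_reps: int = 1000
    coassignment_threshold: float = 0.5
    max_iterations: int = 20
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.coassignment_threshold < 1:
            raise CommunityError("coassignment_threshold must be in (0, 1)")
        if self.n_reps < 1 or self.max_iterations < 1:
            raise CommunityError("n_reps and max_iterations must be >= 1")


def louvain(G: nx.Graph, seed: int, weight: str | None = None) -> Partition:
    """One seeded Louvain run; returns the canonicalized partition."""
    if G.number_of_nodes() == 0:
        raise CommunityError("empty network")
    communities = nx.community.louvain_communities(G, weight=weight, seed=int(seed))
    return Partition.from_sets([set(c) for c in communities], node_order=list(G))


def coassignment_matrix(
    partitions: list[Partition], nodes: list[str]
) -> pd.DataFrame:
    """Fraction of partitions co-assigning each node pair (diag 1)."""
    idx = {n: i for i, n in enumerate(nodes)}
    M = np.zeros((len(nodes), len(nodes)))
    for p in partitions:
        labels = np.array([p.assignment[n] for n in nodes])
        M += (labels[:, None] == labels[None, :]).astype(float)
    M /= len(partitions)
    np.fill_diagonal(M, 1.0)
    return pd.DataFrame(M, index=nodes, columns=nodes)


def consensus_partition(
    G: nx.Graph, config: ConsensusConfig
) -> tuple[Partition, pd.DataFrame]:
    """Consensus over ``n_reps`` Louvain runs.

    Iteratively: run Louvain ``n_reps`` times (distinct sub-seeds), build
    the co-assignment matrix, threshold it at ``coassignment_threshold``
    (surviving entries keep their fraction as edge weight), and recluster
    the agreement graph, until all runs return the same partition.
    Deterministic given ``config.seed``.
    """
    config.validate()
    nodes = list(G)
    work = G
    weight = None
    coassign = None
    for it in range(config.max_iterations):
        base = config.seed + it * config.n_reps
        partitions = [
            louvain(work, seed=base + r, weight=weight) for r in range(config.n_reps)
        ]
        first = partitions[0]
        if all(p.assignment == first.assignment for p in partitions[1:]):
            if coassign is None:
                coassign = coassignment_matrix(partitions, nodes)
            return first, coassign
        coassign = coassignment_matrix(partitions, nodes)
        M = coassign.to_numpy()
        work = nx.Graph()
        work.add_nodes_from(nodes)
        keep = M >= config.coassignment_threshold
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                if keep[i, j]:
                    work.add_edge(nodes[i], nodes[j], weight=float(M[i, j]))
        weight = "weight"
    raise ConsensusError(
        f"consensus did not converge in {config.max_iterations} iterations",
        coassign,
    )


@dataclass(frozen=True)
class PartitionComparison:
    rand_index: float
    adjusted_rand: float


def rand_index(p1: Partition, p2: Partition) -> PartitionComparison:
    """Rand and adjusted Rand index of two partitions of the same nodes."""
    if set(p1.nodes) != set(p2.nodes):
        raise CommunityError("partitions cover different node sets")
    nodes = list(p1.nodes)
    a = [p1.assignment[n] for n in nodes]
    b = [p2.assignment[n] for n in nodes]
    return PartitionComparison(
        rand_index=float(rand_score(a, b)),
        adjusted_rand=float(adjusted_rand_score(a, b)),
    )


@dataclass(frozen=True)
class CategoryDispersion:
    """How one cue category distributes over the identified communities."""

    counts: tuple[int, ...]  # members per occupied community
    sd: float  # sample SD (ddof=1) of counts; 0 if fully clustered
    fully_clustered: bool  # True when the category occupies one community


def category_distribution_sd(
    partition: Partition, cueset: CueSet
) -> dict[str, CategoryDispersion]:
    """Per category: member counts per occupied community and their sample SD.

    Only communities containing at least one member of the category enter
    the count vector; a category occupying a single community is flagged
    ``fully_clustered`` with SD 0.  A two-member category split across
    two communities has counts (1, 1), hence SD 0 — the signature of the
    two core concepts landing in different communities.
    """
    missing = [c for c in cueset.cues if c not in partition.assignment]
    if missing:
        raise CommunityError(f"partition does not cover cues: {missing}")
    out: dict[str, CategoryDispersion] = {}
    for cat in cueset.categories:
        members = cueset.members(cat)
        if not members:
            raise CommunityError(f"empty category {cat!r}")
        cids = [partition.assignment[c] for c in members]
        counts = tuple(
            sorted((cids.count(c) for c in set(cids)), reverse=True)
        )
        if len(counts) == 1:
            out[cat] = CategoryDispersion(counts, 0.0, True)
        else:
            sd = float(np.std(counts, ddof=1))
            out[cat] = CategoryDispersion(counts, sd, False)
    return out


def write_partition(partition: Partition, path) -> None:
    lines = [f"{n}\t{c}" for n, c in partition.assignment.items()]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_partition(path) -> Partition:
    assignment: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                n, c = line.rstrip("\n").split("\t")
                assignment[n] = int(c)
    return Partition(assignment)


def partition_modularity(G: nx.Graph, partition: Partition) -> float:
    """Newman modularity of a partition on a network (convenience re-export)."""
    return modularity(G, partition.assignment)
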