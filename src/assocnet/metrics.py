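"""Graph metrics for semantic networks: CC, ASPL, modularity Q, and
Erdős–Rényi G(n, m) random baselines.

CC (average local clustering) measures local connectivity — how often
two neighbors of a node are themselves neighbors; degree-0/1 nodes
contribute 0 (the Watts–Strogatz convention).  ASPL (average shortest
path length over unit-length edges) measures global spread/segregation.
Q (Newman modularity of a partition) measures how cleanly the network
breaks into communities.  Baselines are means over random graphs with
the same number of nodes and edges; they contextualize CC and ASPL
qualitatively and enter no statistical test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import networkx as nx
import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .community import ConsensusConfig


class MetricError(ValueError):
    pass


def clustering_coefficient(G: nx.Graph) -> float:
    """Mean local clustering coefficient; degree < 2 nodes count as 0."""
    if G.number_of_nodes() < 1:
        raise MetricError("empty network")
    return float(nx.average_clustering(G, count_zeros=True))


def average_shortest_path_length(
    G: nx.Graph, disconnected: str = "error"
) -> float:
    """Mean shortest-path length over all unordered node pairs.

    ``disconnected='largest_component'`` computes the ASPL of the largest
    connected component instead of raising on disconnected input.
    """
    if G.number_of_nodes() < 2:
        raise MetricError("ASPL needs >= 2 nodes")
    if nx.is_connected(G):
        return float(nx.average_shortest_path_length(G))
    if disconnected == "largest_component":
        comp = max(nx.connected_components(G), key=len)
        return float(nx.average_shortest_path_length(G.subgraph(comp)))
    raise MetricError(
        "network is disconnected; pass disconnected='largest_component' to "
        "measure the largest component"
    )


def modularity(G: nx.Graph, assignment: dict) -> float:
    """Newman modularity Q = sum_i (e_ii - a_i^2).

    ``e_ii`` is the fraction of edges with both ends in community i and
    ``a_i`` the fraction of edge endpoints in community i.
    """
    missing = [n for n in G if n not in assignment]
    if missing:
        raise MetricError(f"partition misses nodes: {missing[:5]}")
    m = G.number_of_edges()
    if m == 0:
        return 0.0
    communities = set(assignment[n] for n in G)
    q = 0.0
    for c in communities:
        members = {n for n in G if assignment[n] == c}
        e_ii = sum(1 for u, v in G.edges(members) if u in members and v in members) / m
        a_i = sum(G.degree(n) for n in members) / (2 * m)
        q += e_ii - a_i**2
    return float(q)


def random_baseline(
    G: nx.Graph, n_realizations: int = 1000, seed: int = 0
) -> tuple[float, float]:
    """Mean CC and ASPL over G(n, m) random graphs matching ``G``.

    Disconnected realizations contribute the ASPL of their largest
    component.  Deterministic given ``seed``.
    """
    if n_realizations < 1:
        raise MetricError("n_realizations must be >= 1")
    n, m = G.number_of_nodes(), G.number_of_edges()
    if m > n * (n - 1) // 2:
        raise MetricError(f"m={m} exceeds the maximum for n={n}")
    rng = np.random.default_rng(seed)
    ccs = np.empty(n_realizations)
    aspls = np.empty(n_realizations)
    for i in range(n_realizations):
        R = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        ccs[i] = nx.average_clustering(R, count_zeros=True)
        aspls[i] = average_shortest_path_length(R, disconnected="largest_component")
    return float(ccs.mean()), float(aspls.mean())


@dataclass(frozen=True)
class NetworkMeasures:
    """The per-network measure bundle (one row of a group-measures table)."""

    cc: float
    aspl: float
    q: float
    avg_degree: float
    cc_rand: float
    aspl_rand: float
    n_random_realizations: int
    n_nodes: int
    n_edges: int
    group_label: object = None

    def to_dict(self) -> dict:
        return {
            "group_label": self.group_label,
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "cc": self.cc,
            "aspl": self.aspl,
            "q": self.q,
            "cc_rand": self.cc_rand,
            "aspl_rand": self.aspl_rand,
            "n_random_realizations": self.n_random_realizations,
        }


def measure_network(
    G: nx.Graph,
    consensus_config: "ConsensusConfig | None" = None,
    seed: int = 0,
    n_random_realizations: int = 1000,
    disconnected: str = "error",
    partition=None,
) -> NetworkMeasures:
    """CC, ASPL, average degree, consensus-partition Q and random baselines.

    Pass a precomputed ``partition`` to reuse an existing consensus run;
    otherwise one is computed here with ``consensus_config``.
    """
    from .community import ConsensusConfig, consensus_partition

    if partition is None:
        if consensus_config is None:
            consensus_config = ConsensusConfig(seed=seed)
        partition, _ = consensus_partition(G, consensus_config)
    cc_rand, aspl_rand = random_baseline(G, n_random_realizations, seed=seed)
    n, m = G.number_of_nodes(), G.number_of_edges()
    return NetworkMeasures(
        cc=clustering_coefficient(G),
        aspl=average_shortest_path_length(G, disconnected=disconnected),
        q=modularity(G, partition.assignment),
        avg_degree=2 * m / n,
        cc_rand=cc_rand,
        aspl_rand=aspl_rand,
        n_random_realizations=n_random_realizations,
        n_nodes=n,
        n_edges=m,
        group_label=G.graph.get("group_label"),
    )
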