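"""Louvain consensus, Rand index, and category-dispersion statistics."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from assocnet.community import (
    CommunityError,
    ConsensusConfig,
    Partition,
    category_distribution_sd,
    coassignment_matrix,
    consensus_partition,
    louvain,
    partition_modularity,
    rand_index,
    read_partition,
    write_partition,
)
from oracles import rand_oracle

from assocnet.cueset import CueSet
from assocnet.metrics import modularity


def two_triangles():
    return nx.Graph([(0, 1), (1, 2), (2, 0), (3, 4), (4, 5), (5, 3)])


# -- louvain -----------------------------------------------------------------


def test_louvain_recovers_disconnected_triangles():
    G = two_triangles()
    part = louvain(G, seed=1)
    assert part.as_sets() in ([{0, 1, 2}, {3, 4, 5}],)
    assert modularity(G, part.assignment) == pytest.approx(0.5)


def test_louvain_complete_graph_single_community():
    part = louvain(nx.complete_graph(5), seed=0)
    assert part.n_communities == 1
    assert partition_modularity(nx.complete_graph(5), part) == pytest.approx(0.0)


def test_louvain_deterministic_given_seed():
    G = nx.connected_watts_strogatz_graph(30, 4, 0.2, seed=9)
    assert louvain(G, seed=7).assignment == louvain(G, seed=7).assignment


def test_louvain_q_consistent_with_modularity_op():
    rng = np.random.default_rng(0)
    for s in range(10):
        G = nx.gnp_random_graph(12, 0.4, seed=s)
        if G.number_of_edges() == 0:
            continue
        part = louvain(G, seed=s)
        # returned partition scores at least the trivial single community
        assert modularity(G, part.assignment) >= -1e-12


def test_louvain_empty_network_errors():
    with pytest.raises(CommunityError, match="empty"):
        louvain(nx.Graph(), seed=0)


# -- consensus ---------------------------------------------------------------


def test_consensus_on_disconnected_cliques_is_exact():
    G = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
    part, coassign = consensus_partition(G, ConsensusConfig(n_reps=20, seed=3))
    assert part.as_sets() == [{0, 1, 2, 3}, {4, 5, 6, 7, 8}]
    vals = np.unique(coassign.to_numpy())
    assert set(np.round(vals, 12)) <= {0.0, 1.0}


def test_consensus_deterministic():
    G = nx.connected_watts_strogatz_graph(25, 4, 0.3, seed=2)
    cfg = ConsensusConfig(n_reps=25, seed=11)
    p1, _ = consensus_partition(G, cfg)
    p2, _ = consensus_partition(G, cfg)
    assert p1.assignment == p2.assignment


def test_consensus_concentrates_coassignment():
    """Mean |entry - 0.5| must not decrease from the first to the final
    co-assignment matrix (entries drift toward 0/1)."""
    G = nx.planted_partition_graph(3, 8, 0.8, 0.1, seed=5)
    cfg = ConsensusConfig(n_reps=30, seed=1)
    partitions = [louvain(G, seed=cfg.seed + r) for r in range(cfg.n_reps)]
    first = coassignment_matrix(partitions, list(G))
    _, final = consensus_partition(G, cfg)
    conc = lambda M: np.abs(M.to_numpy() - 0.5).mean()
    assert conc(final) >= conc(first) - 1e-12


def test_consensus_recovers_planted_partition():
    G = nx.planted_partition_graph(3, 8, 0.9, 0.05, seed=7)
    part, _ = consensus_partition(G, ConsensusConfig(n_reps=30, seed=2))
    truth = Partition.from_sets(
        [set(range(8)), set(range(8, 16)), set(range(16, 24))],
        node_order=list(G),
    )
    assert rand_index(part, truth).rand_index >= 0.9


# -- rand index --------------------------------------------------------------


def test_rand_identical_partitions():
    p = Partition({"a": 1, "b": 1, "c": 2})
    cmp = rand_index(p, p)
    assert cmp.rand_index == 1.0
    assert cmp.adjusted_rand == 1.0


def test_rand_singletons_vs_lump():
    p1 = Partition({"a": 1, "b": 2, "c": 3})
    p2 = Partition({"a": 1, "b": 1, "c": 1})
    assert rand_index(p1, p2).rand_index == 0.0


def test_rand_hand_value_one_third():
    p1 = Partition({1: 1, 2: 1, 3: 2, 4: 2})
    p2 = Partition({1: 1, 3: 1, 2: 2, 4: 2})
    assert rand_index(p1, p2).rand_index == pytest.approx(1 / 3)


def test_rand_node_mismatch_errors():
    with pytest.raises(CommunityError, match="node sets"):
        rand_index(Partition({"a": 1}), Partition({"b": 1}))


@given(st.lists(st.integers(0, 3), min_size=2, max_size=6))
def test_rand_matches_oracle_and_is_invariant(labels):
    nodes = [f"n{i}" for i in range(len(labels))]
    rng = np.random.default_rng(len(labels))
    other = [int(x) for x in rng.integers(0, 3, len(labels))]
    p1 = Partition(dict(zip(nodes, labels)))
    p2 = Partition(dict(zip(nodes, other)))
    cmp = rand_index(p1, p2)
    assert cmp.rand_index == pytest.approx(rand_oracle(p1, p2), abs=1e-12)
    assert cmp.rand_index == pytest.approx(rand_index(p2, p1).rand_index)
    # relabeling invariance
    relabeled = Partition({n: c + 17 for n, c in p2.assignment.items()})
    assert rand_index(p1, relabeled).rand_index == pytest.approx(cmp.rand_index)
    assert 0.0 <= cmp.rand_index <= 1.0


def test_rand_exhaustive_small_partitions():
    """Against the oracle on every pair of partitions of a 4-node set."""

    def all_partitions(nodes):
        if not nodes:
            yield []
            return
        first, rest = nodes[0], nodes[1:]
        for smaller in all_partitions(rest):
            for i in range(len(smaller)):
                yield smaller[:i] + [smaller[i] | {first}] + smaller[i + 1 :]
            yield smaller + [{first}]

    nodes = ["a", "b", "c", "d"]
    parts = [Partition.from_sets(p, node_order=nodes) for p in all_partitions(nodes)]
    for p1, p2 in itertools.combinations(parts, 2):
        assert rand_index(p1, p2).rand_index == pytest.approx(
            rand_oracle(p1, p2), abs=1e-12
        )


# -- category dispersion -----------------------------------------------------


@pytest.fixture
def cueset_16():
    cues = [f"a{i}" for i in range(15)] + ["f1"]
    cats = {c: "A" for c in cues[:15]}
    cats["f1"] = "F"
    return CueSet(tuple(cues), cats, ("f1",))


def test_two_focal_concepts_split_gives_sd_zero():
    cues = ("f1", "f2")
    cs = CueSet(cues, {"f1": "concepts", "f2": "concepts"}, cues)
    part = Partition({"f1": 1, "f2": 2})
    disp = category_distribution_sd(part, cs)
    assert disp["concepts"].counts == (1, 1)
    assert disp["concepts"].sd == 0.0
    assert not disp["concepts"].fully_clustered


def test_dispersion_hand_values(cueset_16):
    # counts (14, 1) -> sample SD 9.19
    part = Partition({c: (1 if i < 14 else 2) for i, c in enumerate(cueset_16.cues[:15])} | {"f1": 3})
    disp = category_distribution_sd(part, cueset_16)
    assert disp["A"].counts == (14, 1)
    assert disp["A"].sd == pytest.approx(9.19, abs=0.005)
    # counts (13, 2) -> 7.78
    part = Partition({c: (1 if i < 13 else 2) for i, c in enumerate(cueset_16.cues[:15])} | {"f1": 3})
    assert category_distribution_sd(part, cueset_16)["A"].sd == pytest.approx(7.78, abs=0.005)


def test_fully_clustered_category_flagged(cueset_16):
    part = Partition({c: 1 for c in cueset_16.cues})
    disp = category_distribution_sd(part, cueset_16)
    assert disp["A"].sd == 0.0
    assert disp["A"].fully_clustered
    assert disp["F"].fully_clustered  # single member, single community


def test_dispersion_requires_full_coverage(cueset_16):
    part = Partition({c: 1 for c in cueset_16.cues[:-1]})
    with pytest.raises(CommunityError, match="cover"):
        category_distribution_sd(part, cueset_16)


# -- io ----------------------------------------------------------------------


def test_partition_round_trip(tmp_path):
    p = Partition({"a": 1, "b": 1, "c": 2})
    write_partition(p, tmp_path / "p.tsv")
    assert read_partition(tmp_path / "p.tsv").assignment == p.assignment


def test_canonical_ids_by_smallest_member():
    p = Partition.from_sets([{"z", "y"}, {"a", "b"}], node_order=["a", "b", "y", "z"])
    assert p.assignment == {"a": 1, "b": 1, "y": 2, "z": 2}
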