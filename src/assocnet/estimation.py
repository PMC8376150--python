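"""Semantic-network estimation: response profiles, Pearson similarity,
and planar-maximally-filtered-graph (PMFG) sparsification.

Edges in the semantic network encode overlap in the associative
responses two cues evoke: each cue's *response profile* counts, per
unique response type, how many distinct participants in the group gave
that response to the cue.  Cue–cue similarity is the Pearson correlation
of profiles, giving a complete n x n similarity matrix.  The PMFG filter
keeps the strongest correlations that can be drawn without edge
crossings — greedy insertion in descending weight order subject to
planarity — yielding exactly 3(n-2) edges for a complete candidate set,
so every group network has the same number of nodes *and* edges and can
be compared directly.  Edges are finally binarized (uniform weight 1)
and the networks analyzed as unweighted, undirected graphs.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import pandas as pd

from .cueset import CueSet
from .dataset import select_group, validate_dataset


class EstimationError(ValueError):
    pass


def build_profile_matrix(
    df: pd.DataFrame,
    cueset: CueSet,
    group_filter: dict[str, str] | str = "all",
    min_participants_per_response: int = 1,
) -> pd.DataFrame:
    """Cue x response-type matrix of distinct-participant counts.

    Entry (c, r) = number of distinct participants in the selected group
    who gave response r to cue c at least once.  Rows follow the cue-set
    order; all-zero rows (cues nobody answered) are flagged in
    ``result.attrs["zero_cues"]``.  Responses produced by fewer than
    ``min_participants_per_response`` participants (over the whole
    matrix) can optionally be dropped; the default keeps idiosyncratic
    responses.
    """
    validate_dataset(df, cueset)
    sub = select_group(df, group_filter)
    if sub.empty:
        raise EstimationError(f"group filter {group_filter!r} selects no records")
    n_participants = sub["participant_id"].nunique()
    if n_participants < 2:
        raise EstimationError(
            f"group filter {group_filter!r} selects {n_participants} participant(s); need >= 2"
        )
    counts = (
        sub.drop_duplicates(["participant_id", "cue", "response"])
        .groupby(["cue", "response"], sort=True)
        .size()
        .unstack(fill_value=0)
    )
    profiles = counts.reindex(index=list(cueset.cues), fill_value=0)
    profiles.columns.name = "response"
    profiles.index.name = "cue"
    if min_participants_per_response > 1:
        keep = profiles.max(axis=0) >= min_participants_per_response
        profiles = profiles.loc[:, keep]
    label = group_filter if isinstance(group_filter, str) else dict(group_filter)
    profiles.attrs["group_label"] = label
    profiles.attrs["n_participants"] = int(n_participants)
    profiles.attrs["zero_cues"] = [
        c for c, s in profiles.sum(axis=1).items() if s == 0
    ]
    return profiles


def correlation_matrix(profiles: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of cue response profiles (cue x cue, diag 1).

    Zero-variance profiles (all-zero or constant rows) get similarity 0
    to every other cue and are flagged in ``attrs["degenerate_cues"]``.
    """
    if profiles.shape[1] < 2:
        raise EstimationError(
            f"need >= 2 response-type columns, got {profiles.shape[1]}"
        )
    X = profiles.to_numpy(dtype=float)
    sd = X.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X)
    R[degenerate, :] = 0.0
    R[:, degenerate] = 0.0
    np.fill_diagonal(R, 1.0)
    sim = pd.DataFrame(R, index=profiles.index, columns=profiles.index)
    sim.attrs["group_label"] = profiles.attrs.get("group_label")
    sim.attrs["degenerate_cues"] = [
        c for c, d in zip(profiles.index, degenerate) if d
    ]
    return sim


def _check_similarity(sim: pd.DataFrame) -> np.ndarray:
    A = sim.to_numpy(dtype=float)
    if A.shape[0] != A.shape[1]:
        raise EstimationError("similarity matrix must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise EstimationError("similarity matrix must be symmetric")
    return A


def pmfg(sim: pd.DataFrame) -> nx.Graph:
    """Planar maximally filtered graph of a complete similarity matrix.

    Candidate edges are sorted by descending similarity (ties broken by
    node-pair order in the matrix index, making the filter fully
    deterministic) and inserted greedily, skipping any insertion that
    would break planarity.  For a complete candidate set on n >= 3 nodes
    the result has exactly 3(n-2) edges and is connected.  Edge weights
    keep the similarity until :func:`binarize`.
    """
    A = _check_similarity(sim)
    n = A.shape[0]
    if n < 3:
        raise EstimationError(f"PMFG needs >= 3 nodes, got {n}")
    nodes = list(sim.index)
    iu, ju = np.triu_indices(n, 1)
    order = sorted(range(len(iu)), key=lambda k: (-A[iu[k], ju[k]], iu[k], ju[k]))
    G = nx.Graph()
    G.add_nodes_from(nodes)
    target = 3 * (n - 2)
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        G.add_edge(nodes[i], nodes[j], weight=float(A[i, j]))
        # any graph with <= 8 edges is planar (K5 needs 10 edges, K3,3 9)
        if G.number_of_edges() > 8 and not nx.check_planarity(G)[0]:
            G.remove_edge(nodes[i], nodes[j])
        if G.number_of_edges() == target:
            break
    G.graph["group_label"] = sim.attrs.get("group_label")
    return G


def binarize(G: nx.Graph) -> nx.Graph:
    """Uniform edge weight 1; identical edge set (idempotent)."""
    H = G.copy()
    for _, _, data in H.edges(data=True):
        data["weight"] = 1
    return H


def estimate_network(
    df: pd.DataFrame,
    cueset: CueSet,
    group_filter: dict[str, str] | str = "all",
    min_participants_per_response: int = 1,
) -> nx.Graph:
    """Profile matrix -> Pearson similarity -> PMFG -> binarize."""
    profiles = build_profile_matrix(
        df, cueset, group_filter, min_participants_per_response
    )
    return binarize(pmfg(correlation_matrix(profiles)))


def write_similarity(sim: pd.DataFrame, path) -> None:
    sim.to_csv(path)


def read_similarity(path) -> pd.DataFrame:
    sim = pd.read_csv(path, index_col=0)
    sim.columns.name = sim.index.name = "cue"
    _check_similarity(sim)
    return sim


def write_network(G: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    """Write a network as GraphML and/or a 2-column edge-list TSV."""
    if graphml_path is not None:
        H = G.copy()
        if H.graph.get("group_label") is None:
            H.graph.pop("group_label", None)
        elif not isinstance(H.graph["group_label"], str):
            H.graph["group_label"] = repr(H.graph["group_label"])
        nx.write_graphml(H, graphml_path)
    if edgelist_path is not None:
        lines = [f"{u}\t{v}" for u, v in sorted(G.edges())]
        with open(edgelist_path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
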