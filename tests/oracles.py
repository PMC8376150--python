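"""Brute-force oracles, independent of the library's implementation paths.

Used by the unit suites and the acceptance suite to cross-check CC, ASPL,
modularity and the Rand index by direct enumeration.
"""

import itertools

import numpy as np


def cc_oracle(G):
    """Average local clustering by explicit neighbor-pair enumeration."""
    total = 0.0
    for v in G:
        nbrs = list(G[v])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(1 for a, b in itertools.combinations(nbrs, 2) if G.has_edge(a, b))
        total += links / (k * (k - 1) / 2)
    return total / G.number_of_nodes()


def aspl_oracle(G):
    """Floyd–Warshall all-pairs shortest paths, unit edge lengths."""
    nodes = list(G)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for u, v in G.edges():
        D[idx[u], idx[v]] = D[idx[v], idx[u]] = 1.0
    for k in range(n):
        D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
    iu = np.triu_indices(n, 1)
    return float(D[iu].mean())


def q_oracle(G, assignment):
    """Modularity via the direct double sum with the degree-product null."""
    m = G.number_of_edges()
    q = 0.0
    for u, v in itertools.product(G, repeat=2):
        if assignment[u] != assignment[v]:
            continue
        a = 1.0 if G.has_edge(u, v) else 0.0
        q += a - G.degree(u) * G.degree(v) / (2 * m)
    return q / (2 * m)


def rand_oracle(p1, p2) -> float:
    """Fraction of node pairs classified identically by both partitions."""
    nodes = list(p1.nodes)
    agree = 0
    pairs = 0
    for a, b in itertools.combinations(nodes, 2):
        same1 = p1.assignment[a] == p1.assignment[b]
        same2 = p2.assignment[a] == p2.assignment[b]
        agree += same1 == same2
        pairs += 1
    return agree / pairs
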