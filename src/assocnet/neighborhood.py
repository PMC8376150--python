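"""Focal-concept neighborhood analysis.

The direct semantic neighborhood of a focal cue is the set of nodes it
shares an edge with.  Comparing neighborhoods across a family of
networks (e.g. per-cohort and per-sex networks) identifies *consistent
neighbors* — terms directly connected to the focal concept in every
network — and, per network, the unique neighbors and the category
composition of the neighborhood ("8/16 neighbors from category X").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .cueset import CueSet


class NeighborhoodError(ValueError):
    pass


def neighbors(G: nx.Graph, node: str) -> set[str]:
    """Direct neighbors (directly connected nodes) of ``node``."""
    if node not in G:
        raise NeighborhoodError(f"node {node!r} not in network")
    return set(G[node])


def neighborhood_composition(
    G: nx.Graph, node: str, cueset: CueSet
) -> dict[str, tuple[int, int]]:
    """Neighborhood category counts as (count, neighborhood size) pairs."""
    if node not in cueset.cues:
        raise NeighborhoodError(f"node {node!r} not in cue set")
    nbrs = neighbors(G, node)
    size = len(nbrs)
    counts: dict[str, int] = {}
    for n in nbrs:
        counts[cueset.category_of[n]] = counts.get(cueset.category_of[n], 0) + 1
    return {cat: (c, size) for cat, c in sorted(counts.items())}


def consistent_neighbors(networks: dict[str, nx.Graph], node: str) -> set[str]:
    """Intersection of the node's neighbor sets over all networks."""
    if not networks:
        raise NeighborhoodError("no networks given")
    sets = [neighbors(G, node) for G in networks.values()]
    return set.intersection(*sets)


@dataclass
class NeighborhoodReport:
    """Neighborhoods of each focal cue across a family of networks."""

    focal_cues: tuple[str, ...]
    network_labels: tuple[str, ...]
    neighbor_sets: dict[tuple[str, str], set[str]]  # (label, cue) -> set
    composition: dict[tuple[str, str], dict[str, tuple[int, int]]]
    consistent: dict[str, set[str]] = field(default_factory=dict)
    unique: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "focal_cues": list(self.focal_cues),
            "networks": list(self.network_labels),
            "neighbors": {
                f"{label}:{cue}": sorted(s)
                for (label, cue), s in self.neighbor_sets.items()
            },
            "composition": {
                f"{label}:{cue}": {
                    cat: f"{c}/{size}" for cat, (c, size) in comp.items()
                }
                for (label, cue), comp in self.composition.items()
            },
            "consistent_neighbors": {
                cue: sorted(s) for cue, s in self.consistent.items()
            },
            "unique_neighbors": {
                f"{label}:{cue}": sorted(s) for (label, cue), s in self.unique.items()
            },
        }

    def membership_table(self, cue: str) -> pd.DataFrame:
        """Wide cue x network 0/1 membership table for one focal cue."""
        all_neighbors = sorted(
            set().union(
                *(self.neighbor_sets[(lab, cue)] for lab in self.network_labels)
            )
        )
        return pd.DataFrame(
            {
                lab: [int(n in self.neighbor_sets[(lab, cue)]) for n in all_neighbors]
                for lab in self.network_labels
            },
            index=pd.Index(all_neighbors, name="neighbor"),
        )


def neighborhood_report(
    networks: dict[str, nx.Graph],
    cueset: CueSet,
    focal_cues: tuple[str, ...] | None = None,
) -> NeighborhoodReport:
    """Full neighborhood comparison for the cue set's focal concepts."""
    focal = tuple(focal_cues) if focal_cues is not None else cueset.focal_concepts
    if not focal:
        raise NeighborhoodError("no focal cues given and cue set defines none")
    labels = tuple(networks)
    neighbor_sets = {
        (lab, cue): neighbors(G, cue)
        for lab, G in networks.items()
        for cue in focal
    }
    composition = {
        (lab, cue): neighborhood_composition(G, cue, cueset)
        for lab, G in networks.items()
        for cue in focal
    }
    consistent = {cue: consistent_neighbors(networks, cue) for cue in focal}
    unique = {
        (lab, cue): neighbor_sets[(lab, cue)]
        - set().union(
            *(neighbor_sets[(other, cue)] for other in labels if other != lab),
            set(),
        )
        for lab in labels
        for cue in focal
    }
    return NeighborhoodReport(focal, labels, neighbor_sets, composition, consistent, unique)
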