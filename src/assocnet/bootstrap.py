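"""Without-replacement bootstrap of partial networks and group statistics.

A group-based semantic network yields a single CC/ASPL/Q value, so group
differences cannot be tested directly.  The without-replacement
bootstrap builds sampling distributions instead: each realization draws
a random half of the nodes, re-filters the similarity submatrix into a
partial PMFG for every group, and measures it.  With ``shared_subsets``
(the default) the same node subset is used for every group within a
realization, so each realization contrasts the groups on identical
concept subsets.  Distributions are then compared with a one-way ANOVA
(F, eta^2) and pairwise t tests (Cohen's d).

The pairwise default is the independent pooled-variance t (df =
n_a + n_b - 2); the paired-on-realizations variant (df = n - 1) is
available via ``mode='paired'``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .community import ConsensusConfig, consensus_partition
from .estimation import binarize, pmfg
from .metrics import (
    average_shortest_path_length,
    clustering_coefficient,
    modularity,
)

MEASURES = ("cc", "aspl", "q")


class BootstrapError(ValueError):
    pass


@dataclass(frozen=True)
class BootstrapConfig:
    n_realizations: int = 1000
    node_fraction: float = 0.5
    seed: int = 0
    shared_subsets: bool = True

    def validate(self, n_nodes: int | None = None) -> None:
        if not 0 < self.node_fraction < 1:
            raise BootstrapError("node_fraction must be in (0, 1)")
        if self.n_realizations < 1:
            raise BootstrapError("n_realizations must be >= 1")
        if n_nodes is not None and int(self.node_fraction * n_nodes) < 3:
            raise BootstrapError(
                f"subsets of floor({self.node_fraction} * {n_nodes}) < 3 nodes; "
                "PMFG undefined"
            )


def sample_node_subsets(n_nodes: int, config: BootstrapConfig) -> list[np.ndarray]:
    """``n_realizations`` uniform node subsets of size floor(fraction * n)."""
    config.validate(n_nodes)
    size = int(config.node_fraction * n_nodes)
    rng = np.random.default_rng(config.seed)
    return [
        np.sort(rng.choice(n_nodes, size=size, replace=False))
        for _ in range(config.n_realizations)
    ]


def partial_network(sim: pd.DataFrame, subset) -> nx.Graph:
    """PMFG re-filtered on the similarity submatrix of ``subset`` nodes.

    The partial network is *not* the induced subgraph of the full PMFG:
    the filter is recomputed on the restricted matrix so every partial
    network again has exactly 3(k-2) edges.
    """
    labels = (
        [sim.index[i] for i in np.asarray(subset)]
        if np.issubdtype(np.asarray(subset).dtype, np.integer)
        else list(subset)
    )
    missing = [c for c in labels if c not in sim.index]
    if missing:
        raise BootstrapError(f"subset nodes not in similarity matrix: {missing}")
    sub = sim.loc[labels, labels]
    sub.attrs["group_label"] = sim.attrs.get("group_label")
    return binarize(pmfg(sub))


@dataclass
class BootstrapDistributions:
    """Per-group, per-measure arrays over bootstrap realizations."""

    values: dict[str, dict[str, np.ndarray]]  # group -> measure -> array
    subsets: dict[str, list[np.ndarray]]  # group -> subset sequence
    config: BootstrapConfig
    measures: tuple[str, ...] = MEASURES

    @property
    def groups(self) -> list[str]:
        return list(self.values)

    def frame(self, measure: str) -> pd.DataFrame:
        """Realization x group table for one measure (CSV layout)."""
        return pd.DataFrame({g: self.values[g][measure] for g in self.values})


def bootstrap_measures(
    similarities: dict[str, pd.DataFrame],
    config: BootstrapConfig,
    consensus_config: ConsensusConfig | None = None,
    measures: tuple[str, ...] = MEASURES,
) -> BootstrapDistributions:
    """Bootstrap CC/ASPL/Q distributions for each group's similarity matrix.

    Q is the modularity of each partial network's consensus partition;
    the consensus default here is deliberately light (50 reps) because it
    runs once per realization and group.  All groups must share the same
    cue set.  Deterministic given ``config.seed``.
    """
    if not similarities:
        raise BootstrapError("no groups given")
    unknown = set(measures) - set(MEASURES)
    if unknown:
        raise BootstrapError(f"unknown measures: {sorted(unknown)}")
    cue_sets = [tuple(sim.index) for sim in similarities.values()]
    if any(cs != cue_sets[0] for cs in cue_sets[1:]):
        raise BootstrapError("groups have mismatched cue sets")
    n_nodes = len(cue_sets[0])
    config.validate(n_nodes)
    if consensus_config is None:
        consensus_config = ConsensusConfig(n_reps=50, max_iterations=5, seed=config.seed)

    if config.shared_subsets:
        shared = sample_node_subsets(n_nodes, config)
        subsets = {g: shared for g in similarities}
    else:
        subsets = {
            g: sample_node_subsets(
                n_nodes,
                BootstrapConfig(
                    config.n_realizations,
                    config.node_fraction,
                    seed=config.seed + 1 + gi,
                    shared_subsets=False,
                ),
            )
            for gi, g in enumerate(similarities)
        }

    values = {
        g: {m: np.empty(config.n_realizations) for m in measures}
        for g in similarities
    }
    for gi, (g, sim) in enumerate(similarities.items()):
        for r, subset in enumerate(subsets[g]):
            P = partial_network(sim, subset)
            if "cc" in measures:
                values[g]["cc"][r] = clustering_coefficient(P)
            if "aspl" in measures:
                values[g]["aspl"][r] = average_shortest_path_length(
                    P, disconnected="largest_component"
                )
            if "q" in measures:
                cc_cfg = ConsensusConfig(
                    n_reps=consensus_config.n_reps,
                    coassignment_threshold=consensus_config.coassignment_threshold,
                    max_iterations=consensus_config.max_iterations,
                    seed=consensus_config.seed + 7919 * r + 104729 * gi,
                )
                part, _ = consensus_partition(P, cc_cfg)
                values[g]["q"][r] = modularity(P, part.assignment)
    return BootstrapDistributions(values, subsets, config, tuple(measures))


@dataclass(frozen=True)
class OmnibusStats:
    f: float
    df_between: int
    df_within: int
    p: float
    eta_sq: float


@dataclass(frozen=True)
class PairwiseStat:
    group_a: str
    group_b: str
    t: float
    df: int
    p: float
    cohen_d: float
    mode: str


def anova_oneway(samples: dict[str, np.ndarray]) -> OmnibusStats:
    """Classical one-way ANOVA with eta^2 = SS_between / SS_total."""
    if len(samples) < 2:
        raise BootstrapError("ANOVA needs >= 2 groups")
    arrays = {g: np.asarray(a, dtype=float) for g, a in samples.items()}
    if any(len(a) < 2 for a in arrays.values()):
        raise BootstrapError("each group needs >= 2 values")
    grand = np.concatenate(list(arrays.values()))
    ss_between = sum(len(a) * (a.mean() - grand.mean()) ** 2 for a in arrays.values())
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays.values())
    df_between = len(arrays) - 1
    df_within = len(grand) - len(arrays)
    if ss_within == 0:
        if ss_between == 0:
            raise BootstrapError("F undefined: zero variance everywhere")
        return OmnibusStats(np.inf, df_between, df_within, 0.0, 1.0)
    f = (ss_between / df_between) / (ss_within / df_within)
    p = float(stats.f.sf(f, df_between, df_within))
    eta_sq = float(ss_between / (ss_between + ss_within))
    return OmnibusStats(float(f), df_between, df_within, p, eta_sq)


def ttest_pairwise(
    a: np.ndarray,
    b: np.ndarray,
    mode: str = "independent",
    group_a: str = "a",
    group_b: str = "b",
) -> PairwiseStat:
    """Two-sample t test with Cohen's d; two-sided p.

    ``independent``: pooled-variance t, df = n_a + n_b - 2, d = mean
    difference / pooled SD.  ``paired``: t on differences, df = n - 1,
    d = mean difference / SD of differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise BootstrapError("need >= 2 values per sample")
    if mode == "independent":
        na, nb = len(a), len(b)
        pooled_var = (
            ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        )
        if pooled_var == 0:
            raise BootstrapError("zero pooled variance; t undefined")
        t = (a.mean() - b.mean()) / np.sqrt(pooled_var * (1 / na + 1 / nb))
        df = na + nb - 2
        d = (a.mean() - b.mean()) / np.sqrt(pooled_var)
    elif mode == "paired":
        if len(a) != len(b):
            raise BootstrapError("paired mode requires equal lengths")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            if diff.mean() == 0:
                return PairwiseStat(group_a, group_b, 0.0, len(a) - 1, 1.0, 0.0, mode)
            raise BootstrapError("zero variance of differences; t undefined")
        t = diff.mean() / (sd / np.sqrt(len(diff)))
        df = len(diff) - 1
        d = diff.mean() / sd
    else:
        raise BootstrapError(f"unknown mode {mode!r}")
    p = float(2 * stats.t.sf(abs(t), df))
    return PairwiseStat(group_a, group_b, float(t), int(df), p, float(d), mode)


@dataclass
class ComparisonStats:
    omnibus: OmnibusStats
    pairwise: list[PairwiseStat] = field(default_factory=list)


def compare_groups(
    dists: BootstrapDistributions, mode: str = "independent"
) -> dict[str, ComparisonStats]:
    """Omnibus ANOVA plus all pairwise t tests, per measure."""
    out: dict[str, ComparisonStats] = {}
    for measure in dists.measures:
        samples = {g: dists.values[g][measure] for g in dists.groups}
        omnibus = anova_oneway(samples)
        pairwise = [
            ttest_pairwise(samples[ga], samples[gb], mode, ga, gb)
            for ga, gb in combinations(dists.groups, 2)
        ]
        out[measure] = ComparisonStats(omnibus, pairwise)
    return out


def stats_table(comparisons: dict[str, ComparisonStats]) -> pd.DataFrame:
    """Flat CSV-ready table: one omnibus row and one row per pair, per measure."""
    rows = []
    for measure, cs in comparisons.items():
        o = cs.omnibus
        rows.append(
            {
                "measure": measure,
                "test": "anova",
                "contrast": "omnibus",
                "statistic": o.f,
                "df1": o.df_between,
                "df2": o.df_within,
                "p": o.p,
                "effect_size": o.eta_sq,
            }
        )
        for pw in cs.pairwise:
            rows.append(
                {
                    "measure": measure,
                    "test": f"t_{pw.mode}",
                    "contrast": f"{pw.group_a} vs {pw.group_b}",
                    "statistic": pw.t,
                    "df1": pw.df,
                    "df2": np.nan,
                    "p": pw.p,
                    "effect_size": pw.cohen_d,
                }
            )
    return pd.DataFrame(rows)
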