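"""End-to-end orchestration: simulate/read -> preprocess -> estimate ->
measure -> bootstrap -> communities -> neighborhoods -> report.

All randomness flows from one global seed: every stage derives its own
seed as SHA-256(f"{seed}:{stage}") mod 2^31, so reruns with the same
configuration are byte-identical and stages stay decoupled.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd
import yaml

from . import __version__
from .bootstrap import (
    BootstrapConfig,
    BootstrapDistributions,
    bootstrap_measures,
    compare_groups,
    stats_table,
)
from .community import (
    ConsensusConfig,
    Partition,
    category_distribution_sd,
    consensus_partition,
    rand_index,
    write_partition,
)
from .cueset import CueSet, read_cue_set
from .dataset import group_values, read_associations
from .estimation import (
    build_profile_matrix,
    binarize,
    correlation_matrix,
    pmfg,
    write_network,
    write_similarity,
)
from .metrics import measure_network
from .neighborhood import neighborhood_report
from .preprocess import PreprocessConfig, preprocess
from .synth import GeneratorConfig, generate_dataset, study_like_config, summarize_dataset

log = logging.getLogger("assocnet")

GENERAL = "general"


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one of ``input_path`` / ``generator`` must be set.
    """

    cueset: CueSet
    input_path: str | None = None
    generator: GeneratorConfig | None = None
    group_by: str = "cohort"
    preprocess: PreprocessConfig = field(
        default_factory=lambda: PreprocessConfig(remove_nonwords=False)
    )
    bootstrap: BootstrapConfig = field(default_factory=BootstrapConfig)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    n_random_realizations: int = 1000
    out_dir: str | None = None
    seed: int = 0
    pairwise_mode: str = "independent"

    def validate(self) -> None:
        if (self.input_path is None) == (self.generator is None):
            raise ValueError("exactly one of input_path / generator must be set")
        if self.group_by not in ("cohort", "sex", "all"):
            raise ValueError(f"unknown group_by {self.group_by!r}")
        self.preprocess.validate()


@dataclass
class ReportBundle:
    measures: pd.DataFrame  # per-network measure table
    comparisons: dict  # measure -> ComparisonStats
    stats: pd.DataFrame  # flat stats table
    partitions: dict[str, Partition]
    partition_vs_categories: pd.DataFrame  # rand indices per network
    dispersion: pd.DataFrame  # category x network SD table
    neighborhoods: object  # NeighborhoodReport
    networks: dict[str, nx.Graph]
    similarities: dict[str, pd.DataFrame]
    distributions: BootstrapDistributions | None
    exclusions: object
    summary: pd.DataFrame
    manifest: dict


def plan_stages(config: RunConfig) -> list[str]:
    """The stage graph a run would execute (dry-run output)."""
    stages = ["simulate" if config.generator is not None else "read"]
    stages += ["preprocess", "estimate", "measure"]
    stages += ["bootstrap", "communities", "neighbors", "report"]
    return stages


def run_pipeline(config: RunConfig) -> ReportBundle:
    """Execute the full analysis; deterministic given config + seed."""
    config.validate()
    cueset = config.cueset
    t0 = time.time()

    if config.generator is not None:
        dataset, truth = generate_dataset(config.generator)
        log.info("simulate: %d records", len(dataset))
    else:
        dataset = read_associations(config.input_path, cueset=cueset)
        truth = None
        log.info("read: %d records from %s", len(dataset), config.input_path)

    cleaned, removed, exclusions = preprocess(
        dataset, cueset, config.preprocess,
        group_by=config.group_by if config.group_by != "all" else "cohort",
    )
    summary = summarize_dataset(cleaned, cueset)
    log.info(
        "preprocess: %d records kept, %d participants excluded",
        len(cleaned), len(exclusions.excluded),
    )

    # group networks + pooled "general" network over all participants
    filters: dict[str, dict | str] = {GENERAL: "all"}
    if config.group_by != "all":
        for value in group_values(cleaned, config.group_by):
            filters[value] = {config.group_by: value}

    similarities: dict[str, pd.DataFrame] = {}
    networks: dict[str, nx.Graph] = {}
    for label, flt in filters.items():
        profiles = build_profile_matrix(cleaned, cueset, flt)
        sim = correlation_matrix(profiles)
        sim.attrs["group_label"] = label
        similarities[label] = sim
        G = binarize(pmfg(sim))
        G.graph["group_label"] = label
        networks[label] = G
    log.info("estimate: %d networks (%s)", len(networks), ", ".join(networks))

    consensus_seed = derive_seed(config.seed, "communities")
    partitions: dict[str, Partition] = {}
    rand_rows = []
    dispersion_cols = {}
    category_part = Partition.from_labels(cueset.category_partition())
    for label, G in networks.items():
        cc_cfg = ConsensusConfig(
            n_reps=config.consensus.n_reps,
            coassignment_threshold=config.consensus.coassignment_threshold,
            max_iterations=config.consensus.max_iterations,
            seed=derive_seed(consensus_seed, label),
        )
        part, _ = consensus_partition(G, cc_cfg)
        partitions[label] = part
        cmp = rand_index(part, category_part)
        rand_rows.append(
            {
                "network": label,
                "n_communities": part.n_communities,
                "rand_index": cmp.rand_index,
                "adjusted_rand": cmp.adjusted_rand,
            }
        )
        dispersion_cols[label] = {
            cat: d.sd for cat, d in category_distribution_sd(part, cueset).items()
        }
    partition_vs_categories = pd.DataFrame(rand_rows).set_index("network")
    dispersion = pd.DataFrame(dispersion_cols)
    dispersion.index.name = "category"
    log.info("communities: done")

    measure_rows = []
    for label, G in networks.items():
        m = measure_network(
            G,
            seed=derive_seed(config.seed, f"measure:{label}"),
            n_random_realizations=config.n_random_realizations,
            disconnected="largest_component",
            partition=partitions[label],
        )
        measure_rows.append(m.to_dict())
    measures = pd.DataFrame(measure_rows).set_index("group_label")
    log.info("measure: done")

    distributions = None
    comparisons: dict = {}
    stats = pd.DataFrame()
    group_sims = {k: v for k, v in similarities.items() if k != GENERAL}
    if len(group_sims) >= 2:
        boot_cfg = BootstrapConfig(
            n_realizations=config.bootstrap.n_realizations,
            node_fraction=config.bootstrap.node_fraction,
            seed=derive_seed(config.seed, "bootstrap"),
            shared_subsets=config.bootstrap.shared_subsets,
        )
        distributions = bootstrap_measures(group_sims, boot_cfg)
        comparisons = compare_groups(distributions, mode=config.pairwise_mode)
        stats = stats_table(comparisons)
        log.info("bootstrap: %d realizations", boot_cfg.n_realizations)

    nbr = neighborhood_report(networks, cueset)
    log.info("neighbors: done")

    manifest = {
        "assocnet_version": __version__,
        "seed": config.seed,
        "derived_seeds": {
            stage: derive_seed(config.seed, stage)
            for stage in ("bootstrap", "communities")
        },
        "group_by": config.group_by,
        "n_cues": len(cueset),
        "networks": list(networks),
        "bootstrap": {
            "n_realizations": config.bootstrap.n_realizations,
            "node_fraction": config.bootstrap.node_fraction,
            "shared_subsets": config.bootstrap.shared_subsets,
        },
        "consensus": {
            "n_reps": config.consensus.n_reps,
            "coassignment_threshold": config.consensus.coassignment_threshold,
        },
        "input": config.input_path or "generator",
        "planted_truth": truth.to_json_dict() if truth is not None else None,
    }

    bundle = ReportBundle(
        measures=measures,
        comparisons=comparisons,
        stats=stats,
        partitions=partitions,
        partition_vs_categories=partition_vs_categories,
        dispersion=dispersion,
        neighborhoods=nbr,
        networks=networks,
        similarities=similarities,
        distributions=distributions,
        exclusions=exclusions,
        summary=summary,
        manifest=manifest,
    )
    if config.out_dir is not None:
        write_bundle(bundle, config.out_dir)
    log.info("pipeline finished in %.1f s", time.time() - t0)
    return bundle


def write_bundle(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write every table/network/report of a run; byte-stable given seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.measures.to_csv(out / "network_measures.csv")
    if len(bundle.stats):
        bundle.stats.to_csv(out / "comparison_stats.csv", index=False)
    bundle.partition_vs_categories.to_csv(out / "rand_vs_categories.csv")
    bundle.dispersion.to_csv(out / "category_dispersion.csv")
    bundle.summary.to_csv(out / "group_summary.csv")
    for label, G in bundle.networks.items():
        write_network(
            G,
            graphml_path=out / f"network_{label}.graphml",
            edgelist_path=out / f"network_{label}.tsv",
        )
    for label, sim in bundle.similarities.items():
        write_similarity(sim, out / f"similarity_{label}.csv")
    for label, part in bundle.partitions.items():
        write_partition(part, out / f"partition_{label}.tsv")
    if bundle.distributions is not None:
        for measure in bundle.distributions.measures:
            bundle.distributions.frame(measure).to_csv(
                out / f"bootstrap_{measure}.csv", index_label="realization"
            )
    with open(out / "neighborhoods.json", "w") as fh:
        json.dump(bundle.neighborhoods.to_json_dict(), fh, indent=2, sort_keys=True)
    with open(out / "manifest.json", "w") as fh:
        json.dump(bundle.manifest, fh, indent=2, sort_keys=True)


def load_run_config(path: str | Path) -> RunConfig:
    """Build a RunConfig from a YAML file (nested key/value sections)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "generator" in raw and "input" in raw:
        raise ValueError("config sets both 'generator' and 'input'")
    if "generator" in raw:
        gspec = raw["generator"] or {}
        gen = study_like_config(
            seed=int(gspec.get("seed", raw.get("seed", 0))),
            scale=float(gspec.get("scale", 1.0)),
        )
        cueset = gen.cue_set
        input_path = None
    elif "input" in raw:
        gen = None
        input_path = raw["input"]
        cues_path = raw.get("cues")
        if cues_path is None:
            raise ValueError("config with 'input' must also set 'cues'")
        cueset = read_cue_set(cues_path, tuple(raw.get("focal_concepts", ())))
    else:
        raise ValueError("config must set 'generator' or 'input'")
    pp = raw.get("preprocess", {})
    wordlist = frozenset(
        Path(pp["wordlist"]).read_text().split()
        if "wordlist" in pp
        else (gen.wordlist() if gen is not None else ())
    )
    preprocess_cfg = PreprocessConfig(
        wordlist=wordlist,
        remove_nonwords=bool(pp.get("remove_nonwords", bool(wordlist))),
        depluralize=bool(pp.get("depluralize", True)),
        missing_cue_threshold=float(pp.get("missing_cue_threshold", 0.10)),
        low_output_sd_multiplier=float(pp.get("low_output_sd_multiplier", 2.0)),
        participant_nonword_threshold=float(
            pp.get("participant_nonword_threshold", 0.5)
        ),
    )
    bs = raw.get("bootstrap", {})
    cons = raw.get("consensus", {})
    return RunConfig(
        cueset=cueset,
        input_path=input_path,
        generator=gen,
        group_by=raw.get("group_by", "cohort"),
        preprocess=preprocess_cfg,
        bootstrap=BootstrapConfig(
            n_realizations=int(bs.get("realizations", 1000)),
            node_fraction=float(bs.get("node_fraction", 0.5)),
            shared_subsets=bool(bs.get("shared_subsets", True)),
        ),
        consensus=ConsensusConfig(
            n_reps=int(cons.get("reps", 1000)),
            coassignment_threshold=float(cons.get("threshold", 0.5)),
            max_iterations=int(cons.get("max_iterations", 20)),
        ),
        n_random_realizations=int(raw.get("null_realizations", 1000)),
        out_dir=raw.get("out"),
        seed=int(raw.get("seed", 0)),
        pairwise_mode=raw.get("pairwise_mode", "independent"),
    )


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
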