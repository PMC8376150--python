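"""Focal-concept neighborhoods across a family of group networks.

Estimates one network per cohort plus the pooled network, then reports
for each core concept its direct neighbors, their category composition
("k/n overall neighbors"), and the neighbors consistent across all
networks.
"""

from assocnet import (
    estimate_network,
    generate_dataset,
    neighborhood_report,
    study_like_config,
)

config = study_like_config(seed=7, scale=0.3)
dataset, _ = generate_dataset(config)
cueset = config.cue_set

networks = {"general": estimate_network(dataset, cueset, "all")}
for group in config.groups:
    networks[group.name] = estimate_network(dataset, cueset, {"cohort": group.name})

report = neighborhood_report(networks, cueset)
for cue in cueset.focal_concepts:
    print(f"\n{cue}:")
    for label in report.network_labels:
        comp = report.composition[(label, cue)]
        pretty = ", ".join(f"{cat} {c}/{size}" for cat, (c, size) in comp.items())
        print(f"  {label:12s} {len(report.neighbor_sets[(label, cue)])} neighbors ({pretty})")
    print(f"  consistent across all networks: {sorted(report.consistent[cue])}")
print(
    "\nConsistent neighbors are the intersection over networks — the stable"
    "\ncore of each concept's neighborhood; composition fractions mirror the"
    "\n'k/n overall neighbors' reporting style."
)
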