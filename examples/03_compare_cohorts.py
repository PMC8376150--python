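"""Compare two cohorts with the without-replacement node bootstrap.

Two synthetic groups differing in response concentration (rho) are
bootstrapped: each realization re-filters a PMFG on a shared random
half of the nodes (23 of 47) per group and measures CC.  The bootstrap
distributions are then compared with a pooled-variance t test.
"""

from assocnet import (
    BootstrapConfig,
    GeneratorConfig,
    GroupSpec,
    bootstrap_measures,
    build_profile_matrix,
    correlation_matrix,
    generate_dataset,
    make_synthetic_cue_set,
    ttest_pairwise,
)

cueset, response_cats = make_synthetic_cue_set()
config = GeneratorConfig(
    cue_set=cueset,
    groups=(GroupSpec("younger", 80, rho=1.0), GroupSpec("older", 80, rho=1.5)),
    seed=3,
    response_category_of=response_cats,
)
dataset, _ = generate_dataset(config)

similarities = {
    g.name: correlation_matrix(
        build_profile_matrix(dataset, cueset, {"cohort": g.name})
    )
    for g in config.groups
}
dists = bootstrap_measures(
    similarities, BootstrapConfig(n_realizations=100, seed=4), measures=("cc",)
)
cc_y, cc_o = dists.values["younger"]["cc"], dists.values["older"]["cc"]
stat = ttest_pairwise(cc_y, cc_o, group_a="younger", group_b="older")
print(f"bootstrap CC: younger {cc_y.mean():.4f} (SD {cc_y.std(ddof=1):.4f}), "
      f"older {cc_o.mean():.4f} (SD {cc_o.std(ddof=1):.4f})")
print(f"t({stat.df}) = {stat.t:.2f}, p = {stat.p:.2e}, d = {stat.cohen_d:.2f}")
print(
    "\nThe planted concentration gap makes the older group's network more"
    "\nsegregated: its bootstrap-mean clustering coefficient is lower, and"
    "\nthe difference is far beyond bootstrap noise."
)
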