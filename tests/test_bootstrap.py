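"""Node-subset bootstrap, partial networks, and group statistics."""

import numpy as np
import pandas as pd
import pytest

from assocnet.bootstrap import (
    BootstrapConfig,
    BootstrapError,
    anova_oneway,
    bootstrap_measures,
    compare_groups,
    partial_network,
    sample_node_subsets,
    stats_table,
    ttest_pairwise,
)


# -- subsets -----------------------------------------------------------------


def test_half_of_47_is_23():
    subsets = sample_node_subsets(47, BootstrapConfig(n_realizations=50, seed=0))
    assert all(len(s) == 23 for s in subsets)


def test_subsets_valid_and_duplicate_free():
    subsets = sample_node_subsets(6, BootstrapConfig(n_realizations=30, seed=1))
    for s in subsets:
        assert len(s) == 3
        assert len(set(s.tolist())) == 3
        assert set(s.tolist()) <= set(range(6))


def test_subsets_deterministic():
    cfg = BootstrapConfig(n_realizations=10, seed=9)
    s1 = sample_node_subsets(20, cfg)
    s2 = sample_node_subsets(20, cfg)
    assert all((a == b).all() for a, b in zip(s1, s2))


def test_subset_size_below_3_rejected():
    with pytest.raises(BootstrapError, match="PMFG"):
        sample_node_subsets(5, BootstrapConfig(node_fraction=0.5))


# -- partial networks --------------------------------------------------------


def test_partial_network_edge_formula(similarity_factory):
    sim = similarity_factory(47, seed=2)
    subset = sample_node_subsets(47, BootstrapConfig(n_realizations=1, seed=3))[0]
    P = partial_network(sim, subset)
    assert P.number_of_edges() == 3 * (23 - 2)


def test_full_subset_equals_full_network(similarity_factory):
    from assocnet.estimation import binarize, pmfg

    sim = similarity_factory(12, seed=4)
    P = partial_network(sim, np.arange(12))
    F = binarize(pmfg(sim))
    assert set(map(tuple, map(sorted, P.edges()))) == set(
        map(tuple, map(sorted, F.edges()))
    )


def test_four_node_subset_is_complete_k4(similarity_factory):
    # any 4-node restricted PMFG is K4 (planar), regardless of weights
    sim = similarity_factory(5, seed=5)
    P = partial_network(sim, np.array([0, 1, 2, 4]))
    assert P.number_of_edges() == 6


def test_refiltered_not_induced(similarity_factory):
    """The partial network re-runs the filter on the submatrix; the induced
    subgraph of the full PMFG generally has fewer than 3(k-2) edges."""
    from assocnet.estimation import pmfg

    sim = similarity_factory(20, seed=6)
    subset = np.arange(10)
    P = partial_network(sim, subset)
    induced = pmfg(sim).subgraph([sim.index[i] for i in subset])
    assert P.number_of_edges() == 24
    assert induced.number_of_edges() <= P.number_of_edges()


# -- distributions -----------------------------------------------------------


def test_identical_groups_give_identical_arrays(similarity_factory):
    sim = similarity_factory(16, seed=7)
    sims = {"g1": sim, "g2": sim.copy()}
    dists = bootstrap_measures(
        sims, BootstrapConfig(n_realizations=10, seed=1), measures=("cc", "aspl")
    )
    for m in ("cc", "aspl"):
        np.testing.assert_array_equal(dists.values["g1"][m], dists.values["g2"][m])
    t = ttest_pairwise(dists.values["g1"]["cc"], dists.values["g2"]["cc"], "paired")
    assert t.t == 0.0 and t.cohen_d == 0.0


def test_shared_subsets_invariant_to_group_order(similarity_factory):
    a, b = similarity_factory(14, seed=8), similarity_factory(14, seed=9)
    b.index = b.columns = a.index
    cfg = BootstrapConfig(n_realizations=8, seed=2)
    d1 = bootstrap_measures({"a": a, "b": b}, cfg, measures=("cc",))
    d2 = bootstrap_measures({"b": b, "a": a}, cfg, measures=("cc",))
    np.testing.assert_array_equal(d1.values["a"]["cc"], d2.values["a"]["cc"])
    np.testing.assert_array_equal(d1.values["b"]["cc"], d2.values["b"]["cc"])


def test_cue_set_mismatch_rejected(similarity_factory):
    sims = {"a": similarity_factory(10, seed=1), "b": similarity_factory(11, seed=1)}
    with pytest.raises(BootstrapError, match="mismatch"):
        bootstrap_measures(sims, BootstrapConfig(n_realizations=2))


def test_q_uses_consensus_partitions(similarity_factory):
    from assocnet.community import ConsensusConfig

    sims = {"g": similarity_factory(12, seed=3)}
    dists = bootstrap_measures(
        sims,
        BootstrapConfig(n_realizations=5, seed=4),
        consensus_config=ConsensusConfig(n_reps=10, max_iterations=5, seed=0),
    )
    q = dists.values["g"]["q"]
    assert q.shape == (5,)
    assert np.all(q >= -0.5) and np.all(q <= 1.0)


# -- statistics --------------------------------------------------------------


def test_anova_zero_between_variance():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    out = anova_oneway({"a": base, "b": base.copy(), "c": base.copy()})
    assert out.f == pytest.approx(0.0)
    assert out.eta_sq == pytest.approx(0.0)


def test_anova_hand_table():
    out = anova_oneway(
        {"a": np.array([1.0, 2, 3]), "b": np.array([2.0, 3, 4]), "c": np.array([3.0, 4, 5])}
    )
    assert out.f == pytest.approx(3.0)
    assert out.df_between == 2 and out.df_within == 6
    assert out.eta_sq == pytest.approx(0.5)


def test_anova_df_for_four_groups_of_1000():
    rng = np.random.default_rng(0)
    samples = {g: rng.normal(size=1000) for g in "abcd"}
    out = anova_oneway(samples)
    assert (out.df_between, out.df_within) == (3, 3996)


def test_anova_matches_scipy():
    from scipy import stats

    rng = np.random.default_rng(5)
    samples = {g: rng.normal(loc=i * 0.1, size=40) for i, g in enumerate("abc")}
    ours = anova_oneway(samples)
    ref = stats.f_oneway(*samples.values())
    assert ours.f == pytest.approx(ref.statistic)
    assert ours.p == pytest.approx(ref.pvalue)


def test_ttest_hand_value():
    out = ttest_pairwise(np.array([1.0, 2, 3]), np.array([2.0, 3, 4]))
    assert out.t == pytest.approx(-1.2247, abs=1e-4)
    assert out.df == 4
    assert out.cohen_d == pytest.approx(-1.0)


def test_ttest_df_1998_for_two_thousand():
    rng = np.random.default_rng(1)
    out = ttest_pairwise(rng.normal(size=1000), rng.normal(size=1000))
    assert out.df == 1998


def test_ttest_matches_scipy_both_modes():
    from scipy import stats

    rng = np.random.default_rng(2)
    a, b = rng.normal(size=30), rng.normal(0.3, size=30)
    ind = ttest_pairwise(a, b, "independent")
    ref = stats.ttest_ind(a, b)
    assert ind.t == pytest.approx(ref.statistic)
    assert ind.p == pytest.approx(ref.pvalue)
    par = ttest_pairwise(a, b, "paired")
    ref = stats.ttest_rel(a, b)
    assert par.t == pytest.approx(ref.statistic)
    assert par.p == pytest.approx(ref.pvalue)
    assert par.df == 29


def test_zero_variance_errors():
    with pytest.raises(BootstrapError, match="variance"):
        ttest_pairwise(np.ones(5), np.ones(5), "independent")
    with pytest.raises(BootstrapError, match="F undefined"):
        anova_oneway({"a": np.ones(3), "b": np.ones(3)})


def test_compare_groups_table_layout(similarity_factory):
    a, b = similarity_factory(14, seed=10), similarity_factory(14, seed=11)
    b.index = b.columns = a.index
    dists = bootstrap_measures(
        {"a": a, "b": b}, BootstrapConfig(n_realizations=6, seed=5), measures=("cc",)
    )
    out = compare_groups(dists)
    table = stats_table(out)
    assert set(table["measure"]) == {"cc"}
    assert list(table["contrast"]) == ["omnibus", "a vs b"]
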