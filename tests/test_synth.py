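"""Generator contracts: determinism, vocabulary closure, planted structure."""

import math

import numpy as np
import pandas as pd
import pytest

from assocnet.estimation import build_profile_matrix, correlation_matrix
from assocnet.synth import (
    ConfigurationError,
    GeneratorConfig,
    GroupSpec,
    generate_dataset,
    make_synthetic_cue_set,
    summarize_dataset,
)


def _config(cueset, response_cats, **kw):
    defaults = dict(
        cue_set=cueset,
        groups=(GroupSpec("g1", 5), GroupSpec("g2", 5)),
        seed=0,
        response_category_of=response_cats,
    )
    defaults.update(kw)
    return GeneratorConfig(**defaults)


@pytest.fixture(scope="module")
def six_cue_setup():
    return make_synthetic_cue_set(n_categories=2, per_category=3, n_focal=0)


def test_same_seed_is_byte_identical(six_cue_setup):
    cueset, rc = six_cue_setup
    cfg = _config(cueset, rc, nonword_rate=0.05, plural_rate=0.05, missing_cue_prob=0.1)
    df1, t1 = generate_dataset(cfg)
    df2, t2 = generate_dataset(cfg)
    assert df1.to_csv() == df2.to_csv()
    assert t1 == t2


def test_different_seed_differs(six_cue_setup):
    cueset, rc = six_cue_setup
    df1, _ = generate_dataset(_config(cueset, rc, seed=1))
    df2, _ = generate_dataset(_config(cueset, rc, seed=2))
    assert df1.to_csv() != df2.to_csv()


def test_clean_config_responses_closed_under_vocabulary(six_cue_setup):
    cueset, rc = six_cue_setup
    cfg = _config(cueset, rc)  # all contamination rates zero
    df, truth = generate_dataset(cfg)
    # record count equals the sum of per-(participant, cue) list sizes
    sizes = df.groupby(["participant_id", "cue"]).size()
    assert sizes.sum() == len(df)
    assert (df.groupby(["participant_id", "cue"])["position"].max() == sizes).all()
    assert set(df["response"]) <= cfg.wordlist()
    assert truth.contaminated_records == ()
    # every participant answered every cue (missing_cue_prob = 0)
    assert df.groupby("participant_id")["cue"].nunique().eq(len(cueset)).all()


def test_contaminants_are_logged_and_outside_wordlist(six_cue_setup):
    cueset, rc = six_cue_setup
    cfg = _config(
        cueset, rc, nonword_rate=0.1, plural_rate=0.1, cue_echo_rate=0.1, seed=5
    )
    df, truth = generate_dataset(cfg)
    kinds = {k for *_, k in truth.contaminated_records}
    assert kinds == {"nonword", "plural", "cue_echo"}
    keyed = df.set_index(["participant_id", "cue", "position"])["response"]
    for pid, cue, pos, kind in truth.contaminated_records:
        token = keyed.loc[(pid, cue, pos)]
        if kind == "nonword":
            assert token.startswith("zzq") and token not in cfg.wordlist()
        elif kind == "cue_echo":
            assert token in cueset.cues
        elif kind == "plural":
            assert token.endswith("s") and token[:-1] in cfg.wordlist()


def test_no_duplicate_responses_within_a_list(six_cue_setup):
    cueset, rc = six_cue_setup
    df, _ = generate_dataset(_config(cueset, rc, seed=9))
    dupes = df.groupby(["participant_id", "cue"])["response"].nunique()
    sizes = df.groupby(["participant_id", "cue"]).size()
    assert (dupes == sizes).all()


def test_invalid_configs_name_the_field(six_cue_setup):
    cueset, rc = six_cue_setup
    with pytest.raises(ConfigurationError, match="p_within"):
        _config(cueset, rc, p_within=0.9, p_between=0.2).validate()
    with pytest.raises(ConfigurationError, match="nonword_rate"):
        _config(cueset, rc, nonword_rate=1.5).validate()
    with pytest.raises(ConfigurationError, match="mean_responses"):
        _config(
            cueset, rc, groups=(GroupSpec("g", 5, mean_responses=0.0),)
        ).validate()
    with pytest.raises(ConfigurationError, match="rho"):
        _config(cueset, rc, groups=(GroupSpec("g", 5, rho=-0.1),)).validate()


def test_planted_exclusions_are_recorded(six_cue_setup):
    cueset, rc = six_cue_setup
    cfg = _config(six_cue_setup[0], rc, n_planted_low_output=2, n_planted_high_missing=1)
    df, truth = generate_dataset(cfg)
    assert len(truth.excluded_by_design) == 2 * len(cfg.groups) + 1 * len(cfg.groups)
    assert set(truth.excluded_by_design) <= set(df["participant_id"])
    # low-output plants answer exactly one response per cue
    low = [p for p in truth.excluded_by_design if p.endswith("p0001") or p.endswith("p0002")]
    sizes = df[df["participant_id"].isin(low)].groupby(["participant_id", "cue"]).size()
    assert (sizes == 1).all()


# -- summary statistics ------------------------------------------------------


def test_summary_constant_lists(toy_frame_builder):
    rows = [
        (p, "g", "f", c, f"w{i}", i + 1)
        for p in ("p1", "p2")
        for c in ("a1", "b1")
        for i in range(3)
    ]
    out = summarize_dataset(toy_frame_builder(rows))
    assert out.loc["g", "mean_responses_per_cue"] == 3
    assert out.loc["g", "sd_responses_per_cue"] == 0


def test_summary_two_participant_hand_value(toy_frame_builder):
    # participant means 6 and 8 -> group mean 7, sample SD sqrt(2)
    rows = []
    for p, k in (("p1", 6), ("p2", 8)):
        for c in ("a1", "b1"):
            rows += [(p, "g", "f", c, f"w{i}", i + 1) for i in range(k)]
    out = summarize_dataset(toy_frame_builder(rows))
    assert out.loc["g", "mean_responses_per_cue"] == pytest.approx(7.0)
    assert out.loc["g", "sd_responses_per_cue"] == pytest.approx(math.sqrt(2))


def test_summary_matches_poisson_mean(study_cueset):
    cueset, rc = study_cueset
    cfg = GeneratorConfig(
        cue_set=cueset,
        groups=(GroupSpec("g", 100, mean_responses=7.0),),
        seed=4,
        response_category_of=rc,
    )
    df, _ = generate_dataset(cfg)
    out = summarize_dataset(df, cueset)
    # truncation at 1 raises the mean of Poisson(7) by ~0.006; the band
    # covers sampling error at 100 participants x 47 cues
    assert 6.3 <= out.loc["g", "mean_responses_per_cue"] <= 7.7


def test_summary_rejects_empty():
    with pytest.raises(ValueError):
        summarize_dataset(pd.DataFrame(columns=["cohort", "participant_id", "cue"]))


# -- planted correlation structure ------------------------------------------


def _within_between_gap(p_within, p_between, seeds, n_participants=60, n_categories=2):
    cueset, rc = make_synthetic_cue_set(n_categories=n_categories, per_category=5, n_focal=0)
    gaps = []
    for seed in seeds:
        cfg = GeneratorConfig(
            cue_set=cueset,
            groups=(GroupSpec("g", n_participants),),
            p_within=p_within,
            p_between=p_between,
            seed=seed,
            response_category_of=rc,
        )
        df, _ = generate_dataset(cfg)
        sim = correlation_matrix(build_profile_matrix(df, cueset, "all")).to_numpy()
        cats = [cueset.category_of[c] for c in cueset.cues]
        within, between = [], []
        for i in range(len(cats)):
            for j in range(i + 1, len(cats)):
                (within if cats[i] == cats[j] else between).append(sim[i, j])
        gaps.append(np.mean(within) - np.mean(between))
    return float(np.mean(gaps))


def test_symmetric_mixture_gives_zero_gap():
    """With p_within = p_between and mutual partner categories, within- and
    between-category expected profiles coincide, so the correlation gap
    vanishes up to Monte-Carlo error."""
    gap = _within_between_gap(0.3, 0.3, seeds=range(20), n_participants=200)
    assert abs(gap) < 0.05


def test_gap_increases_with_p_within():
    gaps = [
        _within_between_gap(pw, 0.05, seeds=range(5)) for pw in (0.2, 0.5, 0.8)
    ]
    assert gaps[0] < gaps[1] < gaps[2]
    assert gaps[2] > 0.5
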