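import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from assocnet.cueset import CueSet
from assocnet.synth import GeneratorConfig, GroupSpec, generate_dataset, make_synthetic_cue_set

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_cueset() -> CueSet:
    """Six cues, two categories, one focal concept per category."""
    cues = ("a1", "a2", "a3", "b1", "b2", "b3")
    cats = {"a1": "A", "a2": "A", "a3": "A", "b1": "B", "b2": "B", "b3": "B"}
    return CueSet(cues, cats)


@pytest.fixture(scope="session")
def study_cueset():
    """The reference 47-cue layout: 3 categories x 15 + 2 core concepts."""
    return make_synthetic_cue_set()


@pytest.fixture(scope="session")
def clean_dataset(study_cueset):
    """A contamination-free generated dataset: 2 groups x 30 participants."""
    cueset, response_cats = study_cueset
    config = GeneratorConfig(
        cue_set=cueset,
        groups=(GroupSpec("g1", 30), GroupSpec("g2", 30, rho=0.6)),
        seed=11,
        response_category_of=response_cats,
    )
    df, truth = generate_dataset(config)
    return config, df, truth


def tiny_frame(rows):
    """Long-format frame from (pid, cohort, sex, cue, response, position) rows."""
    return pd.DataFrame(
        rows, columns=["participant_id", "cohort", "sex", "cue", "response", "position"]
    )


@pytest.fixture
def toy_frame_builder():
    return tiny_frame


def random_similarity(n: int, seed: int) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    W = rng.standard_normal((n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    labels = [f"c{i:02d}" for i in range(n)]
    return pd.DataFrame(W, index=labels, columns=labels)


@pytest.fixture
def similarity_factory():
    return random_similarity


def random_graph(n: int, p: float, seed: int) -> nx.Graph:
    return nx.gnp_random_graph(n, p, seed=seed)
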