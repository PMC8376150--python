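"""Synthetic continuous free-association data with planted structure.

The generator emulates the statistical shape of a group free-association
study: each participant sees every cue and produces an unordered list of
single-word responses (roughly Poisson-many, mean ~7, matching published
group norms).  Planted structure enters through three knobs:

* **category vocabularies** — each cue category owns a response
  vocabulary with a shared Zipf-like popularity ranking.  A response to a
  cue is drawn from the cue's own category vocabulary with probability
  ``p_within``, from a designated partner category with ``p_between``,
  and uniformly from a global vocabulary otherwise.  High ``p_within``
  therefore plants high within-category cue–cue response-profile
  correlation and low between-category correlation — a recoverable
  community structure.
* **group concentration** ``rho`` — the Zipf exponent per group,
  modulated per cue by a fixed "generality" ladder.  Higher ``rho``
  concentrates responses on the same top-ranked items across
  participants, raising within-category profile correlations and
  grading them along the ladder; it is the single knob for planting
  group effects.  Downstream, higher concentration yields more
  segregated networks: lower clustering, longer paths, higher
  modularity.
* **contaminants** — non-words, plural variants, echoed cues and missing
  cues injected at configured rates, plus participants engineered to
  violate the exclusion rules, so preprocessing has ground truth to
  recover.

Focal ("core concept") cues respond like members of a designated aligned
category rather than drawing from a two-word vocabulary of their own:
the core cue *beauty* behaves like the beauty-category terms.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cueset import CueSet
from .dataset import COLUMNS, validate_dataset


class ConfigurationError(ValueError):
    """A generator configuration violates its invariants."""


@dataclass(frozen=True)
class GroupSpec:
    """One participant group (a cohort level).

    ``rho`` is the Zipf concentration exponent (>= 0; 0 = uniform use of
    the category vocabulary), ``mean_responses`` the Poisson mean number
    of responses per answered cue (> 0).
    """

    name: str
    n_participants: int
    rho: float = 1.0
    mean_responses: float = 7.0


@dataclass(frozen=True)
class GeneratorConfig:
    cue_set: CueSet
    groups: tuple[GroupSpec, ...]
    category_vocab_size: int = 60
    global_vocab_size: int = 200
    p_within: float = 0.8
    p_between: float = 0.05
    nonword_rate: float = 0.0
    plural_rate: float = 0.0
    cue_echo_rate: float = 0.0
    missing_cue_prob: float = 0.0
    seed: int = 0
    #: response-category override for cues (focal concepts in particular);
    #: cues absent from the map respond as their own category.
    response_category_of: dict[str, str] = field(default_factory=dict, hash=False)
    #: partner category receiving the p_between mass; default cyclic successor.
    partner_of: dict[str, str] = field(default_factory=dict, hash=False)
    #: per-cue generality ladder bounds (see ``_generality``): within each
    #: category, cue generality multipliers span this range.
    generality_range: tuple[float, float] = (0.8, 1.2)
    #: per group: number of participants planted to answer one response per
    #: cue (violating the low-output exclusion rule) ...
    n_planted_low_output: int = 0
    #: ... and to skip 20% of cues (violating the missing-cue rule).
    n_planted_high_missing: int = 0

    def validate(self) -> None:
        if self.p_within < 0 or self.p_between < 0:
            raise ConfigurationError("p_within and p_between must be >= 0")
        if self.p_within + self.p_between > 1 + 1e-12:
            raise ConfigurationError("p_within + p_between must be <= 1")
        for name in ("nonword_rate", "plural_rate", "cue_echo_rate", "missing_cue_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if not self.groups:
            raise ConfigurationError("groups must be non-empty")
        for g in self.groups:
            if g.mean_responses <= 0:
                raise ConfigurationError(
                    f"mean_responses must be > 0 for group {g.name!r}"
                )
            if g.rho < 0:
                raise ConfigurationError(f"rho must be >= 0 for group {g.name!r}")
            if g.n_participants < 1:
                raise ConfigurationError(
                    f"n_participants must be >= 1 for group {g.name!r}"
                )
        if self.category_vocab_size < 2:
            raise ConfigurationError("category_vocab_size must be >= 2")
        if self.global_vocab_size < 0:
            raise ConfigurationError("global_vocab_size must be >= 0")
        if self.global_vocab_size == 0 and self.p_within + self.p_between < 1 - 1e-12:
            raise ConfigurationError(
                "global_vocab_size = 0 requires p_within + p_between = 1"
            )
        lo, hi = self.generality_range
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                "generality_range must satisfy 0 < low <= high"
            )

    # -- vocabulary ---------------------------------------------------------

    def response_categories(self) -> tuple[str, ...]:
        """Categories that own a response vocabulary (focal cues excluded)."""
        cats = []
        mapped = set(self.response_category_of.values())
        for cat in self.cue_set.categories:
            members = self.cue_set.members(cat)
            if all(c in self.response_category_of for c in members) and cat not in mapped:
                continue  # purely focal category; no vocabulary of its own
            cats.append(cat)
        return tuple(cats)

    def vocabulary(self) -> dict[str, list[str]]:
        """Response vocabularies: one list per response category + 'global'."""
        vocab = {
            cat: [f"{cat}_w{r:03d}" for r in range(1, self.category_vocab_size + 1)]
            for cat in self.response_categories()
        }
        vocab["global"] = [f"g_w{r:04d}" for r in range(1, self.global_vocab_size + 1)]
        return vocab

    def wordlist(self) -> set[str]:
        """All legitimate response tokens (the accepted-word dictionary)."""
        return set(itertools.chain.from_iterable(self.vocabulary().values()))


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth recorded alongside a generated dataset."""

    category_of_cue: dict[str, str] = field(hash=False)
    group_params: dict[str, dict[str, float]] = field(hash=False)
    contaminated_records: tuple[tuple[str, str, int, str], ...] = ()
    excluded_by_design: tuple[str, ...] = ()

    def to_json_dict(self) -> dict:
        return {
            "category_of_cue": self.category_of_cue,
            "group_params": self.group_params,
            "contaminated_records": [list(r) for r in self.contaminated_records],
            "excluded_by_design": list(self.excluded_by_design),
        }


def make_synthetic_cue_set(
    n_categories: int = 3,
    per_category: int = 15,
    n_focal: int = 2,
) -> tuple[CueSet, dict[str, str]]:
    """A cue set shaped like the reference design (3x15 + 2 core concepts).

    Returns the cue set and the response-category map aligning each focal
    concept with one of the first ``n_focal`` categories.
    """
    if n_focal > n_categories:
        raise ConfigurationError("need at least one category per focal concept")
    cats = [f"cat{i + 1}" for i in range(n_categories)]
    cues: list[str] = []
    category_of: dict[str, str] = {}
    for cat in cats:
        for k in range(1, per_category + 1):
            cue = f"{cat}_cue{k:02d}"
            cues.append(cue)
            category_of[cue] = cat
    focal = tuple(f"concept_{chr(ord('a') + i)}" for i in range(n_focal))
    for f in focal:
        cues.append(f)
        category_of[f] = "concepts"
    response_category_of = {f: cats[i] for i, f in enumerate(focal)}
    return CueSet(tuple(cues), category_of, focal), response_category_of


def study_like_config(seed: int = 0, scale: float = 1.0) -> GeneratorConfig:
    """A configuration emulating the reference study's shape.

    Four age-generation cohorts with the published group sizes and mean
    response counts (N = 88/118/151/97; ~6.7-7.4 responses per cue), a
    47-cue set (3 categories x 15 + 2 core concepts), and a rising
    concentration gradient so older cohorts yield more segregated
    networks (lower CC, higher ASPL and Q).  ``scale`` shrinks the
    group sizes proportionally.
    """
    cueset, response_cats = make_synthetic_cue_set()
    spec = [
        ("gen_z", 88, 0.8, 6.67),
        ("millennials", 118, 1.0, 7.06),
        ("gen_x", 151, 1.2, 7.45),
        ("boomers", 97, 1.4, 7.37),
    ]
    groups = tuple(
        GroupSpec(name, max(2, round(n * scale)), rho, lam)
        for name, n, rho, lam in spec
    )
    return GeneratorConfig(
        cue_set=cueset,
        groups=groups,
        seed=seed,
        response_category_of=response_cats,
        nonword_rate=0.01,
        plural_rate=0.02,
        cue_echo_rate=0.01,
        missing_cue_prob=0.02,
    )


def _partner_map(config: GeneratorConfig) -> dict[str, str]:
    cats = list(config.response_categories())
    partner = {
        cat: cats[(i + 1) % len(cats)] if len(cats) > 1 else cat
        for i, cat in enumerate(cats)
    }
    partner.update(config.partner_of)
    for cat, p in partner.items():
        if p not in cats:
            raise ConfigurationError(f"partner_of[{cat!r}] = {p!r} is not a category")
    return partner


def _generality(config: GeneratorConfig) -> dict[str, float]:
    """Per-cue concentration multiplier h_i, fixed across groups.

    Within each category the (non-focal) members span
    ``generality_range`` on an evenly spaced ladder; focal cues mapped
    into a category sit at the midpoint of the range, where a cue's mean
    correlation with the rest of its category is largest, anchoring the
    core concepts firmly inside their aligned blocks.  Cue i's effective
    Zipf exponent is ``rho_g * h_i``: raising the group concentration
    ``rho_g`` makes every cue's response distribution more stereotyped
    while spreading the cues apart along the ladder, which grades the
    within-category similarity structure and makes the resulting
    networks more segregated.
    """
    lo, hi = config.generality_range
    h: dict[str, float] = {}
    for cat in config.cue_set.categories:
        members = [
            c
            for c in config.cue_set.members(cat)
            if c not in config.response_category_of
        ]
        ladder = (
            np.linspace(lo, hi, len(members)) if len(members) > 1 else [0.5 * (lo + hi)]
        )
        for c, hv in zip(members, ladder):
            h[c] = float(hv)
    for c in config.response_category_of:
        h[c] = 0.5 * (lo + hi)
    return h


def _mixture_probs(
    config: GeneratorConfig, rho: float, response_cat: dict[str, str]
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Support tokens and per-cue mixture distributions for one group.

    Cue i draws from its own category vocabulary with probability
    ``p_within`` and from the designated partner category with
    ``p_between``, both under the shared category popularity ranking
    with cue-specific Zipf exponent ``rho * h_i``; the remaining mass
    is uniform over the global vocabulary.
    """
    vocab = config.vocabulary()
    cats = config.response_categories()
    partner = _partner_map(config)
    support = np.array(
        list(itertools.chain.from_iterable(vocab[c] for c in cats)) + vocab["global"]
    )
    v = config.category_vocab_size
    ranks = np.arange(1, v + 1, dtype=float)
    block = {cat: slice(i * v, (i + 1) * v) for i, cat in enumerate(cats)}
    g0 = len(cats) * v
    h = _generality(config)
    probs: dict[str, np.ndarray] = {}
    for cue in config.cue_set.cues:
        cat = response_cat[cue]
        zipf = ranks ** (-rho * h[cue])
        zipf /= zipf.sum()
        p = np.zeros(len(support))
        p[block[cat]] = config.p_within * zipf
        if len(cats) > 1:
            p[block[partner[cat]]] += config.p_between * zipf
        else:
            p[block[cat]] += config.p_between * zipf
        rest = 1.0 - config.p_within - config.p_between
        if config.global_vocab_size:
            p[g0:] = rest / config.global_vocab_size
        p /= p.sum()
        probs[cue] = p
    return support, probs


def generate_dataset(config: GeneratorConfig) -> tuple[pd.DataFrame, PlantedTruth]:
    """Generate a long-format association dataset plus its planted truth.

    Deterministic given ``config.seed``.  Responses within one
    (participant, cue) list are distinct; contaminants are injected after
    sampling and logged in the returned :class:`PlantedTruth`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    cueset = config.cue_set
    response_cat = {
        cue: config.response_category_of.get(cue, cueset.category_of[cue])
        for cue in cueset.cues
    }
    cats = set(config.response_categories())
    for cue, rc in response_cat.items():
        if rc not in cats:
            raise ConfigurationError(
                f"cue {cue!r} has response category {rc!r} with no vocabulary; "
                "map it via response_category_of"
            )

    n_cues = len(cueset.cues)
    n_missing_planted = max(1, int(np.ceil(0.2 * n_cues)))
    rows: list[tuple] = []
    contaminated: list[tuple[str, str, int, str]] = []
    excluded_by_design: list[str] = []
    nonword_counter = itertools.count(1)

    for group in config.groups:
        support, probs = _mixture_probs(config, group.rho, response_cat)
        support_size = {c: int(np.count_nonzero(probs[c])) for c in probs}
        for pi in range(group.n_participants):
            pid = f"{group.name}_p{pi + 1:04d}"
            sex = "f" if pi % 2 == 0 else "m"
            low_output = pi < config.n_planted_low_output
            high_missing = (
                config.n_planted_low_output
                <= pi
                < config.n_planted_low_output + config.n_planted_high_missing
            )
            if low_output or high_missing:
                excluded_by_design.append(pid)
            missing = rng.random(n_cues) < config.missing_cue_prob
            if high_missing:
                forced = rng.choice(n_cues, size=n_missing_planted, replace=False)
                missing[forced] = True
            for ci, cue in enumerate(cueset.cues):
                if missing[ci]:
                    continue
                k = 1 if low_output else max(1, int(rng.poisson(group.mean_responses)))
                k = min(k, support_size[cue])
                resp = rng.choice(support, size=k, replace=False, p=probs[cue])
                for pos, token in enumerate(resp, start=1):
                    u = rng.random()
                    if u < config.nonword_rate:
                        token = f"zzq{next(nonword_counter):05d}"
                        contaminated.append((pid, cue, pos, "nonword"))
                    elif u < config.nonword_rate + config.cue_echo_rate:
                        token = cueset.cues[rng.integers(n_cues)]
                        contaminated.append((pid, cue, pos, "cue_echo"))
                    elif u < config.nonword_rate + config.cue_echo_rate + config.plural_rate:
                        token = token + "s"
                        contaminated.append((pid, cue, pos, "plural"))
                    rows.append((pid, group.name, sex, cue, token, pos))

    df = pd.DataFrame(rows, columns=list(COLUMNS))
    validate_dataset(df)
    truth = PlantedTruth(
        category_of_cue=response_cat,
        group_params={
            g.name: {"rho": g.rho, "mean_responses": g.mean_responses}
            for g in config.groups
        },
        contaminated_records=tuple(contaminated),
        excluded_by_design=tuple(excluded_by_design),
    )
    return df, truth


def summarize_dataset(df: pd.DataFrame, cueset: CueSet | None = None) -> pd.DataFrame:
    """Per-group summary: N, mean +- SD responses per answered cue, missing fraction.

    The per-participant statistic is the mean list length over *answered*
    cues; the group SD is the sample SD (ddof=1) of that statistic across
    participants.  Mirrors the "Associations M (SD)" row of a group
    demographics table.
    """
    if len(df) == 0:
        raise ValueError("empty dataset")
    n_cues = len(cueset.cues) if cueset is not None else df["cue"].nunique()
    per_cue = (
        df.groupby(["cohort", "participant_id", "cue"], sort=False)
        .size()
        .rename("n_responses")
        .reset_index()
    )
    per_participant = per_cue.groupby(["cohort", "participant_id"], sort=False).agg(
        mean_responses=("n_responses", "mean"),
        answered=("cue", "nunique"),
    )
    per_participant["missing_fraction"] = 1 - per_participant["answered"] / n_cues
    out = per_participant.groupby(level="cohort", sort=False).agg(
        n_participants=("mean_responses", "size"),
        mean_responses_per_cue=("mean_responses", "mean"),
        sd_responses_per_cue=("mean_responses", lambda s: s.std(ddof=1)),
        missing_cue_fraction=("missing_fraction", "mean"),
    )
    return out
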