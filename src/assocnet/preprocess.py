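"""Response normalization and participant exclusion.

Normalization follows the standard cleaning pipeline for free-association
data: lowercase and trim, convert plural responses to singular (guarded
by a dictionary so mass nouns survive), drop non-words, and drop
responses that echo any cue word.  Exclusion drops participants who
(1) missed more than a fraction of the cues, (2) produced responses per
cue more than ``sd_multiplier`` standard deviations below their group
mean, or (3) entered non-words at a high rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cueset import CueSet
from .dataset import GROUP_AXES, validate_dataset


class PreprocessConfigError(ValueError):
    pass


@dataclass(frozen=True)
class PreprocessConfig:
    """Knobs of the cleaning and exclusion stage.

    ``missing_cue_threshold`` — rule 1: exclude a participant whose
    missed-cue fraction exceeds this (default 0.10).
    ``low_output_sd_multiplier`` — rule 2: exclude a participant whose
    mean responses per answered cue falls below group mean minus this
    many group SDs (default 2.0).
    ``participant_nonword_threshold`` — rule 3: exclude a participant
    whose pre-removal non-word fraction exceeds this (default 0.5).
    """

    wordlist: frozenset[str] = frozenset()
    depluralize: bool = True
    remove_nonwords: bool = True
    remove_cue_echoes: bool = True
    missing_cue_threshold: float = 0.10
    low_output_sd_multiplier: float = 2.0
    participant_nonword_threshold: float = 0.5
    #: rule-2 counting convention: post-normalization counts over answered
    #: cues ("answered_post"); "answered_raw" uses pre-cleaning counts;
    #: "zeros" counts unanswered cues as zero.
    low_output_basis: str = "answered_post"
    spelling_corrections: dict[str, str] = field(default_factory=dict, hash=False)

    def validate(self) -> None:
        for name in ("missing_cue_threshold", "participant_nonword_threshold"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise PreprocessConfigError(f"{name} must be in [0, 1], got {v}")
        if self.low_output_sd_multiplier < 0:
            raise PreprocessConfigError("low_output_sd_multiplier must be >= 0")
        if self.remove_nonwords and not self.wordlist:
            raise PreprocessConfigError(
                "non-word removal enabled but wordlist is empty"
            )
        if self.low_output_basis not in ("answered_post", "answered_raw", "zeros"):
            raise PreprocessConfigError(
                f"unknown low_output_basis {self.low_output_basis!r}"
            )


@dataclass
class ExclusionReport:
    """Who was excluded, by which rule, and what was removed."""

    excluded: list[tuple[str, str, float]] = field(default_factory=list)
    removed_responses: dict[str, int] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def excluded_ids(self) -> set[str]:
        return {pid for pid, _, _ in self.excluded}


def _singularize(token: str, wordlist: frozenset[str]) -> str:
    """Strip a plural suffix only when the singular form is a known word."""
    if token in wordlist:
        return token
    for suffix in ("es", "s"):
        if token.endswith(suffix) and token[: -len(suffix)] in wordlist:
            return token[: -len(suffix)]
    return token


def normalize_responses(
    df: pd.DataFrame, cueset: CueSet, config: PreprocessConfig
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean responses; return the cleaned dataset and a removal log.

    Idempotent: applying the result again changes nothing.  Positions are
    re-indexed contiguously from 1 within each (participant, cue).
    """
    config.validate()
    validate_dataset(df)
    out = df.copy()
    out["response"] = out["response"].astype(str).str.strip().str.lower()
    if config.spelling_corrections:
        out["response"] = out["response"].replace(config.spelling_corrections)
    if config.depluralize:
        out["response"] = out["response"].map(
            lambda t: _singularize(t, config.wordlist)
        )
    removed = {"nonword": 0, "cue_echo": 0, "empty_after_normalization": 0}
    empty = out["response"] == ""
    removed["empty_after_normalization"] = int(empty.sum())
    out = out.loc[~empty]
    if config.remove_cue_echoes:
        echo = out["response"].isin(set(cueset.cues))
        removed["cue_echo"] = int(echo.sum())
        out = out.loc[~echo]
    if config.remove_nonwords:
        nonword = ~out["response"].isin(config.wordlist)
        removed["nonword"] = int(nonword.sum())
        out = out.loc[~nonword]
    out = out.sort_values(["participant_id", "cue", "position"], kind="stable")
    out["position"] = out.groupby(["participant_id", "cue"], sort=False).cumcount() + 1
    out = out.reset_index(drop=True)
    return out, removed


def _per_participant_output(
    df: pd.DataFrame, n_cues: int, basis: str
) -> pd.Series:
    """Mean responses per cue for each participant, under the configured basis."""
    counts = df.groupby(["participant_id", "cue"], sort=False).size()
    if basis == "zeros":
        return counts.groupby(level="participant_id").sum() / n_cues
    return counts.groupby(level="participant_id").mean()


def apply_exclusions(
    df: pd.DataFrame,
    cueset: CueSet,
    config: PreprocessConfig,
    raw_df: pd.DataFrame | None = None,
    group_by: str = "cohort",
) -> tuple[pd.DataFrame, ExclusionReport]:
    """Apply the three participant-exclusion rules to a cleaned dataset.

    ``df`` should already be normalized; ``raw_df`` (the pre-cleaning
    dataset) supplies the non-word fractions for rule 3 and the raw
    response counts when ``low_output_basis='answered_raw'``.  Rule-2
    group statistics are computed within the ``group_by`` stratum.
    """
    config.validate()
    validate_dataset(df)
    if group_by not in GROUP_AXES and group_by != "all":
        raise PreprocessConfigError(f"unknown group_by axis {group_by!r}")
    report = ExclusionReport()
    n_cues = len(cueset.cues)

    # rule 1: missing cues
    answered = df.groupby("participant_id", sort=False)["cue"].nunique()
    missing_frac = 1 - answered / n_cues
    for pid, frac in missing_frac.items():
        if frac > config.missing_cue_threshold:
            report.excluded.append((pid, "missing_cues", float(frac)))

    # rule 3: non-word fraction, on pre-removal responses
    if config.remove_nonwords:
        source = raw_df if raw_df is not None else df
        resp = source["response"].astype(str).str.strip().str.lower()
        if config.depluralize:
            resp = resp.map(lambda t: _singularize(t, config.wordlist))
        is_nonword = ~resp.isin(config.wordlist) & ~resp.isin(set(cueset.cues))
        nw_frac = is_nonword.groupby(source["participant_id"], sort=False).mean()
        for pid, frac in nw_frac.items():
            if frac > config.participant_nonword_threshold:
                report.excluded.append((pid, "nonwords", float(frac)))

    # rule 2: low output relative to the analysis group
    basis_df = raw_df if (config.low_output_basis == "answered_raw" and raw_df is not None) else df
    output = _per_participant_output(
        basis_df, n_cues, "zeros" if config.low_output_basis == "zeros" else "answered"
    )
    groups = (
        df.drop_duplicates("participant_id").set_index("participant_id")[group_by]
        if group_by != "all"
        else pd.Series("all", index=output.index)
    )
    already = report.excluded_ids
    for _, members in output.groupby(groups.reindex(output.index), sort=False):
        mean, sd = members.mean(), members.std(ddof=1)
        if pd.isna(sd):
            continue
        cutoff = mean - config.low_output_sd_multiplier * sd
        for pid, value in members.items():
            if value < cutoff and pid not in already:
                report.excluded.append((pid, "low_output", float(value)))

    cleaned = df.loc[~df["participant_id"].isin(report.excluded_ids)].reset_index(
        drop=True
    )
    if group_by != "all":
        sizes = cleaned.groupby(group_by, sort=False)["participant_id"].nunique()
        for grp, n in sizes.items():
            if n < 2:
                report.warnings.append(
                    f"group {grp!r} has {n} remaining participant(s); "
                    "statistics unreliable"
                )
    return cleaned, report


def preprocess(
    raw_df: pd.DataFrame,
    cueset: CueSet,
    config: PreprocessConfig,
    group_by: str = "cohort",
) -> tuple[pd.DataFrame, dict[str, int], ExclusionReport]:
    """Normalize then exclude: the standard two-step cleaning pipeline."""
    cleaned, removed = normalize_responses(raw_df, cueset, config)
    final, report = apply_exclusions(
        cleaned, cueset, config, raw_df=raw_df, group_by=group_by
    )
    report.removed_responses = removed
    return final, removed, report
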