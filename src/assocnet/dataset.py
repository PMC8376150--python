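"""Long-format free-association tables and their on-disk round trip.

The canonical container is a pandas DataFrame with columns
``participant_id, cohort, sex, cue, response, position`` — one row per
associative response.  ``cohort`` and ``sex`` are the grouping axes;
``position`` is the 1-based rank of the response within its
(participant, cue) list.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .cueset import CueSet

#: canonical column order of the long format
COLUMNS = ("participant_id", "cohort", "sex", "cue", "response", "position")

#: columns that identify a single record
KEY = ("participant_id", "cue", "position")

#: grouping axes available to the analysis
GROUP_AXES = ("cohort", "sex")


class FormatError(ValueError):
    """A file does not follow the canonical long format."""


class IntegrityError(ValueError):
    """A dataset violates a structural invariant."""


def validate_dataset(df: pd.DataFrame, cueset: CueSet | None = None) -> pd.DataFrame:
    """Validate a long-format association table, returning it unchanged.

    Checks the canonical columns, (participant, cue, position) uniqueness,
    position contiguity from 1 within each (participant, cue), single-word
    responses, and — when ``cueset`` is given — that every cue is a member
    of the cue set.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing required columns: {missing}")
    if len(df) == 0:
        return df
    dup = df.duplicated(list(KEY), keep=False)
    if dup.any():
        rows = df.index[dup].tolist()[:5]
        raise IntegrityError(
            f"duplicate (participant, cue, position) records at rows {rows}"
        )
    if (df["position"] < 1).any():
        raise IntegrityError("positions must be positive integers")
    bad_pos = (
        df.groupby(["participant_id", "cue"], sort=False)["position"]
        .agg(lambda s: sorted(s) != list(range(1, len(s) + 1)))
    )
    if bad_pos.any():
        key = bad_pos.index[bad_pos.argmax()]
        raise IntegrityError(f"positions not contiguous from 1 for {key}")
    if df["response"].astype(str).str.contains(r"\s").any():
        raise FormatError("responses must be single words (no whitespace)")
    if cueset is not None:
        unknown = sorted(set(df["cue"]) - set(cueset.cues))
        if unknown:
            raise IntegrityError(f"cues not in cue set: {unknown}")
    return df


def read_associations(
    path: str | Path, dialect: str = "tsv", cueset: CueSet | None = None
) -> pd.DataFrame:
    """Read a long-format association table from CSV/TSV and validate it."""
    if dialect not in ("csv", "tsv"):
        raise ValueError(f"dialect must be 'csv' or 'tsv', got {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns: {missing}")
    try:
        df["position"] = df["position"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer position field: {exc}") from exc
    df = df.loc[:, list(COLUMNS)]
    try:
        return validate_dataset(df, cueset)
    except IntegrityError as exc:
        # +2: header line and 1-based file lines
        raise IntegrityError(f"{path}: {exc} (data line = row + 2)") from exc


def write_associations(df: pd.DataFrame, path: str | Path, dialect: str = "tsv") -> None:
    """Write a validated association table in the canonical column order."""
    validate_dataset(df)
    sep = "\t" if dialect == "tsv" else ","
    df.loc[:, list(COLUMNS)].to_csv(path, sep=sep, index=False)


def group_values(df: pd.DataFrame, axis: str) -> list[str]:
    """Distinct values of a grouping axis, in order of first appearance."""
    if axis not in GROUP_AXES:
        raise ValueError(f"unknown grouping axis {axis!r}; use one of {GROUP_AXES}")
    return list(dict.fromkeys(df[axis]))


def select_group(df: pd.DataFrame, group_filter: dict[str, str] | str) -> pd.DataFrame:
    """Rows matching a {axis: value} filter; ``"all"`` selects everything."""
    if group_filter == "all" or group_filter == {}:
        return df
    mask = pd.Series(True, index=df.index)
    for axis, value in dict(group_filter).items():
        if axis not in GROUP_AXES:
            raise ValueError(f"unknown grouping axis {axis!r}")
        mask &= df[axis] == value
    return df.loc[mask]
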