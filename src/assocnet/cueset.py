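"""Cue sets: the fixed node vocabulary of a group-based semantic network.

A cue set is an ordered list of cue words, a category label for each cue,
and a (usually two-element) subset of *focal concepts* — the core words
whose semantic neighborhoods the analysis targets.  The reference design
is 47 cues: three categories of 15 terms plus the two core concepts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class CueSet:
    """An ordered cue vocabulary with category labels and focal concepts.

    Parameters
    ----------
    cues
        Ordered, unique cue tokens; the node set of every network built
        from the data.
    category_of
        Mapping cue -> category label.  Every cue must be mapped to
        exactly one category.
    focal_concepts
        The core concept cues (a subset of ``cues``); conventionally the
        members of the "Concepts" category.
    """

    cues: tuple[str, ...]
    category_of: dict[str, str] = field(hash=False)
    focal_concepts: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.cues)) != len(self.cues):
            dupes = sorted({c for c in self.cues if list(self.cues).count(c) > 1})
            raise ValueError(f"duplicate cues: {dupes}")
        missing = [c for c in self.cues if c not in self.category_of]
        if missing:
            raise ValueError(f"cues without a category: {missing}")
        extra = [c for c in self.category_of if c not in self.cues]
        if extra:
            raise ValueError(f"categories for unknown cues: {extra}")
        bad_focal = [c for c in self.focal_concepts if c not in self.cues]
        if bad_focal:
            raise ValueError(f"focal concepts not in cue set: {bad_focal}")

    def __len__(self) -> int:
        return len(self.cues)

    @property
    def categories(self) -> tuple[str, ...]:
        """Category labels in order of first appearance over ``cues``."""
        seen: dict[str, None] = {}
        for c in self.cues:
            seen.setdefault(self.category_of[c], None)
        return tuple(seen)

    def members(self, category: str) -> tuple[str, ...]:
        return tuple(c for c in self.cues if self.category_of[c] == category)

    def category_partition(self) -> dict[str, str]:
        """The corpus-based partition: each cue assigned to its category."""
        return dict(self.category_of)


def read_cue_set(
    path: str | Path, focal_concepts: tuple[str, ...] | list[str] = ()
) -> CueSet:
    """Read a 2-column TSV ``cue<TAB>category`` into a :class:`CueSet`."""
    cues: list[str] = []
    cats: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 tab-separated fields")
        cue, cat = parts[0].strip(), parts[1].strip()
        cues.append(cue)
        cats[cue] = cat
    return CueSet(tuple(cues), cats, tuple(focal_concepts))


def write_cue_set(cueset: CueSet, path: str | Path) -> None:
    lines = [f"{c}\t{cueset.category_of[c]}" for c in cueset.cues]
    Path(path).write_text("\n".join(lines) + "\n")
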