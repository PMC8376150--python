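"""Stimulus construction: nearest-neighbor term lists around concept
vectors, and selection of category-exclusive terms.

Works over any supplied embedding table (word2vec-style text format) and
corpus-frequency ranking; training embeddings is out of scope.  The
combined target (A+B) is queried with the elementwise sum of the two
concept vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .cueset import CueSet


class EmbeddingError(ValueError):
    pass


@dataclass
class EmbeddingTable:
    """Token embeddings plus a corpus frequency ranking (1 = most frequent)."""

    vocabulary: list[str]
    vectors: np.ndarray  # shape (n_tokens, dim)
    frequency_rank: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or self.vectors.shape[1] < 1:
            raise EmbeddingError("vectors must be a 2-D array with dim >= 1")
        if len(self.vocabulary) != self.vectors.shape[0]:
            raise EmbeddingError("vocabulary and vectors disagree in length")
        if len(set(self.vocabulary)) != len(self.vocabulary):
            raise EmbeddingError("vocabulary tokens must be unique")
        self._index = {t: i for i, t in enumerate(self.vocabulary)}

    def vector(self, token: str) -> np.ndarray:
        try:
            return self.vectors[self._index[token]]
        except KeyError:
            raise EmbeddingError(f"token {token!r} not in vocabulary") from None

    def rank(self, token: str) -> int:
        # unranked tokens sort last
        return self.frequency_rank.get(token, len(self.vocabulary) + 1)


def read_word2vec_text(path: str | Path) -> tuple[list[str], np.ndarray]:
    """Read the word2vec text format: header ``n dim``, then token + floats."""
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise EmbeddingError(f"{path}: empty file")
    try:
        n, dim = (int(x) for x in lines[0].split())
    except ValueError as exc:
        raise EmbeddingError(f"{path}: malformed header {lines[0]!r}") from exc
    tokens: list[str] = []
    vecs = np.empty((n, dim))
    for i, line in enumerate(lines[1 : n + 1]):
        parts = line.rstrip().split(" ")
        if len(parts) != dim + 1:
            raise EmbeddingError(f"{path}: line {i + 2} has {len(parts) - 1} values, expected {dim}")
        tokens.append(parts[0])
        vecs[i] = [float(x) for x in parts[1:]]
    if len(tokens) != n:
        raise EmbeddingError(f"{path}: header promised {n} rows, found {len(tokens)}")
    return tokens, vecs


def read_frequency_ranks(path: str | Path) -> dict[str, int]:
    """Read a 2-column TSV ``token<TAB>rank``."""
    ranks: dict[str, int] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        token, rank = line.split("\t")
        ranks[token] = int(rank)
    return ranks


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u.v / (|u||v|); errors on zero vectors."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise EmbeddingError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise EmbeddingError("cosine similarity undefined for a zero vector")
    return float(np.dot(u, v) / (nu * nv))


def nearest_terms(
    table: EmbeddingTable,
    target_vector: np.ndarray,
    k: int,
    restrict_to: set[str] | None = None,
    exclude_phrases: bool = True,
) -> list[tuple[str, float]]:
    """Top-``k`` tokens by cosine similarity to a target vector.

    Ties broken by better (smaller) frequency rank, then lexicographic
    token order.  ``restrict_to`` limits the candidate vocabulary (e.g.
    to the most frequent decile); phrase tokens (containing ``_``) are
    skipped by default.
    """
    candidates = [
        t
        for t in table.vocabulary
        if (restrict_to is None or t in restrict_to)
        and not (exclude_phrases and "_" in t)
    ]
    if not candidates:
        raise EmbeddingError("empty candidate vocabulary after restriction")
    if k > len(candidates):
        raise EmbeddingError(f"k={k} exceeds candidate vocabulary size {len(candidates)}")
    target = np.asarray(target_vector, dtype=float)
    sims = [(t, cosine_similarity(table.vector(t), target)) for t in candidates]
    sims.sort(key=lambda ts: (-ts[1], table.rank(ts[0]), ts[0]))
    return sims[:k]


def candidate_lists(
    table: EmbeddingTable,
    concept_a: str,
    concept_b: str,
    k: int,
    restrict_to: set[str] | None = None,
) -> dict[str, list[tuple[str, float]]]:
    """Ranked nearest-term lists for targets A, B and A+B (vector sum)."""
    va, vb = table.vector(concept_a), table.vector(concept_b)
    return {
        concept_a: nearest_terms(table, va, k, restrict_to),
        concept_b: nearest_terms(table, vb, k, restrict_to),
        f"{concept_a}+{concept_b}": nearest_terms(table, va + vb, k, restrict_to),
    }


def select_exclusive_terms(
    lists: dict[str, list[tuple[str, float]]],
    per_category: int,
    table: EmbeddingTable | None = None,
    focal_concepts: tuple[str, ...] = (),
) -> CueSet:
    """Pick the ``per_category`` most frequent terms unique to each list.

    A term appearing in two or more candidate lists is excluded from all
    selections; within a list, exclusive terms are ordered by descending
    corpus frequency (ascending rank), ties lexicographic.  Returns a
    :class:`CueSet` whose categories are the list labels (focal concepts,
    if given, appended under category ``"concepts"``).
    """
    membership: dict[str, set[str]] = {}
    for label, lst in lists.items():
        for token, _ in lst:
            membership.setdefault(token, set()).add(label)
    cues: list[str] = []
    category_of: dict[str, str] = {}
    shortfall: dict[str, int] = {}
    for label, lst in lists.items():
        exclusive = [t for t, _ in lst if membership[t] == {label} and t not in focal_concepts]
        if table is not None:
            exclusive.sort(key=lambda t: (table.rank(t), t))
        if len(exclusive) < per_category:
            shortfall[label] = len(exclusive)
            continue
        for t in exclusive[:per_category]:
            cues.append(t)
            category_of[t] = label
    if shortfall:
        raise EmbeddingError(
            f"not enough exclusive terms: attainable counts {shortfall} "
            f"(need {per_category} per list)"
        )
    for f in focal_concepts:
        cues.append(f)
        category_of[f] = "concepts"
    return CueSet(tuple(cues), category_of, tuple(focal_concepts))
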