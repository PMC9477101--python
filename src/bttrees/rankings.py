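"""Ranking and paired-comparison pattern algebra.

A complete ranking of J labeled items induces J(J-1)/2 forced binary
decisions, one per unordered item pair.  Collected over the canonical pair
order (1,2),(1,3),...,(1,J),(2,3),...,(J-1,J) these decisions form a signed
pattern vector; exactly the J! transitive patterns can arise from rankings
(a cycle such as a>b, b>c, c>a cannot be produced by an ordering).  The
Bradley-Terry pattern model in :mod:`bttrees.llbt` is a multinomial model
over these J! cells, and its sufficient statistic per pattern is the item
score vector x, where x_j is the signed number of pairwise wins of item j.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MAX_ITEMS",
    "ItemSet",
    "Ranking",
    "PCPattern",
    "PatternTable",
    "InvalidRankingError",
    "IntransitivePatternError",
    "canonical_pairs",
    "ranking_to_pattern",
    "pattern_to_ranking",
    "enumerate_patterns",
    "item_scores",
    "tabulate_patterns",
    "correct_ranking_rate",
    "read_rankings_csv",
    "write_rankings_csv",
]

#: Largest supported number of items for pattern enumeration (7! = 5040
#: patterns).  The J!-cell design grows factorially, so enumeration beyond
#: this is refused rather than attempted.
MAX_ITEMS = 7


class InvalidRankingError(ValueError):
    """A ranking is not a complete, duplicate-free permutation of the items."""


class IntransitivePatternError(ValueError):
    """A paired-comparison pattern contains a preference cycle."""


@dataclass(frozen=True)
class ItemSet:
    """An ordered set of distinct item labels to be ranked on one attribute.

    Parameters
    ----------
    labels
        Distinct item identifiers; their order fixes the canonical pair
        order of patterns and the column order of score vectors.
    attribute_name
        The judged attribute (e.g. ``"abstraction"``), free text.
    intended_order
        Optional reference ordering (the "correct" ranking agreed by the
        study designers), a permutation of ``labels``.
    """

    labels: tuple[str, ...]
    attribute_name: str = ""
    intended_order: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "labels", tuple(str(x) for x in self.labels))
        if len(self.labels) < 2:
            raise ValueError("an ItemSet needs at least 2 items")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError(f"duplicate item labels in {self.labels!r}")
        if self.intended_order is not None:
            io = tuple(str(x) for x in self.intended_order)
            object.__setattr__(self, "intended_order", io)
            if sorted(io) != sorted(self.labels):
                raise ValueError(
                    "intended_order must be a permutation of the item labels"
                )

    @property
    def n_items(self) -> int:
        return len(self.labels)

    @property
    def n_pairs(self) -> int:
        j = len(self.labels)
        return j * (j - 1) // 2

    def index_of(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise InvalidRankingError(f"unknown item label {label!r}") from None


@dataclass(frozen=True)
class Ranking:
    """One subject's complete ordering of the items.

    Position 1 (index 0) holds the item judged highest on the attribute
    (e.g. most round, most realistic).
    """

    subject_id: str
    ordering: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "subject_id", str(self.subject_id))
        object.__setattr__(self, "ordering", tuple(str(x) for x in self.ordering))


#: A paired-comparison pattern: tuple of +1/-1 over canonical pairs.
PCPattern = tuple[int, ...]


def canonical_pairs(n_items: int) -> list[tuple[int, int]]:
    """Index pairs (j, k), j < k, in the canonical order (1,2),(1,3),...,(J-1,J)."""
    return [(j, k) for j in range(n_items) for k in range(j + 1, n_items)]


def _validate_ranking(ranking: Ranking, items: ItemSet) -> None:
    seen: set[str] = set()
    for label in ranking.ordering:
        if label not in items.labels:
            raise InvalidRankingError(
                f"subject {ranking.subject_id!r}: unknown item label {label!r}"
            )
        if label in seen:
            raise InvalidRankingError(
                f"subject {ranking.subject_id!r}: duplicate item label {label!r}"
            )
        seen.add(label)
    if len(ranking.ordering) != items.n_items:
        missing = sorted(set(items.labels) - seen)
        raise InvalidRankingError(
            f"subject {ranking.subject_id!r}: incomplete ranking, missing {missing!r}"
        )


def ranking_to_pattern(ranking: Ranking, items: ItemSet) -> PCPattern:
    """Convert a complete ranking into its signed paired-comparison pattern.

    Entry for pair (j, k) is +1 if item j precedes item k in the ordering
    (j is judged higher on the attribute) and -1 otherwise.  Patterns
    produced this way are transitive by construction.
    """
    _validate_ranking(ranking, items)
    pos = {label: i for i, label in enumerate(ranking.ordering)}
    return tuple(
        1 if pos[items.labels[j]] < pos[items.labels[k]] else -1
        for j, k in canonical_pairs(items.n_items)
    )


def _expected_score_multiset(n_items: int) -> list[int]:
    return [n_items - 1 - 2 * i for i in range(n_items)]


def _find_cycle(pattern: PCPattern, items: ItemSet) -> tuple[str, str, str] | None:
    """Return a violating triple (a, b, c) with a>b, b>c, c>a, if any."""
    j = items.n_items
    beats = np.zeros((j, j), dtype=bool)
    for (a, b), y in zip(canonical_pairs(j), pattern):
        if y == 1:
            beats[a, b] = True
        else:
            beats[b, a] = True
    for a, b, c in itertools.permutations(range(j), 3):
        if beats[a, b] and beats[b, c] and beats[c, a]:
            return items.labels[a], items.labels[b], items.labels[c]
    return None


def pattern_to_ranking(
    pattern: PCPattern, items: ItemSet, subject_id: str = ""
) -> Ranking:
    """Invert :func:`ranking_to_pattern` for a transitive pattern.

    Raises
    ------
    IntransitivePatternError
        If the pattern contains a preference cycle; the message names a
        violating triple.
    """
    if len(pattern) != items.n_pairs:
        raise ValueError(
            f"pattern length {len(pattern)} != {items.n_pairs} canonical pairs"
        )
    if any(y not in (-1, 1) for y in pattern):
        raise ValueError("pattern entries must be +1 or -1")
    scores = item_scores(pattern, items)
    # A transitive pattern's scores are exactly {J-1, J-3, ..., -(J-1)}:
    # ordering items by descending score then recovers the ranking.
    if sorted(scores, reverse=True) != _expected_score_multiset(items.n_items):
        triple = _find_cycle(pattern, items)
        raise IntransitivePatternError(
            f"intransitive pattern: cycle {triple[0]} > {triple[1]} > "
            f"{triple[2]} > {triple[0]}"
        )
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranking = Ranking(subject_id, tuple(items.labels[i] for i in order))
    if ranking_to_pattern(ranking, items) != tuple(pattern):  # pragma: no cover
        raise IntransitivePatternError("pattern does not round-trip")
    return ranking


def enumerate_patterns(n_items: int) -> list[PCPattern]:
    """All J! transitive patterns, lexicographic by generating permutation.

    The i-th pattern corresponds to the i-th permutation of the item
    *positions* in lexicographic order, so the first pattern is the
    identity ranking (all +1) and the last the full reversal (all -1).
    """
    if not 2 <= n_items <= MAX_ITEMS:
        raise ValueError(
            f"n_items must be between 2 and {MAX_ITEMS} (got {n_items}); "
            f"the pattern space has J! cells and is enumerated exhaustively"
        )
    pairs = canonical_pairs(n_items)
    out: list[PCPattern] = []
    for perm in itertools.permutations(range(n_items)):
        pos = {item: i for i, item in enumerate(perm)}
        out.append(tuple(1 if pos[j] < pos[k] else -1 for j, k in pairs))
    return out


def item_scores(pattern: PCPattern, items: ItemSet | int) -> tuple[int, ...]:
    """Signed pairwise win counts x_j = sum_{k != j} y_(jk) per item.

    For a pattern derived from a complete ranking the scores are the
    arithmetic sequence J-1, J-3, ..., -(J-1) along the ranking order,
    and they always sum to zero by antisymmetry.
    """
    n_items = items if isinstance(items, int) else items.n_items
    x = [0] * n_items
    for (j, k), y in zip(canonical_pairs(n_items), pattern):
        x[j] += y
        x[k] -= y
    return tuple(x)


def score_matrix(n_items: int) -> np.ndarray:
    """(J!, J) array of item scores for every pattern of enumerate_patterns."""
    return np.array(
        [item_scores(p, n_items) for p in enumerate_patterns(n_items)], dtype=float
    )


@dataclass
class PatternTable:
    """Counts of subjects per transitive pattern — the J!-cell multinomial.

    ``counts`` covers every pattern of :func:`enumerate_patterns` (zero for
    unobserved ones), keyed by the pattern tuple.  Observed tables hold
    integers; fractional counts (expected frequencies n*p(y)) are accepted
    so fits can be evaluated at exact expectations.
    """

    items: ItemSet
    counts: dict[PCPattern, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        full: dict[PCPattern, float] = {
            p: 0 for p in enumerate_patterns(self.items.n_items)
        }
        for p, c in self.counts.items():
            key = tuple(p)
            if key not in full:
                raise ValueError(f"not a transitive pattern: {key!r}")
            if c < 0:
                raise ValueError("pattern counts must be non-negative")
            full[key] = int(c) if float(c).is_integer() else float(c)
        self.counts = full

    @property
    def n(self) -> float:
        return sum(self.counts.values())

    def count_vector(self) -> np.ndarray:
        """Counts in enumeration order (length J!)."""
        return np.array(
            [self.counts[p] for p in enumerate_patterns(self.items.n_items)],
            dtype=float,
        )


def tabulate_patterns(rankings: Iterable[Ranking], items: ItemSet) -> PatternTable:
    """Tabulate rankings into pattern counts; unobserved patterns get 0."""
    counts: dict[PCPattern, int] = {}
    for r in rankings:
        p = ranking_to_pattern(r, items)
        counts[p] = counts.get(p, 0) + 1
    return PatternTable(items, counts)


def correct_ranking_rate(rankings: Sequence[Ranking], items: ItemSet) -> float:
    """Fraction of rankings equal to the intended reference order."""
    if items.intended_order is None:
        raise ValueError("ItemSet has no intended_order")
    rankings = list(rankings)
    if not rankings:
        raise ValueError("no rankings given")
    hits = sum(1 for r in rankings if r.ordering == items.intended_order)
    return hits / len(rankings)


def expanded_design_rows(n_subjects: int, n_items: int) -> int:
    """Row count of the subject-expanded pattern design: n * J!.

    Each subject contributes one block of all J! pattern cells in the
    loglinear formulation, so the design grows factorially in J.
    """
    return n_subjects * math.factorial(n_items)


# ---------------------------------------------------------------------------
# CSV I/O — header ``subject_id,pos1,...,posJ``; cells are item labels.

def read_rankings_csv(
    path, items: ItemSet, *, delimiter: str = ","
) -> list[Ranking]:
    """Read rankings from delimited text, validating every row strictly."""
    df = pd.read_csv(path, sep=delimiter, dtype=str, encoding="utf-8")
    expected = ["subject_id"] + [f"pos{i + 1}" for i in range(items.n_items)]
    if list(df.columns) != expected:
        raise ValueError(
            f"bad rankings header: expected {expected}, got {list(df.columns)}"
        )
    out: list[Ranking] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=2):
        vals = tuple(row)
        if any(pd.isna(v) for v in vals):
            raise InvalidRankingError(f"row {row_no}: missing cell")
        r = Ranking(vals[0], vals[1:])
        try:
            _validate_ranking(r, items)
        except InvalidRankingError as exc:
            raise InvalidRankingError(f"row {row_no}: {exc}") from None
        out.append(r)
    return out


def write_rankings_csv(path, rankings: Sequence[Ranking], items: ItemSet) -> None:
    df = pd.DataFrame(
        [[r.subject_id, *r.ordering] for r in rankings],
        columns=["subject_id"] + [f"pos{i + 1}" for i in range(items.n_items)],
    )
    df.to_csv(path, index=False, encoding="utf-8")
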