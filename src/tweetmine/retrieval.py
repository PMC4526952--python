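"""Corpus-wide application of a trained classifier.

Argmax category assignment, per-category frequency estimates (exact rational
fractions), and threshold-based retrieval of confident tweets per category —
the "sift by confidence" workflow: a high threshold returns a few confident
hits, a low threshold a large candidate pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np

from .labels import CategoryScheme

__all__ = [
    "ScoredTweet",
    "score_tweets",
    "assign_categories",
    "category_frequencies",
    "retrieve",
]


@dataclass(frozen=True)
class ScoredTweet:
    """One tweet's score vector with its argmax category."""

    id: str
    scores: tuple[float, ...]
    category: str
    score: float


def assign_categories(scores: np.ndarray, scheme: CategoryScheme) -> list[str]:
    """Argmax category per row; exact ties break by scheme order."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        return []
    if scores.shape[1] != len(scheme):
        raise ValueError(
            f"score matrix has {scores.shape[1]} columns, scheme has {len(scheme)}"
        )
    idx = np.argmax(scores, axis=1)  # first maximum wins
    return [scheme.names[i] for i in idx]


def score_tweets(
    ids: Sequence[str], scores: np.ndarray, scheme: CategoryScheme
) -> list[ScoredTweet]:
    scores = np.asarray(scores, dtype=float)
    if len(ids) != scores.shape[0]:
        raise ValueError("id count and score rows differ")
    cats = assign_categories(scores, scheme)
    return [
        ScoredTweet(str(i), tuple(row), cat, float(row.max()))
        for i, row, cat in zip(ids, scores, cats)
    ]


def category_frequencies(assignments: Sequence[str]) -> dict[str, Fraction]:
    """Per-category fraction of assignments as exact rationals (sum == 1)."""
    if not assignments:
        return {}
    counts: dict[str, int] = {}
    for cat in assignments:
        counts[cat] = counts.get(cat, 0) + 1
    total = len(assignments)
    return {cat: Fraction(c, total) for cat, c in sorted(counts.items())}


def retrieve(
    scored: Sequence[ScoredTweet],
    category: str,
    threshold: float,
    scheme: CategoryScheme,
) -> list[ScoredTweet]:
    """Tweets whose score for ``category`` meets the threshold (closed >=),
    sorted by that score descending, ties by id ascending."""
    if category not in scheme:
        raise ValueError(f"unknown category {category!r}")
    if not (0.0 <= threshold <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    j = scheme.index(category)
    hits = [s for s in scored if s.scores[j] >= threshold]
    hits.sort(key=lambda s: (-s.scores[j], s.id))
    return hits
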