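"""Bag-of-stems feature engineering.

A tweet becomes a fixed-length binary vector:

* one presence bit per vocabulary stem (class-informed bag of words: up to
  the top ``per_class_top`` stems of each labeled class, plus the top
  ``overall_top`` stems over the whole corpus),
* 10 one-hot tweet-length bins of width 10 characters (raw character length,
  clamped into the top bin at >= 100), and
* one URL-presence bit.

With a 1372-stem vocabulary this yields the 1383-dimensional layout used for
the antibiotic-stream classifier.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .ingest import Tweet
from .stemming import stem_tokens

__all__ = [
    "STOPWORDS",
    "tokenize",
    "stem",
    "Vocabulary",
    "build_vocabulary",
    "FeatureSpec",
    "FeatureMatrix",
    "featurize",
    "featurize_all",
]

#: Standard English stopword list (classic IR list; function words only).
STOPWORDS = frozenset(
    """a about above after again against all am an and any are aren as at be
    because been before being below between both but by can cannot could
    couldn did didn do does doesn doing don down during each few for from
    further had hadn has hasn have haven having he her here hers herself him
    himself his how i if in into is isn it its itself just ll me mightn more
    most mustn my myself needn no nor not now o of off on once only or other
    our ours ourselves out over own re s same shan she should shouldn so some
    such t than that the their theirs them themselves then there these they
    this those through to too under until up ve very was wasn we were weren
    what when where which while who whom why will with won would wouldn you
    your yours yourself yourselves""".split()
    # plus the tweet-dialect noise token: the bare retweet marker
    + ["rt"]
)

_URL_RE = re.compile(r"(?:https?://|www\.)\S+")
_MENTION_RE = re.compile(r"@\w+")
_SPLIT_RE = re.compile(r"[^a-z0-9]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, strip URLs/@-mentions/'#', split on non-alphanumerics,
    drop empties and stopwords."""
    low = _URL_RE.sub(" ", text.lower())
    low = _MENTION_RE.sub(" ", low)
    return [t for t in _SPLIT_RE.split(low) if t and t not in STOPWORDS]


def stem(tokens: Sequence[str]) -> list[str]:
    """English Snowball stems, element-wise."""
    return stem_tokens(list(tokens))


def text_stems(text: str) -> list[str]:
    """tokenize + stem in one step."""
    return stem(tokenize(text))


@dataclass(frozen=True)
class Vocabulary:
    """Frozen ordered stem list plus its construction record."""

    stems: tuple[str, ...]
    per_class_top: Mapping[str, tuple[str, ...]] = field(default_factory=dict)
    overall_top: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.stems)) != len(self.stems):
            raise ValueError("vocabulary stems must be unique")

    def __len__(self) -> int:
        return len(self.stems)

    @property
    def index(self) -> dict[str, int]:
        return {s: i for i, s in enumerate(self.stems)}


def _top_stems(counts: Counter, k: int) -> list[str]:
    # ties broken by stem ascending
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [s for s, _ in ranked[:k]]


def build_vocabulary(
    texts_by_class: Mapping[str, Sequence[str]],
    all_texts: Sequence[str],
    per_class_top: int = 50,
    overall_top: int = 1000,
) -> Vocabulary:
    """Class-informed vocabulary construction.

    ``texts_by_class`` maps category name -> that class's tweet texts, in
    category-scheme order (insertion order of the mapping defines the
    concatenation order).  Frequencies count stem occurrences; ties break by
    stem ascending; the final list is the per-class lists followed by the
    overall list, deduplicated in first-seen order.
    """
    if not any(len(v) for v in texts_by_class.values()):
        raise ValueError("labeled set is empty")
    per_class: dict[str, tuple[str, ...]] = {}
    ordered: list[str] = []
    seen: set[str] = set()
    for cls, texts in texts_by_class.items():
        counts: Counter = Counter()
        for text in texts:
            counts.update(text_stems(text))
        top = _top_stems(counts, per_class_top)
        per_class[cls] = tuple(top)
        for s in top:
            if s not in seen:
                seen.add(s)
                ordered.append(s)
    overall_counts: Counter = Counter()
    for text in all_texts:
        overall_counts.update(text_stems(text))
    overall = _top_stems(overall_counts, overall_top)
    for s in overall:
        if s not in seen:
            seen.add(s)
            ordered.append(s)
    return Vocabulary(tuple(ordered), per_class, tuple(overall))


@dataclass(frozen=True)
class FeatureSpec:
    """Frozen vector-space layout: bag stems + length bins + URL flag."""

    vocabulary: Vocabulary
    n_length_bins: int = 10
    bin_width: int = 10

    @property
    def total_dim(self) -> int:
        return len(self.vocabulary) + self.n_length_bins + 1

    def length_bin(self, n_chars: int) -> int:
        return min(n_chars // self.bin_width, self.n_length_bins - 1)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "format": "tweetmine-feature-spec",
            "version": 1,
            "stems": list(self.vocabulary.stems),
            "n_length_bins": self.n_length_bins,
            "bin_width": self.bin_width,
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "FeatureSpec":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "tweetmine-feature-spec":
            raise ValueError(f"{path} is not a feature-spec file")
        return cls(
            vocabulary=Vocabulary(tuple(payload["stems"])),
            n_length_bins=payload["n_length_bins"],
            bin_width=payload["bin_width"],
        )


@dataclass(frozen=True)
class FeatureMatrix:
    """Binary design matrix with a row-to-tweet-id map."""

    X: np.ndarray  # (n_tweets, total_dim), uint8
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.X.shape[0] != len(self.ids):
            raise ValueError("row count does not match id count")


def featurize(tweet: Tweet, spec: FeatureSpec) -> np.ndarray:
    """Binary feature vector for one tweet under a frozen spec.

    Bag bits fire on stem presence (>= 1 occurrence); exactly one length bin
    fires, computed from the raw character length of the stored text; the
    last bit mirrors ``has_url``. Out-of-vocabulary stems are ignored.
    """
    vec = np.zeros(spec.total_dim, dtype=np.uint8)
    index = spec.vocabulary.index
    for s in text_stems(tweet.text):
        j = index.get(s)
        if j is not None:
            vec[j] = 1
    vec[len(spec.vocabulary) + spec.length_bin(len(tweet.text))] = 1
    if tweet.has_url:
        vec[-1] = 1
    return vec


def featurize_all(tweets: Iterable[Tweet], spec: FeatureSpec) -> FeatureMatrix:
    tweets = list(tweets)
    X = np.zeros((len(tweets), spec.total_dim), dtype=np.uint8)
    for i, t in enumerate(tweets):
        X[i] = featurize(t, spec)
    return FeatureMatrix(X, tuple(t.id for t in tweets))
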