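"""Reading, filtering, and normalizing tweet records.

Tweets travel as JSON Lines in a small, documented dialect (a subset of the
Twitter API v1.1 payload)::

    {"id": str, "text": str, "created_at": ISO-8601 str,
     "user": {"screen_name": str},
     "entities": {"hashtags": [{"text": str}], "urls": [{"url": str}]},
     "retweeted_status": {"id": str}}          # optional

``created_at`` carries a UTC offset and is resolved to UTC on read; day
boundaries downstream are UTC midnights.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from datetime import date, datetime, timezone
from pathlib import Path
from typing import Iterable, Iterator, Optional, Sequence

logger = logging.getLogger(__name__)

_URL_RE = re.compile(r"https?://")


@dataclass(frozen=True)
class Tweet:
    """One post: identity, text, UTC timestamp, author, entities.

    ``retweet_of`` holds the source tweet id when the platform metadata
    identified a retweet; prefix-style retweets ("RT @user: ...") without
    metadata have ``retweet_of=None`` but still count as retweets
    (see :meth:`is_retweet`).
    """

    id: str
    text: str
    created_at: datetime
    screen_name: str
    hashtags: tuple[str, ...] = ()
    has_url: bool = False
    retweet_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.created_at.tzinfo is None:
            raise ValueError(f"tweet {self.id}: created_at must be timezone-aware")
        object.__setattr__(
            self, "created_at", self.created_at.astimezone(timezone.utc)
        )
        for tag in self.hashtags:
            if "#" in tag or any(c.isspace() for c in tag):
                raise ValueError(f"tweet {self.id}: malformed hashtag {tag!r}")

    @property
    def is_retweet(self) -> bool:
        return self.retweet_of is not None or self.text.startswith("RT @")

    @property
    def day(self) -> date:
        return self.created_at.date()


@dataclass(frozen=True)
class FilterConfig:
    """Keyword filter: retain on any include term, reject on any exclude pattern.

    Include terms match at token boundaries after lowercasing, where a term
    also matches a token it prefixes ("antibiotic" matches "antibiotics").
    Exclude patterns are plain substrings of the lowercased text, which is how
    a cashtag like "$abx" is caught.
    """

    include_terms: tuple[str, ...]
    exclude_patterns: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.include_terms:
            raise ValueError("include_terms must be non-empty for filtering runs")
        for t in (*self.include_terms, *self.exclude_patterns):
            if t != t.lower():
                raise ValueError(f"filter terms must be lowercase: {t!r}")


#: Representative default keyword list: the full collection vocabulary of the
#: original stream (89 antibiotic-related terms) is not public; users supply
#: their own lists for real runs.
DEFAULT_INCLUDE_TERMS = (
    "antibiotic",
    "antibiotics",
    "abx",
    "amoxicillin",
    "penicillin",
    "doxycycline",
    "cephalexin",
    "antiboitic",
)

_TOKEN_SPLIT_RE = re.compile(r"[^a-z0-9]+")


class TweetStore:
    """Ordered collection of tweets with a UTC-date index.

    Iteration order is ascending ``(created_at, id)``; ids are unique.
    """

    def __init__(self, tweets: Iterable[Tweet] = ()):
        ordered = sorted(tweets, key=lambda t: (t.created_at, t.id))
        seen: set[str] = set()
        for t in ordered:
            if t.id in seen:
                raise ValueError(f"duplicate tweet id {t.id!r}")
            seen.add(t.id)
        self._tweets: list[Tweet] = ordered
        self._by_id = {t.id: t for t in ordered}
        self._date_index: dict[date, list[str]] = {}
        for t in ordered:
            self._date_index.setdefault(t.day, []).append(t.id)

    def __len__(self) -> int:
        return len(self._tweets)

    def __iter__(self) -> Iterator[Tweet]:
        return iter(self._tweets)

    def __getitem__(self, tweet_id: str) -> Tweet:
        return self._by_id[tweet_id]

    def __contains__(self, tweet_id: str) -> bool:
        return tweet_id in self._by_id

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TweetStore) and self._tweets == other._tweets

    def ids_on(self, day: date) -> list[str]:
        return list(self._date_index.get(day, []))

    @property
    def date_span(self) -> tuple[date, date]:
        if not self._tweets:
            raise ValueError("empty store has no date span")
        return self._tweets[0].day, self._tweets[-1].day

    @property
    def dates(self) -> list[date]:
        return sorted(self._date_index)


def _tweet_from_record(rec: dict) -> Tweet:
    entities = rec.get("entities", {}) or {}
    hashtags = tuple(
        h["text"].lower() for h in entities.get("hashtags", []) or []
    )
    urls = entities.get("urls", []) or []
    text = rec["text"]
    has_url = bool(urls) or bool(_URL_RE.search(text))
    rt = rec.get("retweeted_status")
    return Tweet(
        id=str(rec["id"]),
        text=text,
        created_at=datetime.fromisoformat(rec["created_at"]),
        screen_name=rec["user"]["screen_name"],
        hashtags=hashtags,
        has_url=has_url,
        retweet_of=str(rt["id"]) if rt else None,
    )


def read_jsonl(path: str | Path) -> tuple[TweetStore, int]:
    """Read a JSON Lines corpus; returns ``(store, n_skipped)``.

    Malformed lines (bad JSON, missing required fields, unparseable
    timestamps) are counted and skipped rather than aborting the read.
    """
    path = Path(path)
    tweets: list[Tweet] = []
    skipped = 0
    with path.open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            try:
                tweets.append(_tweet_from_record(json.loads(line)))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError):
                skipped += 1
    if skipped:
        logger.warning("read_jsonl(%s): skipped %d malformed lines", path, skipped)
    if not tweets:
        logger.warning("read_jsonl(%s): no valid tweets", path)
    return TweetStore(tweets), skipped


def tweet_to_record(t: Tweet) -> dict:
    """Serialize one tweet into the JSON Lines dialect (stable field order)."""
    rec: dict = {
        "id": t.id,
        "text": t.text,
        "created_at": t.created_at.isoformat(),
        "user": {"screen_name": t.screen_name},
        "entities": {
            "hashtags": [{"text": h} for h in t.hashtags],
            "urls": [{"url": f"http://t.co/{t.id}"}] if t.has_url else [],
        },
    }
    if t.retweet_of is not None:
        rec["retweeted_status"] = {"id": t.retweet_of}
    return rec


def write_jsonl(store: TweetStore, path: str | Path) -> None:
    """Write a store as JSON Lines; ``read_jsonl`` round-trips losslessly."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for t in store:
            fh.write(json.dumps(tweet_to_record(t), ensure_ascii=False))
            fh.write("\n")


def _matches_include(text_lower: str, terms: Sequence[str]) -> bool:
    tokens = _TOKEN_SPLIT_RE.split(text_lower)
    return any(tok.startswith(term) for tok in tokens if tok for term in terms)


def apply_filter(store: TweetStore, cfg: FilterConfig) -> TweetStore:
    """Retain tweets matching an include term and no exclude pattern.

    Output preserves input order and is always a subsequence of the input;
    the operation is idempotent.
    """
    kept = []
    for t in store:
        low = t.text.lower()
        if not _matches_include(low, cfg.include_terms):
            continue
        if any(pat in low for pat in cfg.exclude_patterns):
            continue
        kept.append(t)
    return TweetStore(kept)
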