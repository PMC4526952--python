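"""Corpus characterization: the query-style summaries of the tweet stream.

Everything a Hive-style table scan answered for the original stream is
reproduced in memory: daily volumes with Z-score spike flagging, hashtag
usage tables, retweet structure, user concentration, and per-day frequent
stems.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import date, timedelta
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np
import pandas as pd

from .features import text_stems
from .ingest import TweetStore

__all__ = [
    "daily_counts",
    "zscore_spikes",
    "SpikeReport",
    "hashtag_stats",
    "HashtagTable",
    "user_concentration",
    "UserConcentration",
    "retweet_summary",
    "RetweetSummary",
    "top_stems_for_day",
    "render_percent",
]

_RT_PREFIX_RE = re.compile(r"^rt @\S+:?\s*")


def render_percent(numerator: float, denominator: float, decimals: int = 2) -> str:
    """Render a ratio as a percentage string with banker's rounding.

    round-half-even at the requested precision, e.g.
    ``render_percent(164973, 591091)`` -> ``"27.90%"``.
    """
    if denominator == 0:
        raise ZeroDivisionError("cannot render a percentage of zero")
    pct = Decimal(numerator) / Decimal(denominator) * 100
    q = Decimal(1).scaleb(-decimals)
    return f"{pct.quantize(q, rounding=ROUND_HALF_EVEN)}%"


def daily_counts(store: TweetStore) -> pd.Series:
    """Dense per-day tweet counts over the store's UTC date span.

    Days without tweets are zero-filled; the series sums to ``len(store)``.
    """
    if len(store) == 0:
        raise ValueError("daily_counts: empty store has no date span")
    first, last = store.date_span
    days = [first + timedelta(days=i) for i in range((last - first).days + 1)]
    counts = pd.Series(
        [len(store.ids_on(d)) for d in days], index=pd.Index(days, name="date"),
        name="count", dtype=int,
    )
    return counts


@dataclass(frozen=True)
class SpikeReport:
    """Per-day Z scores with the flagged high-activity subset."""

    table: pd.DataFrame  # columns: date, count, z_score
    flagged: tuple[date, ...]
    mean: float
    sd: float
    threshold: float


def zscore_spikes(series: pd.Series, threshold: float = 2.0) -> SpikeReport:
    """Flag days whose count sits more than ``threshold`` population SDs
    above the series mean.

    z_i = (c_i - mean) / SD with the population SD (divisor n), computed over
    the full series; a constant series (SD = 0) flags nothing.
    """
    if len(series) < 2:
        raise ValueError("zscore_spikes: need at least 2 days")
    counts = series.to_numpy(dtype=float)
    mean = float(counts.mean())
    sd = float(counts.std(ddof=0))
    if sd == 0.0:
        z = np.zeros_like(counts)
    else:
        z = (counts - mean) / sd
    table = pd.DataFrame(
        {"date": list(series.index), "count": series.to_numpy(), "z_score": z}
    )
    flagged = tuple(d for d, zi in zip(series.index, z) if sd > 0 and zi > threshold)
    return SpikeReport(table, flagged, mean, sd, threshold)


@dataclass(frozen=True)
class HashtagTable:
    """Hashtag usage counts, sorted by count desc then tag asc."""

    table: pd.DataFrame  # columns: tag, count, rel_freq
    n_distinct: int
    total_usages: int
    n_rare: int  # tags used fewer than rare_cutoff times
    rare_cutoff: int


def hashtag_stats(store: TweetStore, rare_cutoff: int = 100) -> HashtagTable:
    """Count every hashtag occurrence (a tag used twice in one tweet counts
    twice); relative frequency = count / total usages."""
    counts: dict[str, int] = {}
    for t in store:
        for tag in t.hashtags:
            counts[tag] = counts.get(tag, 0) + 1
    total = sum(counts.values())
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    table = pd.DataFrame(rows, columns=["tag", "count"])
    table["rel_freq"] = table["count"] / total if total else 0.0
    n_rare = sum(1 for _, c in counts.items() if c < rare_cutoff)
    return HashtagTable(table, len(counts), total, n_rare, rare_cutoff)


@dataclass(frozen=True)
class UserConcentration:
    """How much of the stream the most active accounts produced."""

    n_users: int
    n_heavy_users: int
    heavy_user_tweets: int
    heavy_user_share: float  # fraction of all tweets
    min_tweets: int


def user_concentration(store: TweetStore, min_tweets: int = 10) -> UserConcentration:
    """Share of all tweets contributed by users with >= ``min_tweets`` posts."""
    per_user: dict[str, int] = {}
    for t in store:
        per_user[t.screen_name] = per_user.get(t.screen_name, 0) + 1
    heavy = {u: c for u, c in per_user.items() if c >= min_tweets}
    heavy_total = sum(heavy.values())
    share = heavy_total / len(store) if len(store) else 0.0
    return UserConcentration(len(per_user), len(heavy), heavy_total, share, min_tweets)


@dataclass(frozen=True)
class RetweetSummary:
    """Retweet volume and per-source-message reach."""

    total: int
    n_retweets: int
    retweet_fraction: float
    tallies: pd.Series  # index: source id or normalized text; values: counts
    n_viral: int  # messages retweeted more than viral_cutoff times
    viral_cutoff: int


def normalize_text(text: str) -> str:
    """Normalization used to tally prefix-style retweets without source ids:
    strip the "RT @user:" lead-in, lowercase, collapse whitespace."""
    low = _RT_PREFIX_RE.sub("", text.lower())
    return " ".join(low.split())


def retweet_summary(store: TweetStore, viral_cutoff: int = 500) -> RetweetSummary:
    """Retweet fraction plus per-message tallies.

    Tallies key on the source tweet id when the retweet carries one, falling
    back to the normalized text for prefix-only retweets.
    """
    tallies: dict[str, int] = {}
    n_rt = 0
    for t in store:
        if not t.is_retweet:
            continue
        n_rt += 1
        key = t.retweet_of if t.retweet_of is not None else normalize_text(t.text)
        tallies[key] = tallies.get(key, 0) + 1
    total = len(store)
    frac = n_rt / total if total else 0.0
    series = pd.Series(tallies, dtype=int).sort_values(ascending=False)
    n_viral = int((series > viral_cutoff).sum()) if len(series) else 0
    return RetweetSummary(total, n_rt, frac, series, n_viral, viral_cutoff)


def top_stems_for_day(
    store: TweetStore, day: date, k: int, stopword_filtered: bool = True
) -> list[tuple[str, int]]:
    """Top-k stems on one UTC day, ties broken by stem ascending.

    Stems come from the feature stage's tokenize+stem (stopwords removed
    there), so the ranking matches what the classifier vocabulary sees.
    """
    first, last = store.date_span
    if not (first <= day <= last):
        raise ValueError(f"{day} outside the collection span {first}..{last}")
    counts: dict[str, int] = {}
    for tid in store.ids_on(day):
        for s in text_stems(store[tid].text):
            counts[s] = counts.get(s, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
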