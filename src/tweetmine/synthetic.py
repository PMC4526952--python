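"""Synthetic tweet-stream generator.

Emulates the statistical structure the pipeline assumes of a keyword-filtered
health-topic stream: Poisson daily volume with injected spike days,
class-conditional signature vocabulary over a fixed category scheme,
Zipf-distributed hashtag and user activity, a retweet fraction, per-class URL
probability, and simulated raters with controllable agreement.  Texts are
space-joined sequences of already-stemmed tokens, so the feature stage's
stemmer acts as the identity on synthetic text and generator correctness is
decoupled from stemmer behavior.

All randomness flows from one seeded generator: identical config + seed gives
a byte-identical serialized corpus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime, timedelta, timezone
from typing import Mapping, Optional

import numpy as np

from .ingest import Tweet, TweetStore
from .labels import DEFAULT_SCHEME, CategoryScheme, RaterTable

__all__ = [
    "GeneratorConfig",
    "ConfigError",
    "default_config",
    "generate_corpus",
    "generate_rater_table",
    "zipf_weights",
]


class ConfigError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


#: Default per-category signature stems (disjoint, Snowball fixed points).
DEFAULT_SIGNATURES: dict[str, tuple[str, ...]] = {
    "Advertisement": ("buy", "cheap", "deal", "promo", "pharmaci"),
    "Advice/Information": ("news", "studi", "research", "report", "develop"),
    "Animals": ("farm", "anim", "cattl", "livestock", "poultri"),
    "General use": ("doctor", "prescrib", "bronchit", "rest", "sick"),
    "Other": ("hospit", "word", "song", "random", "school"),
    "Resistance": ("resist", "superbug", "bacteria", "evolv", "combat"),
    "Side effects": ("stomach", "hurt", "itch", "nausea", "harm"),
    "Wanting/Needing": ("want", "need", "wait", "hope", "final"),
    "Misuse": ("mix", "alcohol", "skip", "leftov", "share"),
}

#: Empirical category prior of the adjudicated antibiotic labeled set
#: (counts 21, 88, 28, 38, 72, 132, 16, 15, 7 in scheme order, normalized
#: by their sum).
_PRIOR_COUNTS = (21, 88, 28, 38, 72, 132, 16, 15, 7)
DEFAULT_CATEGORY_PRIOR = tuple(c / sum(_PRIOR_COUNTS) for c in _PRIOR_COUNTS)

#: Per-class probability that a tweet carries a URL (link-heavy classes such
#: as advertisements and shared news stories sit high; personal anecdotes low).
DEFAULT_URL_PROB = (0.9, 0.7, 0.5, 0.2, 0.3, 0.6, 0.2, 0.1, 0.1)


def _default_background_vocab(n: int = 500) -> tuple[str, ...]:
    # "antibiot" leads: every tweet in a keyword-collected stream mentions the
    # topic; the rest is generic ranked filler.
    return ("antibiot",) + tuple(f"bg{i:03d}" for i in range(n - 1))


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic collection run.

    Defaults are a desk-scale stand-in for a one-season keyword stream:
    60 collection days at 100 tweets/day expected volume with a single x5
    spike day, the 9-category scheme with the labeled-set prior, a 27.9%
    retweet fraction and 0.386 hashtag usages per tweet.
    """

    n_days: int = 60
    base_rate: float = 100.0
    spike_days: tuple[tuple[int, float], ...] = ((30, 5.0),)
    n_categories: int = 9
    category_prior: tuple[float, ...] = DEFAULT_CATEGORY_PRIOR
    signature_vocab: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SIGNATURES)
    )
    background_vocab: tuple[str, ...] = field(
        default_factory=_default_background_vocab
    )
    background_zipf_exponent: float = 1.1
    tokens_per_tweet: tuple[int, int] = (6, 14)
    hashtag_prob: float = 0.386
    n_hashtags: int = 200
    hashtag_zipf_exponent: float = 1.3
    # ~0.55 distinct accounts per expected tweet, the ratio observed in the
    # antibiotic stream (327,930 users / 591,091 tweets); most accounts post
    # once while a Zipf head contributes disproportionately
    n_users: int = 3300
    user_zipf_exponent: float = 0.6
    retweet_prob: float = 0.279
    url_prob_per_category: tuple[float, ...] = DEFAULT_URL_PROB
    rater_agreement: float = 0.75
    signature_token_rate: float = 0.3
    start_date: str = "2014-05-27"
    seed: int = 0

    def scheme(self) -> CategoryScheme:
        names = tuple(self.signature_vocab.keys())
        return CategoryScheme(names)

    def validate(self) -> None:
        if self.n_days < 0:
            raise ConfigError("n_days: must be >= 0")
        if self.base_rate < 0:
            raise ConfigError("base_rate: must be >= 0")
        for day, mult in self.spike_days:
            if not (0 <= day < self.n_days):
                raise ConfigError(f"spike_days: day_index {day} outside [0, {self.n_days})")
            if mult < 0:
                raise ConfigError("spike_days: rate_multiplier must be >= 0")
        if len(self.signature_vocab) != self.n_categories:
            raise ConfigError(
                f"signature_vocab: {len(self.signature_vocab)} categories, "
                f"n_categories={self.n_categories}"
            )
        if len(self.category_prior) != self.n_categories:
            raise ConfigError("category_prior: length must equal n_categories")
        if abs(sum(self.category_prior) - 1.0) > 1e-9:
            raise ConfigError("category_prior: must sum to 1 within 1e-9")
        if any(p < 0 or p > 1 for p in self.category_prior):
            raise ConfigError("category_prior: probabilities must lie in [0, 1]")
        all_sigs = [s for sigs in self.signature_vocab.values() for s in sigs]
        if len(set(all_sigs)) != len(all_sigs):
            raise ConfigError("signature_vocab: per-category lists must be disjoint")
        if set(all_sigs) & set(self.background_vocab):
            raise ConfigError("background_vocab: overlaps signature_vocab")
        lo, hi = self.tokens_per_tweet
        if not (1 <= lo <= hi):
            raise ConfigError("tokens_per_tweet: need 1 <= min <= max")
        for name in ("hashtag_prob", "retweet_prob", "rater_agreement",
                     "signature_token_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name}: must lie in [0, 1]")
        if len(self.url_prob_per_category) != self.n_categories:
            raise ConfigError("url_prob_per_category: length must equal n_categories")
        if any(p < 0 or p > 1 for p in self.url_prob_per_category):
            raise ConfigError("url_prob_per_category: probabilities must lie in [0, 1]")
        for name in ("background_zipf_exponent", "hashtag_zipf_exponent",
                     "user_zipf_exponent"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name}: must be > 0")
        if self.n_users < 1:
            raise ConfigError("n_users: must be >= 1")
        if self.n_hashtags < 1:
            raise ConfigError("n_hashtags: must be >= 1")


def default_config(**overrides) -> GeneratorConfig:
    """The study conditions, with selective overrides."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def zipf_weights(n: int, exponent: float) -> np.ndarray:
    """Exactly normalized rank^(-s) weights over a finite vocabulary of n items."""
    ranks = np.arange(1, n + 1, dtype=float)
    w = ranks ** (-exponent)
    return w / w.sum()


def generate_corpus(config: GeneratorConfig) -> tuple[TweetStore, dict[str, str]]:
    """Generate a corpus and its true-label map.

    Each day's tweet count is Poisson(base_rate x multiplier); each original
    tweet draws its category from the prior and its text as >= 1 signature
    stem of that category plus Zipf background stems, optionally a hashtag
    token ("#tag") and a URL flag.  Retweets (probability ``retweet_prob``,
    given an earlier original exists) copy an earlier original verbatim with
    an "RT @<user>: " prefix and set the retweet linkage.  The label map
    records every tweet's generating category (retweets inherit the source's).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scheme = config.scheme()
    categories = list(scheme.names)
    sig_lists = [list(config.signature_vocab[c]) for c in categories]

    multipliers = np.ones(config.n_days)
    for day, mult in config.spike_days:
        multipliers[day] = mult
    day_counts = rng.poisson(config.base_rate * multipliers) if config.n_days else []

    bg = list(config.background_vocab)
    bg_w = zipf_weights(len(bg), config.background_zipf_exponent)
    tag_w = zipf_weights(config.n_hashtags, config.hashtag_zipf_exponent)
    user_w = zipf_weights(config.n_users, config.user_zipf_exponent)
    start = datetime.fromisoformat(config.start_date).replace(tzinfo=timezone.utc)

    tweets: list[Tweet] = []
    labels: dict[str, str] = {}
    originals: list[int] = []  # indices into tweets
    counter = 0
    lo, hi = config.tokens_per_tweet
    for day_idx in range(config.n_days):
        n_today = int(day_counts[day_idx])
        # spread timestamps uniformly over the UTC day, in increasing order
        secs = np.sort(rng.uniform(0, 86400, size=n_today))
        for s in secs:
            tid = f"t{counter:07d}"
            counter += 1
            ts = start + timedelta(days=day_idx, seconds=float(s))
            user = f"user{rng.choice(config.n_users, p=user_w):05d}"
            if originals and rng.random() < config.retweet_prob:
                src = tweets[originals[int(rng.integers(len(originals)))]]
                tweet = Tweet(
                    id=tid,
                    text=f"RT @{src.screen_name}: {src.text}",
                    created_at=ts,
                    screen_name=user,
                    hashtags=src.hashtags,
                    has_url=src.has_url,
                    retweet_of=src.id,
                )
                labels[tid] = labels[src.id]
            else:
                ci = int(rng.choice(config.n_categories, p=np.asarray(config.category_prior)))
                cat = categories[ci]
                n_tok = int(rng.integers(lo, hi + 1))
                sigs = sig_lists[ci]
                tokens = [sigs[int(rng.integers(len(sigs)))]]
                for _ in range(n_tok - 1):
                    if rng.random() < config.signature_token_rate:
                        tokens.append(sigs[int(rng.integers(len(sigs)))])
                    else:
                        tokens.append(bg[int(rng.choice(len(bg), p=bg_w))])
                hashtags: tuple[str, ...] = ()
                if rng.random() < config.hashtag_prob:
                    tag = f"tag{int(rng.choice(config.n_hashtags, p=tag_w)):03d}"
                    tokens.append(f"#{tag}")
                    hashtags = (tag,)
                tweet = Tweet(
                    id=tid,
                    text=" ".join(tokens),
                    created_at=ts,
                    screen_name=user,
                    hashtags=hashtags,
                    has_url=bool(rng.random() < config.url_prob_per_category[ci]),
                    retweet_of=None,
                )
                originals.append(len(tweets))
                labels[tid] = cat
            tweets.append(tweet)
    return TweetStore(tweets), labels


def generate_rater_table(
    true_labels: Mapping[str, str],
    n_raters: int = 3,
    agreement: float = 0.75,
    seed: int = 0,
    scheme: Optional[CategoryScheme] = None,
) -> RaterTable:
    """Simulate independent raters over a true-label map.

    Each rater reports the item's true category with probability
    ``agreement`` and otherwise a uniformly random *other* category.
    """
    if not true_labels:
        raise ValueError("true_labels is empty")
    if n_raters < 2:
        raise ValueError("need at least 2 raters")
    if not (0.0 <= agreement <= 1.0):
        raise ValueError("agreement must lie in [0, 1]")
    if scheme is None:
        scheme = DEFAULT_SCHEME
    rng = np.random.default_rng(seed)
    names = list(scheme.names)
    votes: dict[str, dict[str, str]] = {}
    for item in true_labels:
        true_cat = true_labels[item]
        cell: dict[str, str] = {}
        for r in range(n_raters):
            if rng.random() < agreement:
                cell[f"rater{r}"] = true_cat
            else:
                others = [c for c in names if c != true_cat]
                cell[f"rater{r}"] = others[int(rng.integers(len(others)))]
        votes[item] = cell
    return RaterTable(votes)
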