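"""Rater adjudication and inter-rater agreement.

Several raters independently assign each tweet to one category of a fixed
scheme. An item enters the labeled set when at least ``min_agree`` raters
agree (2-of-3 majority by default); items with no such category are dropped.
Agreement across the whole table is quantified with Fleiss' kappa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CategoryScheme",
    "DEFAULT_SCHEME",
    "RaterTable",
    "LabeledSet",
    "adjudicate",
    "fleiss_kappa",
]


@dataclass(frozen=True)
class CategoryScheme:
    """Ordered, unique category names; order fixes output-unit order."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names) or not all(self.names):
            raise ValueError("category names must be unique and non-empty")

    def __len__(self) -> int:
        return len(self.names)

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def index(self, name: str) -> int:
        return self.names.index(name)


#: The 9-category topic scheme for antibiotic-related tweets.
DEFAULT_SCHEME = CategoryScheme(
    (
        "Advertisement",
        "Advice/Information",
        "Animals",
        "General use",
        "Other",
        "Resistance",
        "Side effects",
        "Wanting/Needing",
        "Misuse",
    )
)


class RaterTable:
    """Complete item x rater category assignments.

    Every item must carry a vote from every rater (Fleiss' formula assumes a
    constant number of ratings per item); incomplete items are rejected.
    """

    def __init__(self, votes: Mapping[str, Mapping[str, str]]):
        if not votes:
            raise ValueError("rater table is empty")
        raters = sorted(next(iter(votes.values())).keys())
        if len(raters) < 2:
            raise ValueError("at least 2 raters required")
        for item, cell in votes.items():
            if sorted(cell.keys()) != raters:
                raise ValueError(f"item {item!r} is missing rater votes")
        self._votes = {i: dict(votes[i]) for i in votes}
        self._raters = raters

    @property
    def items(self) -> list[str]:
        return list(self._votes)

    @property
    def raters(self) -> list[str]:
        return list(self._raters)

    @property
    def n_raters(self) -> int:
        return len(self._raters)

    def votes_for(self, item: str) -> dict[str, str]:
        return dict(self._votes[item])

    def categories_used(self) -> list[str]:
        return sorted({c for cell in self._votes.values() for c in cell.values()})

    def to_frame(self) -> pd.DataFrame:
        """Long format: (tweet_id, rater_id, category)."""
        rows = [
            (item, rater, cat)
            for item, cell in self._votes.items()
            for rater, cat in sorted(cell.items())
        ]
        return pd.DataFrame(rows, columns=["tweet_id", "rater_id", "category"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RaterTable":
        votes: dict[str, dict[str, str]] = {}
        for tweet_id, rater_id, category in df[
            ["tweet_id", "rater_id", "category"]
        ].itertuples(index=False):
            votes.setdefault(str(tweet_id), {})[str(rater_id)] = str(category)
        return cls(votes)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RaterTable":
        return cls.from_frame(pd.read_csv(path, dtype=str))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def count_matrix(self, scheme: CategoryScheme) -> pd.DataFrame:
        """Item x category vote counts (rows sum to n_raters)."""
        items = self.items
        data = [[0] * len(scheme) for _ in items]
        for r, item in enumerate(items):
            for cat in self._votes[item].values():
                if cat not in scheme:
                    raise ValueError(f"category {cat!r} not in scheme")
                data[r][scheme.index(cat)] += 1
        return pd.DataFrame(data, index=items, columns=list(scheme.names))


@dataclass(frozen=True)
class LabeledSet:
    """Adjudicated labels with provenance and the dropped-item list."""

    labels: Mapping[str, str]
    dropped: tuple[str, ...]
    provenance: Mapping[str, Mapping[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)


def adjudicate(table: RaterTable, min_agree: int = 2) -> LabeledSet:
    """Label items where >= ``min_agree`` raters agree; drop the rest.

    With 3 raters and ``min_agree=2`` the winning category is unique whenever
    one exists.
    """
    if min_agree < 2:
        raise ValueError("min_agree must be >= 2")
    if min_agree > table.n_raters:
        raise ValueError(
            f"min_agree={min_agree} exceeds the number of raters ({table.n_raters})"
        )
    labels: dict[str, str] = {}
    dropped: list[str] = []
    for item in table.items:
        cell = table.votes_for(item)
        counts: dict[str, int] = {}
        for cat in cell.values():
            counts[cat] = counts.get(cat, 0) + 1
        winners = sorted(c for c, k in counts.items() if k >= min_agree)
        if winners:
            # ties possible only when min_agree <= n_raters/2; break by name
            labels[item] = winners[0]
        else:
            dropped.append(item)
    return LabeledSet(labels, tuple(dropped), {i: table.votes_for(i) for i in table.items})


def fleiss_kappa(table: RaterTable, scheme: Optional[CategoryScheme] = None) -> float:
    """Fleiss' kappa over a complete rater table.

    kappa = (P_bar - Pe_bar) / (1 - Pe_bar) with per-item agreement
    P_i = (sum_j n_ij^2 - n) / (n (n - 1)) and chance agreement
    Pe_bar = sum_j p_j^2, p_j the overall share of votes on category j.
    Degenerate case: when every vote lands on one category Pe_bar = 1 and the
    ratio is undefined; 1.0 is returned (perfect agreement) with a warning.
    """
    if scheme is None:
        scheme = CategoryScheme(tuple(table.categories_used()))
    counts = table.count_matrix(scheme).to_numpy()
    n_items, _ = counts.shape
    n = table.n_raters
    if n_items < 2:
        raise ValueError("Fleiss' kappa needs at least 2 items")
    p_i = (counts.astype(float) ** 2).sum(axis=1)
    p_i = (p_i - n) / (n * (n - 1))
    p_bar = p_i.mean()
    p_j = counts.sum(axis=0) / (n_items * n)
    pe_bar = float((p_j**2).sum())
    if pe_bar >= 1.0 - 1e-12:
        logger.warning("fleiss_kappa: all votes on one category; returning 1.0")
        return 1.0
    return float((p_bar - pe_bar) / (1.0 - pe_bar))
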