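"""Paired categorical ratings from two raters and their agreement summary.

Two raters independently classify the same ``N`` cases into one of ``n``
mutually exclusive categories.  Everything downstream — Cohen's kappa,
Gwet's AC1 and the maximum-likelihood kappa — is a function of the
case-level agreement indicators and of the per-category marginal rates,
both of which are derived here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Sequence

import numpy as np

from .exceptions import EmptyRatingsError, KappamlError, UnknownLabelError

logger = logging.getLogger(__name__)

Label = Hashable

#: Cell values treated as a missing rating when cleaning raw input.
MISSING_SENTINELS = frozenset({None, "", "NA", "N/A", "NaN", "nan"})


def _is_missing(value: object) -> bool:
    if value in MISSING_SENTINELS:
        return True
    return isinstance(value, float) and np.isnan(value)


def drop_missing_pairs(
    ratings_a: Iterable[Label], ratings_b: Iterable[Label]
) -> tuple[list[Label], list[Label], int]:
    """Drop every case where either rating is missing.

    Returns the cleaned pair of lists and the number of dropped cases.
    All agreement statistics assume both ratings are present, so missing
    cells are removed pairwise before a :class:`PairedRatings` is built.
    """
    a_clean: list[Label] = []
    b_clean: list[Label] = []
    dropped = 0
    for a, b in zip(ratings_a, ratings_b, strict=True):
        if _is_missing(a) or _is_missing(b):
            dropped += 1
        else:
            a_clean.append(a)
            b_clean.append(b)
    if dropped:
        logger.warning("dropped %d case(s) with a missing rating", dropped)
    return a_clean, b_clean, dropped


@dataclass(frozen=True)
class PairedRatings:
    """Ratings of the same N cases by two raters.

    Parameters
    ----------
    ratings_a, ratings_b
        Category labels assigned by each rater, one entry per case.
    categories
        Ordered tuple of the n >= 2 distinct category labels.  Inferred as
        the sorted union of observed labels when not supplied; supply it
        explicitly whenever a category may be unobserved in the data,
        because the multi-category ML formulas depend on n.
    n_dropped
        Number of cases removed because a rating was missing (bookkeeping
        only; does not participate in equality).
    """

    ratings_a: tuple[Label, ...]
    ratings_b: tuple[Label, ...]
    categories: tuple[Label, ...]
    n_dropped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if len(self.ratings_a) != len(self.ratings_b):
            raise KappamlError(
                f"raters scored different numbers of cases: "
                f"{len(self.ratings_a)} vs {len(self.ratings_b)}"
            )
        if len(self.ratings_a) == 0:
            raise EmptyRatingsError("no cases to summarize")
        if len(set(self.categories)) != len(self.categories):
            raise KappamlError("categories contain duplicates")
        if len(self.categories) < 2:
            raise KappamlError(
                f"need at least 2 categories, got {len(self.categories)}; "
                "pass categories explicitly if some are unobserved"
            )
        members = set(self.categories)
        for name, seq in (("rater A", self.ratings_a), ("rater B", self.ratings_b)):
            for label in seq:
                if label not in members:
                    raise UnknownLabelError(
                        f"{name} used label {label!r} which is not in "
                        f"categories {list(self.categories)}"
                    )

    @classmethod
    def from_sequences(
        cls,
        ratings_a: Sequence[Label],
        ratings_b: Sequence[Label],
        categories: Sequence[Label] | None = None,
        *,
        drop_missing: bool = False,
    ) -> "PairedRatings":
        """Build a :class:`PairedRatings`, optionally cleaning missing cells.

        When ``categories`` is omitted it is inferred as the sorted union
        of the observed labels.
        """
        dropped = 0
        if drop_missing:
            ratings_a, ratings_b, dropped = drop_missing_pairs(ratings_a, ratings_b)
        if categories is None:
            try:
                categories = tuple(sorted(set(ratings_a) | set(ratings_b)))
            except TypeError:  # unorderable mixed labels
                categories = tuple(dict.fromkeys(list(ratings_a) + list(ratings_b)))
        return cls(tuple(ratings_a), tuple(ratings_b), tuple(categories), dropped)

    @property
    def n_cases(self) -> int:
        return len(self.ratings_a)

    @property
    def n_categories(self) -> int:
        return len(self.categories)

    def codes(self) -> tuple[np.ndarray, np.ndarray]:
        """Integer-encoded ratings (index into ``categories``)."""
        index = {label: k for k, label in enumerate(self.categories)}
        a = np.fromiter((index[x] for x in self.ratings_a), dtype=np.int64)
        b = np.fromiter((index[x] for x in self.ratings_b), dtype=np.int64)
        return a, b


@dataclass(frozen=True)
class AgreementSummary:
    """Counts and rates of observed agreement between the two raters."""

    n_cases: int
    n_agree: int
    n_disagree: int
    p_agree: float
    p_disagree: float

    @classmethod
    def from_counts(cls, n_agree: int, n_disagree: int) -> "AgreementSummary":
        n = n_agree + n_disagree
        if n <= 0:
            raise EmptyRatingsError("no cases to summarize")
        return cls(n, n_agree, n_disagree, n_agree / n, n_disagree / n)


@dataclass(frozen=True)
class MarginalRates:
    """Per-rater rates for one designated category and their average."""

    p_a_plus: float
    p_b_plus: float

    @property
    def pi_plus(self) -> float:
        return 0.5 * (self.p_a_plus + self.p_b_plus)


def summarize_agreement(ratings: PairedRatings) -> AgreementSummary:
    """Count agreements and disagreements case by case.

    ``Na`` is the number of cases where the raters gave the same label,
    ``Nd = N - Na``, ``Pa = Na/N`` and ``Pd = Nd/N``.
    """
    n_agree = sum(a == b for a, b in zip(ratings.ratings_a, ratings.ratings_b))
    return AgreementSummary.from_counts(n_agree, ratings.n_cases - n_agree)


def marginal_rates(ratings: PairedRatings, category: Label | None = None) -> MarginalRates:
    """Rates at which each rater assigns cases to ``category``.

    Defaults to the first category.  The average rate pi_plus feeds Gwet's
    chance-agreement formula 2*pi*(1-pi), which is symmetric under
    pi -> 1-pi, so for binary ratings the choice of category is immaterial.
    """
    if category is None:
        category = ratings.categories[0]
    if category not in ratings.categories:
        raise UnknownLabelError(f"{category!r} is not in categories")
    n = ratings.n_cases
    p_a = sum(x == category for x in ratings.ratings_a) / n
    p_b = sum(x == category for x in ratings.ratings_b) / n
    return MarginalRates(p_a, p_b)


def category_counts(ratings: PairedRatings) -> tuple[np.ndarray, np.ndarray]:
    """Per-category assignment counts for each rater, in category order."""
    a, b = ratings.codes()
    n = ratings.n_categories
    return np.bincount(a, minlength=n), np.bincount(b, minlength=n)
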