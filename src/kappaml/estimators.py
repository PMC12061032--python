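"""Point estimators of chance-corrected agreement: Cohen, Gwet AC1, ML.

All three fit the template kappa = (Pa - Pc)/(1 - Pc) and differ only in
how they estimate the chance-agreement probability Pc:

* Cohen — "always guess": Pc is the sum over categories of the product of
  the raters' marginal rates.
* Gwet (AC1, binary) — variance-ratio heuristic: Pc = 2*pi*(1-pi) where pi
  is the raters' average rate for either category.
* ML — exact maximum likelihood under the occasional-guessing model: the
  estimated guessing fraction is r_ML = (Nd/N) * n/(n-1), hence
  Pc = r_ML/n, which for binary ratings is simply the observed
  disagreement rate Nd/N.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import DegenerateMarginalsError, UnsupportedCategoriesError
from .ratings import (
    PairedRatings,
    category_counts,
    marginal_rates,
    summarize_agreement,
)

__all__ = ["KappaEstimate", "cohen_kappa", "gwet_kappa", "ml_kappa"]

_TOL = 1e-12


@dataclass(frozen=True)
class KappaEstimate:
    """A chance-corrected agreement estimate.

    ``r_hat`` is the estimated guessing fraction where the estimator has
    one (ML and Gwet); ``model_violation`` is set when the raw ML estimate
    exceeds 1, i.e. the observed disagreement rate is larger than the model
    can produce even with all cases hard.
    """

    estimator: str
    kappa: float
    p_chance: float
    n_categories: int
    r_hat: float | None = None
    model_violation: bool = False

    def to_dict(self) -> dict:
        return asdict(self)


def _kappa(p_agree: float, p_chance: float) -> float:
    denom = 1.0 - p_chance
    if abs(denom) < _TOL:
        return float("-inf") if p_agree < 1.0 else float("nan")
    return (p_agree - p_chance) / denom


def cohen_kappa(ratings: PairedRatings) -> KappaEstimate:
    """Cohen's kappa with the marginal-product chance model.

    Pc = sum_k pA_k * pB_k where pA_k, pB_k are each rater's observed
    rates for category k.  Raises :class:`DegenerateMarginalsError` when
    both raters put every case in the same single category (Pc = 1, kappa
    undefined).
    """
    summary = summarize_agreement(ratings)
    counts_a, counts_b = category_counts(ratings)
    n = summary.n_cases
    p_chance = float(np.dot(counts_a / n, counts_b / n))
    if p_chance >= 1.0 - _TOL:
        raise DegenerateMarginalsError(
            "both raters assigned every case to one category; chance "
            "agreement is 1 and Cohen's kappa is undefined"
        )
    return KappaEstimate(
        estimator="cohen",
        kappa=_kappa(summary.p_agree, p_chance),
        p_chance=p_chance,
        n_categories=ratings.n_categories,
    )


def gwet_kappa(ratings: PairedRatings) -> KappaEstimate:
    """Gwet's AC1 for binary ratings.

    The guessing fraction is estimated as the ratio of the observed rating
    variance pi*(1-pi) to its maximum 1/4, giving r = 4*pi*(1-pi) and
    Pc = 2*pi*(1-pi); pi is the average of the two raters' rates for
    either category (the formula is symmetric in the category choice).
    """
    if ratings.n_categories != 2:
        raise UnsupportedCategoriesError(
            f"Gwet's AC1 chance model is defined here for 2 categories, "
            f"got {ratings.n_categories}"
        )
    summary = summarize_agreement(ratings)
    pi = marginal_rates(ratings).pi_plus
    p_chance = 2.0 * pi * (1.0 - pi)  # <= 1/2, so 1 - Pc >= 1/2
    return KappaEstimate(
        estimator="gwet",
        kappa=_kappa(summary.p_agree, p_chance),
        p_chance=p_chance,
        n_categories=2,
        r_hat=4.0 * pi * (1.0 - pi),
    )


def ml_kappa(ratings: PairedRatings, *, clamp: bool = False) -> KappaEstimate:
    """Maximum-likelihood kappa under the occasional-guessing model.

    The guessing fraction maximizing the likelihood of the observed
    agreement pattern is ``r_ML = (Nd/N) * n/(n-1)`` (twice the observed
    disagreement rate for binary ratings); the chance agreement is
    ``Pc = r_ML/n``.  The resulting kappa equals the theoretical curve
    (1 - r_ML)/(1 - r_ML/n) exactly.

    When the observed disagreement rate exceeds (n-1)/n the raw ``r_ML``
    is greater than 1, outside the model's support.  By default the
    unclamped (negative) kappa is reported with ``model_violation=True``
    and a warning — data this discordant contradict the model, and
    silently hiding that would be worse.  With ``clamp=True`` the estimate
    is truncated to the boundary r = 1, i.e. kappa = 0.
    """
    summary = summarize_agreement(ratings)
    n = ratings.n_categories
    raw_r = summary.p_disagree * n / (n - 1)
    violation = raw_r > 1.0
    if violation:
        warnings.warn(
            f"observed disagreement rate {summary.p_disagree:.3f} exceeds the "
            f"occasional-guessing maximum {(n - 1) / n:.3f} for n={n}; the "
            "model cannot have generated these data",
            stacklevel=2,
        )
    if violation and clamp:
        r_hat = 1.0
    else:
        r_hat = raw_r
    p_chance = r_hat / n
    if violation and clamp:
        kappa = 0.0
    else:
        # identical to (1 - r_hat)/(1 - r_hat/n): Pa = 1 - r_hat*(n-1)/n by
        # construction of r_hat
        kappa = _kappa(summary.p_agree, p_chance)
    return KappaEstimate(
        estimator="ml",
        kappa=kappa,
        p_chance=p_chance,
        n_categories=n,
        r_hat=r_hat,
        model_violation=bool(violation),
    )


ESTIMATORS = {"cohen": cohen_kappa, "gwet": gwet_kappa, "ml": ml_kappa}


# ---------------------------------------------------------------------------
# Vectorized kernels over integer-coded rating matrices, shared by the
# bootstrap and the Monte-Carlo sweep.  Rows are datasets (resamples or
# replicates), columns are cases.


def _vec_ml_kappa(codes_a: np.ndarray, codes_b: np.ndarray, n: int) -> np.ndarray:
    p_d = np.mean(codes_a != codes_b, axis=-1)
    raw_r = p_d * n / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (1.0 - raw_r) / (1.0 - raw_r / n)


def _vec_ml_r(codes_a: np.ndarray, codes_b: np.ndarray, n: int) -> np.ndarray:
    return np.mean(codes_a != codes_b, axis=-1) * n / (n - 1)


def _vec_gwet_terms(
    codes_a: np.ndarray, codes_b: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(kappa, p_chance) of binary AC1 per row; category 0 plays '+'."""
    p_a = np.mean(codes_a == 0, axis=-1)
    p_b = np.mean(codes_b == 0, axis=-1)
    pi = 0.5 * (p_a + p_b)
    p_chance = 2.0 * pi * (1.0 - pi)
    pa = np.mean(codes_a == codes_b, axis=-1)
    return (pa - p_chance) / (1.0 - p_chance), p_chance


def _vec_cohen_kappa(codes_a: np.ndarray, codes_b: np.ndarray, n: int) -> np.ndarray:
    pa = np.mean(codes_a == codes_b, axis=-1)
    p_chance = np.zeros_like(pa)
    for k in range(n):
        p_chance += np.mean(codes_a == k, axis=-1) * np.mean(codes_b == k, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = (pa - p_chance) / (1.0 - p_chance)
    # degenerate marginals with full agreement: conventionally kappa = 1
    kappa = np.where((p_chance >= 1.0 - _TOL) & (pa >= 1.0 - _TOL), 1.0, kappa)
    return kappa
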