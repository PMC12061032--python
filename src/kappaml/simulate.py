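"""Generative simulator for the occasional-guessing model.

Each case is independently *hard* with probability ``r`` — both raters
guess uniformly over the ``n`` categories, independently of each other —
or *easy* with probability ``1 - r``, in which case a true label is drawn
from the easy-case category distribution ``q`` and both raters report it.
Hard cases carry no true label: the model only ever conditions on the
agreement indicator, for which none is needed.

All draws come from one ``numpy.random.Generator`` seeded per call, so a
given ``(params, n_cases, seed)`` always reproduces the same ratings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .exceptions import KappamlError
from .model import TheoreticalValues
from .ratings import PairedRatings

__all__ = [
    "OGModelParams",
    "simulate_ratings",
    "simulate_rating_blocks",
    "simulate_disagreement_counts",
    "theoretical_values",
]


def _default_labels(n: int) -> tuple[str, ...]:
    return ("+", "-") if n == 2 else tuple(f"c{k + 1}" for k in range(n))


@dataclass(frozen=True)
class OGModelParams:
    """Parameters of the occasional-guessing model.

    Parameters
    ----------
    r
        Fraction of hard cases, in [0, 1].
    q
        Easy-case category distribution.  For binary ratings a scalar q is
        the proportion of easy cases whose true label is the first
        category ("+"), i.e. the distribution (q, 1-q).  For n > 2 supply
        a probability vector of length n.
    n_categories
        Number of rating categories, >= 2.
    categories
        Labels used for generated ratings; defaults to ("+", "-") for the
        binary model and ("c1", ..., "cn") otherwise.
    """

    r: float
    q: float | Sequence[float] = 0.5
    n_categories: int = 2
    categories: tuple | None = field(default=None)

    def __post_init__(self) -> None:
        if not (0.0 <= self.r <= 1.0):
            raise KappamlError(f"r must be in [0, 1], got {self.r}")
        n = self.n_categories
        if int(n) != n or n < 2:
            raise KappamlError(f"n_categories must be an integer >= 2, got {n}")
        qv = self.q_vector  # validates
        if len(qv) != n:
            raise KappamlError(
                f"q has length {len(qv)} but there are {n} categories"
            )
        if self.categories is not None and len(self.categories) != n:
            raise KappamlError("categories length must equal n_categories")

    @property
    def q_vector(self) -> np.ndarray:
        if np.isscalar(self.q):
            if self.n_categories != 2:
                raise KappamlError(
                    "scalar q is only meaningful for the binary model; "
                    "pass a probability vector for n > 2"
                )
            q = float(self.q)
            if not (0.0 <= q <= 1.0):
                raise KappamlError(f"q must be in [0, 1], got {q}")
            return np.array([q, 1.0 - q])
        qv = np.asarray(self.q, dtype=float)
        if np.any(qv < 0) or np.any(qv > 1):
            raise KappamlError("q entries must be in [0, 1]")
        if abs(qv.sum() - 1.0) > 1e-12:
            raise KappamlError(f"q must sum to 1, got {qv.sum()!r}")
        return qv

    @property
    def labels(self) -> tuple:
        return self.categories or _default_labels(self.n_categories)


def _draw_block(
    rng: np.random.Generator, params: OGModelParams, n_cases: int, n_replicates: int
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded ratings for ``n_replicates`` independent datasets.

    Returns two (n_replicates, n_cases) arrays, one per rater.  The draw
    order (hardness, rater A guesses, rater B guesses, easy true labels)
    is fixed so seeded output is stable.
    """
    n = params.n_categories
    shape = (n_replicates, n_cases)
    hard = rng.random(shape) < params.r
    guess_a = rng.integers(0, n, size=shape)
    guess_b = rng.integers(0, n, size=shape)
    # inverse-CDF draw of easy-case true labels from q
    truth = np.searchsorted(np.cumsum(params.q_vector), rng.random(shape), side="right")
    truth = np.minimum(truth, n - 1)  # guard fp edge at cdf == 1
    return np.where(hard, guess_a, truth), np.where(hard, guess_b, truth)


def simulate_ratings(params: OGModelParams, n_cases: int, seed: int) -> PairedRatings:
    """Generate one dataset of paired ratings.

    Deterministic given ``seed``; labels come from ``params.labels``.
    """
    if n_cases < 1:
        raise KappamlError(f"n_cases must be >= 1, got {n_cases}")
    rng = np.random.default_rng(seed)
    codes_a, codes_b = _draw_block(rng, params, n_cases, 1)
    labels = np.asarray(params.labels, dtype=object)
    return PairedRatings(
        ratings_a=tuple(labels[codes_a[0]]),
        ratings_b=tuple(labels[codes_b[0]]),
        categories=tuple(params.labels),
    )


def simulate_rating_blocks(
    params: OGModelParams, n_cases: int, n_replicates: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Integer-coded ratings for many replicate datasets at once.

    Vectorized equivalent of calling :func:`simulate_ratings` repeatedly;
    used by the Monte-Carlo sweeps where only category indices matter.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _draw_block(rng, params, n_cases, n_replicates)


def simulate_disagreement_counts(
    params: OGModelParams, n_cases: int, n_replicates: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Number of disagreements Nd in each of ``n_replicates`` datasets."""
    codes_a, codes_b = simulate_rating_blocks(params, n_cases, n_replicates, seed)
    return np.sum(codes_a != codes_b, axis=1)


def theoretical_values(params: OGModelParams) -> TheoreticalValues:
    """Population quantities (Pa, Pc, kappa*, pi_plus) implied by ``params``."""
    q = float(params.q_vector[0]) if params.n_categories == 2 else None
    return TheoreticalValues.from_r(params.r, params.n_categories, q)
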