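"""Closed-form quantities of the occasional-guessing agreement model.

The model: a fraction ``r`` of cases is *hard* — each rater independently
guesses uniformly over the ``n`` categories — and the remaining ``1 - r``
is *easy*, where both raters give the (correct) true label.  Under this
model

    Pc = r/n                  chance (guessing) agreement probability
    Pa = 1 - r*(n-1)/n        overall agreement probability
    kappa* = (Pa - Pc)/(1 - Pc) = (1 - r)/(1 - r/n)

``kappa*`` is the true reliability implied by the model; the estimators in
:mod:`kappaml.estimators` target it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import KappamlError
from .ratings import AgreementSummary

__all__ = [
    "TheoreticalValues",
    "kappa_star_from_r",
    "r_from_kappa_star",
    "gwet_bias_delta_pc",
    "og_log_likelihood",
    "classification_variance",
    "MAX_CLASSIFICATION_VARIANCE",
]

#: Largest possible variance of a binary rating indicator, pi*(1-pi) at pi=1/2.
#: Gwet's AC1 estimates the guessing fraction as the observed-to-maximal
#: variance ratio, r = pi*(1-pi) / (1/4).
MAX_CLASSIFICATION_VARIANCE = 0.25


def _check_unit(value: float, name: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise KappamlError(f"{name} must be in [0, 1], got {value}")


def _check_n(n: int) -> None:
    if int(n) != n or n < 2:
        raise KappamlError(f"number of categories must be an integer >= 2, got {n}")


def kappa_star_from_r(r: float, n: int = 2) -> float:
    """True kappa implied by guessing fraction ``r`` with ``n`` categories.

    Returns ``(1 - r)/(1 - r/n)``, which decreases monotonically from 1 at
    r = 0 (no guessing) to 0 at r = 1 (all cases guessed).
    """
    _check_unit(r, "r")
    _check_n(n)
    return (1.0 - r) / (1.0 - r / n)


def r_from_kappa_star(kappa_star: float, n: int = 2) -> float:
    """Guessing fraction that produces a given true kappa.

    Inverse of :func:`kappa_star_from_r`: ``r = (1 - k)/(1 - k/n)``.
    """
    _check_unit(kappa_star, "kappa_star")
    _check_n(n)
    return (1.0 - kappa_star) / (1.0 - kappa_star / n)


def gwet_bias_delta_pc(r: float, q: float = 0.0) -> float:
    """Bias of Gwet's binary chance-agreement formula at guessing fraction r.

    Gwet's Pc = 2*pi*(1-pi) evaluated at the model's rating rate
    pi = r/2 + (1-r)*q exceeds the true chance agreement r/2 by

        delta = r/2 - r**2/2 + 2*q*(1-q)*(1-r)**2

    where q is the easy-case prevalence of the "+" category.  The widely
    quoted simplification r/2 - r**2/2 is the special case q in {0, 1}
    (all easy cases carry the same label), which is the default here; for
    intermediate q the extra 2*q*(1-q)*(1-r)**2 term makes the
    chance-agreement overstatement strictly larger.  At r = 1 the bias
    vanishes for every q; at r = 0 it vanishes only for q in {0, 1}, yet
    AC1's *kappa* is still well calibrated there because Pa = 1 forces
    kappa = 1 regardless of Pc.
    """
    _check_unit(r, "r")
    _check_unit(q, "q")
    return r / 2.0 - r * r / 2.0 + 2.0 * q * (1.0 - q) * (1.0 - r) ** 2


def classification_variance(pi: float) -> float:
    """Variance pi*(1-pi) of the indicator that a rater picks a category.

    Maximized at pi = 1/2 where it equals :data:`MAX_CLASSIFICATION_VARIANCE`.
    """
    _check_unit(pi, "pi")
    return pi * (1.0 - pi)


def og_log_likelihood(r, summary: AgreementSummary, n: int = 2):
    """Log-likelihood of agreement counts under the occasional-guessing model.

    Each case disagrees with probability ``r*(n-1)/n`` and agrees with
    probability ``1 - r*(n-1)/n``, so

        L(r) = Nd*log(r*(n-1)/n) + Na*log(1 - r*(n-1)/n)

    ``r`` may be a scalar or an array (the grid-search oracle evaluates the
    whole surface at once).  At r = 0 with Nd > 0 the likelihood is -inf by
    convention rather than an error.
    """
    _check_n(n)
    r = np.asarray(r, dtype=float)
    if np.any((r < 0) | (r > 1)):
        raise KappamlError("r must be in [0, 1]")
    frac = (n - 1) / n
    with np.errstate(divide="ignore"):
        log_pa = np.log1p(-r * frac)
        ll = summary.n_agree * log_pa
        if summary.n_disagree > 0:  # avoid 0 * log(0) at the boundary
            ll = ll + summary.n_disagree * np.log(r * frac)
    return ll if ll.ndim else float(ll)


@dataclass(frozen=True)
class TheoreticalValues:
    """Model-implied population quantities for given (r, n[, q])."""

    r: float
    n_categories: int
    p_agree: float
    p_chance: float
    kappa_star: float
    pi_plus: float | None = None  # binary model only; needs q

    @classmethod
    def from_r(cls, r: float, n: int = 2, q: float | None = None) -> "TheoreticalValues":
        _check_unit(r, "r")
        _check_n(n)
        pi = None
        if q is not None:
            if n != 2:
                raise KappamlError("pi_plus is defined for the binary model only")
            _check_unit(q, "q")
            pi = r / 2.0 + (1.0 - r) * q
        return cls(
            r=r,
            n_categories=n,
            p_agree=1.0 - r * (n - 1) / n,
            p_chance=r / n,
            kappa_star=kappa_star_from_r(r, n),
            pi_plus=pi,
        )
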