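"""Variance and confidence intervals for the ML agreement estimates.

For binary ratings the guessing-fraction estimate r_ML = 2*Nd/N has exact
variance r*(2 - r)/N, obtained from the first two moments of Nd.  A normal
plug-in interval for r can be transferred to the kappa scale two ways:

* Lipschitz — the map f(r) = (1 - r)/(1 - r/2) has |f'| <= 2 on [0, 1], so
  an r-interval of half-width delta gives [f(r0) - 2*delta, f(r0) + 2*delta].
  Conservative but simple.
* monotone — f is strictly decreasing, so the exact image of the
  r-interval is [f(r_upper), f(r_lower)].  Never wider than the Lipschitz
  interval.

A percentile bootstrap over case resampling works for any of the three
estimators and for any number of categories.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .estimators import (
    ESTIMATORS,
    _vec_cohen_kappa,
    _vec_gwet_terms,
    _vec_ml_kappa,
)
from .exceptions import KappamlError
from .model import kappa_star_from_r
from .ratings import PairedRatings, summarize_agreement

__all__ = [
    "IntervalEstimate",
    "var_r_ml",
    "ci_r_normal",
    "ci_kappa_lipschitz",
    "ci_kappa_monotone",
    "bootstrap_ci",
]


@dataclass(frozen=True)
class IntervalEstimate:
    """A point estimate with a two-sided confidence interval."""

    point: float
    lower: float
    upper: float
    level: float
    method: str
    degenerate: bool = False

    def __post_init__(self) -> None:
        for name in ("point", "lower", "upper", "level"):
            object.__setattr__(self, name, float(getattr(self, name)))
        object.__setattr__(self, "degenerate", bool(self.degenerate))
        if not (self.lower <= self.point <= self.upper):
            raise KappamlError(
                f"interval [{self.lower}, {self.upper}] does not contain "
                f"its point estimate {self.point}"
            )

    @property
    def width(self) -> float:
        return self.upper - self.lower

    def to_dict(self) -> dict:
        return asdict(self)


def var_r_ml(r: float, n_cases: int) -> float:
    """Sampling variance of r_ML = 2*Nd/N at guessing fraction r (binary).

    Equals r*(2 - r)/N: zero when nothing is guessed, 1/N when everything
    is.
    """
    if not (0.0 <= r <= 1.0):
        raise KappamlError(f"r must be in [0, 1], got {r}")
    if n_cases < 1:
        raise KappamlError(f"n_cases must be >= 1, got {n_cases}")
    return r * (2.0 - r) / n_cases


def ci_r_normal(r_hat: float, n_cases: int, level: float = 0.95) -> IntervalEstimate:
    """Normal-approximation interval for r with the plug-in variance.

    ``r_hat`` is clipped into [0, 1] before substitution into the variance
    formula (a raw ML estimate above 1 signals a model violation but still
    needs an interval), and the interval bounds are clipped to [0, 1].
    At r_hat = 0 the plug-in variance vanishes and the interval degenerates
    to a point, which is flagged.
    """
    if not (0.0 < level < 1.0):
        raise KappamlError(f"level must be in (0, 1), got {level}")
    r0 = min(max(float(r_hat), 0.0), 1.0)
    half_width = stats.norm.ppf(0.5 + level / 2.0) * np.sqrt(var_r_ml(r0, n_cases))
    return IntervalEstimate(
        point=r0,
        lower=max(0.0, r0 - half_width),
        upper=min(1.0, r0 + half_width),
        level=level,
        method="normal_r",
        degenerate=half_width == 0.0,
    )


def _half_width(interval: IntervalEstimate) -> float:
    # after clipping to [0, 1] the interval may be asymmetric; take the
    # larger side so the Lipschitz transfer stays conservative
    return max(interval.point - interval.lower, interval.upper - interval.point)


def ci_kappa_lipschitz(r_interval: IntervalEstimate, n: int = 2) -> IntervalEstimate:
    """Kappa interval from an r-interval via the Lipschitz bound on f.

    |f'(r)| <= n/(n-1) on [0, 1] (equal to 2 for binary ratings), so an
    r-interval of half-width delta maps into
    [f(r0) - L*delta, f(r0) + L*delta].  Always contains the exact
    monotone-image interval.  Bounds clipped to [-1, 1].
    """
    lipschitz = n / (n - 1)
    delta = _half_width(r_interval)
    center = kappa_star_from_r(r_interval.point, n)
    return IntervalEstimate(
        point=center,
        lower=max(-1.0, center - lipschitz * delta),
        upper=min(1.0, center + lipschitz * delta),
        level=r_interval.level,
        method="lipschitz_kappa",
        degenerate=delta == 0.0,
    )


def ci_kappa_monotone(r_interval: IntervalEstimate, n: int = 2) -> IntervalEstimate:
    """Exact image of an r-interval under the decreasing map f.

    [f(r_upper), f(r_lower)] — never wider than the Lipschitz interval.
    """
    return IntervalEstimate(
        point=kappa_star_from_r(r_interval.point, n),
        lower=kappa_star_from_r(r_interval.upper, n),
        upper=kappa_star_from_r(r_interval.lower, n),
        level=r_interval.level,
        method="monotone_kappa",
        degenerate=r_interval.width == 0.0,
    )


def bootstrap_ci(
    ratings: PairedRatings,
    estimator: str = "ml",
    n_boot: int = 2000,
    level: float = 0.95,
    *,
    seed: int,
) -> IntervalEstimate:
    """Percentile bootstrap interval for a kappa estimator.

    Cases are resampled with replacement ``n_boot`` times and the named
    estimator ("cohen", "gwet" or "ml") is recomputed on each resample;
    the interval is the (1-level)/2 and (1+level)/2 empirical quantiles.
    Deterministic given ``seed``.  An all-agree input yields the
    degenerate interval [1, 1] (every resample also agrees everywhere).

    Resampled Cohen replicates with degenerate marginals (all cases in one
    agreeing category) are assigned kappa = 1 by convention.
    """
    if estimator not in ESTIMATORS:
        raise KappamlError(f"unknown estimator {estimator!r}")
    if n_boot < 100:
        raise KappamlError(f"n_boot must be >= 100, got {n_boot}")
    if ratings.n_cases < 2:
        raise KappamlError("bootstrap needs at least 2 cases")
    if not (0.0 < level < 1.0):
        raise KappamlError(f"level must be in (0, 1), got {level}")

    point = ESTIMATORS[estimator](ratings).kappa
    summary = summarize_agreement(ratings)
    if summary.n_disagree == 0:
        return IntervalEstimate(
            point=point, lower=point, upper=point, level=level,
            method="bootstrap", degenerate=True,
        )

    codes_a, codes_b = ratings.codes()
    n_cat = ratings.n_categories
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, ratings.n_cases, size=(n_boot, ratings.n_cases))
    a_star, b_star = codes_a[idx], codes_b[idx]
    if estimator == "ml":
        kappas = _vec_ml_kappa(a_star, b_star, n_cat)
    elif estimator == "gwet":
        kappas, _ = _vec_gwet_terms(a_star, b_star)
    else:
        kappas = _vec_cohen_kappa(a_star, b_star, n_cat)
    alpha = (1.0 - level) / 2.0
    lower, upper = np.quantile(kappas, [alpha, 1.0 - alpha])
    lower, upper = float(min(lower, point)), float(max(upper, point))
    # kappa-scale bounds live in [-1, 1] unless the point itself is outside
    # (possible for an unclamped out-of-model ML estimate)
    if point >= -1.0:
        lower = max(lower, -1.0)
    if point <= 1.0:
        upper = min(upper, 1.0)
    return IntervalEstimate(
        point=point,
        lower=lower,
        upper=upper,
        level=level,
        method="bootstrap",
    )
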