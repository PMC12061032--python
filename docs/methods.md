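# Methods

## The occasional-guessing model

Two raters independently classify N cases into n ≥ 2 mutually exclusive
categories.  Each case is *hard* with probability r ∈ [0, 1]: both raters
guess, independently and uniformly over the n categories.  Otherwise the
case is *easy*: a true label drawn from the easy-case category
distribution q is reported by both raters.  Hard cases carry no true
label — every quantity the model needs conditions only on the agreement
indicator Xᵢ ∈ {0, 1}, and for hard cases P(agree) = 1/n regardless of
any notion of truth.

Population quantities implied by the model:

| quantity              | value                      |
|-----------------------|----------------------------|
| chance agreement Pc   | r/n                        |
| overall agreement Pa  | 1 − r(n−1)/n               |
| true reliability κ*   | (Pa − Pc)/(1 − Pc) = (1−r)/(1−r/n) |
| binary "+"-rate π₊    | r/2 + (1−r)q               |

κ*(r) decreases monotonically from 1 (r = 0) to 0 (r = 1); its inverse
r(κ*) = (1−κ*)/(1−κ*/n) is used by the simulator and the bias sweep to
target a desired true reliability.

## Maximum-likelihood estimation

Each case disagrees with probability r(n−1)/n, so with Nd observed
disagreements among N cases the log-likelihood is

    L(r) = Nd·log(r(n−1)/n) + Na·log(1 − r(n−1)/n),

maximized at r̂ML = (Nd/N)·n/(n−1).  The estimated chance agreement is
Pc = r̂ML/n — for binary ratings, exactly the observed disagreement rate.
Because Pa = 1 − r̂ML(n−1)/n identically, κML = (Pa − Pc)/(1 − Pc) equals
the theoretical curve evaluated at the estimate, κML = (1−r̂ML)/(1−r̂ML/n).

E[r̂ML] = r exactly (Nd is binomial with mean N·r(n−1)/n), and for the
binary model Var[r̂ML] = r(2−r)/N from the second moment of Nd.

**Out-of-model data.** When the observed disagreement rate exceeds
(n−1)/n the raw r̂ML is > 1, which no parameter value can produce.  The
default is to report the unclamped (negative) κ with a
`model_violation` flag and a warning — comparable to the below-chance
convention of other κ coefficients and honest about the model
contradiction; truncation to the boundary (r = 1, κ = 0) is available as
an explicit `clamp=True` option.  Silent clamping was rejected because it
hides data that falsify the model.

## Why Gwet's AC1 is biased at intermediate agreement

AC1 estimates the guessing fraction as the ratio of the observed rating
variance π₊(1−π₊) to its maximum 1/4, giving Pc = 2π₊(1−π₊) for binary
ratings.  Substituting the model's π₊ = r/2 + (1−r)q and subtracting the
true chance agreement r/2 yields the exact bias

    ΔPc(r, q) = r/2 − r²/2 + 2q(1−q)(1−r)².

The first two terms are the frequently quoted bias curve (zero at
r ∈ {0, 1}, maximum 1/8 at r = 1/2); they are the whole story only when
all easy cases carry the same label (q ∈ {0, 1}).  For intermediate q the
additional 2q(1−q)(1−r)² term is strictly positive — note that it does
*not* vanish as r → 0, where AC1's Pc tends to 2q(1−q) rather than to the
true 0.  AC1's *κ* nevertheless remains well calibrated at the extremes:
at r = 0, Pa = 1 forces κ = 1 whatever Pc; at r = 1 the bias itself
vanishes.  In between, the inflated Pc depresses AC1 by up to ≈ 0.14
(N = 100, q = 0.2 configuration).  `gwet_bias_delta_pc(r, q)` implements
the full expression, with q = 0 as the default so the classical two-term
curve is what a bare call returns; the sweep's analytic-bias column uses
the sweep's own q.  The closed form was verified symbolically (sympy
expansion of 2π(1−π) − r/2) and against simulation.

## Uncertainty

* **Normal interval for r** — r̂ ± z·√(r̂(2−r̂)/N), the plug-in of the
  analytic variance, clipped to [0, 1].  The plug-in uses the estimate
  because the true r is unknown in practice; r̂ = 0 degenerates to a
  flagged point interval.
* **Transfer to the κ scale** — two routes.  The *Lipschitz* interval
  uses |f′(r)| ≤ n/(n−1) (= 2 for binary) for f(r) = (1−r)/(1−r/n):
  half-width δ on the r scale becomes at most (n/(n−1))·δ on the κ scale,
  centered at f(r̂).  The *monotone* interval is the exact image
  [f(r_hi), f(r_lo)] of the r-interval under the decreasing map f; it is
  never wider than the Lipschitz interval and is the default reported CI.
  (A centered reading of the Lipschitz transfer is used; mapping the
  displaced endpoints through the decreasing f would produce a reversed
  interval.)
* **Percentile bootstrap** — cases resampled with replacement, the chosen
  estimator recomputed on each resample (vectorized over integer-coded
  ratings), interval from the empirical (1±level)/2 quantiles.
  Percentile rather than BCa: simplest defensible choice, exactly
  reproducible under a mandatory caller-supplied seed.  n_boot defaults
  to 2000, level to 0.95.  An all-agree sample returns the flagged
  degenerate interval [1, 1].  Variance of r̂ML for n > 2 is left to the
  bootstrap (the closed form above is binary).

## Simulator

`simulate_ratings` draws, per case: a hardness indicator (prob. r), two
independent uniform guesses, and an easy-case true label from q (scalar
q for binary = distribution (q, 1−q); a full probability vector for
n > 2).  One seeded `numpy.random.Generator` per call, fixed draw order,
so output is bit-reproducible.  `simulate_rating_blocks` /
`simulate_disagreement_counts` run the identical generative steps
vectorized over replicates for the Monte-Carlo studies.

What the generator does *not* emulate about real rating data: rater
asymmetry (different skill or thresholds), correlated guessing, partially
hard cases, easy-case errors, missingness.  Tests passing against this
generator certify the estimators under the model's own assumptions — the
model-recovery claim — not robustness to these violations.

## Bias sweep

Default configuration: two raters, N = 100 cases, q = 0.2, 21 equally
spaced κ* values spanning [0, 1], 1000 replicates per point, 95%
percentile bands, independent child seed streams per grid point.  The
sweep records, per point, both estimators' mean/band/SE, mean Pc, the
analytic ΔPc(r, q), and the mean r̂ML.

Unbiasedness is asserted on r̂ML, where it is exact.  On the κ scale the
decreasing convex map f introduces a finite-N Jensen term: at the κ* = 0
endpoint (r = 1, N = 100) the exact expectation of κML − κ* is −0.0206
(computable by summing f(2Nd/N) over the binomial law of Nd), shrinking
like 1/N and vanishing by mid-grid.  κML is therefore described as
asymptotically unbiased on the κ scale and exactly unbiased on the r
scale.

## Numerical and testing choices

* All proportions in double precision; exact-equality assertions use
  absolute tolerance 1e−12.
* Likelihood at r = 0 with Nd > 0 is −∞ by convention, not an error; the
  grid-search oracle for the ML solution uses a 1e−4-step grid on (0, 1].
* Cohen's κ is cross-checked against an independent reference
  implementation (scikit-learn) in the tests; Gwet's AC1 and κML are
  checked against hand-evaluated worked examples and closed forms.
* Monte-Carlo test tolerances are 3–4 standard errors of the quantity
  under test.  Where a plug-in statistic has a known exact finite-N
  expectation (the mean of AC1's Pc is the population value minus twice
  the variance of π̂₊), the comparison target is that exact expectation,
  keeping 3-SE bands valid at any replicate count.
* Problem sizes: 100,000 replicates for the r̂ML moment checks, 4000
  replicates of N = 200 for the Pc-bias check, 1000 outer simulations ×
  2000 bootstrap resamples for coverage — all vectorized, together a few
  seconds on one core.
* Category order: inferred categories are the sorted union of observed
  labels; contingency tables fix the order by their row labels; AC1 and
  all other statistics are invariant to the designation.

## Known limitations

Two raters only; unweighted (nominal) agreement; uniform hard-case
guessing with a single shared r; AC1 implemented for binary ratings only
(its multi-category chance model is a different formula and out of
scope); no closed-form variance for κML itself (use the mapped r-interval
or the bootstrap); no hypothesis tests comparing coefficients.
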