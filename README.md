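# kappaml

Chance-corrected interrater agreement for two raters: Cohen's κ, Gwet's
AC1, and a maximum-likelihood κ for the *occasional-guessing* model of
chance agreement, with analytic variance, confidence intervals, a
generative simulator and a Monte-Carlo bias study.

## The problem

When two raters (radiologists scoring scans, coders labelling
transcripts, clinicians classifying EEGs) assign the same N cases to n
mutually exclusive categories, the raw percent agreement Pa overstates
their reliability because some agreement happens by accident.  Every
κ-type coefficient subtracts an estimate of the chance-agreement
probability Pc:

    κ = (Pa − Pc) / (1 − Pc)

and the coefficients differ only in how they model Pc:

* **Cohen's κ** — the "always guess" model: Pc = Σₖ p^A_k · p^B_k, the
  product of the raters' marginal rates summed over categories.  Known to
  behave paradoxically when the category prevalences are far from
  balanced.
* **Gwet's AC1** — the *occasional-guessing* model: a fraction r of cases
  is hard (both raters guess uniformly), the rest are easy (both rate
  correctly).  AC1 estimates r heuristically from the variance ratio
  π₊(1−π₊)/¼, giving Pc = 2π₊(1−π₊) for binary ratings, where π₊ is the
  raters' average rate for one category.
* **κML** (this package's focus) — the exact maximum-likelihood solution
  of the same occasional-guessing model.  The likelihood of the observed
  agreement pattern is maximized at

      r̂ML = (Nd/N) · n/(n−1),      Pc = r̂ML/n,

  i.e. for binary ratings the chance-agreement probability is simply the
  observed disagreement rate Nd/N, and r̂ML is twice the disagreement
  rate.  E[r̂ML] = r exactly, Var[r̂ML] = r(2−r)/N (binary), and the
  resulting κML = (1−r̂ML)/(1−r̂ML/n) tracks the model's true reliability
  κ* = (1−r)/(1−r/n) without the systematic distortion that AC1's
  heuristic Pc carries at intermediate agreement levels (see
  `docs/methods.md` for the exact bias curve).

## Worked example

Simulate 100 cases from the occasional-guessing model with r = 0.4 hard
cases and easy-case "+" prevalence q = 0.2 — the true reliability is
κ* = (1−0.4)/(1−0.2) = 0.75 — then estimate all three coefficients with
bootstrap intervals:

```sh
kappaml simulate --r 0.4 --q 0.2 --n-cases 100 --seed 7 --out demo.csv
kappaml compute --input demo.csv --ci bootstrap --n-boot 2000 --seed 7
```

The report (abridged) shows 83/100 agreements, so Pa = 0.83:

```json
{
  "summary": {"n_cases": 100, "n_agree": 83, "p_agree": 0.83},
  "estimates": {
    "ml":    {"kappa": 0.795, "p_chance": 0.17,  "r_hat": 0.34,
              "ci": {"lower": 0.667, "upper": 0.889}},
    "gwet":  {"kappa": 0.705, "p_chance": 0.424, "r_hat": 0.848},
    "cohen": {"kappa": 0.599, "p_chance": 0.576}
  }
}
```

κML's chance agreement is the observed disagreement rate (0.17), its
guessing-fraction estimate 0.34 is close to the generating r = 0.4, and
κML = 0.795 lands near the true 0.75 with the 95% interval covering it.
AC1's variance-ratio heuristic overestimates the guessing fraction
(r̂ = 0.85) and lands lower; Cohen's κ is lower still because its
always-guess Pc charges the raters for their shared knowledge of the
prevalence.

The same numbers come from the library API:

```python
from kappaml import read_ratings, ml_kappa
est = ml_kappa(read_ratings("demo.csv"))
est.kappa, est.r_hat            # (0.795..., 0.34)
```

The bias study behind the estimator comparison is one command:

```sh
kappaml bias-sweep --grid-size 21 --replicates 1000 --seed 11 \
    --out sweep.csv --plot sweep.png
```

which sweeps the true κ* over [0, 1] (two raters, N = 100, q = 0.2),
simulates 1000 datasets per point and tabulates both estimators' bias;
Gwet's AC1 undershoots by up to ≈ 0.14 in the mid-range while the ML
estimate of r is unbiased at every point.

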