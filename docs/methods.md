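# Methods

## Problem and model

`toxdta` analyses direct toxicity assessment (DTA) trials in which replicate
vials of marine invertebrates (10 individuals per vial) are held in undiluted,
salinity-adjusted groundwater test solutions (TS1–TS7) or in reference waters
— a hypersaline-brine control (HSB, matching the salinity-adjustment medium)
and a natural seawater control (SW) — as a static press exposure for 14 or
21 days, with survivors counted on a fixed schedule. Two questions are asked
of each species × test-solution × round combination: *how fast* does survival
decline (lethal time), and *is there a response at all* (the weighted
response matrix).

### Time–response curves and lethal times

Percent survival `y` at day `t` is fitted by nonlinear least squares with the
standard sigmoidal dose–response families, written with the conventional
parameter names `b` (slope), `c` (lower asymptote, %), `d` (upper asymptote,
%), `e` (inflection time, days), `f` (asymmetry), and `z = (t/e)^b`:

- log-logistic: `y = c + (d − c) / (1 + z)^f`
- Weibull-1: `y = c + (d − c) · exp(−z)`
- Weibull-2: `y = c + (d − c) · (1 − exp(−z))`

Six candidate families are fitted: `LL3u100` (log-logistic with `c = 0`,
`d = 100`, `f = 1`; two free parameters), `LL3` (`c = 0`, `f = 1`), `LL4`
(`f = 1`), `W14`, `W24`, and `LL5`. `LL3u100` — the biologically natural
model when every cohort starts at 100% survival — is the expected winner for
clean data and is listed first in the deterministic tie-break order.

The response variable is replicate-level percent survival at each observation
day, treated as independent homoscedastic Gaussian observations. This uses
all the data but ignores two features of the truth: counts are binomial (the
variance shrinks near 0% and 100%) and the six observations of one replicate
share the same ten individuals, so their errors are positively correlated.
The consequences are quantified below.

Model selection is by minimum AIC among converged fits, with
`AIC = n·ln(RSS/n) + 2(k + 1)` where `k` counts the free curve parameters and
the `+1` the residual variance. Only the ordering across families fitted to
the same data is meaningful. Ties go to fewer parameters, then to the fixed
family order above. A group whose data cannot identify a curve (e.g. a
control with constant 100% survival) is reported as non-modellable
(`converged = False`), never as an exception.

The lethal time LT_p inverts the selected curve at a p% decline read against
the fitted asymptote range: solve `f(t) = d̂ − (p/100)(d̂ − ĉ)`. All families
admit a closed form, e.g. `LT_p = ê · (p/(100 − p))^(1/b̂)` for the
log-logistic. With the dominant model (`c = 0`, `d = 100`) the relative and
absolute (`f(t) = 100 − p`) readings coincide; the absolute reading is
available via `estimate_lt(..., relative=False)`. Confidence limits use the
delta method on the natural (day) scale — gradient of LT_p in the free
parameters, Gauss–Newton covariance `(JᵀJ)⁻¹ · RSS/(n − k)`, t quantile at
`n − k` degrees of freedom. A weakly identified early decline can produce a
negative lower limit; it is reported as-is rather than truncated, since the
interval's width is the information. A fitted curve that does not decrease
with time (`b̂ ≤ 0` for log-logistic and Weibull-1, `b̂ ≥ 0` for Weibull-2)
is flagged as non-toxic-direction and yields no LT.

Optimizer: `scipy.optimize.least_squares` (trust-region reflective) with
starting values `e₀ = median day`, `c₀ = min y`, `d₀ = max y`, `f₀ = 1`, and
a deterministic multi-start over slopes `b₀ ∈ {1, 0.5, 5, −1, −0.5, −5}`
(the negative starts serve the Weibull-2 orientation); the best RSS wins.
Bounds keep `e` and `f` positive. No randomness is involved.

### The response matrix

Each species × test solution × round combination receives five criterion
scores in {0, 0.5, 1} (1 = met, 0.5 = borderline, 0 = not met):

| # | Criterion | Weight |
|---|-----------|--------|
| 1 | survival through time distinct from both HSB and SW controls at ≥ 1 day | 4 |
| 2 | end-of-test mean survival ≥ 20 points below the HSB control (borderline 15–20) | 3 |
| 3 | end-of-test mean survival < 80% (borderline 80–85%) | 2 |
| 4 | LT10 95% range below the HSB control's LT10 range (borderline: upper limit overlaps but estimate is below the control's lower limit) | 1 |
| 5 | as criterion 4, for LT50 | 1 |

The response score is `100 · Σwᵢsᵢ / Σwᵢ` (denominator 11 with the default
weights, so attainable scores lie on the 100/22 half-step lattice);
combinations scoring ≥ 65% are classified "Response". Rounding to integer
percentages is half-away-from-zero and for reporting only — classification
uses the unrounded score.

Boundary conventions, where the verbal rules leave room: criterion 2 is met
at exactly 20 and borderline at exactly 15; criterion 3 is borderline at both
80 and 85 (the 85 endpoint is pinned borderline by the published worked
example). Microtox EC50 bands are half-open with the severe bound inclusive:
≤ 25% extremely toxic, (25, 50] highly, (50, 75] moderately, (75, 100]
slightly, > 100% no measurable toxicity.

Criterion 1 is, in origin, an expert visual judgment of raw survival plots.
The automatic rule implemented here scores the largest day-wise shortfall of
the test-solution mean below *both* control means (binding comparison: the
nearer control), with the same 20/15-point bands as criterion 2 so the two
magnitude scales agree. Both margins are configurable, and a manual-override
CSV channel injects externally judged scores verbatim (flagged
`basis=manual`), which is how the published criterion scores are reproduced
exactly.

Criteria 4/5 fallback: when the HSB control is non-modellable — the usual
case, since a healthy control never declines — its lethal time behaves as
"beyond test end", so the test solution scores 1 exactly when its LT upper
limit lies within the test duration. A test solution with no estimable LT
scores 0 with evidence "not estimable".

Summaries pool both rounds: percent toxic per test solution (across species
and external assay rows, e.g. Microtox) and percent toxic response per
species/assay, each `100 · responses / tested cells` rounded to integer;
not-tested cells leave the denominator.

## Synthetic data

The generator mirrors the trial design: per group, `n_replicates` vials of
`n_individuals` (defaults 5 × 10 for test solutions, 6 × 10 for controls) on
the 14-day schedule {1, 2, 4, 7, 10, 14} or the 21-day schedule
{4, 7, 10, 14, 21}. Because the exposure is a static press on a fixed cohort,
each individual gets a *single latent death time*: immune with probability π
(never dies within the horizon), otherwise `T = e*·(U/(1−U))^(1/β*)` — the
inverse-CDF draw from the log-logistic law `S(t) = 1/(1 + (t/e*)^β*)`, whose
scale `e*` is the true LT50 when π = 0. Counting survivors gives exactly
non-increasing within-replicate counts and expected percent survival
`100·(π + (1−π)·S(t))`. Control-level background mortality is emulated with a
high immune fraction (π ≈ 0.8 reproduces the ~78–80% control end survival
typical of these trials) rather than a separate hazard. One seed drives a
hierarchical stream keyed by (group label, replicate), so adding a group
never perturbs another group's draws.

What the generator does *not* emulate: between-round environmental drift,
chemistry covariates, interval-censored observation error, or overdispersion
beyond binomial sampling. Tests passing on synthetic data therefore validate
the arithmetic and the estimation machinery under the stated model, not the
field realism of any particular dataset.

## Verification and known limitations

- **Oracle equivalence.** Closed-form LT_p agrees with independent bisection
  root-finding on the curve to 1e−8 across randomized parameter draws for
  all six families.
- **Wald calibration under the model.** With iid Gaussian noise (σ = 5) on
  the true curve, the 95% Wald intervals for both free parameters of
  `LL3u100` cover the truth in ≈95% of simulations (0.946/0.958 observed
  over 500) — the covariance machinery is correct under its own assumptions.
- **Accuracy under the trial design.** With 5 replicates × 10 individuals on
  the 14-day schedule, true LT50 = 8 d, β = 3, π = 0, the median relative
  LT50 error is ≈5% over 500 simulated trials.
- **Interval under-coverage under the trial design (known limitation).**
  Under the same design the delta-method LT50 interval covers the truth in
  only ≈68–70% of trials, not 95%. The cause is the ignored within-replicate
  correlation: the six observations of a vial share ten individuals, so the
  independent-Gaussian covariance understates Var(LT50) by roughly 4×
  (empirical SD ≈ 0.67 d versus a mean CI half-width ≈ 0.69 d ≈ 1 SE).
  Fitting replicate *means* instead is worse still (≈54% coverage: fewer
  points, same correlation). Honest intervals for this design would need a
  cluster-robust (per-replicate sandwich) variance or a survival-likelihood
  treatment of the latent death times, both outside the scope of the
  curve-fitting approach implemented here; reported intervals should be read
  as optimistic.
- The repeated-measures and binomial-variance approximations affect interval
  width, not point estimates: LT bias is small (≲0.1 d at LT50 = 8 d).

## Problem sizes and defaults

Simulation-backed tests use 300–500 replicate trials (seconds on one core);
the oracle-equivalence check uses 1000 random parameter draws. Defaults
throughout are the study's: weights (4, 3, 2, 1, 1), threshold 65%,
criterion margins 20/15 points, confidence level 0.95, LT levels {10, 50},
initial cohort 10, replicate counts 5 (solutions) / 6 (controls). All are
overridable through `PipelineConfig` (YAML/JSON) to support sensitivity
analysis of the expert-judgment constants. Reported tables print LT values
to 1 decimal and scores as integers, with fixed formatting so identical
inputs reproduce byte-identical outputs.
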