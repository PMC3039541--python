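# Methods

## Scientific setting

Volunteer cohorts of older people are usually healthier than the population
they were sampled from, and in this age range attrition is dominated by
death.  `relsurv` quantifies that *healthy-volunteer* survival advantage the
way cancer registries quantify excess disease mortality, but in reverse: it
compares the cohort's observed survival with the survival expected under
published population life tables matched on age, calendar year and stratum
(e.g. State or Territory), and asks how much better the cohort does.  Two
complementary estimators are provided — an actuarial life table with
Ederer II expected survival, and a multiplicative relative-mortality
regression — plus survey-comparison and direct-standardisation utilities,
and a synthetic-data generator that reproduces the statistical structure of
such a study with known ground truth.

## Cohort life table with Ederer II expected survival

Follow-up is divided into annual intervals `[i, i+1)` from entry.  For each
interval the (weighted) number at risk `L`, deaths `D` and withdrawals `W`
are tabulated; withdrawals and deaths are assumed uniform over the interval,
so the effective at-risk is `L' = L - W/2` and interval observed survival is
`P = 1 - D/L'`.  Cumulative observed survival follows the product recursion
`CP(i+1) = CP(i) P(i)`, `CP(0) = 1`.

Expected survival uses the Ederer II convention: expected deaths `D*` in
interval `i` are summed only over the individuals actually at risk at that
interval's start, each contributing its weight times its own life-table
annual death probability `q*` at attained age `entry_age + i`, attained
calendar year `entry_year + i`, and stratum.  Individuals withdrawn within
the interval contribute half, mirroring `L'`.  Then `P* = 1 - D*/L'`, `CP*`
by the same recursion, and the relative-survival ratios are `R = P/P*` and
`CR = CP/CP*` (not clamped; values below 1 are meaningful).

With sampling weights (inverse sampling fractions correcting design
oversampling) all counts are weighted sums and every formula applies
unchanged; `P`, `P*`, `R`, `CR` are invariant to rescaling all weights by a
constant.

**Confidence intervals.** `CR` bounds use the Greenwood variance of
`log CP`, `var = sum_k D_k/(L'_k(L'_k - D_k))`, treating the expected curve
as fixed — the standard large-cohort approximation when the expected curve
comes from national tables built on populations orders of magnitude larger
than the cohort.  Bounds are `exp(log CR ± z sqrt(var))`.  A percentile
bootstrap over cohort records is used in the test suite as an independent
check; on a synthetic cohort of 2 000 the two agree to well within 15% of
the interval width.

**Conventions and degenerate cases.**

* Interval membership is half-open; a death at exactly `t = k·width` counts
  in interval `k`.  A *censoring* at exactly a boundary (within 1e-9) is
  assigned to the preceding interval: such a record was fully exposed
  through that interval and never entered the next.  This is how a fixed
  administrative end of follow-up appears in published cohort life tables
  (all withdrawals in the final interval).
* Intervals with non-positive effective at-risk are dropped with a warning;
  `D > L'` and `P* <= 0` are errors naming the interval; `L' = D` makes the
  Greenwood variance undefined and is an error.
* Published tables print truncated at-risk numbers (e.g. 9106 for an
  effective 9106.5); internal computation keeps full precision throughout
  and only display rounds.
* In validation mode the stage accepts pre-tabulated `(L, D, W)` counts and
  an injected expected-survival vector.  If a published *cumulative*
  expected column is supplied alongside the interval column it is used as
  given rather than recomputed from the rounded interval values, because a
  12-term product of 3-decimal numbers compounds rounding by ~0.1-0.2%.

**Known limitation — censored-interval bias.**  In an interval where almost
the whole risk set is administratively withdrawn (the final year of a study
with staggered entry and a fixed end date), the actuarial observed estimator
converges to `1 - 2f_d/(1 + f_d)` (with `f_d` the probability of death
before censoring), which exceeds the true interval survival `e^-mu` by about
`mu^2/3`, while the Ederer II expected side estimates `1 - q = e^-mu`
exactly.  Interval `R` in such an interval is therefore biased upward by
roughly 0.001 at the hazards of ages 80-86.  This is a property of the
classical printed formulas, not of this implementation; the test suite
verifies both that uncensored intervals are unbiased and that the censored
final interval sits at this closed-form limit.  Cumulative `CR` inherits at
most this one-interval effect.

## Multiplicative relative-mortality regression

The hazard model is `lambda_i(a, s) = lambda*_i(a, s) exp(beta' z_i)`: the
known population hazard `lambda* = -ln(1 - q*)` (piecewise constant over
single years of age and calendar time) scaled by a log-linear function of
baseline categorical covariates.  A hazard ratio `exp(beta) < 1` means
mortality below the matched population.  A multiplicative (relative) model
rather than an additive (excess) one is appropriate here because a cohort
may be uniformly healthier than its reference, making a non-negative excess
hazard untenable.

Follow-up is split into annual person-time cells at attained-age boundaries
(a Lexis expansion); exposures sum to follow-up exactly and the event flag
sits on the final cell.  With the baseline fully known the log likelihood

    l(beta) = sum_cells w [ d (log mu* + beta'z) - mu* * exposure * e^{beta'z} ]

is a Poisson likelihood with offset `log(mu* * exposure)`.  It is maximised
by Newton-Raphson with analytic gradient and Hessian, initialised at
`beta = 0`, with step-halving whenever a step would decrease the likelihood;
convergence is declared when the relative likelihood change falls below
1e-8 (at most 50 iterations; non-convergence returns a flagged fit rather
than raising).  The covariance is the inverse observed information; a
record-clustered sandwich estimator is available but off by default, since
weighted fits here use weights as pseudo-likelihood multipliers and the
model-based variance matches the unweighted design the published tables
reflect.

An intercept is included by default.  It absorbs the cohort-wide log
standardised mortality ratio (SMR) of the reference group, so reported
hazard ratios are pure contrasts between covariate levels: with one binary
covariate the fitted HR is exactly `SMR_1/SMR_0`.  Without an intercept a
cohort-wide healthy-volunteer effect would leak into every coefficient.
Covariates are time-fixed baseline values; the only time dependence of the
linear predictor is through the attained age and year in `mu*`.

Degenerate inputs: a death in a cell with `mu* = 0` has infinite likelihood
and is an error; zero-hazard or zero-exposure event-free cells are dropped
with a warning; rank-deficient designs raise naming the aliased columns;
zero-length censored records are dropped (complete-case behaviour is
logged), while a death with zero follow-up is an error.

## Survey comparison and counterfactual reweighting

Baseline category distributions are compared with a contemporaneous
reference survey by Pearson chi-square on the k x 2 count table
(`df = k - 1`), without continuity correction by default (multi-category
tables at large N); counts can be reconstructed from published percentages
by rounding against the printed totals, with an optional largest-remainder
repair when an exact total is required.  Inputs that look like percentages
(both columns summing to ~100 with non-integer cells) are rejected with a
pointer to the reconstruction helper.

The counterfactual question "what would the cohort's cumulative mortality
be with the reference survey's mix of, say, self-rated health?" is answered
by direct standardisation: the life-table stage is run within each category
`k`, `M_k = 1 - CP_k(horizon)` is taken as its cumulative mortality, and
observed and counterfactual mortality are `sum pi_k M_k` under the cohort's
weighted proportions and the target proportions respectively.  The ratio is
scale-free in cohort size and invariant to category order.  Using the
life-table `CP` as the per-category mortality estimator keeps the
counterfactual internally consistent with the rest of the pipeline.

## Synthetic-data generator

The generator emulates the design of a national women's-health cohort:
entry at ages 70-75 in a fixed calendar year (default 19% at each of 70-74
and 5% at 75), up to 12 years of follow-up, strata sampled with probability
proportional to `population_share x sampling_fraction` carrying weight
`1/sampling_fraction`, independent categorical covariates, and death times
drawn by inverse transform from the piecewise-constant annual hazard
`f * mu*(attained age, year, stratum) * exp(beta'z)`, where `f` is a
cohort-wide healthy-volunteer factor (`f < 1` = uniformly healthier cohort).

Follow-up ends at a fixed calendar date with entry staggered uniformly over
`entry_spread` years (default 1.0, a survey fielded over a year), so
administrative censoring times fall within the final follow-up interval —
the pattern published cohort life tables show, and the configuration under
which the `L - W/2` convention's uniform-withdrawal assumption actually
holds.  Setting `entry_spread = 0` censors everyone exactly at the horizon;
the boundary convention then books those withdrawals into the final
interval, but the half-exposure correction badly understates their exposure
and interval estimates there should not be trusted.

Population mortality is Gompertz, `mu(age) = b e^{c age}`, with per-stratum
level multipliers; defaults `c = ln2/8` (hazard doubling every 8 years —
standard for ages 70+) and `b = 3.94e-5`, calibrated so the annual death
probability at age 72 is ~0.020 and 12-year expected survival from age 72 is
~0.665, the scale of the published expected-survival column.  Calendar-year
drift is omitted (national tables move slowly at these ages over a decade);
the nearest-year lookup makes sparse synthetic tables safe.

The preset scenario (`alswh_like_preset`) sets n = 12 424, entry year 1996,
the published baseline marginals for smoking, self-rated health and marital
status, State strata whose sampling fractions reproduce the cohort's
observed State distribution from the reference survey's population shares,
a healthy-volunteer factor of 0.92, and within-cohort covariate contrasts
equal to the published multivariate hazard ratios *recentred* so that the
population-average relative hazard per covariate is 1 (`centred_log_hr`):
the factor alone then controls the cohort-wide advantage while the
regression still recovers the published contrasts exactly.  Covariates are
drawn independently — the published tables give marginals only — so the
preset underrepresents real-world confounding between, say, smoking and
self-rated health; passing tests demonstrate estimator correctness under
the stated model, not robustness to covariate dependence, linkage error
(incomplete death ascertainment) or non-proportional effects, none of which
are generated.

## Problem sizes and numerics in the test and acceptance runs

Simulation checks use the sizes natural to the design: parameter recovery
averages 100 cohorts of n = 10 000; null calibration averages 200 cohorts of
n = 5 000; bootstrap validation of the Greenwood interval uses 1 000
resamples of a 2 000-record cohort.  All random draws flow from explicit
integer seeds through `numpy.random.default_rng`; identical seeds produce
byte-identical cohort CSVs.  Boundary comparisons use an absolute tolerance
of 1e-9 on event times; likelihood convergence is relative 1e-8; exposures
and weighted counts are conserved to 1e-9.
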