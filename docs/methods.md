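# Methods

## Model family

All four regressions are maximum-likelihood fits of one family.  With
per-observation rate λ_i = exp(X_i'β), dispersion ν_i = exp(S_i'δ) and
structural-zero probability π_i = expit(W_i'γ), the log-likelihood
contribution is

    y_i = 0:  log( π_i + (1 − π_i) / Z(λ_i, ν_i) )
    y_i > 0:  log(1 − π_i) + y_i log λ_i − ν_i log(y_i!) − log Z(λ_i, ν_i)

with Z(λ, ν) = Σ_j λ^j/(j!)^ν.  Poisson fixes ν ≡ 1 and π ≡ 0, CMP fixes
π ≡ 0, ZIP fixes ν ≡ 1.  Case weights multiply each contribution, which
makes a frequency table (one row per distinct outcome, weight = its
count) exactly equivalent to the expanded record-level data; the test
suite asserts this equivalence to 1e-8.

Assumptions: observations independent given covariates; categorical
covariates enter by treatment (dummy) coding with the first coded level
as baseline; the dispersion design defaults to an intercept (a single ν)
but any S is accepted.

## Series evaluation

Z and the series moments E[Y], E[Y²], E[log Y!] are computed by direct
summation on the log scale (log-sum-exp; log(y!) via the log-gamma
function, so log(0!) = 0 without special-casing).  The terms are
unimodal in j with mode ≈ λ^(1/ν), so truncation is accepted only once
the index has passed the mode *and* the current term is below
`rel_tol` × the accumulated sum.  Defaults: `rel_tol = 1e-12`,
`max_terms = 10,000`; exceeding the cap raises a convergence error, and
ν = 0 with λ ≥ 1 raises a divergence error up front (for ν = 0, λ < 1
the series is geometric and the same machinery applies).  In regression
fits the per-row statistics are computed once per *unique* (λ, ν) pair,
which collapses intercept-only designs to a handful of series
evaluations regardless of n.

Two mean formulas are exposed.  The default is the exact series mean.
The asymptotic approximations E(Y) ≈ λ^(1/ν) − (ν−1)/(2ν) and
Var(Y) ≈ λ^(1/ν)/ν are also provided because published CMP analyses
often report them; at the small rates typical of fatality data they are
materially biased (λ = 0.332, ν = 1.550 gives 0.313 approximate vs
0.302 exact), so both must be available to reconcile fitted means
against the literature.

## Optimization, standard errors, boundaries

Quasi-Newton (L-BFGS-B) on the unconstrained coefficient scale with
analytic gradients; the gradient uses the identities
∂logZ/∂logλ = E[Y] and ∂logZ/∂ν = −E[log Y!].  Initialization: β from
the Poisson fit (whose own intercept starts at log of the weighted mean,
i.e. at its closed-form MLE), δ = 0, and the zero-part intercept at the
logit of the excess-zero fraction max(n₀/n − p̄₀, 1e-3) where p̄₀ is the
mean Poisson zero probability.  Convergence: gradient norm < 1e-8 or
relative likelihood change < 1e-13, at most 500 iterations;
non-convergence is flagged on the result, never silent.

Standard errors are square roots of the diagonal of the pseudo-inverse
of a central-difference Hessian of the negative log-likelihood at the
optimum (step 1e-5·(1+|θ|), differencing the analytic gradient).

Zero-part coefficients are bounded at ±30 on the logit scale.  When data
carry no structural zeros the likelihood is maximized as π → 0 and γ
drifts down a likelihood ridge that is flat to machine precision; where
a quasi-Newton method stops on that ridge is round-off dependent.  Any
|γ| ≥ 15 (π within 3e-7 of the boundary) is therefore (a) flagged as a
boundary estimate with unreliable SE — the classic symptom being a
hugely inflated SE on an insignificant zero-part coefficient — and
(b) pinned to ±30 exactly with the remaining parameters re-optimized,
*provided* pinning does not cost likelihood (with several zero-part
terms a large coefficient can be offset by another, in which case the
unpinned optimum is kept).  This makes boundary fits deterministic
across algebraically equivalent data representations.

Degenerate inputs are rejected with explicit errors: all-zero outcomes
(log of a zero mean), rank-deficient design matrices (the collinear
columns are named), unknown factor levels (the record index is named).

## Tests and comparison statistics

* Dispersion LRT: 2·(loglik_full − loglik_restricted) for Poisson ⊂ CMP
  and ZIP ⊂ ZICMP, floored at 0, referred to χ²(1).
* Zero-inflation LRT: CMP ⊂ ZICMP (and Poisson ⊂ ZIP), same reference.
  No boundary-null mixture correction is applied — the plain χ²(1)
  reference is the convention in the applied literature this package
  follows; it is conservative for testing π = 0, which the simulated
  type-I-error checks in the test suite confirm.
* Score test for zero inflation, computable from the Poisson null alone:
  S = (n₀ − n·p₀)² / (n·p₀(1−p₀) − n·ȳ·p₀²) with p₀ = exp(−ȳ).  The
  denominator is mathematically positive for any finite positive mean
  but can underflow for extreme means; that pathology is reported as an
  error.
* Goodness of fit: the generalized Pearson χ² Σ w_i (y_i − Ê_i)²/Ê_i
  with Ê_i the exact model mean (variant `pearson`).  A second variant,
  `ssq_approx_mean`, returns the *unnormalized* squared-deviation sum
  about the approximate CMP mean; it exists solely because some
  published CMP comparisons report that quantity under the Pearson
  label, and it is labelled as such in reports.  Note that for an
  intercept-only CMP fit the exact fitted mean equals the sample mean
  (ML moment matching), so variant `pearson` coincides with the Poisson
  value there — the dramatic "70% drop" sometimes reported for CMP
  columns is a property of the approximate-mean variant, not of Eq-style
  Pearson.
* AIC = −2·loglik + 2k with k the number of estimated coefficients.
* Cramér's V for covariate screening via the contingency χ²
  (no continuity correction).

## Synthetic data generator

`generate_covariates` draws the six categorical covariates
independently, with the marginal proportions observed in the 2015 study
year as packaged defaults (e.g. National highway 0.4319, Dry 0.9270,
Clear 0.9292, April 0.1829).  Independence is the generator's own
assumption: the real records show weak pairwise association (Cramér's V
up to 0.59), and dependence is deliberately not emulated.  The generator
also does not emulate spatial or temporal clustering, exposure/traffic
volume, or reporting artifacts.  Passing tests on synthetic data
therefore validate the estimation machinery, not the epidemiology of
real accident records.

`generate_deaths` draws per-row ZICMP outcomes at user-specified
coefficients by a two-stage scheme: Bernoulli(π_i) structural zero,
otherwise inversion of the row's cumulative CMP pmf; rows sharing a
parameter combination share one tabulated pmf.  One master seed spawns
independent child streams per replicate, and generated datasets
round-trip exactly through the CSV writer/reader.

## Identifiability of the intercept-only ZICMP

The recovery experiments (analysis/03) map an important practical
boundary.  At truths echoing the study's fitted intercepts (rate
intercept −1.1, dispersion intercept 0.44, zero intercept −1.0):

* n = 20,000, 50 replicates: intercept biases are within 3 Monte-Carlo
  standard errors of zero and 95% Wald coverage is 0.92–0.96.
* n = 5,000, 50 replicates: the likelihood develops a second mode in
  which a large-ν CMP degenerates toward a Bernoulli and absorbs the
  zero mass; estimates swing between modes and Wald coverage collapses
  to ~0.5–0.6 even though every replicate's fitted likelihood exceeds
  the likelihood at the generating truth.

At rates around 0.3 deaths per accident, separating structural zeros
from CMP zeros needs samples on the order of the study's own size; the
calibration claims in the acceptance tests are therefore made at
n = 20,000.  Simulation sizes used elsewhere in the suite (10⁵ draws for
sampler checks, 1,000 × 2,000 for score-test calibration, 50 × 20,000
for recovery) were chosen as the smallest sizes at which the Monte-Carlo
error bands in the assertions are decisive.

## Known limitations

* No negative-binomial or geometric fits; no Bayesian estimation; no
  random effects; no exposure offsets.
* Wald SEs at or near the π = 0 boundary are flagged rather than
  corrected; profile or bootstrap intervals are out of scope.
* The asymptotic moment formulas are supplied for reconciliation only
  and should not be used for inference at small rates.
* The packaged covariate coding assumes the study's level sets; other
  datasets must supply their own coding and code maps.
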