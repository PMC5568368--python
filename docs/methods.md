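# Methods

## Pooled significance tests after multiple imputation

Multiple imputation replaces each missing cell with m plausible draws from
its posterior predictive distribution, giving m completed datasets.  The
analysis model here is a logistic regression; fitting it to each completed
dataset gives m coefficient vectors, covariance matrices, deviances and
p-values, which the package pools in five ways.

**Rubin's Rules (RR).**  For one parameter, θ̄ = m⁻¹Σθⱼ with total variance
T = W + (1+1/m)B, where W is the mean within-imputation sampling variance and
B the between-imputation variance of the θⱼ.  The two-sided test refers
(θ̄−θ₀)²/T to χ²(1).  An optional small-sample reference (F(1, ν) with
ν = (m−1)(1+1/r)², r = (1+1/m)B/W) sits behind `reference="adjusted"`;
the χ²(1) reference is the default because it is the form the univariate
statistic is classically stated in, and at the package's default m and n the
difference is negligible.  RR cannot test a k-level factor as a whole —
that is the gap the remaining methods fill.

**D1, pooled sampling variance.**  With per-imputation coefficient blocks
θⱼ ∈ ℝᵏ and covariance blocks Uⱼ, let Ū be the average within covariance
and B the between covariance.  The average relative increase in variance is
r₁ = (1+1/m)·tr(BŪ⁻¹)/k and

    D1 = (θ̄−θ₀)′ Ū⁻¹ (θ̄−θ₀) / [k(1+r₁)],   D1 ~ F(k, ν₁).

**D2, combined chi-square.**  From per-imputation k-df statistics χ²ⱼ
(likelihood-ratio by default, Wald optionally): r₂ = (1+1/m)·var(√χ²ⱼ) and

    D2 = [mean(χ²ⱼ)/k − (m+1)/(m−1)·r₂] / (1+r₂),   D2 ~ F(k, ν₂),

floored at zero when the between-imputation correction exceeds the mean
statistic (the raw formula can go negative; a negative quadratic-form
statistic has no meaning and would give p > 1 territory).

**D3, likelihood-ratio pooling.**  Both nested models are fitted on every
completed dataset; d̄_L is the mean deviance difference at the per-imputation
MLEs and d̄_m the mean deviance difference re-evaluated at the averaged
coefficient vectors of each model.  With r₃ = (m+1)/[k(m−1)]·(d̄_L−d̄_m),

    D3 = d̄_m / [k(1+r₃)],   D3 ~ F(k, ν₃).

Sampling noise can make d̄_m exceed d̄_L; r₃ is floored at 0 (an estimated
fraction of missing information cannot be negative) and the statistic at 0.

**Median-P rule (MPR).**  The pooled p-value is the median of the m
per-imputation overall-test p-values; for even m, the mean of the two central
order statistics.  The rejection rule is the strict inequality
median p < α.  Its level-α validity rests on the per-imputation p-values
being multivariate normal after a probit transform — the diagnostic below
makes that assumption checkable in simulations.

**Denominator degrees of freedom.**  With t = k(m−1):

    ν_wald = 4 + (t−4)[1 + (1−2/t)/r]²   if t > 4,
             t(1+1/k)(1+1/r)²/2          otherwise      (D1, D3)
    ν_chi  = k^(−3/m) (m−1)(1+1/r)²                      (D2)

r = 0 yields ν = ∞, i.e. the χ²(k)/k reference.  The formulas live behind a
single `DfPolicy` object so an alternative rule can be swapped in without
touching the statistics; `DfPolicy(unbounded=True)` forces ν = ∞ everywhere,
which the degenerate-stack tests use to compare against complete-data
chi-square p-values.

Model fits use an in-package Newton–Raphson for binary and baseline-category
multinomial logistic regression (step-halving, warm starts).  The simulation
engine performs ~10⁵ small fits per design cell, which is why these are
written directly on numpy arrays; the test suite verifies coefficients,
covariances and log-likelihoods against statsmodels to ~1e-8.  Exactly
singular designs (e.g. a constant-zero column) take the minimum-norm Newton
step, pinning unidentified coefficients at zero so that dropping such a
covariate yields a zero likelihood-ratio statistic and p = 1.

## Chained-equations imputation

Each incomplete column is imputed in turn from a conditional model on all
other covariates (plus the outcome iff `include_outcome`), cycling
`iterations` times (default 10) before the completed copy is recorded; the m
imputations are independent chains with substreams spawned from one master
seed, so increasing m never alters earlier chains.  Conditional models:

- continuous — Bayesian linear regression under a flat prior: σ² is drawn
  from RSS/χ²(n_obs−p), coefficients from N(β̂, σ²(X′X)⁻¹), and predictive
  noise σ·z is added;
- binary / categorical — logistic / multinomial-logistic MLE with a
  coefficient vector drawn from the large-sample normal posterior
  approximation, then category membership drawn from the implied
  probabilities.

Parameter draws make the imputation *proper*: the between-imputation variance
B then reflects estimation uncertainty in the imputation model, which the
pooled tests rely on.  (Predictive mean matching, a common donor-based
alternative, is deliberately out of scope: it has donor-pool tie-breaking
degrees of freedom that are hard to pin down reproducibly.)  Separation in a
conditional fit is handled by refitting with a weak ridge (0.1), logged and
recorded in `ImputedStack.notes`.

## Simulation design

One design cell draws n = 250 cases of five standard normals with common
pairwise correlation ρ ∈ {0.2, 0.4, 0.6, 0.8}.  The first variable is cut at
its three sample quartiles into a 4-level factor (right-closed intervals,
ties to the lower level — a measure-zero event for continuous draws); the
rest remain continuous (Covar1..Covar4).  The outcome is Bernoulli with
probability expit(η), η = β₀ + Σγᵢdᵢ + β(C1+C2+C3+C4); the three dummy
coefficients γᵢ are redrawn each replication from N(0, s²).  The coefficient
grid ties s² = β, both running over {0.0, 0.1, …, 1.0}; β₀ defaults to 0
(outcome prevalence ~50%, configurable).  The inverse-logit link is the only
reading of the generating mechanism consistent with a logistic analysis
model.

Missingness is induced in the factor and in Covar1 by a missing-at-random
mechanism: the missingness log-odds are a + 1.0·z̄, where z̄ is the
standardized mean of the fully observed Covar2..Covar4 (slope 1.0 gives a
moderate, clearly-MAR dependence) and the intercept a is calibrated by root
finding so the *expected* missing fraction equals the target (0.25 or 0.40);
realized fractions vary binomially.

Each replication records full-data p-values (k-df LRT for the factor, 1-df
Wald for continuous covariates), imputes the incomplete data twice (outcome
included and excluded), applies every pooling method, and tabulates
rejections at α = 0.05 with Monte-Carlo standard errors √(p̂(1−p̂)/reps).
MPR_in pools the outcome-included per-imputation p-values, MPR_out the
outcome-excluded ones; RR/D1/D2/D3 use the outcome-included stack, the
recommended imputation for coefficient-based pooling.  Replications with a
non-convergent fit are flagged and excluded; tables carry effective counts.

**Problem sizes.**  The package's default profile is m = 10 imputations and
250 replications per cell — 10 imputations are the smallest m that still
allows the MVN diagnostic's inverse-covariance estimate, and 250
replications give rejection-rate standard errors ≤ 0.032.  The engine
accepts the full profile (m = 100, 1000 replications, the complete
correlation × coefficient × missingness grid) unchanged; only wall-clock
time grows.

**What the generator does and does not emulate.**  It reproduces the joint
covariate law, the quartile-cut factor, the MAR mechanism and the logistic
outcome exactly as specified, so passing tests demonstrate correct behaviour
of the pooling machinery under a *correctly specified* imputation model.
Real data bring misspecified conditional models, non-normal covariates,
interactions and MNAR mechanisms, none of which the generator produces —
conclusions about robustness to those do not follow from these tests.

## MVN diagnostic

For one variable, collect the per-imputation overall-test p-values over many
null replications into an n_sim × m matrix, map each p through the
standard-normal lower-tail quantile (the direction is irrelevant to a
Mahalanobis distance after centring; the lower tail is fixed for
determinism), estimate the mean vector and covariance across replications,
and compare each replication's squared Mahalanobis distance to χ²(m) by a
Kolmogorov–Smirnov statistic and decile QQ points.  n_sim must substantially
exceed m or the covariance is near-singular (the implementation raises and
suggests more replications or fewer imputations).

## Data-based bootstrap verification

To check the operating characteristics on one's own dataset: estimate the
covariate mean vector and covariance from the completed data (categorical
columns as integer level codes; a non-PSD estimate is repaired by eigenvalue
clipping, logged), draw bootstrap covariate samples of the original size from
that multivariate normal, re-discretize categorical columns by quantile-
cutting the drawn values at the original marginal category frequencies,
simulate the outcome through the logistic link from the pooled coefficients
of the covariates selected by median-P p < 0.05, re-apply the per-variable
missingness models (logistic fits of each missingness indicator on the fully
observed covariates, refitted from the incomplete data rather than resampling
the realized pattern), and push every sample through imputation and all
pooling methods.  Variables in the generating model yield power rows, the
others type-I-error rows.

## Known limitations

- The power *ordering* between the median-P rule under outcome-excluded
  imputation and the D1/D2/D3 tests is sensitive to the imputation variant.
  With this package's proper Bayesian-draw imputation, MPR_out is
  conservative under the null (rejection ≈ 0.02–0.03 at α = 0.05) and its
  power for the factor trails D1–D3 at small effect sizes; the gap does not
  close at m = 100.  Analysts choosing MPR for its simplicity should verify
  power on their own data with the bootstrap scheme rather than assume
  dominance.
- The D2/D3 denominator-df expressions are asymptotic; for k(m−1) ≤ 4 the
  small-sample variant is used but m = 2 remains fragile.
- The imputer supports continuous, binary and categorical columns only; no
  passive imputation, custom predictor matrices or convergence plots.
- The bootstrap's multivariate-normal covariate draw linearises dependence;
  strongly non-normal covariates are only rank-matched through the
  re-discretization step.
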