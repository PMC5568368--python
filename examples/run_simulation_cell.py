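"""Run one cell of the type-I-error/power simulation design.

Generates `reps` datasets under the null (all coefficients zero), deletes 25%
of Factor1 and Covar1 at random given the observed covariates, imputes each
dataset with and without the outcome in the imputation model, applies every
pooling method, and prints the rejection proportions at alpha = 0.05.  Under
the null these proportions estimate the type-I error; the mc_se column is the
binomial Monte-Carlo standard error sqrt(p(1-p)/reps).
"""
from mipool import SimulationCondition, run_condition

cond = SimulationCondition(
    n=250, correlation=0.2, beta_continuous=0.0, beta_cat_sd=0.0,
    miss_pct=0.25, m=10, reps=100, seed=42,
)
table = run_condition(cond)
print(table.table.to_string(index=False))
print(
    "\nRates near 0.05 mean the method holds its level; MPR_in on the "
    "incomplete continuous covariate (Covar1) is expected to exceed it — "
    "outcome-based imputation makes the median-P rule anti-conservative."
)
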