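# mipool

Significance testing of covariates — especially categorical covariates with
more than two levels — in logistic regression models fitted to multiply
imputed data.

## The problem

After multiple imputation (MI), an analysis model is fitted to each of the
*m* completed datasets and the results must be pooled.  For a single
coefficient, Rubin's Rules give the pooled estimate
θ̄ = m⁻¹ Σ θⱼ and total variance

    T = W + (1 + 1/m) B,     W = m⁻¹ Σ Var(θⱼ),   B = (m−1)⁻¹ Σ (θⱼ − θ̄)²,

and W_single = (θ̄ − θ₀)²/T is referred to χ²(1).  But a k-level categorical
covariate is one hypothesis on k−1 parameters, and Rubin's Rules alone give
only per-dummy p-values.  `mipool` implements the four ways to get one
overall p-value:

- **D1 (pooled sampling variance / multivariate Wald)** —
  D1 = (θ̄−θ₀)′Ū⁻¹(θ̄−θ₀) / [k(1+r₁)], with Ū the averaged within-imputation
  covariance, B the between-imputation covariance and
  r₁ = (1+1/m)·tr(BŪ⁻¹)/k the average relative increase in variance;
  referred to F(k, ν₁).
- **D2 (combined chi-square)** — pools the m per-imputation k-df Wald or
  likelihood-ratio statistics through their square roots;
  referred to F(k, ν₂).
- **D3 (Meng–Rubin likelihood-ratio pooling)** — fits the full and the
  restricted model on every completed dataset and combines the deviance
  differences, re-evaluated at the averaged coefficients; referred to
  F(k, ν₃).
- **MPR (median-P rule)** — the median of the m per-imputation overall-test
  p-values, rejecting when median p < α.  Nothing but p-values is pooled,
  so the rule works in any software that can run MI.

The package also ships a minimal chained-equations imputer with an explicit
outcome-inclusion switch (the median-P rule needs outcome-*excluded*
imputation to hold its level, while coefficient estimation wants the outcome
*included*), a simulation engine that measures type-I error and power of all
methods, the Mahalanobis/χ² diagnostic for the multivariate-normality
assumption behind the median-P rule, and a data-based bootstrap scheme to
verify all of this on one's own dataset.

## Worked example

```python
import numpy as np
from mipool import (SimulationCondition, analyse_stack, generate_complete_data,
                    impute, induce_mar, simulation_schema)

cond = SimulationCondition.from_beta(0.4, n=250, correlation=0.4, seed=1)
complete, truth = generate_complete_data(cond, np.random.default_rng(1))
incomplete = induce_mar(complete, 0.25, seed=2)      # 25% MAR in Factor1, Covar1
stack = impute(incomplete, simulation_schema(), m=15, seed=3)
results = analyse_stack(stack.datasets, simulation_schema(), ["Factor1"])
for method, res in results["Factor1"].items():
    print(method, round(res.statistic, 4), round(res.p_value, 4))
```

prints (seed-exact):

```
RR:Factor1[Q2] 0.2109 0.6461
RR:Factor1[Q3] 2.4629 0.1166
RR:Factor1[Q4] 0.1551 0.6937
D1 1.5332 0.2057
D2 1.5958 0.1941
D3 1.4986 0.2151
MPR 0.0398 0.0398
```

Each of D1/D2/D3/MPR tests the 4-level factor as a whole (3 parameters at
once); Rubin's Rules can only test each dummy separately.  Here the median
per-imputation likelihood-ratio p-value (0.0398) falls below 0.05 while the
three F-referenced tests stay above it — exactly the kind of disagreement
the simulation engine quantifies.  More narrative walk-throughs live in
`examples/`.

A thin CLI mirrors the library:

```bash
mipool simulate --n 250 --cor 0.4 --beta 0 --miss 0.25 --m 10 --reps 50 --seed 7 --out results/
mipool pool --data stack.csv --schema schema.json
mipool diagnose --pvalues pmatrix.csv
mipool bootstrap --data incomplete.csv --schema schema.json --n-boot 200
mipool fixtures --out fixtures/
```

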