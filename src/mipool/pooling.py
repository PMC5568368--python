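"""Rubin's Rules for scalar parameters and the pooled univariate Wald test.

After multiple imputation the same analysis is run on each of the m completed
datasets, giving estimates theta_j with sampling variances Var(theta_j).
Rubin's Rules combine them as

    theta_bar   = mean_j theta_j
    W (within)  = mean_j Var(theta_j)
    B (between) = sum_j (theta_j - theta_bar)^2 / (m - 1)
    T (total)   = W + (1 + 1/m) B

and the two-sided single-parameter Wald statistic is
(theta_bar - theta_0)^2 / T, referred to a chi-square(1) distribution by
default.  A Barnard–Rubin-style adjusted-denominator-df reference (F(1, nu)
with nu = (m - 1)(1 + 1/r)^2, r = (1 + 1/m) B / W) is available behind the
``reference`` flag for small m.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgument

#: relative tolerance for the total-variance identity check
VAR_TOTAL_RTOL = 1e-10


@dataclass(frozen=True)
class ImputedScalarEstimates:
    """Per-imputation estimates theta_j and sampling variances Var(theta_j)."""

    estimates: np.ndarray
    variances: np.ndarray

    def __post_init__(self) -> None:
        est = np.asarray(self.estimates, dtype=np.float64)
        var = np.asarray(self.variances, dtype=np.float64)
        if est.ndim != 1 or var.ndim != 1 or est.size != var.size:
            raise InvalidArgument("estimates and variances must be 1-d of equal length")
        if est.size < 1:
            raise InvalidArgument("need at least one imputation (m >= 1)")
        if np.any(var < 0):
            raise InvalidArgument("sampling variances must be nonnegative")
        object.__setattr__(self, "estimates", est)
        object.__setattr__(self, "variances", var)

    @property
    def m(self) -> int:
        return int(self.estimates.size)


@dataclass(frozen=True)
class PooledScalar:
    """Rubin-pooled estimate with its variance decomposition."""

    theta_bar: float
    var_within: float
    var_between: float
    var_total: float
    m: int

    def __post_init__(self) -> None:
        expected = self.var_within + (1.0 + 1.0 / self.m) * self.var_between
        scale = max(abs(expected), abs(self.var_total), 1e-300)
        if abs(expected - self.var_total) > VAR_TOTAL_RTOL * scale:
            raise InvalidArgument("var_total violates the total-variance identity")


@dataclass(frozen=True)
class TestResult:
    """A pooled significance test: statistic, reference df and p-value.

    ``df_den`` is ``inf`` for chi-square references.  For the median-P rule
    the statistic slot carries the median p-value itself.
    """

    statistic: float
    df_num: float
    df_den: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidArgument("p_value must be in [0, 1]")


def pool_scalar(est: ImputedScalarEstimates) -> PooledScalar:
    """Pool per-imputation scalar estimates with Rubin's Rules.

    For m = 1 the between-imputation variance is defined as 0, so the result
    reduces to the single completed-data analysis.
    """
    theta = est.estimates
    m = est.m
    theta_bar = float(theta.mean())
    var_within = float(est.variances.mean())
    if m == 1:
        var_between = 0.0
    else:
        var_between = float(np.sum((theta - theta_bar) ** 2) / (m - 1))
    var_total = var_within + (1.0 + 1.0 / m) * var_between
    return PooledScalar(
        theta_bar=theta_bar,
        var_within=var_within,
        var_between=var_between,
        var_total=var_total,
        m=m,
    )


def wald_univariate(
    pooled: PooledScalar,
    theta0: float = 0.0,
    *,
    reference: str = "chi2",
) -> TestResult:
    """Two-sided Wald test of theta = theta0 on Rubin-pooled quantities.

    reference="chi2" (default) refers the statistic to chi-square(1);
    reference="adjusted" uses F(1, nu) with the adjusted denominator df
    nu = (m - 1)(1 + 1/r)^2 where r = (1 + 1/m) B / W.
    """
    if pooled.var_total <= 0:
        raise InvalidArgument("wald_univariate requires var_total > 0")
    stat = (pooled.theta_bar - theta0) ** 2 / pooled.var_total
    if reference == "chi2":
        return TestResult(
            statistic=stat,
            df_num=1.0,
            df_den=np.inf,
            p_value=float(stats.chi2.sf(stat, 1)),
            method="RR-Wald",
        )
    if reference == "adjusted":
        if pooled.var_within <= 0:
            raise InvalidArgument("adjusted reference requires var_within > 0")
        r = (1.0 + 1.0 / pooled.m) * pooled.var_between / pooled.var_within
        nu = np.inf if r == 0 else (pooled.m - 1) * (1.0 + 1.0 / r) ** 2
        p = float(stats.chi2.sf(stat, 1)) if np.isinf(nu) else float(stats.f.sf(stat, 1, nu))
        return TestResult(statistic=stat, df_num=1.0, df_den=float(nu), p_value=p, method="RR-Wald")
    raise InvalidArgument(f"unknown reference {reference!r}")
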