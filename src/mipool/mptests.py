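"""Pooled significance tests for a k-parameter hypothesis after multiple
imputation.

Four routes to an overall p-value for (say) a categorical covariate tested as
a whole in a logistic regression fitted on each of m completed datasets:

D1 (VAR pooling)
    Multivariate Wald statistic on the pooled coefficients using the averaged
    within-imputation covariance matrix Ubar, corrected by the average
    relative increase in variance r1 = (1 + 1/m) tr(B Ubar^-1) / k, where B is
    the between-imputation covariance of the coefficient vectors:

        D1 = (theta_bar - theta0)' Ubar^-1 (theta_bar - theta0) / [k (1 + r1)]

D2 (CHI pooling)
    Combines the m per-imputation k-df chi-square statistics through their
    square roots: with r2 = (1 + 1/m) var(sqrt(chi2_j)),

        D2 = [mean(chi2_j)/k - (m+1)/(m-1) r2] / (1 + r2)   (floored at 0)

D3 (Meng–Rubin pooling)
    Combines likelihood-ratio statistics from nested fits: d_L is the mean of
    the per-imputation deviance differences at their own MLEs, d_m the mean
    deviance difference re-evaluated at the across-imputation average
    coefficient vectors of each model; r3 = (m+1)/[k(m-1)] (d_L - d_m) and

        D3 = d_m / [k (1 + r3)]

MPR (median-P rule)
    The median of the m per-imputation overall-test p-values, rejected when
    median p < alpha.  No statistic is pooled at all, which is what makes the
    rule applicable in any software that can run multiple imputation.

D1–D3 are referred to F(k, nu) with denominator df nu supplied by a
:class:`DfPolicy`; nu = inf recovers the chi-square(k)/k reference.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FitFailure, InvalidArgument, SingularMatrixError
from .glm import fit_logistic, logistic_loglik
from .pooling import ImputedScalarEstimates, TestResult, pool_scalar, wald_univariate
from .schema import DataSchema, design_matrix

__all__ = [
    "DfPolicy",
    "MultiParamEstimates",
    "ChiSquareStack",
    "PValueStack",
    "NestedModelPair",
    "d1_var_pooling",
    "d2_chi_pooling",
    "d3_meng_rubin",
    "mpr_median_p",
    "per_imputation_overall_test",
    "analyse_stack",
]


# ---------------------------------------------------------------------------
# denominator degrees of freedom
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DfPolicy:
    """Denominator-df rules for the F references of D1, D2 and D3.

    ``unbounded=True`` forces nu = inf for every test, which turns each F(k,
    nu) reference into chi-square(k)/k; useful for oracle comparisons against
    complete-data tests.  The default rules are the canonical ones from the
    multivariate-Wald, combined-chi-square and likelihood-ratio pooling
    literature: with t = k(m-1),

        nu_wald = 4 + (t - 4) [1 + (1 - 2/t)/r]^2        if t > 4
                  t (1 + 1/k) (1 + 1/r)^2 / 2            otherwise
        nu_chi  = k^(-3/m) (m - 1) (1 + 1/r)^2

    D1 and D3 use nu_wald, D2 uses nu_chi; r = 0 gives nu = inf.
    """

    unbounded: bool = False

    def _wald_style(self, k: int, m: int, r: float) -> float:
        if self.unbounded or r <= 0:
            return np.inf
        t = k * (m - 1)
        if t > 4:
            return 4.0 + (t - 4.0) * (1.0 + (1.0 - 2.0 / t) / r) ** 2
        return t * (1.0 + 1.0 / k) * (1.0 + 1.0 / r) ** 2 / 2.0

    def d1(self, k: int, m: int, r: float) -> float:
        return self._wald_style(k, m, r)

    def d2(self, k: int, m: int, r: float) -> float:
        if self.unbounded or r <= 0:
            return np.inf
        return k ** (-3.0 / m) * (m - 1.0) * (1.0 + 1.0 / r) ** 2

    def d3(self, k: int, m: int, r: float) -> float:
        return self._wald_style(k, m, r)


DEFAULT_DF_POLICY = DfPolicy()


def _f_sf(stat: float, k: float, nu: float) -> float:
    """Upper tail of F(k, nu), with nu = inf meaning chi-square(k)/k."""
    if np.isinf(nu):
        return float(stats.chi2.sf(stat * k, k))
    return float(stats.f.sf(stat, k, nu))


# ---------------------------------------------------------------------------
# input containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MultiParamEstimates:
    """Per-imputation coefficient vectors and their covariance matrices."""

    thetas: np.ndarray       # (m, k)
    covariances: np.ndarray  # (m, k, k)

    def __post_init__(self) -> None:
        th = np.atleast_2d(np.asarray(self.thetas, dtype=np.float64))
        cov = np.asarray(self.covariances, dtype=np.float64)
        if cov.ndim == 2:
            cov = cov[None, :, :]
        if th.ndim != 2 or cov.ndim != 3:
            raise InvalidArgument("thetas must be (m,k), covariances (m,k,k)")
        m, k = th.shape
        if cov.shape != (m, k, k):
            raise InvalidArgument("covariance stack shape inconsistent with thetas")
        if not np.allclose(cov, np.swapaxes(cov, 1, 2), atol=1e-8):
            raise InvalidArgument("covariance matrices must be symmetric")
        if np.any(np.einsum("mkk->mk", cov) < -1e-12):
            raise InvalidArgument("covariance matrices must have nonnegative diagonals")
        object.__setattr__(self, "thetas", th)
        object.__setattr__(self, "covariances", cov)

    @property
    def m(self) -> int:
        return self.thetas.shape[0]

    @property
    def k(self) -> int:
        return self.thetas.shape[1]


@dataclass(frozen=True)
class ChiSquareStack:
    """m per-imputation chi-square statistics, each on k df."""

    chi2: np.ndarray
    k: int

    def __post_init__(self) -> None:
        c = np.asarray(self.chi2, dtype=np.float64).ravel()
        if c.size < 2:
            raise InvalidArgument("D2 needs m >= 2 chi-square values")
        if np.any(c < 0):
            raise InvalidArgument("chi-square statistics must be nonnegative")
        if self.k < 1:
            raise InvalidArgument("k must be >= 1")
        object.__setattr__(self, "chi2", c)

    @property
    def m(self) -> int:
        return self.chi2.size


@dataclass(frozen=True)
class PValueStack:
    """m per-imputation overall-test p-values."""

    pvalues: np.ndarray
    test_label: str = "lrt"

    def __post_init__(self) -> None:
        p = np.asarray(self.pvalues, dtype=np.float64).ravel()
        if p.size < 1:
            raise InvalidArgument("need at least one p-value")
        if np.any((p < 0) | (p > 1)):
            raise InvalidArgument("p-values must lie in [0, 1]")
        object.__setattr__(self, "pvalues", p)

    @property
    def m(self) -> int:
        return self.pvalues.size


@dataclass(frozen=True)
class NestedModelPair:
    """A full and a restricted logistic model over m completed datasets.

    Stored as per-imputation design matrices; the restricted design must be a
    strict column subset of the full design (the dropped block is the tested
    covariate, k = difference in column count).
    """

    y: tuple[np.ndarray, ...]
    X_full: tuple[np.ndarray, ...]
    X_restricted: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        m = len(self.y)
        if not (len(self.X_full) == len(self.X_restricted) == m) or m < 1:
            raise InvalidArgument("inconsistent number of completed datasets")
        pf = self.X_full[0].shape[1]
        pr = self.X_restricted[0].shape[1]
        if pr >= pf:
            raise InvalidArgument("restricted model must have strictly fewer parameters")
        for j in range(m):
            if self.X_full[j].shape[1] != pf or self.X_restricted[j].shape[1] != pr:
                raise InvalidArgument("parameter counts differ across imputations")

    @classmethod
    def from_datasets(
        cls,
        datasets: list[pd.DataFrame],
        schema: DataSchema,
        tested: str,
    ) -> "NestedModelPair":
        ys, Xf, Xr = [], [], []
        for df in datasets:
            X, y, _ = design_matrix(df, schema)
            Xres, _, _ = design_matrix(df, schema, drop=(tested,))
            ys.append(y)
            Xf.append(X)
            Xr.append(Xres)
        return cls(tuple(ys), tuple(Xf), tuple(Xr))

    @property
    def m(self) -> int:
        return len(self.y)

    @property
    def k(self) -> int:
        return self.X_full[0].shape[1] - self.X_restricted[0].shape[1]


# ---------------------------------------------------------------------------
# the four pooled tests
# ---------------------------------------------------------------------------

def d1_var_pooling(
    est: MultiParamEstimates,
    theta0: np.ndarray | None = None,
    *,
    df_policy: DfPolicy = DEFAULT_DF_POLICY,
) -> TestResult:
    """Pooled-sampling-variance multivariate Wald test (D1)."""
    m, k = est.m, est.k
    if m < 2:
        raise InvalidArgument("D1 needs m >= 2 imputations")
    t0 = np.zeros(k) if theta0 is None else np.asarray(theta0, dtype=np.float64)
    if t0.shape != (k,):
        raise InvalidArgument("theta0 must have length k")
    theta_bar = est.thetas.mean(axis=0)
    Ubar = est.covariances.mean(axis=0)
    dev = est.thetas - theta_bar
    B = dev.T @ dev / (m - 1)
    try:
        Uinv = np.linalg.inv(Ubar)
    except np.linalg.LinAlgError as exc:
        raise SingularMatrixError(
            f"average within-covariance matrix is singular for the {k} tested parameters"
        ) from exc
    if not np.all(np.isfinite(Uinv)) or np.linalg.cond(Ubar) > 1e12:
        raise SingularMatrixError(
            f"average within-covariance matrix is ill-conditioned for the {k} tested parameters"
        )
    r1 = (1.0 + 1.0 / m) * float(np.trace(B @ Uinv)) / k
    diff = theta_bar - t0
    stat = float(diff @ Uinv @ diff) / (k * (1.0 + r1))
    nu = df_policy.d1(k, m, r1)
    return TestResult(statistic=stat, df_num=float(k), df_den=float(nu),
                      p_value=_f_sf(stat, k, nu), method="D1")


def d2_chi_pooling(
    stack: ChiSquareStack,
    *,
    df_policy: DfPolicy = DEFAULT_DF_POLICY,
) -> TestResult:
    """Combined chi-square test over per-imputation k-df statistics (D2)."""
    c, m, k = stack.chi2, stack.m, stack.k
    root = np.sqrt(c)
    r2 = (1.0 + 1.0 / m) * float(np.var(root, ddof=1))
    stat = (float(c.mean()) / k - (m + 1.0) / (m - 1.0) * r2) / (1.0 + r2)
    stat = max(stat, 0.0)  # the correction can exceed the mean statistic
    nu = df_policy.d2(k, m, r2)
    return TestResult(statistic=stat, df_num=float(k), df_den=float(nu),
                      p_value=_f_sf(stat, k, nu), method="D2")


def d3_meng_rubin(
    pair: NestedModelPair,
    *,
    df_policy: DfPolicy = DEFAULT_DF_POLICY,
) -> TestResult:
    """Meng–Rubin pooled likelihood-ratio test (D3).

    Fits both nested logistic models on every completed dataset, then
    re-evaluates the deviance difference at the across-imputation mean
    coefficients of each model.
    """
    m, k = pair.m, pair.k
    betas_f, betas_r = [], []
    ll_f, ll_r = [], []
    bf = br = None
    for j in range(m):
        try:
            fit_f = fit_logistic(pair.X_full[j], pair.y[j], beta0=bf)
            fit_r = fit_logistic(pair.X_restricted[j], pair.y[j], beta0=br)
        except (FitFailure, SingularMatrixError) as exc:
            raise FitFailure(f"model fit failed on imputation {j + 1}: {exc}") from exc
        bf, br = fit_f.beta, fit_r.beta
        betas_f.append(fit_f.beta)
        betas_r.append(fit_r.beta)
        ll_f.append(fit_f.loglik)
        ll_r.append(fit_r.loglik)
    d_L = 2.0 * (np.asarray(ll_f) - np.asarray(ll_r))
    beta_f_bar = np.mean(betas_f, axis=0)
    beta_r_bar = np.mean(betas_r, axis=0)
    d_m = np.array(
        [
            2.0
            * (
                logistic_loglik(beta_f_bar, pair.X_full[j], pair.y[j])
                - logistic_loglik(beta_r_bar, pair.X_restricted[j], pair.y[j])
            )
            for j in range(m)
        ]
    )
    d_L_bar = float(d_L.mean())
    d_m_bar = float(d_m.mean())
    if m > 1:
        r3 = (m + 1.0) / (k * (m - 1.0)) * (d_L_bar - d_m_bar)
    else:
        r3 = 0.0
    r3 = max(r3, 0.0)  # sampling noise can make d_m exceed d_L
    stat = max(d_m_bar / (k * (1.0 + r3)), 0.0)
    nu = df_policy.d3(k, m, r3)
    return TestResult(statistic=stat, df_num=float(k), df_den=float(nu),
                      p_value=_f_sf(stat, k, nu), method="D3")


def mpr_median_p(stack: PValueStack, alpha: float = 0.05) -> TestResult:
    """Median-P rule: the pooled p-value is the median of the m p-values.

    For even m the median is the mean of the two central order statistics;
    the significance rule is the strict inequality median p < alpha.  The
    returned statistic slot carries the median itself.
    """
    if not 0.0 < alpha < 1.0:
        raise InvalidArgument("alpha must be in (0, 1)")
    med = float(np.median(stack.pvalues))
    return TestResult(statistic=med, df_num=np.nan, df_den=np.nan,
                      p_value=med, method="MPR")


def mpr_rejects(result: TestResult, alpha: float = 0.05) -> bool:
    """Strict-inequality rejection rule for the median-P test."""
    return result.p_value < alpha


# ---------------------------------------------------------------------------
# per-imputation overall test and stack-level orchestration
# ---------------------------------------------------------------------------

def per_imputation_overall_test(
    df: pd.DataFrame,
    schema: DataSchema,
    tested: str,
    *,
    statistic: str = "lrt",
) -> tuple[float, float]:
    """k-df overall test for dropping ``tested`` on one completed dataset.

    statistic="lrt" (default) compares the deviances of the nested fits;
    statistic="wald" uses the quadratic form in the tested coefficient block.
    Returns (chi-square value, p-value on k df).
    """
    X, y, info = design_matrix(df, schema)
    if tested not in info.slices:
        raise InvalidArgument(f"covariate {tested!r} not in the model")
    k = info.slices[tested].stop - info.slices[tested].start
    fit_full = fit_logistic(X, y)
    if statistic == "lrt":
        Xr, _, _ = design_matrix(df, schema, drop=(tested,))
        fit_r = fit_logistic(Xr, y)
        chi2 = max(2.0 * (fit_full.loglik - fit_r.loglik), 0.0)
    elif statistic == "wald":
        sl = info.slices[tested]
        b = fit_full.beta[sl]
        V = fit_full.cov[sl, sl]
        chi2 = float(b @ np.linalg.solve(V, b))
    else:
        raise InvalidArgument("statistic must be 'lrt' or 'wald'")
    return chi2, float(stats.chi2.sf(chi2, k))


def analyse_stack(
    datasets: list[pd.DataFrame],
    schema: DataSchema,
    tested: list[str] | None = None,
    *,
    methods: tuple[str, ...] = ("RR", "D1", "D2", "D3", "MPR"),
    df_policy: DfPolicy = DEFAULT_DF_POLICY,
    per_imp_statistic: str = "lrt",
    alpha: float = 0.05,
) -> dict[str, dict[str, TestResult]]:
    """Run every requested pooled test for every tested covariate on a stack
    of m completed datasets sharing one analysis model.

    Returns ``{covariate: {method: TestResult}}``.  For categorical
    covariates RR yields per-dummy results under keys ``"RR:<label>"`` (no
    overall RR p-value exists); continuous covariates get a single ``"RR"``.
    """
    m = len(datasets)
    if m < 1:
        raise InvalidArgument("need at least one completed dataset")
    if tested is None:
        tested = [c.name for c in schema.covariates]

    # one full fit per completed dataset, reused by every covariate
    designs = []
    bf = None
    for j, df in enumerate(datasets):
        X, y, info = design_matrix(df, schema)
        try:
            fit = fit_logistic(X, y, beta0=bf)
        except (FitFailure, SingularMatrixError) as exc:
            raise FitFailure(f"full-model fit failed on imputation {j + 1}: {exc}") from exc
        bf = fit.beta
        designs.append((X, y, info, fit))

    out: dict[str, dict[str, TestResult]] = {}
    for name in tested:
        info0 = designs[0][2]
        if name not in info0.slices:
            raise InvalidArgument(f"covariate {name!r} not in the model")
        sl = info0.slices[name]
        k = sl.stop - sl.start
        res: dict[str, TestResult] = {}

        thetas = np.array([fit.beta[sl] for _, _, _, fit in designs])
        covs = np.array([fit.cov[sl, sl] for _, _, _, fit in designs])

        # restricted fits (needed by LRT-based D2/D3/MPR)
        need_restricted = per_imp_statistic == "lrt" and any(
            meth in methods for meth in ("D2", "D3", "MPR")
        ) or "D3" in methods
        rfits = []
        if need_restricted:
            br = None
            for j, df in enumerate(datasets):
                Xr, yr, _ = design_matrix(df, schema, drop=(name,))
                try:
                    fr = fit_logistic(Xr, yr, beta0=br)
                except (FitFailure, SingularMatrixError) as exc:
                    raise FitFailure(
                        f"restricted fit (dropping {name!r}) failed on imputation {j + 1}: {exc}"
                    ) from exc
                br = fr.beta
                rfits.append((Xr, fr))

        chi2_j = p_j = None
        if any(meth in methods for meth in ("D2", "D3", "MPR")):
            if per_imp_statistic == "lrt":
                chi2_j = np.array(
                    [
                        max(2.0 * (designs[j][3].loglik - rfits[j][1].loglik), 0.0)
                        for j in range(m)
                    ]
                )
            else:
                chi2_j = np.array(
                    [float(th @ np.linalg.solve(cv, th)) for th, cv in zip(thetas, covs)]
                )
            p_j = stats.chi2.sf(chi2_j, k)

        if "RR" in methods:
            if k == 1:
                pooled = pool_scalar(
                    ImputedScalarEstimates(thetas[:, 0], covs[:, 0, 0])
                )
                res["RR"] = wald_univariate(pooled)
            else:
                labels = designs[0][2].names[sl]
                for i, lab in enumerate(labels):
                    pooled = pool_scalar(
                        ImputedScalarEstimates(thetas[:, i], covs[:, i, i])
                    )
                    res[f"RR:{lab}"] = wald_univariate(pooled)
        if "D1" in methods and m >= 2:
            res["D1"] = d1_var_pooling(
                MultiParamEstimates(thetas, covs), df_policy=df_policy
            )
        if "D2" in methods and m >= 2:
            res["D2"] = d2_chi_pooling(
                ChiSquareStack(chi2_j, k), df_policy=df_policy
            )
        if "D3" in methods:
            betas_f = np.array([fit.beta for _, _, _, fit in designs])
            betas_r = np.array([fr.beta for _, fr in rfits])
            bf_bar = betas_f.mean(axis=0)
            br_bar = betas_r.mean(axis=0)
            d_L = chi2_j if per_imp_statistic == "lrt" else np.array(
                [
                    max(2.0 * (designs[j][3].loglik - rfits[j][1].loglik), 0.0)
                    for j in range(m)
                ]
            )
            d_m = np.array(
                [
                    2.0
                    * (
                        logistic_loglik(bf_bar, designs[j][0], designs[j][1])
                        - logistic_loglik(br_bar, rfits[j][0], designs[j][1])
                    )
                    for j in range(m)
                ]
            )
            d_L_bar, d_m_bar = float(d_L.mean()), float(d_m.mean())
            r3 = 0.0 if m == 1 else max(
                (m + 1.0) / (k * (m - 1.0)) * (d_L_bar - d_m_bar), 0.0
            )
            stat = max(d_m_bar / (k * (1.0 + r3)), 0.0)
            nu = df_policy.d3(k, m, r3)
            res["D3"] = TestResult(
                statistic=stat, df_num=float(k), df_den=float(nu),
                p_value=_f_sf(stat, k, nu), method="D3",
            )
        if "MPR" in methods:
            res["MPR"] = mpr_median_p(PValueStack(p_j), alpha=alpha)
        out[name] = res
    return out
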