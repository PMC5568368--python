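"""Diagnostics and data-based verification.

Two tools:

``mvn_check``
    The median-P rule's type-I-error guarantee rests on the per-imputation
    p-value vector being multivariate normal after a probit transform.  On
    simulated replications this is checkable: transform each p to the normal
    scale, estimate the mean and covariance across replications, and compare
    the squared Mahalanobis distances with their asymptotic chi-square(m)
    reference (m = number of imputations).

``databased_bootstrap``
    A verification scheme for a user's own dataset: draw bootstrap covariate
    samples from a multivariate normal fitted to the (completed) data,
    simulate the outcome from the significant pooled coefficients through the
    logistic link, re-apply the dataset's missingness pattern, and push every
    bootstrap sample through imputation + all pooling methods.  Variables in
    the generating model yield power estimates; the rest yield type-I error.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .errors import FitFailure, InvalidArgument, SingularMatrixError
from .glm import fit_logistic
from .impute import impute
from .mptests import DEFAULT_DF_POLICY, DfPolicy, analyse_stack
from .schema import CONTINUOUS, DataSchema, design_matrix
from .simulate import RejectionTable, mc_se

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PValueMatrix:
    """n_sim x m matrix of per-imputation p-values (rows = replications)."""

    pvalues: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.pvalues, dtype=np.float64)
        if p.ndim != 2:
            raise InvalidArgument("p-value matrix must be 2-d (n_sim x m)")
        if np.any((p <= 0.0) | (p >= 1.0)):
            raise InvalidArgument("all p-values must lie strictly in (0, 1)")
        object.__setattr__(self, "pvalues", p)

    @property
    def n_sim(self) -> int:
        return self.pvalues.shape[0]

    @property
    def m(self) -> int:
        return self.pvalues.shape[1]


@dataclass(frozen=True)
class MahalanobisDiagnostic:
    """Squared Mahalanobis distances of probit-transformed p-value vectors
    with a goodness-of-fit summary against chi-square(m)."""

    d_squared: np.ndarray
    df: int
    ks_statistic: float
    ks_pvalue: float
    qq_theoretical: np.ndarray
    qq_empirical: np.ndarray

    @property
    def distances(self) -> np.ndarray:
        return np.sqrt(self.d_squared)


def mvn_check(pm: PValueMatrix) -> MahalanobisDiagnostic:
    """Check the multivariate-normal assumption behind the median-P rule.

    Each p-value is mapped to the standard-normal scale by the lower-tail
    quantile function; the squared Mahalanobis distance of every replication
    from the estimated mean (with the estimated covariance) is compared to
    chi-square(m) via a Kolmogorov–Smirnov statistic and decile QQ points.
    """
    if pm.n_sim <= pm.m + 1:
        raise InvalidArgument(
            "n_sim must substantially exceed m to estimate the inverse covariance"
        )
    Z = stats.norm.ppf(pm.pvalues)
    mu = Z.mean(axis=0)
    S = np.cov(Z, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    if np.linalg.cond(S) > 1e12 or not np.all(np.isfinite(S)):
        raise SingularMatrixError(
            "estimated covariance of transformed p-values is singular; "
            "use more replications or fewer imputations"
        )
    dev = Z - mu
    d2 = np.einsum("ij,ij->i", dev, np.linalg.solve(S, dev.T).T)
    ks = stats.kstest(d2, "chi2", args=(pm.m,))
    qs = np.arange(0.1, 1.0, 0.1)
    return MahalanobisDiagnostic(
        d_squared=d2,
        df=pm.m,
        ks_statistic=float(ks.statistic),
        ks_pvalue=float(ks.pvalue),
        qq_theoretical=stats.chi2.ppf(qs, pm.m),
        qq_empirical=np.quantile(d2, qs),
    )


def ks_critical_value(n: int, alpha: float = 0.01) -> float:
    """Asymptotic Kolmogorov–Smirnov critical value at level alpha."""
    return float(np.sqrt(-0.5 * np.log(alpha / 2.0)) / np.sqrt(n))


# ---------------------------------------------------------------------------
# data-based bootstrap verification
# ---------------------------------------------------------------------------

def nearest_psd(S: np.ndarray, eps: float = 1e-10) -> np.ndarray:
    """Project a symmetric matrix to the nearest positive semi-definite one
    by clipping negative eigenvalues."""
    S = 0.5 * (S + S.T)
    w, V = np.linalg.eigh(S)
    if np.all(w > eps):
        return S
    logger.warning("covariance matrix not positive definite; repairing by eigenvalue clipping")
    w = np.clip(w, eps, None)
    return V @ np.diag(w) @ V.T


def _numeric_code(df: pd.DataFrame, schema: DataSchema) -> pd.DataFrame:
    """Covariates as numeric columns: categorical/binary as level codes."""
    out = {}
    for c in schema.covariates:
        if c.kind == CONTINUOUS:
            out[c.name] = df[c.name].to_numpy(dtype=np.float64)
        else:
            codes = np.full(len(df), -1, dtype=np.float64)
            for i, lv in enumerate(c.levels):
                codes[df[c.name].to_numpy() == lv] = i
            out[c.name] = codes
    return pd.DataFrame(out)


def fit_mar_models(incomplete: pd.DataFrame, schema: DataSchema) -> dict[str, tuple]:
    """Fit a logistic missingness model per incomplete covariate on the fully
    observed covariates; returns {name: (predictor names, coefficients)}."""
    observed = [
        c.name
        for c in schema.covariates
        if not incomplete[c.name].isna().any() and c.kind == CONTINUOUS
    ]
    models = {}
    for c in schema.covariates:
        ind = incomplete[c.name].isna().to_numpy().astype(np.float64)
        if ind.sum() == 0:
            continue
        X = np.column_stack(
            [np.ones(len(incomplete))]
            + [incomplete[p].to_numpy(dtype=np.float64) for p in observed]
        )
        try:
            fit = fit_logistic(X, ind)
        except (FitFailure, SingularMatrixError):
            fit = fit_logistic(X, ind, ridge=0.1)
        models[c.name] = (tuple(observed), fit.beta)
    return models


def application_verification(
    incomplete: pd.DataFrame,
    schema: DataSchema,
    *,
    m: int = 10,
    iterations: int = 5,
    n_boot: int = 100,
    alpha: float = 0.05,
    methods: tuple[str, ...] = ("RR", "D1", "D2", "D3", "MPR_in", "MPR_out"),
    seed: int | None = None,
) -> RejectionTable:
    """End-to-end data-based verification starting from an incomplete dataset.

    Imputes the data twice (outcome included for coefficient estimation,
    excluded for the median-P selection of categorical covariates), pools the
    coefficients by averaging, keeps the covariates whose median-P-rule
    p-value falls below ``alpha`` as the generating model, refits the
    per-variable missingness models, and runs :func:`databased_bootstrap`.
    """
    ss = np.random.SeedSequence(seed)
    s_ref, s_in, s_out, s_boot = ss.spawn(4)
    # single imputation provides the completed reference dataset
    completed = impute(
        incomplete, schema, 1, iterations=iterations,
        include_outcome=True, seed=s_ref,
    ).datasets[0]
    stack_in = impute(
        incomplete, schema, m, iterations=iterations,
        include_outcome=True, seed=s_in,
    )
    stack_out = impute(
        incomplete, schema, m, iterations=iterations,
        include_outcome=False, seed=s_out,
    )
    cov_names = [c.name for c in schema.covariates]
    res_out = analyse_stack(stack_out.datasets, schema, cov_names, methods=("MPR",))
    selected = {v for v in cov_names if res_out[v]["MPR"].p_value < alpha}

    # pooled coefficients (average across imputations) restricted to selection
    betas = []
    info = None
    for df in stack_in.datasets:
        X, y, info = design_matrix(df, schema)
        betas.append(fit_logistic(X, y).beta)
    beta_bar = np.mean(betas, axis=0)
    coefficients = {"Intercept": float(beta_bar[0])}
    for v in selected:
        sl = info.slices[v]
        for i in range(sl.start, sl.stop):
            coefficients[info.names[i]] = float(beta_bar[i])

    miss_models = fit_mar_models(incomplete, schema)
    return databased_bootstrap(
        completed, schema, coefficients,
        selected=selected, miss_models=miss_models,
        n_boot=n_boot, m=m, iterations=iterations,
        methods=methods, alpha=alpha,
        seed=int(s_boot.generate_state(1)[0] % (2**31 - 1)),
    )


def databased_bootstrap(
    completed: pd.DataFrame,
    schema: DataSchema,
    coefficients: dict[str, float],
    *,
    selected: set[str] | None = None,
    miss_models: dict[str, tuple] | None = None,
    n_boot: int = 100,
    m: int = 10,
    iterations: int = 5,
    methods: tuple[str, ...] = ("RR", "D1", "D2", "D3", "MPR_in", "MPR_out"),
    alpha: float = 0.05,
    df_policy: DfPolicy = DEFAULT_DF_POLICY,
    seed: int | None = None,
) -> RejectionTable:
    """Verify type-I error and power of the pooling methods on one's own data.

    Parameters
    ----------
    completed : the dataset with no missing cells (e.g. singly imputed).
    coefficients : generating logistic coefficients keyed by design-column
        label (as produced by :func:`mipool.schema.design_matrix`), usually
        the pooled estimates of the significant covariates only.
    selected : covariate names present in the generating model (power rows);
        inferred from nonzero coefficient labels when omitted.
    miss_models : per-variable MAR missingness models from
        :func:`fit_mar_models`; omit for a no-missingness run.
    """
    rng_master = np.random.SeedSequence(seed)
    n = len(completed)
    num = _numeric_code(completed, schema)
    mean = num.mean().to_numpy()
    cov = nearest_psd(np.cov(num.to_numpy(), rowvar=False, ddof=1))
    L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    cov_names = [c.name for c in schema.covariates]

    # marginal category frequencies for re-discretizing categorical draws
    cat_cuts: dict[str, np.ndarray] = {}
    for c in schema.covariates:
        if c.kind != CONTINUOUS:
            freqs = (
                pd.Series(completed[c.name]).value_counts(normalize=True)
                .reindex(list(c.levels)).fillna(0.0).to_numpy()
            )
            cat_cuts[c.name] = np.cumsum(freqs)[:-1]

    if selected is None:
        selected = set()
        for c in schema.covariates:
            labels = (
                [c.name]
                if c.kind == CONTINUOUS
                else [f"{c.name}[{lv}]" for lv in c.levels[1:]]
            )
            if any(coefficients.get(lab, 0.0) != 0.0 for lab in labels):
                selected.add(c.name)

    rejects: dict[tuple[str, str], int] = {}
    effective: dict[tuple[str, str], int] = {}
    need_in = any(mth in methods for mth in ("RR", "D1", "D2", "D3", "MPR_in"))
    stack_methods = tuple(
        mth for mth in ("RR", "D1", "D2", "D3") if mth in methods
    ) + (("MPR",) if "MPR_in" in methods else ())
    failures = 0

    for boot_ss in rng_master.spawn(n_boot):
        streams = boot_ss.spawn(3)
        rng = np.random.default_rng(streams[0])
        draw = mean + rng.standard_normal((n, len(cov_names))) @ L.T
        df = pd.DataFrame(draw, columns=cov_names)
        for name, cuts in cat_cuts.items():
            # quantile-cut the normal draw at the original category frequencies
            ranks = stats.rankdata(df[name].to_numpy(), method="ordinal") / n
            codes = np.searchsorted(cuts, ranks, side="left")
            levels = np.asarray(list(schema[name].levels), dtype=object)
            df[name] = levels[codes]
        out_spec = schema.outcome
        df[out_spec.name] = 0  # placeholder so design_matrix can run
        X, _, info = design_matrix(df, schema)
        beta = np.array([coefficients.get(lab, 0.0) for lab in info.names])
        prob = expit(X @ beta)
        y = (rng.random(n) < prob).astype(np.int64)
        df[out_spec.name] = np.asarray(out_spec.levels, dtype=object)[y]
        try:
            df[out_spec.name] = df[out_spec.name].astype(completed[out_spec.name].dtype)
        except (TypeError, ValueError):
            pass

        incomplete = df.copy()
        if miss_models:
            for vname, (pred, b) in miss_models.items():
                Xm = np.column_stack(
                    [np.ones(n)] + [df[p].to_numpy(dtype=np.float64) for p in pred]
                )
                mask = rng.random(n) < expit(Xm @ b)
                if incomplete[vname].dtype.kind in "if":
                    col = incomplete[vname].to_numpy(dtype=np.float64).copy()
                    col[mask] = np.nan
                else:
                    col = incomplete[vname].to_numpy(dtype=object).copy()
                    col[mask] = None
                incomplete[vname] = col

        try:
            results: dict[str, dict] = {}
            if need_in:
                stack = impute(
                    incomplete, schema, m,
                    iterations=iterations, include_outcome=True, seed=streams[1],
                )
                results["in"] = analyse_stack(
                    stack.datasets, schema, cov_names,
                    methods=stack_methods, df_policy=df_policy,
                )
            if "MPR_out" in methods:
                stack_o = impute(
                    incomplete, schema, m,
                    iterations=iterations, include_outcome=False, seed=streams[2],
                )
                results["out"] = analyse_stack(
                    stack_o.datasets, schema, cov_names,
                    methods=("MPR",), df_policy=df_policy,
                )
        except (FitFailure, SingularMatrixError):
            failures += 1
            continue

        for v in cov_names:
            for mth in methods:
                if mth == "MPR_out":
                    res = results.get("out", {}).get(v, {}).get("MPR")
                elif mth == "MPR_in":
                    res = results.get("in", {}).get(v, {}).get("MPR")
                else:
                    res = results.get("in", {}).get(v, {}).get(mth)
                if res is None:
                    continue
                key = (v, mth)
                effective[key] = effective.get(key, 0) + 1
                if res.p_value < alpha:
                    rejects[key] = rejects.get(key, 0) + 1

    rows = []
    for v in cov_names:
        for mth in methods:
            key = (v, mth)
            if key not in effective:
                continue
            n_eff = effective[key]
            rate = rejects.get(key, 0) / n_eff
            rows.append(
                {
                    "variable": v,
                    "method": mth,
                    "in_model": v in selected,
                    "rejection_rate": rate,
                    "mc_se": mc_se(rate, n_eff),
                    "reps_effective": n_eff,
                }
            )
    return RejectionTable(
        table=pd.DataFrame(rows),
        condition={"n_boot": n_boot, "m": m, "alpha": alpha, "seed": seed,
                   "failures": failures},
        alpha=alpha,
    )
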