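"""Simulation engine: type-I error and power of the pooling methods.

The design emulated here: n cases of five jointly normal covariates with a
common pairwise correlation; the first is cut at its sample quartiles into a
4-level factor (Factor1, entering the model as three dummies), the remaining
four stay continuous (Covar1..Covar4).  A binary outcome is drawn from a
logistic model whose continuous coefficients share one value and whose three
dummy coefficients are drawn from N(0, beta_cat_sd^2), by default redrawn
each replication.  Missingness is then induced in Factor1 and Covar1 by a
missing-at-random mechanism driven by the fully observed Covar2..Covar4, the
incomplete data are imputed twice (outcome included and excluded from the
imputation model), every pooling method is applied to every covariate, and
rejection proportions at alpha are tabulated against the full-data analysis.

Scaled-down default profile: reps=250, m=10.  The engine accepts the full
profile (reps=1000, m=100 over all design cells) unchanged; only run time
grows.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import brentq
from scipy.special import expit

from .errors import CalibrationError, FitFailure, InvalidArgument, SingularMatrixError
from .glm import fit_logistic
from .impute import impute
from .mptests import DEFAULT_DF_POLICY, DfPolicy, analyse_stack
from .schema import BINARY, CATEGORICAL, CONTINUOUS, ColumnSpec, DataSchema, design_matrix

FACTOR = "Factor1"
COVARS = ("Covar1", "Covar2", "Covar3", "Covar4")
OUTCOME = "Outcome"
VARIABLES = (FACTOR,) + COVARS
FACTOR_LEVELS = ("Q1", "Q2", "Q3", "Q4")

#: methods known to run_condition; D1=VAR, D2=CHI, D3=MR pooling
ALL_METHODS = ("fulldata", "RR", "D1", "D2", "D3", "MPR_in", "MPR_out")

#: MAR dependence of the missingness log-odds on standardized mean(Covar2..4)
MAR_SLOPE = 1.0


def simulation_schema() -> DataSchema:
    """Schema of the simulated dataset (factor + four continuous + outcome)."""
    return DataSchema(
        (
            ColumnSpec(FACTOR, "covariate", CATEGORICAL, FACTOR_LEVELS),
            ColumnSpec("Covar1", "covariate", CONTINUOUS),
            ColumnSpec("Covar2", "covariate", CONTINUOUS),
            ColumnSpec("Covar3", "covariate", CONTINUOUS),
            ColumnSpec("Covar4", "covariate", CONTINUOUS),
            ColumnSpec(OUTCOME, "outcome", BINARY, (0, 1)),
        )
    )


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design grid.

    ``beta_cat_sd`` is the SD of the normal distribution the three dummy
    coefficients are drawn from (the design grid varies its square).
    """

    n: int = 250
    correlation: float = 0.2
    beta_continuous: float = 0.0
    beta_cat_sd: float = 0.0
    miss_pct: float = 0.25
    m: int = 10
    reps: int = 250
    seed: int = 0
    intercept: float = 0.0
    iterations: int = 10
    redraw_betas: bool = True

    def __post_init__(self) -> None:
        if not -1.0 < self.correlation < 1.0:
            raise InvalidArgument("correlation must lie in (-1, 1)")
        if not 0.0 <= self.miss_pct < 1.0:
            raise InvalidArgument("miss_pct must lie in [0, 1)")
        if self.n < 50:
            raise InvalidArgument("n must be >= 50")
        if self.m < 1 or self.reps < 1:
            raise InvalidArgument("m and reps must be >= 1")

    @classmethod
    def from_beta(cls, beta: float, **kwargs) -> "SimulationCondition":
        """Joint coefficient setting: continuous coefficients = beta, dummy
        coefficients drawn with variance beta (sd = sqrt(beta))."""
        return cls(beta_continuous=beta, beta_cat_sd=math.sqrt(beta), **kwargs)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "correlation": self.correlation,
            "beta_continuous": self.beta_continuous,
            "beta_cat_sd": self.beta_cat_sd,
            "miss_pct": self.miss_pct,
            "m": self.m,
            "reps": self.reps,
            "seed": self.seed,
            "intercept": self.intercept,
            "iterations": self.iterations,
            "redraw_betas": self.redraw_betas,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationCondition":
        return cls(**d)


def mc_se(p_hat: float, reps: int) -> float:
    """Monte-Carlo standard error of a rejection proportion,
    sqrt(p_hat (1 - p_hat) / reps)."""
    if not 0.0 <= p_hat <= 1.0:
        raise InvalidArgument("p_hat must lie in [0, 1]")
    if reps < 1:
        raise InvalidArgument("reps must be >= 1")
    return math.sqrt(p_hat * (1.0 - p_hat) / reps)


# ---------------------------------------------------------------------------
# data generation
# ---------------------------------------------------------------------------

def _latent_correlated(rng, n: int, rho: float) -> np.ndarray:
    """n x 5 standard normals with common pairwise correlation rho, via the
    Cholesky square root of the equicorrelation matrix."""
    R = np.full((5, 5), rho)
    np.fill_diagonal(R, 1.0)
    L = np.linalg.cholesky(R)
    return rng.standard_normal((n, 5)) @ L.T


def quartile_factor(z: np.ndarray) -> np.ndarray:
    """Cut a continuous vector at its three sample quartiles into codes 0..3.

    Right-closed intervals; a value tied with a cut point goes to the lower
    level (a measure-zero event for continuous draws)."""
    qs = np.quantile(z, [0.25, 0.5, 0.75])
    return np.searchsorted(qs, z, side="left")


def generate_complete_data(
    cond: SimulationCondition,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Generate one complete dataset; returns (dataset, true coefficients).

    Dummy coefficients are drawn from N(0, beta_cat_sd^2) using ``rng``
    (i.e. per replication when the caller passes the replication stream).
    """
    if rng is None:
        rng = np.random.default_rng(cond.seed)
    Z = _latent_correlated(rng, cond.n, cond.correlation)
    codes = quartile_factor(Z[:, 0])
    dummies = np.column_stack([(codes == c).astype(float) for c in (1, 2, 3)])
    beta_cat = rng.normal(0.0, 1.0, size=3) * cond.beta_cat_sd
    lp = (
        cond.intercept
        + dummies @ beta_cat
        + cond.beta_continuous * Z[:, 1:].sum(axis=1)
    )
    prob = expit(lp)
    y = (rng.random(cond.n) < prob).astype(np.int64)
    df = pd.DataFrame(
        {
            FACTOR: np.asarray(FACTOR_LEVELS, dtype=object)[codes],
            "Covar1": Z[:, 1],
            "Covar2": Z[:, 2],
            "Covar3": Z[:, 3],
            "Covar4": Z[:, 4],
            OUTCOME: y,
        }
    )
    true_betas = {
        "intercept": cond.intercept,
        "factor_dummies": beta_cat,
        "continuous": cond.beta_continuous,
    }
    return df, true_betas


def induce_mar(
    df: pd.DataFrame,
    miss_pct: float,
    seed: int | np.random.SeedSequence | None = None,
    *,
    targets: tuple[str, ...] = (FACTOR, "Covar1"),
    predictors: tuple[str, ...] = ("Covar2", "Covar3", "Covar4"),
    slope: float = MAR_SLOPE,
) -> pd.DataFrame:
    """Delete values in ``targets`` by a missing-at-random mechanism.

    The missingness log-odds depend on the standardized mean of the fully
    observed ``predictors`` with the given slope; the intercept is calibrated
    numerically so the *expected* missing fraction equals ``miss_pct`` on
    this dataset.  Realized fractions vary binomially around the target.
    """
    if miss_pct == 0.0:
        return df.copy()
    rng = np.random.default_rng(seed)
    s = df[list(predictors)].to_numpy(dtype=np.float64).mean(axis=1)
    sd = s.std()
    s = (s - s.mean()) / (sd if sd > 0 else 1.0)
    driver = slope * s

    def expected(a: float) -> float:
        return float(np.mean(expit(a + driver))) - miss_pct

    try:
        a0 = brentq(expected, -40.0, 40.0, xtol=1e-12)
    except ValueError as exc:
        raise CalibrationError(
            f"could not calibrate missingness intercept for target {miss_pct}"
        ) from exc
    out = df.copy()
    probs = expit(a0 + driver)
    for t in targets:
        mask = rng.random(len(df)) < probs
        if out[t].dtype.kind in "if":
            col = out[t].to_numpy(dtype=np.float64).copy()
            col[mask] = np.nan
            out[t] = col
        else:
            col = out[t].to_numpy(dtype=object).copy()
            col[mask] = None
            out[t] = col
    return out


# ---------------------------------------------------------------------------
# full-data analysis and per-replication work
# ---------------------------------------------------------------------------

def _full_data_pvalues(df: pd.DataFrame, schema: DataSchema) -> dict[str, float]:
    """Complete-data p-values: k-df LRT for the factor, 1-df Wald for the
    continuous covariates (the Rubin-pooled test with m = 1)."""
    X, y, info = design_matrix(df, schema)
    fit = fit_logistic(X, y)
    out: dict[str, float] = {}
    for name in VARIABLES:
        sl = info.slices[name]
        k = sl.stop - sl.start
        if k == 1:
            w = fit.beta[sl.start] ** 2 / fit.cov[sl.start, sl.start]
            out[name] = float(stats.chi2.sf(w, 1))
        else:
            Xr, _, _ = design_matrix(df, schema, drop=(name,))
            fr = fit_logistic(Xr, y)
            lrt = max(2.0 * (fit.loglik - fr.loglik), 0.0)
            out[name] = float(stats.chi2.sf(lrt, k))
    return out


@dataclass
class RejectionTable:
    """Per-variable, per-method rejection proportions with MC standard errors."""

    table: pd.DataFrame
    condition: dict = field(default_factory=dict)
    alpha: float = 0.05

    def rate(self, variable: str, method: str) -> float:
        row = self.table[
            (self.table["variable"] == variable) & (self.table["method"] == method)
        ]
        if row.empty:
            raise KeyError((variable, method))
        return float(row["rejection_rate"].iloc[0])

    def to_csv(self, path) -> None:
        wide = self.table.copy()
        for key, val in self.condition.items():
            wide.insert(0, key, val)
        wide.to_csv(path, index=False)


def run_condition(
    cond: SimulationCondition,
    methods: tuple[str, ...] | None = None,
    *,
    alpha: float = 0.05,
    df_policy: DfPolicy = DEFAULT_DF_POLICY,
    collect_pvalues: bool = False,
) -> RejectionTable:
    """Run one design cell: generate, delete, impute, pool, tabulate.

    ``methods`` is a subset of :data:`ALL_METHODS`; MPR_in pools the
    per-imputation p-values from the outcome-included stack, MPR_out from the
    outcome-excluded stack; RR, D1, D2, D3 use the outcome-included stack.
    Replications on which any required model fit fails are flagged and
    excluded; the table reports effective replication counts.

    With ``collect_pvalues`` the returned table object additionally carries
    ``pvalues`` (pooled p per replication) and ``per_imputation_pvalues``
    (reps x m matrices of per-imputation overall-test p-values for Factor1
    and Covar1 from the outcome-excluded stack) for diagnostics.
    """
    methods = tuple(methods) if methods is not None else ALL_METHODS
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise InvalidArgument(f"unknown methods: {sorted(unknown)}")
    schema = simulation_schema()
    need_in = any(mth in methods for mth in ("RR", "D1", "D2", "D3", "MPR_in"))
    need_out = "MPR_out" in methods
    stack_methods = tuple(
        mth for mth in ("RR", "D1", "D2", "D3") if mth in methods
    ) + (("MPR",) if "MPR_in" in methods else ())

    master = np.random.SeedSequence(cond.seed)
    rep_seeds = master.spawn(cond.reps)
    fixed_rng = np.random.default_rng(master.spawn(1)[0])
    fixed_betas = (
        None
        if cond.redraw_betas
        else fixed_rng.normal(0.0, cond.beta_cat_sd, size=3)
    )

    rejects: dict[tuple[str, str], int] = {}
    effective: dict[tuple[str, str], int] = {}
    pvals_store: dict[tuple[str, str], list[float]] = {}
    per_imp_store = {FACTOR: [], "Covar1": []} if collect_pvalues else None
    failures = 0

    for rep_ss in rep_seeds:
        child = rep_ss.spawn(4)
        rng_data = np.random.default_rng(child[0])
        try:
            rep = _replicate(
                cond, schema, rng_data, child[1], child[2], child[3],
                methods, stack_methods, need_in, need_out,
                df_policy, fixed_betas, collect_pvalues,
            )
        except (FitFailure, SingularMatrixError):
            failures += 1
            continue
        for (variable, method), p in rep["pvalues"].items():
            key = (variable, method)
            effective[key] = effective.get(key, 0) + 1
            if not np.isnan(p) and p < alpha:
                rejects[key] = rejects.get(key, 0) + 1
            pvals_store.setdefault(key, []).append(p)
        if collect_pvalues and rep.get("per_imp") is not None:
            for v in per_imp_store:
                per_imp_store[v].append(rep["per_imp"][v])

    rows = []
    for variable in VARIABLES:
        for method in methods:
            key = (variable, method)
            if key not in effective:
                continue
            n_eff = effective[key]
            rate = rejects.get(key, 0) / n_eff
            rows.append(
                {
                    "variable": variable,
                    "method": method,
                    "rejection_rate": rate,
                    "mc_se": mc_se(rate, n_eff),
                    "reps_effective": n_eff,
                }
            )
    table = RejectionTable(
        table=pd.DataFrame(rows),
        condition={**cond.to_dict(), "alpha": alpha, "failures": failures},
        alpha=alpha,
    )
    if collect_pvalues:
        table.pvalues = {k: np.asarray(v) for k, v in pvals_store.items()}
        table.per_imputation_pvalues = {
            v: np.vstack(mats) for v, mats in per_imp_store.items() if mats
        }
    return table


def _replicate(
    cond, schema, rng_data, mar_ss, imp_in_ss, imp_out_ss,
    methods, stack_methods, need_in, need_out,
    df_policy, fixed_betas, collect_pvalues,
):
    """One replication; returns pooled p-values per (variable, method)."""
    if fixed_betas is not None:
        df, _ = _generate_with_betas(cond, rng_data, fixed_betas)
    else:
        df, _ = generate_complete_data(cond, rng_data)

    pvalues: dict[tuple[str, str], float] = {}
    if "fulldata" in methods:
        for v, p in _full_data_pvalues(df, schema).items():
            pvalues[(v, "fulldata")] = p

    incomplete = induce_mar(df, cond.miss_pct, mar_ss)
    per_imp = None
    if need_in:
        stack_in = impute(
            incomplete, schema, cond.m,
            iterations=cond.iterations, include_outcome=True, seed=imp_in_ss,
        )
        res_in = analyse_stack(
            stack_in.datasets, schema, list(VARIABLES),
            methods=stack_methods, df_policy=df_policy,
        )
        for v in VARIABLES:
            for mth in ("D1", "D2", "D3"):
                if mth in methods and mth in res_in[v]:
                    pvalues[(v, mth)] = res_in[v][mth].p_value
            if "RR" in methods and "RR" in res_in[v]:
                pvalues[(v, "RR")] = res_in[v]["RR"].p_value
            if "MPR_in" in methods and "MPR" in res_in[v]:
                pvalues[(v, "MPR_in")] = res_in[v]["MPR"].p_value
    if need_out or collect_pvalues:
        stack_out = impute(
            incomplete, schema, cond.m,
            iterations=cond.iterations, include_outcome=False, seed=imp_out_ss,
        )
        res_out = analyse_stack(
            stack_out.datasets, schema, list(VARIABLES),
            methods=("MPR",), df_policy=df_policy,
        )
        if need_out:
            for v in VARIABLES:
                pvalues[(v, "MPR_out")] = res_out[v]["MPR"].p_value
        if collect_pvalues:
            per_imp = {}
            for v in (FACTOR, "Covar1"):
                from .mptests import per_imputation_overall_test

                ps = [
                    per_imputation_overall_test(d, schema, v)[1]
                    for d in stack_out.datasets
                ]
                per_imp[v] = np.asarray(ps)[None, :]
    return {"pvalues": pvalues, "per_imp": per_imp}


def _generate_with_betas(cond, rng, beta_cat):
    """Like generate_complete_data but with fixed dummy coefficients."""
    Z = _latent_correlated(rng, cond.n, cond.correlation)
    codes = quartile_factor(Z[:, 0])
    dummies = np.column_stack([(codes == c).astype(float) for c in (1, 2, 3)])
    # keep the stream aligned with the redraw path
    rng.normal(0.0, 1.0, size=3)
    lp = cond.intercept + dummies @ np.asarray(beta_cat) + cond.beta_continuous * Z[:, 1:].sum(axis=1)
    y = (rng.random(cond.n) < expit(lp)).astype(np.int64)
    df = pd.DataFrame(
        {
            FACTOR: np.asarray(FACTOR_LEVELS, dtype=object)[codes],
            "Covar1": Z[:, 1],
            "Covar2": Z[:, 2],
            "Covar3": Z[:, 3],
            "Covar4": Z[:, 4],
            OUTCOME: y,
        }
    )
    return df, {"factor_dummies": np.asarray(beta_cat)}


def plot_power_curves(
    grid_table: pd.DataFrame,
    variable: str,
    path,
    *,
    beta_column: str = "beta_continuous",
) -> None:
    """Plot rejection rate vs coefficient value per method for one variable.

    ``grid_table`` is the tidy output of :func:`run_grid`.  Requires
    matplotlib (an optional dependency).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = grid_table[grid_table["variable"] == variable]
    fig, ax = plt.subplots(figsize=(6, 4))
    for method, g in sub.groupby("method"):
        g = g.sort_values(beta_column)
        ax.errorbar(
            g[beta_column], g["rejection_rate"], yerr=g["mc_se"],
            marker="o", capsize=2, label=method,
        )
    ax.set_xlabel("coefficient value")
    ax.set_ylabel("rejection rate")
    ax.set_title(variable)
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_grid(
    conditions: list[SimulationCondition],
    methods: tuple[str, ...] | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Run several design cells and stack the tidy tables."""
    frames = []
    for cond in conditions:
        rt = run_condition(cond, methods, **kwargs)
        t = rt.table.copy()
        for key, val in rt.condition.items():
            t[key] = val
        frames.append(t)
    return pd.concat(frames, ignore_index=True)
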