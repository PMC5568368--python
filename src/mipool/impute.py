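"""Multivariate imputation by chained equations (MICE), minimal but proper.

Each incomplete column is imputed in turn from a conditional regression on
all other covariates (plus, optionally, the outcome), cycling for a number of
burn-in iterations before a completed copy is recorded.  Conditional models
are Bayesian-draw regressions:

continuous
    Linear regression; residual variance drawn from its scaled inverse
    chi-square posterior under a flat prior, coefficients drawn from their
    normal posterior, then predictive noise added.
binary / categorical
    Logistic / multinomial-logistic fit; a coefficient vector is drawn from
    the large-sample normal approximation to the posterior and category
    membership is drawn from the implied probabilities.

Each of the m imputations is an independent chain with its own substream of
the master seed, so increasing m never changes earlier chains.  The outcome
column can be included in or excluded from every conditional model via
``include_outcome`` — the pooled tests downstream are sensitive to this
choice, which is why it is a first-class switch here.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import FitFailure, InvalidArgument, SingularMatrixError
from .glm import fit_logistic, fit_multinomial
from .schema import BINARY, CATEGORICAL, CONTINUOUS, DataSchema

logger = logging.getLogger(__name__)

_FALLBACK_RIDGE = 0.1  # weak stabiliser used only when the MLE separates


@dataclass
class ImputedStack:
    """m completed copies of one incomplete dataset.

    Invariants: observed cells are identical across copies and equal to the
    original; no missing cells remain; categorical imputations stay within
    the declared level set.
    """

    datasets: list[pd.DataFrame]
    original: pd.DataFrame
    schema: DataSchema
    m: int
    iterations: int
    include_outcome: bool
    seed: int | None = None
    notes: list[str] = field(default_factory=list)

    def to_long(self, include_original: bool = True) -> pd.DataFrame:
        """Long-format stack: original columns + `.imp` (1..m) + `.id`.

        With ``include_original`` an `.imp = 0` block carries the incomplete
        data, missing cells empty.
        """
        frames = []
        if include_original:
            d0 = self.original.copy()
            d0.insert(0, ".imp", 0)
            d0.insert(1, ".id", np.arange(len(d0)))
            frames.append(d0)
        for j, df in enumerate(self.datasets, start=1):
            d = df.copy()
            d.insert(0, ".imp", j)
            d.insert(1, ".id", np.arange(len(d)))
            frames.append(d)
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_long(cls, long: pd.DataFrame, schema: DataSchema) -> "ImputedStack":
        from .errors import DataError

        if ".imp" not in long.columns or ".id" not in long.columns:
            raise DataError("long-format stack needs `.imp` and `.id` columns")
        imps = long[".imp"].to_numpy()
        if np.any(pd.isna(imps)):
            raise DataError("`.imp` column contains missing values")
        try:
            imps = imps.astype(int)
        except (TypeError, ValueError) as exc:
            raise DataError("`.imp` column is not integer-valued") from exc
        idx = sorted(set(imps))
        m_idx = [i for i in idx if i > 0]
        if m_idx != list(range(1, len(m_idx) + 1)):
            raise DataError("`.imp` must cover 1..m contiguously")
        cols = [c for c in long.columns if c not in (".imp", ".id")]
        datasets = []
        for j in m_idx:
            d = long.loc[imps == j, cols].reset_index(drop=True)
            datasets.append(d)
        if 0 in idx:
            original = long.loc[imps == 0, cols].reset_index(drop=True)
        else:
            original = datasets[0].copy()
        return cls(
            datasets=datasets,
            original=original,
            schema=schema,
            m=len(datasets),
            iterations=0,
            include_outcome=True,
            seed=None,
        )


class _WorkingData:
    """Numeric working representation: floats for continuous columns,
    integer level codes for binary/categorical (-1 while missing)."""

    def __init__(self, df: pd.DataFrame, schema: DataSchema) -> None:
        self.schema = schema
        self.n = len(df)
        self.values: dict[str, np.ndarray] = {}
        self.miss: dict[str, np.ndarray] = {}
        for c in schema.columns:
            if c.name not in df.columns:
                raise InvalidArgument(f"column {c.name!r} missing from data")
            s = df[c.name]
            na = pd.isna(s).to_numpy()
            if c.kind == CONTINUOUS:
                # force a copy: to_numpy may return a view of the frame's
                # buffer, and chains must never write into the caller's data
                v = np.array(s.to_numpy(dtype=np.float64, na_value=np.nan), copy=True)
            else:
                levels = list(c.levels)
                v = np.full(self.n, -1, dtype=np.int64)
                raw = s.to_numpy()
                for code, lv in enumerate(levels):
                    v[raw == lv] = code
                if np.any((v < 0) & ~na):
                    raise InvalidArgument(
                        f"column {c.name!r} has values outside its declared levels"
                    )
            if na.all():
                raise InvalidArgument(f"column {c.name!r} is entirely missing")
            self.values[c.name] = v
            self.miss[c.name] = na

    def predictor_matrix(self, target: str, include_outcome: bool) -> np.ndarray:
        cols = [np.ones((self.n, 1))]
        for c in self.schema.columns:
            if c.name == target:
                continue
            if c.role == "outcome" and not include_outcome:
                continue
            v = self.values[c.name]
            if c.kind == CONTINUOUS:
                cols.append(v[:, None].astype(np.float64))
            elif c.kind == BINARY:
                cols.append(v[:, None].astype(np.float64))
            else:
                K = len(c.levels)
                d = np.zeros((self.n, K - 1))
                for code in range(1, K):
                    d[:, code - 1] = v == code
                cols.append(d)
        return np.concatenate(cols, axis=1)


def _draw_linear(rng, X, y, obs, mis):
    """Bayesian linear-regression imputation draw (flat prior)."""
    Xo, yo = X[obs], y[obs]
    n_obs, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    Xty = Xo.T @ yo
    beta_hat = np.linalg.solve(XtX, Xty)
    resid = yo - Xo @ beta_hat
    df = max(n_obs - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(df)
    V = np.linalg.inv(XtX)
    L = np.linalg.cholesky(0.5 * (V + V.T) * sigma2 + 1e-14 * np.eye(p))
    beta_draw = beta_hat + L @ rng.standard_normal(p)
    return X[mis] @ beta_draw + np.sqrt(sigma2) * rng.standard_normal(int(mis.sum()))


def _draw_coefficients(rng, beta_hat, cov):
    flat = np.ravel(beta_hat)
    C = 0.5 * (cov + cov.T) + 1e-12 * np.eye(len(flat))
    L = np.linalg.cholesky(C)
    return (flat + L @ rng.standard_normal(len(flat))).reshape(np.shape(beta_hat))


def impute(
    data: pd.DataFrame,
    schema: DataSchema,
    m: int = 5,
    *,
    iterations: int = 10,
    include_outcome: bool = True,
    seed: int | np.random.SeedSequence | None = None,
) -> ImputedStack:
    """Impute an incomplete dataset m times by chained equations.

    Parameters
    ----------
    data : rectangular dataset; missing cells as NaN/None.
    schema : column roles, types and level sets.
    m : number of imputations (independent chains).
    iterations : burn-in cycles over the incomplete columns per chain.
    include_outcome : whether the outcome enters the conditional models.
    seed : master seed; chain j uses the j-th spawned substream.
    """
    if m < 1:
        raise InvalidArgument("m must be >= 1")
    if iterations < 1:
        raise InvalidArgument("iterations must be >= 1")
    base = _WorkingData(data, schema)  # validates columns and level sets
    incomplete = [c for c in schema.columns if base.miss[c.name].any()]
    notes: list[str] = []

    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(m)
    completed: list[pd.DataFrame] = []
    for j in range(m):
        rng = np.random.default_rng(children[j])
        work = _WorkingData(data, schema)
        if not incomplete:
            completed.append(data.copy())
            continue
        # initial fill: random draws from the observed values of each column
        for c in incomplete:
            mis = work.miss[c.name]
            obs_vals = work.values[c.name][~mis]
            work.values[c.name][mis] = rng.choice(obs_vals, size=int(mis.sum()))
        warm: dict[str, np.ndarray] = {}
        for it in range(iterations):
            for c in incomplete:
                mis = work.miss[c.name]
                obs = ~mis
                Z = work.predictor_matrix(
                    c.name,
                    include_outcome=include_outcome or c.role == "outcome",
                )
                if c.kind == CONTINUOUS:
                    work.values[c.name][mis] = _draw_linear(
                        rng, Z, work.values[c.name], obs, mis
                    )
                    continue
                codes = work.values[c.name]
                try:
                    if c.kind == BINARY:
                        fit = fit_logistic(
                            Z[obs], codes[obs].astype(np.float64),
                            beta0=warm.get(c.name),
                        )
                        beta, cov = fit.beta, fit.cov
                    else:
                        fit = fit_multinomial(
                            Z[obs], codes[obs], len(c.levels),
                            beta0=warm.get(c.name),
                        )
                        beta, cov = fit.beta, fit.cov
                except (FitFailure, SingularMatrixError):
                    msg = (
                        f"conditional model for {c.name!r} unstable at "
                        f"chain {j + 1}, iteration {it + 1}; "
                        f"applying ridge {_FALLBACK_RIDGE}"
                    )
                    logger.warning(msg)
                    if msg not in notes:
                        notes.append(msg)
                    if c.kind == BINARY:
                        fit = fit_logistic(
                            Z[obs], codes[obs].astype(np.float64),
                            ridge=_FALLBACK_RIDGE,
                        )
                    else:
                        fit = fit_multinomial(
                            Z[obs], codes[obs], len(c.levels),
                            ridge=_FALLBACK_RIDGE,
                        )
                    beta, cov = fit.beta, fit.cov
                warm[c.name] = beta
                bdraw = _draw_coefficients(rng, beta, cov)
                if c.kind == BINARY:
                    from scipy.special import expit

                    p1 = expit(Z[mis] @ bdraw)
                    codes[mis] = (rng.random(int(mis.sum())) < p1).astype(np.int64)
                else:
                    from .glm import _softmax_probs

                    P = _softmax_probs(np.atleast_2d(bdraw), Z[mis])
                    u = rng.random(int(mis.sum()))
                    codes[mis] = (P.cumsum(axis=1) < u[:, None]).sum(axis=1)
        completed.append(_to_frame(data, schema, work))
    return ImputedStack(
        datasets=completed,
        original=data.copy(),
        schema=schema,
        m=m,
        iterations=iterations,
        include_outcome=include_outcome,
        seed=seed,
        notes=notes,
    )


def _to_frame(original: pd.DataFrame, schema: DataSchema, work: _WorkingData) -> pd.DataFrame:
    out = original.copy()
    for c in schema.columns:
        mis = work.miss[c.name]
        if not mis.any():
            continue
        if c.kind == CONTINUOUS:
            col = out[c.name].to_numpy(dtype=np.float64, na_value=np.nan)
            col[mis] = work.values[c.name][mis]
            out[c.name] = col
        else:
            levels = np.asarray(list(c.levels), dtype=object)
            col = out[c.name].to_numpy(dtype=object)
            col[mis] = levels[work.values[c.name][mis]]
            out[c.name] = col
            try:
                out[c.name] = out[c.name].astype(original[c.name].dtype)
            except (TypeError, ValueError):
                pass
    return out
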