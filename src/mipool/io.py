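"""CSV readers/writers and programmatic fixture generation.

Missing cells are encoded as empty fields on write; the reader accepts both
empty fields and the string "NA".  Imputed stacks travel in long format:
original columns plus `.imp` (1..m; 0 for the optional incomplete original)
and `.id` (row index within a dataset).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .impute import ImputedStack
from .schema import BINARY, CATEGORICAL, CONTINUOUS, ColumnSpec, DataSchema
from .simulate import SimulationCondition, generate_complete_data, induce_mar

_NA_VALUES = ["", "NA"]


def read_dataset(path, schema: DataSchema | None = None) -> pd.DataFrame:
    """Read a rectangular CSV; empty fields and "NA" become missing cells."""
    df = pd.read_csv(path, na_values=_NA_VALUES, keep_default_na=False)
    if schema is not None:
        missing = [c.name for c in schema.columns if c.name not in df.columns]
        if missing:
            raise DataError(f"dataset lacks schema columns: {missing}")
        for c in schema.columns:
            if c.kind == CONTINUOUS:
                df[c.name] = pd.to_numeric(df[c.name], errors="coerce")
            elif all(isinstance(lv, (int, np.integer)) for lv in c.levels):
                df[c.name] = pd.to_numeric(df[c.name], errors="coerce").astype("Int64")
    return df


def write_dataset(df: pd.DataFrame, path) -> None:
    """Write a dataset CSV with missing cells as empty fields."""
    df.to_csv(path, index=False, na_rep="")


def write_stack(stack: ImputedStack, path, include_original: bool = True) -> None:
    write_dataset(stack.to_long(include_original=include_original), path)


def read_stack(path, schema: DataSchema) -> ImputedStack:
    long = read_dataset(path)
    if ".imp" not in long.columns:
        raise DataError("stack file lacks the `.imp` column")
    for c in schema.columns:
        if c.name not in long.columns:
            raise DataError(f"stack file lacks schema column {c.name!r}")
        if c.kind == CONTINUOUS:
            long[c.name] = pd.to_numeric(long[c.name], errors="coerce")
        elif all(isinstance(lv, (int, np.integer)) for lv in c.levels):
            long[c.name] = pd.to_numeric(long[c.name], errors="coerce").astype("Int64")
    return ImputedStack.from_long(long, schema)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def thirty_row_fixture() -> tuple[pd.DataFrame, DataSchema]:
    """A 30-row hand-checkable logistic dataset: one 3-level factor, one
    continuous covariate, binary outcome.  Deterministic by construction."""
    rng = np.random.default_rng(20170822)
    n = 30
    grp = np.asarray(["a", "b", "c"], dtype=object)[np.arange(n) % 3]
    x = np.round(rng.normal(0, 1, n), 3)
    lp = 0.8 * (grp == "b") - 0.5 * (grp == "c") + 0.6 * x
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    df = pd.DataFrame({"grp": grp, "x": x, "y": y})
    schema = DataSchema(
        (
            ColumnSpec("grp", "covariate", CATEGORICAL, ("a", "b", "c")),
            ColumnSpec("x", "covariate", CONTINUOUS),
            ColumnSpec("y", "outcome", BINARY, (0, 1)),
        )
    )
    return df, schema


def application_schema() -> DataSchema:
    """Schema of the synthetic application-shaped dataset (see
    :func:`synthetic_application_data`)."""
    return DataSchema(
        (
            ColumnSpec("group", "covariate", CATEGORICAL, ("usual", "low", "high")),
            ColumnSpec("age", "covariate", CONTINUOUS),
            ColumnSpec("gender", "covariate", BINARY, ("f", "m")),
            ColumnSpec("bmi", "covariate", CONTINUOUS),
            ColumnSpec("education", "covariate", CATEGORICAL, ("e1", "e2", "e3", "e4", "e5")),
            ColumnSpec("sitting", "covariate", CATEGORICAL, ("s1", "s2", "s3", "s4")),
            ColumnSpec("lifting", "covariate", CATEGORICAL, ("l1", "l2", "l3", "l4")),
            ColumnSpec("vibration", "covariate", CATEGORICAL, ("v1", "v2", "v3", "v4")),
            ColumnSpec("pain_baseline", "covariate", CONTINUOUS),
            ColumnSpec("physical_functioning", "covariate", CONTINUOUS),
            ColumnSpec("disability", "covariate", CONTINUOUS),
            ColumnSpec("kinesiophobia", "covariate", CONTINUOUS),
            ColumnSpec("pain_improved", "outcome", BINARY, (0, 1)),
        )
    )


#: configured missing fractions per variable in the synthetic application data
APPLICATION_MISS = {
    "bmi": 0.06,
    "pain_baseline": 0.054,
    "physical_functioning": 0.255,
    "kinesiophobia": 0.06,
    "education": 0.078,
    "sitting": 0.057,
    "lifting": 0.054,
    "vibration": 0.10,
}


def synthetic_application_data(seed: int = 299) -> tuple[pd.DataFrame, pd.DataFrame, DataSchema]:
    """A synthetic stand-in with the shape of a 299-worker low-back-pain
    trial: 6 continuous and 4+ categorical covariates, a binary outcome and
    MAR missingness at the configured per-variable fractions.

    Entirely simulated; returns (complete, incomplete, schema).
    """
    rng = np.random.default_rng(seed)
    n = 299
    schema = application_schema()
    # correlated continuous block
    rho = 0.3
    C = np.full((6, 6), rho)
    np.fill_diagonal(C, 1.0)
    Lc = np.linalg.cholesky(C)
    Zc = rng.standard_normal((n, 6)) @ Lc.T
    df = pd.DataFrame(
        {
            "group": np.asarray(["usual", "low", "high"], dtype=object)[
                rng.integers(0, 3, n)
            ],
            "age": np.round(40 + 10 * Zc[:, 0], 1),
            "gender": np.asarray(["f", "m"], dtype=object)[rng.integers(0, 2, n)],
            "bmi": np.round(26 + 4 * Zc[:, 1], 1),
            "education": np.asarray(["e1", "e2", "e3", "e4", "e5"], dtype=object)[
                rng.integers(0, 5, n)
            ],
            "sitting": np.asarray(["s1", "s2", "s3", "s4"], dtype=object)[
                rng.integers(0, 4, n)
            ],
            "lifting": np.asarray(["l1", "l2", "l3", "l4"], dtype=object)[
                rng.integers(0, 4, n)
            ],
            "vibration": np.asarray(["v1", "v2", "v3", "v4"], dtype=object)[
                rng.integers(0, 4, n)
            ],
            "pain_baseline": np.round(5 + 2 * Zc[:, 2], 2),
            "physical_functioning": np.round(Zc[:, 3], 3),
            "disability": np.round(Zc[:, 4], 3),
            "kinesiophobia": np.round(35 + 8 * Zc[:, 5], 1),
        }
    )
    lp = (
        -0.3
        + 0.7 * (df["group"] == "high")
        + 0.4 * (df["group"] == "low")
        + 0.35 * (df["pain_baseline"] - 5) / 2
        - 0.8 * df["disability"]
        + 0.05 * (df["bmi"] - 26)
    )
    df["pain_improved"] = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)

    # MAR missingness driven by the always-observed age and disability
    driver = (df["age"].to_numpy() - 40) / 10 + df["disability"].to_numpy()
    driver = (driver - driver.mean()) / driver.std()
    incomplete = df.copy()
    from scipy.optimize import brentq
    from scipy.special import expit as _expit

    for name, frac in APPLICATION_MISS.items():
        a = brentq(lambda a_: float(np.mean(_expit(a_ + driver))) - frac, -30, 30)
        mask = rng.random(n) < _expit(a + driver)
        if incomplete[name].dtype.kind in "if":
            col = incomplete[name].to_numpy(dtype=np.float64).copy()
            col[mask] = np.nan
        else:
            col = incomplete[name].to_numpy(dtype=object).copy()
            col[mask] = None
        incomplete[name] = col
    return df, incomplete, schema


def make_fixtures(outdir, seed: int = 20170822) -> dict[str, Path]:
    """Write the package's example fixture files into ``outdir``.

    (a) a complete simulated dataset at the default design plus its
    MAR-incomplete version and schema; (b) the 30-row hand-checkable logistic
    fixture; (c) the synthetic application-shaped dataset (n=299) complete
    and incomplete.  Regeneration under the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    from .simulate import simulation_schema

    cond = SimulationCondition.from_beta(0.5, n=250, correlation=0.4, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    complete, _ = generate_complete_data(cond, rng)
    complete = complete.copy()
    for c in ("Covar1", "Covar2", "Covar3", "Covar4"):
        complete[c] = np.round(complete[c], 6)
    incomplete = induce_mar(complete, cond.miss_pct, np.random.SeedSequence(seed + 1))
    paths["sim_complete"] = outdir / "sim_complete.csv"
    paths["sim_incomplete"] = outdir / "sim_incomplete.csv"
    paths["sim_schema"] = outdir / "sim_schema.json"
    write_dataset(complete, paths["sim_complete"])
    write_dataset(incomplete, paths["sim_incomplete"])
    paths["sim_schema"].write_text(simulation_schema().to_json())

    df30, schema30 = thirty_row_fixture()
    paths["logistic30"] = outdir / "logistic30.csv"
    paths["logistic30_schema"] = outdir / "logistic30_schema.json"
    write_dataset(df30, paths["logistic30"])
    paths["logistic30_schema"].write_text(schema30.to_json())

    app_complete, app_incomplete, app_schema = synthetic_application_data(seed=seed)
    paths["application_complete"] = outdir / "application_synthetic_complete.csv"
    paths["application_incomplete"] = outdir / "application_synthetic_incomplete.csv"
    paths["application_schema"] = outdir / "application_synthetic_schema.json"
    write_dataset(app_complete, paths["application_complete"])
    write_dataset(app_incomplete, paths["application_incomplete"])
    paths["application_schema"].write_text(app_schema.to_json())
    return paths
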