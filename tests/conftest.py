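import numpy as np
import pandas as pd
import pytest

from mipool.schema import (
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    ColumnSpec,
    DataSchema,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20170822)


@pytest.fixture
def small_schema():
    """One 3-level factor, two continuous covariates, binary outcome."""
    return DataSchema(
        (
            ColumnSpec("grp", "covariate", CATEGORICAL, ("a", "b", "c")),
            ColumnSpec("x1", "covariate", CONTINUOUS),
            ColumnSpec("x2", "covariate", CONTINUOUS),
            ColumnSpec("y", "outcome", BINARY, (0, 1)),
        )
    )


def make_small_data(rng, n=200, beta_grp=(0.7, -0.4), beta_x=(0.5, 0.0)):
    grp = np.asarray(["a", "b", "c"], dtype=object)[rng.integers(0, 3, n)]
    x1 = rng.standard_normal(n)
    x2 = 0.4 * x1 + np.sqrt(1 - 0.4**2) * rng.standard_normal(n)
    lp = beta_grp[0] * (grp == "b") + beta_grp[1] * (grp == "c") + beta_x[0] * x1 + beta_x[1] * x2
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-lp))).astype(int)
    return pd.DataFrame({"grp": grp, "x1": x1, "x2": x2, "y": y})


@pytest.fixture
def small_data(rng):
    return make_small_data(rng)


@pytest.fixture
def small_incomplete(rng, small_data):
    """small_data with ~25% MAR-ish missingness in grp and x1 (driven by x2)."""
    df = small_data.copy()
    from scipy.special import expit

    p = expit(-1.4 + 0.8 * df["x2"].to_numpy())
    for col in ("grp", "x1"):
        mask = rng.random(len(df)) < p
        if df[col].dtype.kind in "if":
            v = df[col].to_numpy(dtype=float).copy()
            v[mask] = np.nan
        else:
            v = df[col].to_numpy(dtype=object).copy()
            v[mask] = None
        df[col] = v
    return df
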