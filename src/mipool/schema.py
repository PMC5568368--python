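"""Dataset schema: column roles and types, and design-matrix construction.

A :class:`DataSchema` declares, for every column of a rectangular dataset,
whether it is a covariate or the (single, binary) outcome and whether it is
continuous, binary or categorical with a fixed level set.  The same schema
drives the chained-equations imputer and the logistic analysis model, so the
dummy coding used to impute and the one used to test are guaranteed to agree.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, InvalidArgument

CONTINUOUS = "continuous"
BINARY = "binary"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, BINARY, CATEGORICAL)


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    role: str  # 'covariate' | 'outcome'
    kind: str  # continuous | binary | categorical
    levels: tuple | None = None  # fixed level set for binary/categorical

    def __post_init__(self) -> None:
        if self.role not in ("covariate", "outcome"):
            raise InvalidArgument(f"bad role {self.role!r} for column {self.name!r}")
        if self.kind not in _KINDS:
            raise InvalidArgument(f"bad kind {self.kind!r} for column {self.name!r}")
        if self.kind in (BINARY, CATEGORICAL):
            if self.levels is None or len(self.levels) < 2:
                raise InvalidArgument(f"column {self.name!r} needs >= 2 declared levels")
            if self.kind == BINARY and len(self.levels) != 2:
                raise InvalidArgument(f"binary column {self.name!r} must have 2 levels")


@dataclass(frozen=True)
class DataSchema:
    """Ordered column specifications with exactly one binary outcome."""

    columns: tuple[ColumnSpec, ...]

    def __post_init__(self) -> None:
        outcomes = [c for c in self.columns if c.role == "outcome"]
        if len(outcomes) != 1:
            raise InvalidArgument("schema must declare exactly one outcome column")
        if outcomes[0].kind != BINARY:
            raise InvalidArgument("the outcome column must be binary")
        names = [c.name for c in self.columns]
        if len(set(names)) != len(names):
            raise InvalidArgument("duplicate column names in schema")

    @property
    def outcome(self) -> ColumnSpec:
        return next(c for c in self.columns if c.role == "outcome")

    @property
    def covariates(self) -> tuple[ColumnSpec, ...]:
        return tuple(c for c in self.columns if c.role == "covariate")

    def __getitem__(self, name: str) -> ColumnSpec:
        for c in self.columns:
            if c.name == name:
                return c
        raise KeyError(name)

    def n_params(self, name: str) -> int:
        """Number of regression parameters (dummies) the covariate contributes."""
        c = self[name]
        return 1 if c.kind == CONTINUOUS else len(c.levels) - 1

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        outcome: str,
        categorical: dict[str, list] | None = None,
    ) -> "DataSchema":
        """Infer a schema from a dataframe.

        Columns listed in ``categorical`` (name -> levels; levels may be None
        to take the sorted observed values) become categorical; two-valued
        non-float columns become binary; everything else continuous.
        """
        categorical = dict(categorical or {})
        cols: list[ColumnSpec] = []
        for name in df.columns:
            role = "outcome" if name == outcome else "covariate"
            s = df[name]
            observed = sorted(s.dropna().unique().tolist())
            if name in categorical:
                levels = categorical[name] or observed
                kind = BINARY if len(levels) == 2 else CATEGORICAL
                cols.append(ColumnSpec(name, role, kind, tuple(levels)))
            elif role == "outcome" or (len(observed) == 2 and not pd.api.types.is_float_dtype(s)):
                cols.append(ColumnSpec(name, role, BINARY, tuple(observed)))
            else:
                cols.append(ColumnSpec(name, role, CONTINUOUS))
        return cls(tuple(cols))

    def to_json(self) -> str:
        return json.dumps(
            [
                {
                    "name": c.name,
                    "role": c.role,
                    "kind": c.kind,
                    "levels": list(c.levels) if c.levels is not None else None,
                }
                for c in self.columns
            ],
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "DataSchema":
        spec = json.loads(text)
        return cls(
            tuple(
                ColumnSpec(
                    d["name"],
                    d["role"],
                    d["kind"],
                    tuple(d["levels"]) if d.get("levels") is not None else None,
                )
                for d in spec
            )
        )


@dataclass(frozen=True)
class DesignInfo:
    """Mapping from covariates to their column block in a design matrix."""

    names: tuple[str, ...]  # design column labels, intercept first
    slices: dict = field(default_factory=dict)  # covariate -> slice into X


def _encode_column(spec: ColumnSpec, values: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Numeric design columns (n, q) and their labels for one covariate."""
    if spec.kind == CONTINUOUS:
        return values.to_numpy(dtype=np.float64)[:, None], [spec.name]
    levels = list(spec.levels)
    arr = values.to_numpy()
    bad = ~pd.isna(arr) & ~np.isin(arr, np.asarray(levels, dtype=object))
    if bad.any():
        raise DataError(f"column {spec.name!r} has values outside declared levels")
    cols = np.column_stack([(arr == lv).astype(np.float64) for lv in levels[1:]])
    labels = [f"{spec.name}[{lv}]" for lv in levels[1:]]
    return cols, labels


def design_matrix(
    df: pd.DataFrame,
    schema: DataSchema,
    drop: tuple[str, ...] = (),
) -> tuple[np.ndarray, np.ndarray, DesignInfo]:
    """Build (X, y, info) for the logistic analysis model.

    X has an intercept first, then each covariate's block in schema order
    (reference-level dummy coding).  ``drop`` removes covariates, giving the
    restricted design for a likelihood-ratio test.
    """
    n = len(df)
    blocks = [np.ones((n, 1))]
    labels = ["Intercept"]
    slices: dict[str, slice] = {}
    pos = 1
    for c in schema.covariates:
        if c.name in drop:
            continue
        if c.name not in df.columns:
            raise DataError(f"covariate {c.name!r} missing from data")
        cols, labs = _encode_column(c, df[c.name])
        if np.isnan(cols).any():
            raise DataError(f"covariate {c.name!r} contains missing values in a completed dataset")
        blocks.append(cols)
        labels.extend(labs)
        slices[c.name] = slice(pos, pos + cols.shape[1])
        pos += cols.shape[1]
    X = np.concatenate(blocks, axis=1)
    out = schema.outcome
    yv = df[out.name].to_numpy()
    y = (yv == out.levels[1]).astype(np.float64)
    if pd.isna(yv).any():
        raise DataError("outcome contains missing values")
    return X, y, DesignInfo(tuple(labels), slices)
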