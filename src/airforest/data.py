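"""Typed tabular data: column schemas, the DataMatrix container and encoding.

Covariate kinds
---------------
``continuous``
    Real-valued; split with thresholds.
``binary`` / ``snp``
    0/1 indicators and 0/1/2 additive genotype codes; handled as numeric
    with threshold splits (GWAS convention).
``ordered``
    Ordered factor; level codes are split with thresholds.
``nominal``
    Unordered factor; split by enumerating level subsets.

Internally every covariate becomes a float64 column: numeric kinds keep
their values, factor kinds hold level codes ``0..k-1`` in the declared
level order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .errors import DataError, SchemaError

COVARIATE_KINDS = ("continuous", "binary", "snp", "ordered", "nominal")
OUTCOME_KINDS = ("binary", "multiclass", "continuous")

# nominal level subsets are stored as int64 bitmasks
MAX_NOMINAL_LEVELS = 63


@dataclass
class ColumnSchema:
    """Declared name, role and kind of one column."""

    name: str
    kind: str
    role: str = "covariate"  # "covariate" | "outcome"
    levels: tuple | None = None

    def __post_init__(self):
        if self.role not in ("covariate", "outcome"):
            raise SchemaError(f"column {self.name!r}: unknown role {self.role!r}")
        valid = OUTCOME_KINDS if self.role == "outcome" else COVARIATE_KINDS
        if self.kind not in valid:
            raise SchemaError(
                f"column {self.name!r}: kind {self.kind!r} not one of {valid}"
            )
        if self.kind in ("ordered", "nominal"):
            if self.levels is None or len(self.levels) < 2:
                raise SchemaError(
                    f"factor column {self.name!r} needs >= 2 declared levels"
                )
            self.levels = tuple(self.levels)
            if self.kind == "nominal" and len(self.levels) > MAX_NOMINAL_LEVELS:
                raise SchemaError(
                    f"nominal column {self.name!r} has {len(self.levels)} levels; "
                    f"at most {MAX_NOMINAL_LEVELS} are supported"
                )


@dataclass
class EncodedData:
    """Numeric view of a DataMatrix, ready for the tree kernels."""

    X: np.ndarray          # (n, p) float64, C order
    y_cls: np.ndarray      # (n,) int64 labels (dummy for regression)
    y_reg: np.ndarray      # (n,) float64 (dummy for classification)
    task: int              # K.TASK_CLS | K.TASK_REG
    J: int                 # number of classes (1 for regression)
    kinds: np.ndarray      # (p,) int8, K.KIND_NUMERIC | K.KIND_NOMINAL
    n_levels: np.ndarray   # (p,) int64, 0 for numeric columns
    names: list            # covariate names
    classes: np.ndarray | None = None  # original class labels


@dataclass
class DataMatrix:
    """Outcome vector plus typed covariate columns.

    The universal input of the package: simulation produces it, the IO
    layer reads it from delimited text, and the estimators accept either
    a DataMatrix or a raw ``(X, y)`` pair.
    """

    X: pd.DataFrame
    y: pd.Series
    schema: list = field(default_factory=list)  # covariate ColumnSchema, in order
    outcome_kind: str = "binary"

    def __post_init__(self):
        if len(self.X) != len(self.y):
            raise DataError("outcome and covariates have different lengths")
        if not self.schema:
            self.schema = infer_covariate_schema(self.X)
        if len(self.schema) != self.X.shape[1]:
            raise SchemaError("schema does not cover every covariate column")
        if self.outcome_kind not in OUTCOME_KINDS:
            raise SchemaError(f"unknown outcome kind {self.outcome_kind!r}")
        _check_no_missing(self.X, self.y)

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def task(self) -> str:
        return "regression" if self.outcome_kind == "continuous" else "classification"

    def encode(self) -> EncodedData:
        return encode(self.X, self.y, self.schema, self.outcome_kind)


def _check_no_missing(X: pd.DataFrame, y: pd.Series | None = None):
    na_cols = [c for c in X.columns if X[c].isna().any()]
    if y is not None and y.isna().any():
        na_cols = ["<outcome>"] + na_cols
    if na_cols:
        raise DataError(
            "missing values are not supported (columns: " + ", ".join(map(str, na_cols)) + ")"
        )


def infer_covariate_schema(X: pd.DataFrame) -> list:
    """Derive covariate kinds from dtypes.

    Numeric columns become continuous, ordered categoricals become
    ordered factors, everything else (object/string/unordered
    categorical/bool) becomes a nominal factor with levels taken from
    the data in sorted order.
    """
    schema = []
    for name in X.columns:
        col = X[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            kind = "ordered" if col.dtype.ordered else "nominal"
            schema.append(ColumnSchema(str(name), kind, levels=tuple(col.dtype.categories)))
        elif col.dtype == bool:
            schema.append(ColumnSchema(str(name), "binary"))
        elif pd.api.types.is_numeric_dtype(col):
            schema.append(ColumnSchema(str(name), "continuous"))
        else:
            levels = tuple(sorted(pd.unique(col.astype(str))))
            schema.append(ColumnSchema(str(name), "nominal", levels=levels))
    return schema


def _encode_factor(col: pd.Series, spec: ColumnSchema) -> np.ndarray:
    if isinstance(col.dtype, pd.CategoricalDtype):
        codes = np.asarray(col.cat.set_categories(list(spec.levels)).cat.codes,
                           dtype=np.int64)
    else:
        if spec.levels and all(isinstance(l, str) for l in spec.levels):
            col = col.astype(str)
        codes = np.asarray(pd.Categorical(col, categories=list(spec.levels)).codes,
                           dtype=np.int64)
    if (codes < 0).any():
        bad = sorted(set(np.asarray(col)[codes < 0].tolist()))
        raise SchemaError(
            f"column {spec.name!r}: value(s) {bad} are not declared levels"
        )
    return codes.astype(np.float64)


def encode(X: pd.DataFrame, y, schema: list, outcome_kind: str) -> EncodedData:
    """Turn a typed DataFrame + schema into the kernel representation."""
    n, p = X.shape
    if n < 2:
        raise DataError("need at least 2 samples")
    X_enc = np.empty((n, p), dtype=np.float64, order="C")
    kinds = np.zeros(p, dtype=np.int8)
    n_levels = np.zeros(p, dtype=np.int64)
    names = []
    for i, spec in enumerate(schema):
        col = X.iloc[:, i]
        names.append(spec.name)
        if spec.kind == "nominal":
            X_enc[:, i] = _encode_factor(col, spec)
            kinds[i] = K.KIND_NOMINAL
            n_levels[i] = len(spec.levels)
        elif spec.kind == "ordered":
            X_enc[:, i] = _encode_factor(col, spec)
            kinds[i] = K.KIND_NUMERIC
            n_levels[i] = len(spec.levels)
        else:
            vals = pd.to_numeric(col, errors="coerce")
            if vals.isna().any():
                raise SchemaError(f"column {spec.name!r}: non-numeric values in a numeric column")
            X_enc[:, i] = np.asarray(vals, dtype=np.float64)
            kinds[i] = K.KIND_NUMERIC

    y = pd.Series(y).reset_index(drop=True)
    if outcome_kind == "continuous":
        y_reg = np.asarray(pd.to_numeric(y), dtype=np.float64)
        return EncodedData(X_enc, np.zeros(n, np.int64), y_reg, K.TASK_REG, 1,
                           kinds, n_levels, names)
    classes, y_cls = np.unique(np.asarray(y), return_inverse=True)
    if outcome_kind == "binary" and len(classes) > 2:
        raise SchemaError(
            f"binary outcome has {len(classes)} distinct values"
        )
    return EncodedData(X_enc, y_cls.astype(np.int64), np.zeros(n, np.float64),
                       K.TASK_CLS, max(len(classes), 1), kinds, n_levels, names,
                       classes=classes)
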