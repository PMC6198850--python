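"""Elementary split-search operations, exposed for direct use and testing.

These are thin Python wrappers over the numba kernels that the forest
uses internally, so a property verified here holds verbatim inside the
trees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels as K
from .errors import DegenerateNodeError, ParameterError, UnsupportedConfigurationError


def gini_impurity(class_counts) -> float:
    """Gini impurity ``sum_j phi_j (1 - phi_j)`` of a node.

    ``class_counts`` are nonnegative per-class counts; at least one must
    be positive.  The value lies in ``[0, 1 - 1/J]`` and is zero iff the
    node is pure.
    """
    c = np.asarray(class_counts, dtype=np.float64)
    if c.ndim != 1 or (c < 0).any():
        raise ParameterError("class counts must be a nonnegative vector")
    total = c.sum()
    if total == 0:
        raise DegenerateNodeError("all class counts are zero")
    phi = c / total
    return float(np.sum(phi * (1.0 - phi)))


def sse_impurity(values) -> float:
    """Sum of squares ``sum (y - ybar)^2`` of a node's outcome values.

    The variance differs only by the constant factor 1/n; the node-size-
    weighted decreases the forest accumulates are identical either way,
    so the plain sum of squares is the canonical internal unit.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise DegenerateNodeError("empty node")
    return float(np.sum((v - v.mean()) ** 2))


@dataclass
class Split:
    """One split rule plus its node-size-weighted impurity decrease.

    ``variable_index`` is the raw candidate-pool index (0-based here;
    indices >= p denote shadow variables inside a forest).  Exactly one
    of ``threshold`` / ``left_levels`` is set.
    """

    variable_index: int
    decrease: float
    node_size: int
    threshold: float | None = None
    left_levels: frozenset | None = None


def best_split_for_variable(values, kind, outcome, task,
                            n_levels: int | None = None,
                            max_exhaustive_partition_levels: int = 12,
                            variable_index: int = 0) -> Split | None:
    """Best single-variable split, or None if no split has positive gain.

    ``kind`` is one of the covariate kinds ("continuous", "binary",
    "snp", "ordered", "nominal"); nominal values must be level codes
    0..k-1.  ``task`` is "classification" (outcome = integer labels) or
    "regression".  The returned ``decrease`` is the node-size-weighted
    impurity reduction ``n * [Gamma(parent) - (nL/n) Gamma(L) -
    (nR/n) Gamma(R)]`` (SSE analogue for regression).
    """
    v = np.ascontiguousarray(values, dtype=np.float64)
    m = v.shape[0]
    if m < 2:
        return None
    if task == "classification":
        y = np.ascontiguousarray(outcome, dtype=np.int64)
        J = int(y.max()) + 1 if y.size else 1
    else:
        y = np.ascontiguousarray(outcome, dtype=np.float64)
        J = 1
    nominal = kind == "nominal"
    if nominal:
        k = int(n_levels) if n_levels is not None else int(v.max()) + 1
        k_obs = np.unique(v).size
        if task == "classification" and J > 2 and k_obs > max_exhaustive_partition_levels:
            raise UnsupportedConfigurationError(
                "multiclass nominal splitting beyond exhaustive enumeration "
                f"(observed levels {k_obs} > {max_exhaustive_partition_levels}) "
                "is not supported"
            )
        if task == "classification":
            gain, mask = K._split_nominal_cls(v, y, J, k, max_exhaustive_partition_levels)
        else:
            gain, mask = K._split_nominal_reg(v, y, k, max_exhaustive_partition_levels)
        if gain <= 0.0:
            return None
        left = frozenset(l for l in range(k) if (int(mask) >> l) & 1)
        return Split(variable_index, float(gain), m, left_levels=left)
    if task == "classification":
        gain, thr = K._split_numeric_cls(v, y, J)
    else:
        gain, thr = K._split_numeric_reg(v, y)
    if gain <= 0.0:
        return None
    return Split(variable_index, float(gain), m, threshold=float(thr))


def draw_candidates(pool_size: int, mtry: int, rng) -> np.ndarray:
    """Sample mtry distinct candidate indices uniformly from 0..pool_size-1.

    In augmented mode the pool has size 2p, so an original variable and
    its shadow may both be drawn at the same node.
    """
    if mtry > pool_size:
        raise ParameterError(f"mtry={mtry} exceeds the candidate pool size {pool_size}")
    if mtry < 1:
        raise ParameterError("mtry must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    return rng.choice(pool_size, size=mtry, replace=False)


def resolve_candidate(j: int, X, reordering=None) -> np.ndarray:
    """Resolve a raw pool index to a covariate column.

    ``j < p`` returns column j unchanged; ``j >= p`` returns column
    ``j - p`` with its rows rearranged by the forest reordering, i.e. the
    shadow copy, whose marginal distribution equals the original's
    exactly.
    """
    X = np.asarray(X, dtype=np.float64)
    p = X.shape[1]
    if not 0 <= j < 2 * p:
        raise ParameterError(f"candidate index {j} outside the pool 0..{2 * p - 1}")
    if j < p:
        return X[:, j].copy()
    if reordering is None:
        raise ParameterError("shadow index requested but the forest has no reordering")
    perm = np.asarray(reordering, dtype=np.int64)
    return X[perm, j - p].copy()
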