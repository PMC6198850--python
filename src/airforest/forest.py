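"""Random-forest estimators with an optional shadow-variable candidate pool.

The estimators follow scikit-learn conventions (``fit`` / ``predict``,
``get_params`` / ``set_params``, trailing-underscore fitted attributes)
and accept numpy arrays, pandas DataFrames with typed columns, or a
:class:`~airforest.data.DataMatrix`.

``candidate_pool="augmented"`` implements the debiasing device behind the
AIR importance: before training, a single random reordering ``pi`` of the
sample indices is drawn; at every node the mtry split candidates are
sampled from the doubled pool ``{1..2p}``, where index ``p+i`` resolves to
covariate ``i`` read through ``pi`` (a shadow copy with the same marginal
distribution but no residual association with the outcome).  Impurity
decreases won by original indices accrue positively to a variable's
importance, decreases won by its shadow accrue negatively, giving the
actual-impurity-reduction (AIR) score

    AIR_i = VIM_i(original splits) - VIM_i(shadow splits).

Forests grown with the augmented pool waste a fraction of their splits on
uninformative shadows, so they are importance estimators, not prediction
models; ``predict`` refuses to run on them unless forced.
"""

from __future__ import annotations

import logging
import math
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin

from . import _kernels as K
from .data import DataMatrix, EncodedData, encode, infer_covariate_schema
from .errors import (
    DataError,
    ParameterError,
    UnsupportedConfigurationError,
    WrongMethodError,
)

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1


def _spawn_seeds(rng: np.random.Generator, n: int) -> np.ndarray:
    """Derive independent kernel seeds from a master generator."""
    return rng.integers(0, _MAX_SEED, size=n, dtype=np.int64)


class ForestArrays:
    """Flat array storage for a grown forest (one 2-D array per field)."""

    __slots__ = ("sv", "sval", "smask", "lc", "rc", "leaf", "n_nodes",
                 "inbag_count", "acc", "perm", "pool_size", "n_trees", "n", "p")

    def __init__(self, n_trees: int, n: int, p: int, pool_size: int):
        cap = 2 * n + 3
        self.sv = np.full((n_trees, cap), -1, dtype=np.int64)
        self.sval = np.full((n_trees, cap), np.nan, dtype=np.float64)
        self.smask = np.full((n_trees, cap), -1, dtype=np.int64)
        self.lc = np.zeros((n_trees, cap), dtype=np.int64)
        self.rc = np.zeros((n_trees, cap), dtype=np.int64)
        self.leaf = np.zeros((n_trees, cap), dtype=np.float64)
        self.n_nodes = np.zeros(n_trees, dtype=np.int64)
        self.inbag_count = np.zeros((n_trees, n), dtype=np.int64)
        self.acc = np.zeros(pool_size, dtype=np.float64)
        self.perm = np.arange(n, dtype=np.int64)
        self.pool_size = pool_size
        self.n_trees = n_trees
        self.n = n
        self.p = p

    def oob_rows(self, t: int) -> np.ndarray:
        return np.nonzero(self.inbag_count[t] == 0)[0].astype(np.int64)


def grow_forest_arrays(enc: EncodedData, *, n_trees: int, mtry: int,
                       min_node_size: int, resampling: str,
                       subsample_fraction: float, pool_size: int,
                       max_exhaustive_partition_levels: int,
                       perm: np.ndarray, tree_seeds: np.ndarray,
                       reorder_per_tree: bool = False,
                       per_tree_perms: np.ndarray | None = None) -> ForestArrays:
    """Grow ``n_trees`` trees on encoded data; the workhorse behind fit."""
    n, p = enc.X.shape
    fa = ForestArrays(n_trees, n, p, pool_size)
    fa.perm = np.asarray(perm, dtype=np.int64)
    mode = K.RESAMPLE_BOOTSTRAP if resampling == "bootstrap" else K.RESAMPLE_SUBSAMPLE
    sub_k = max(2, int(round(subsample_fraction * n)))
    for t in range(n_trees):
        tree_perm = per_tree_perms[t] if (reorder_per_tree and per_tree_perms is not None) else fa.perm
        fa.n_nodes[t] = K.grow_tree(
            enc.X, enc.y_cls, enc.y_reg, enc.task, enc.J, enc.kinds,
            enc.n_levels, tree_perm, mode, sub_k, mtry, min_node_size,
            pool_size, max_exhaustive_partition_levels,
            int(tree_seeds[t]),
            fa.sv[t], fa.sval[t], fa.smask[t], fa.lc[t], fa.rc[t],
            fa.leaf[t], fa.acc, fa.inbag_count[t])
    return fa


class BaseShadowForest(BaseEstimator):
    """Shared machinery of the classifier and regressor."""

    _task = None  # overridden

    def __init__(self, n_estimators=500, mtry=None, min_node_size=None,
                 resampling="bootstrap", subsample_fraction=0.632,
                 candidate_pool="original", scale_mtry_with_pool=False,
                 reorder_per_tree=False, max_exhaustive_partition_levels=12,
                 column_kinds=None, random_state=None):
        self.n_estimators = n_estimators
        self.mtry = mtry
        self.min_node_size = min_node_size
        self.resampling = resampling
        self.subsample_fraction = subsample_fraction
        self.candidate_pool = candidate_pool
        self.scale_mtry_with_pool = scale_mtry_with_pool
        self.reorder_per_tree = reorder_per_tree
        self.max_exhaustive_partition_levels = max_exhaustive_partition_levels
        self.column_kinds = column_kinds
        self.random_state = random_state

    # -- encoding ---------------------------------------------------------

    def _outcome_kind(self, y):
        if self._task == "regression":
            return "continuous"
        return "binary" if len(pd.unique(np.asarray(y))) <= 2 else "multiclass"

    def _encode_fit_input(self, X, y) -> EncodedData:
        from .data import ColumnSchema  # local to avoid cycle in docs builds

        if isinstance(X, DataMatrix):
            dm = X
            self._schema = dm.schema
            self._frame_input = True
            return dm.encode()
        if isinstance(X, pd.DataFrame):
            schema = infer_covariate_schema(X)
            if self.column_kinds is not None:
                schema = self._apply_kind_overrides(X, schema)
            self._schema = schema
            self._frame_input = True
            return encode(X, y, schema, self._outcome_kind(y))
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise DataError("X must be 2-dimensional")
        df = pd.DataFrame(X, columns=[f"x{i + 1}" for i in range(X.shape[1])])
        schema = []
        kinds = self.column_kinds
        for i, name in enumerate(df.columns):
            kind = kinds[i] if kinds is not None else "continuous"
            if kind in ("nominal", "ordered"):
                levels = tuple(int(v) for v in np.sort(np.unique(X[:, i])))
                # codes must be the values themselves: require 0..k-1 coding
                if levels != tuple(range(len(levels))):
                    df[name] = pd.Categorical(X[:, i].astype(np.int64),
                                              categories=[int(v) for v in np.sort(np.unique(X[:, i]))])
                    levels = tuple(df[name].cat.categories)
                schema.append(ColumnSchema(name, kind, levels=levels))
            else:
                schema.append(ColumnSchema(name, kind))
        self._schema = schema
        self._frame_input = False
        return encode(df, y, schema, self._outcome_kind(y))

    def _apply_kind_overrides(self, X, schema):
        from .data import ColumnSchema

        kinds = self.column_kinds
        if isinstance(kinds, dict):
            mapping = kinds
        else:
            mapping = dict(zip([s.name for s in schema], kinds))
        out = []
        for s in schema:
            kind = mapping.get(s.name, s.kind)
            if kind == s.kind:
                out.append(s)
            elif kind in ("nominal", "ordered"):
                levels = s.levels or tuple(sorted(pd.unique(X[s.name])))
                out.append(ColumnSchema(s.name, kind, levels=levels))
            else:
                out.append(ColumnSchema(s.name, kind))
        return out

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None):
        if isinstance(X, DataMatrix) and y is None:
            y = X.y
        enc = self._encode_fit_input(X, y)
        n, p = enc.X.shape
        if n < 2:
            raise DataError("need at least 2 samples to grow a forest")
        if self.n_estimators < 1:
            raise ParameterError("n_estimators must be positive")
        if self.resampling not in ("bootstrap", "subsample"):
            raise ParameterError(f"unknown resampling {self.resampling!r}")
        if self.candidate_pool not in ("original", "original_only", "augmented"):
            raise ParameterError(f"unknown candidate_pool {self.candidate_pool!r}")
        augmented = self.candidate_pool == "augmented"
        pool_size = 2 * p if augmented else p

        max_exh = int(self.max_exhaustive_partition_levels)
        if enc.task == K.TASK_CLS and enc.J > 2:
            for i in range(p):
                if enc.kinds[i] == K.KIND_NOMINAL and enc.n_levels[i] > max_exh:
                    raise UnsupportedConfigurationError(
                        f"nominal covariate {enc.names[i]!r} has {enc.n_levels[i]} "
                        f"levels; with a multiclass outcome only exhaustive "
                        f"partitioning (<= {max_exh} levels) is supported"
                    )

        mtry = self.mtry
        if mtry is None:
            if enc.task == K.TASK_CLS:
                mtry = max(1, int(math.floor(math.sqrt(p))))
            else:
                mtry = max(1, p // 3)
        if self.scale_mtry_with_pool and augmented:
            mtry = min(pool_size, 2 * mtry)
        if not 1 <= mtry <= pool_size:
            raise ParameterError(
                f"mtry={mtry} must be in 1..{pool_size} (candidate pool size)"
            )

        min_node = self.min_node_size
        if min_node is None:
            min_node = 1 if enc.task == K.TASK_CLS else 5
        if min_node < 1:
            raise ParameterError("min_node_size must be positive")

        rng = np.random.default_rng(self.random_state)
        # pi is drawn once per forest, before any tree
        perm = rng.permutation(n).astype(np.int64) if augmented else np.arange(n, dtype=np.int64)
        per_tree_perms = None
        if augmented and self.reorder_per_tree:
            per_tree_perms = np.stack([
                rng.permutation(n).astype(np.int64) for _ in range(self.n_estimators)
            ])
        tree_seeds = _spawn_seeds(rng, self.n_estimators)

        fa = grow_forest_arrays(
            enc, n_trees=self.n_estimators, mtry=mtry, min_node_size=min_node,
            resampling=self.resampling, subsample_fraction=self.subsample_fraction,
            pool_size=pool_size, max_exhaustive_partition_levels=max_exh,
            perm=perm, tree_seeds=tree_seeds,
            reorder_per_tree=bool(augmented and self.reorder_per_tree),
            per_tree_perms=per_tree_perms,
        )

        self._enc = enc
        self.forest_ = fa
        self.n_features_in_ = p
        self.feature_names_in_ = np.asarray(enc.names, dtype=object)
        self.mtry_ = mtry
        self.min_node_size_ = min_node
        self.reordering_ = perm
        self.augmented_ = augmented
        self.split_decrease_sums_ = fa.acc.copy()
        if enc.classes is not None:
            self.classes_ = enc.classes
        oob = self.oob_error()
        logger.info("forest grown: %d trees, n=%d, p=%d, mtry=%d, OOB error %.4f",
                    self.n_estimators, n, p, mtry, oob if oob == oob else float("nan"))
        return self

    # -- importance accessors ---------------------------------------------

    @property
    def feature_importances_(self) -> np.ndarray:
        """MDI scores (original pool) or AIR scores (augmented pool)."""
        fa = self.forest_
        if self.augmented_:
            return (fa.acc[:fa.p] - fa.acc[fa.p:]) / fa.n_trees
        return fa.acc / fa.n_trees

    # -- prediction --------------------------------------------------------

    def _encode_predict_input(self, X) -> np.ndarray:
        if isinstance(X, DataMatrix):
            X = X.X
        if isinstance(X, pd.DataFrame):
            enc = encode(X, pd.Series(np.zeros(len(X))), self._schema, "continuous")
            return enc.X
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise DataError("X has the wrong number of columns")
        return np.ascontiguousarray(X)

    def _raw_predict(self, X_enc: np.ndarray) -> np.ndarray:
        fa = self.forest_
        n_rows = X_enc.shape[0]
        rows = np.arange(n_rows, dtype=np.int64)
        perm = fa.perm
        if X_enc.shape[0] != perm.shape[0]:
            perm = np.arange(n_rows, dtype=np.int64)
        out = np.empty(n_rows, np.float64)
        if self._enc.task == K.TASK_CLS:
            votes = np.zeros((n_rows, self._enc.J), dtype=np.int64)
            for t in range(fa.n_trees):
                K.predict_rows(X_enc, perm, fa.p, fa.sv[t], fa.sval[t], fa.smask[t],
                               fa.lc[t], fa.rc[t], fa.leaf[t], rows, out, -1,
                               np.empty(0, np.float64))
                votes[rows, out.astype(np.int64)] += 1
            return votes.argmax(axis=1).astype(np.float64)
        acc = np.zeros(n_rows, np.float64)
        for t in range(fa.n_trees):
            K.predict_rows(X_enc, perm, fa.p, fa.sv[t], fa.sval[t], fa.smask[t],
                           fa.lc[t], fa.rc[t], fa.leaf[t], rows, out, -1,
                           np.empty(0, np.float64))
            acc += out
        return acc / fa.n_trees

    def predict(self, X, force=False):
        self._check_fitted()
        if self.augmented_ and not force:
            raise WrongMethodError(
                "this forest was grown with the augmented (shadow) candidate "
                "pool for importance estimation; a fraction of its splits is "
                "deliberately uninformative, so predictions are degraded. "
                "Grow a separate forest with candidate_pool='original' for "
                "prediction, or pass force=True to override."
            )
        if self.augmented_:
            warnings.warn("predicting with an augmented-pool forest; accuracy "
                          "is degraded by shadow splits", stacklevel=2)
        raw = self._raw_predict(self._encode_predict_input(X))
        if self._enc.task == K.TASK_CLS:
            return self.classes_[raw.astype(np.int64)]
        return raw

    # -- OOB ---------------------------------------------------------------

    def oob_error(self, per_tree: bool = False):
        """OOB misclassification rate (classification) or MSE (regression).

        ``per_tree=True`` returns one value per tree (its error on its
        own OOB rows; NaN for trees with an empty OOB set)."""
        self._check_fitted()
        fa = self.forest_
        enc = self._enc
        out_buf = np.empty(fa.n, np.float64)
        if per_tree:
            errs = np.full(fa.n_trees, np.nan)
            for t in range(fa.n_trees):
                rows = fa.oob_rows(t)
                if rows.size == 0:
                    logger.info("tree %d has an empty OOB set; skipped", t)
                    continue
                K.predict_rows(enc.X, fa.perm, fa.p, fa.sv[t], fa.sval[t],
                               fa.smask[t], fa.lc[t], fa.rc[t], fa.leaf[t],
                               rows, out_buf[:rows.size], -1, np.empty(0, np.float64))
                preds = out_buf[:rows.size]
                if enc.task == K.TASK_CLS:
                    errs[t] = np.mean(preds.astype(np.int64) != enc.y_cls[rows])
                else:
                    errs[t] = np.mean((preds - enc.y_reg[rows]) ** 2)
            return errs
        # ensemble OOB: aggregate per-row over the trees where the row is OOB
        if enc.task == K.TASK_CLS:
            votes = np.zeros((fa.n, enc.J), dtype=np.int64)
        else:
            sums = np.zeros(fa.n, np.float64)
            cnts = np.zeros(fa.n, np.int64)
        for t in range(fa.n_trees):
            rows = fa.oob_rows(t)
            if rows.size == 0:
                continue
            K.predict_rows(enc.X, fa.perm, fa.p, fa.sv[t], fa.sval[t],
                           fa.smask[t], fa.lc[t], fa.rc[t], fa.leaf[t],
                           rows, out_buf[:rows.size], -1, np.empty(0, np.float64))
            preds = out_buf[:rows.size]
            if enc.task == K.TASK_CLS:
                votes[rows, preds.astype(np.int64)] += 1
            else:
                sums[rows] += preds
                cnts[rows] += 1
        if enc.task == K.TASK_CLS:
            covered = votes.sum(axis=1) > 0
            if not covered.any():
                return np.nan
            pred = votes[covered].argmax(axis=1)
            return float(np.mean(pred != enc.y_cls[covered]))
        covered = cnts > 0
        if not covered.any():
            return np.nan
        pred = sums[covered] / cnts[covered]
        return float(np.mean((pred - enc.y_reg[covered]) ** 2))

    def _check_fitted(self):
        if not hasattr(self, "forest_"):
            raise WrongMethodError("forest not fitted; call fit first")


class ShadowForestClassifier(ClassifierMixin, BaseShadowForest):
    """Classification forest (Gini splitting), grown to purity by default.

    Parameters follow ranger-style conventions: ``mtry`` defaults to
    ``floor(sqrt(p))`` and ``min_node_size`` to 1.
    """

    _task = "classification"


class ShadowForestRegressor(RegressorMixin, BaseShadowForest):
    """Regression forest (sum-of-squares splitting).

    ``mtry`` defaults to ``floor(p/3)`` and ``min_node_size`` to 5.
    """

    _task = "regression"


def grow_forest(data: DataMatrix, **params) -> BaseShadowForest:
    """Functional wrapper: grow a forest appropriate for the outcome kind."""
    cls = ShadowForestRegressor if data.task == "regression" else ShadowForestClassifier
    est = cls(**params)
    est.fit(data, data.y)
    return est


def oob_error(forest: BaseShadowForest, per_tree: bool = False):
    """Functional wrapper around :meth:`BaseShadowForest.oob_error`."""
    return forest.oob_error(per_tree=per_tree)
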