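"""The four variable-importance measures: MDI, MDA, holdout and AIR.

MDI (mean decrease of impurity / Gini importance)
    Sum of node-size-weighted impurity decreases at all nodes split on a
    variable, divided by the number of trees.  Always nonnegative and
    biased in favour of variables with many split points or high minor
    allele frequency.

MDA (mean decrease of accuracy / permutation importance)
    Per tree, the increase in OOB error after permuting a variable's
    OOB values, averaged over trees.  Unbiased in location but with a
    skew towards positive values under the null.

Holdout importance
    Permutation importance via a 2-fold split: a forest grown on each
    half is scored on the other half, the two directions are averaged.
    Symmetric around zero under the null.

AIR (actual impurity reduction)
    The debiased impurity importance: decreases won by a variable's
    original column minus decreases won by its shadow copy, both
    competing inside a single forest whose candidate pool is doubled.
    Symmetric around zero under the null at the cost of one forest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels as K
from .data import DataMatrix
from .errors import DataError, WrongMethodError
from .forest import (BaseShadowForest, ShadowForestClassifier,
                     ShadowForestRegressor, _spawn_seeds)

logger = logging.getLogger(__name__)

METHODS = ("mdi", "mda", "holdout", "air")


@dataclass
class ImportanceResult:
    """Per-variable scores tagged with their method and forest metadata."""

    method: str
    scores: np.ndarray
    names: list
    n_trees: int
    task: str
    seed: object = None
    extras: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.names, "method": self.method,
                             "score": self.scores})

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)


def _forest_cls(task: str):
    return ShadowForestRegressor if task == "regression" else ShadowForestClassifier


def _resolve_xy(data, y):
    if isinstance(data, DataMatrix):
        return data, data.y, data.task
    return data, y, None


def impurity_importance(forest: BaseShadowForest) -> ImportanceResult:
    """MDI scores of a fitted original-pool forest."""
    forest._check_fitted()
    if forest.augmented_:
        raise WrongMethodError(
            "impurity importance of an augmented-pool forest mixes original "
            "and shadow decreases; use air_importance / air_scores_from_forest"
        )
    fa = forest.forest_
    scores = fa.acc[:fa.p] / fa.n_trees
    return ImportanceResult("mdi", scores, list(forest.feature_names_in_),
                            fa.n_trees, forest._task, forest.random_state)


def air_scores_from_forest(forest: BaseShadowForest) -> ImportanceResult:
    """AIR accounting on any fitted forest.

    Scores are (original-index decreases - shadow-index decreases) per
    tree.  On a forest whose shadow pool was never drawn (in particular
    any original-pool forest) this reduces exactly to the MDI.
    """
    forest._check_fitted()
    fa = forest.forest_
    pos = fa.acc[:fa.p]
    neg = fa.acc[fa.p:] if fa.pool_size == 2 * fa.p else np.zeros(fa.p)
    scores = (pos - neg) / fa.n_trees
    return ImportanceResult("air", scores, list(forest.feature_names_in_),
                            fa.n_trees, forest._task, forest.random_state,
                            extras={"positive": pos / fa.n_trees,
                                    "negative": neg / fa.n_trees})


def air_importance(data, y=None, *, random_state=None, **forest_params) -> ImportanceResult:
    """Grow one augmented-pool forest and return its AIR scores.

    No replications are performed: a single reordering pi and a single
    forest suffice.
    """
    data, y, task = _resolve_xy(data, y)
    task = forest_params.pop("task", task) or "classification"
    est = _forest_cls(task)(candidate_pool="augmented", random_state=random_state,
                            **forest_params)
    est.fit(data, y)
    res = air_scores_from_forest(est)
    res.seed = random_state
    res.extras["forest"] = est
    return res


def permutation_importance(forest: BaseShadowForest, data=None, y=None,
                           random_state=None) -> ImportanceResult:
    """MDA scores of a fitted original-pool forest.

    One fresh permutation per (tree, variable) of the variable's OOB
    values; the per-tree error increases are averaged over the trees
    with at least 2 OOB rows.  Variables never used by any tree score
    exactly zero.
    """
    forest._check_fitted()
    if forest.augmented_:
        raise WrongMethodError("permutation importance needs an original-pool forest")
    fa = forest.forest_
    enc = forest._enc
    rng = np.random.default_rng(random_state)
    seeds = _spawn_seeds(rng, fa.n_trees)
    scores = np.zeros(fa.p, np.float64)
    n_used = 0
    for t in range(fa.n_trees):
        rows = fa.oob_rows(t)
        base = K.tree_permutation_scores(
            enc.X, enc.y_cls, enc.y_reg, enc.task, fa.perm, fa.p,
            fa.sv[t], fa.sval[t], fa.smask[t], fa.lc[t], fa.rc[t], fa.leaf[t],
            rows, int(seeds[t]), scores)
        if base < 0.0:
            logger.info("tree %d skipped in permutation importance: %d OOB rows",
                        t, rows.size)
            continue
        n_used += 1
    if n_used == 0:
        raise DataError("no tree had enough OOB rows for permutation importance")
    scores /= n_used
    return ImportanceResult("mda", scores, list(forest.feature_names_in_),
                            fa.n_trees, forest._task, random_state,
                            extras={"n_trees_used": n_used})


def holdout_importance(data, y=None, *, random_state=None, stratify=False,
                       **forest_params) -> ImportanceResult:
    """Holdout (2-fold) permutation importance.

    The data are split into random halves; a forest grown on each half
    is scored on the other, with the held-out half playing the OOB role
    for every tree.  The two direction scores are averaged.
    """
    data, y, task = _resolve_xy(data, y)
    task = forest_params.pop("task", task) or "classification"
    params = dict(forest_params)
    n_trees = params.pop("n_estimators", 500)
    cls = _forest_cls(task)
    probe = cls(n_estimators=1, random_state=0, **params)
    enc = probe._encode_fit_input(data, y)
    n, p = enc.X.shape
    if n < 4:
        raise DataError("holdout importance needs at least 4 samples")

    rng = np.random.default_rng(random_state)

    def _draw_halves():
        if stratify and enc.task == K.TASK_CLS:
            idx = []
            for c in range(enc.J):
                rows = np.nonzero(enc.y_cls == c)[0]
                idx.append(rng.permutation(rows))
            order = np.concatenate([np.concatenate([r[i::2] for r in idx])
                                    for i in range(2)])
            half = n // 2
            return np.sort(order[:half]), np.sort(order[half:])
        order = rng.permutation(n)
        half = n // 2
        return np.sort(order[:half]), np.sort(order[half:])

    halves = _draw_halves()
    if enc.task == K.TASK_CLS:
        for attempt in range(2):
            ok = all(np.unique(enc.y_cls[h]).size >= 2 for h in halves)
            if ok:
                break
            if attempt == 1:
                raise DataError("a holdout half contains a single outcome class "
                                "even after resplitting")
            logger.info("holdout half with a single class; resplitting once")
            halves = _draw_halves()

    from .forest import grow_forest_arrays
    import math as _math

    mtry = params.get("mtry") or (
        max(1, int(_math.floor(_math.sqrt(p)))) if enc.task == K.TASK_CLS
        else max(1, p // 3))
    min_node = params.get("min_node_size") or (1 if enc.task == K.TASK_CLS else 5)

    total = np.zeros(p, np.float64)
    perm_full = np.arange(n, dtype=np.int64)
    for train_rows, eval_rows in (halves, halves[::-1]):
        sub_rng = np.random.default_rng(int(rng.integers(0, 2**31 - 1)))
        enc_rows = _subset_encoded(enc, train_rows)
        fa = grow_forest_arrays(
            enc_rows, n_trees=n_trees, mtry=mtry, min_node_size=min_node,
            resampling=params.get("resampling", "bootstrap"),
            subsample_fraction=params.get("subsample_fraction", 0.632),
            pool_size=p,
            max_exhaustive_partition_levels=params.get(
                "max_exhaustive_partition_levels", 12),
            perm=np.arange(len(train_rows), dtype=np.int64),
            tree_seeds=_spawn_seeds(sub_rng, n_trees))
        # score every tree on the full held-out half; the split rules carry
        # over because encoding is global, so trees can read the full matrix
        seeds = _spawn_seeds(sub_rng, n_trees)
        dir_scores = np.zeros(p, np.float64)
        n_used = 0
        eval_rows64 = eval_rows.astype(np.int64)
        for t in range(n_trees):
            base = K.tree_permutation_scores(
                enc.X, enc.y_cls, enc.y_reg, enc.task, perm_full, p,
                fa.sv[t], fa.sval[t], fa.smask[t], fa.lc[t], fa.rc[t], fa.leaf[t],
                eval_rows64, int(seeds[t]), dir_scores)
            if base >= 0.0:
                n_used += 1
        total += dir_scores / max(n_used, 1)
    scores = total / 2.0
    return ImportanceResult("holdout", scores, [s.name for s in probe._schema],
                            n_trees, task, random_state)


def _subset_encoded(enc, rows):
    from .data import EncodedData
    return EncodedData(np.ascontiguousarray(enc.X[rows]), enc.y_cls[rows],
                       enc.y_reg[rows], enc.task, enc.J, enc.kinds,
                       enc.n_levels, enc.names, enc.classes)


def compute_importance(method: str, data, y=None, *, random_state=None,
                       **forest_params) -> ImportanceResult:
    """Dispatch on the method name ('mdi' | 'mda' | 'holdout' | 'air')."""
    method = method.lower()
    if method not in METHODS:
        raise WrongMethodError(f"unknown importance method {method!r}")
    if method == "air":
        return air_importance(data, y, random_state=random_state, **forest_params)
    if method == "holdout":
        return holdout_importance(data, y, random_state=random_state, **forest_params)
    data, y, task = _resolve_xy(data, y)
    task = forest_params.pop("task", task) or "classification"
    rng = np.random.default_rng(random_state)
    est = _forest_cls(task)(random_state=int(rng.integers(0, 2**31 - 1)),
                            **forest_params)
    est.fit(data, y)
    if method == "mdi":
        res = impurity_importance(est)
    else:
        res = permutation_importance(est, random_state=int(rng.integers(0, 2**31 - 1)))
    res.seed = random_state
    res.extras["forest"] = est
    return res
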