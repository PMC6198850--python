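"""Forest growing: determinism, stopping rules, the shadow pool, OOB
error, and the impurity-decrease conservation identity."""

import numpy as np
import pandas as pd
import pytest

from airforest import (DataMatrix, ShadowForestClassifier,
                       ShadowForestRegressor, WrongMethodError, gini_impurity,
                       grow_forest, sse_impurity)
from airforest.simulation import NullScenario, simulate_null


def _forest_fingerprint(est):
    fa = est.forest_
    return (fa.sv.tobytes(), fa.sval.tobytes(), fa.smask.tobytes(),
            fa.inbag_count.tobytes(), fa.acc.tobytes())


class TestDeterminism:
    @pytest.mark.parametrize("pool", ["original", "augmented"])
    def test_same_seed_identical_forest(self, pool):
        dm = simulate_null(NullScenario("A", seed=3))
        a = ShadowForestClassifier(n_estimators=20, candidate_pool=pool,
                                   random_state=7).fit(dm, dm.y)
        b = ShadowForestClassifier(n_estimators=20, candidate_pool=pool,
                                   random_state=7).fit(dm, dm.y)
        assert _forest_fingerprint(a) == _forest_fingerprint(b)
        assert np.array_equal(a.feature_importances_, b.feature_importances_)

    def test_different_seed_different_inbag(self):
        dm = simulate_null(NullScenario("A", seed=3))
        a = ShadowForestClassifier(n_estimators=20, random_state=7).fit(dm, dm.y)
        b = ShadowForestClassifier(n_estimators=20, random_state=8).fit(dm, dm.y)
        assert not np.array_equal(a.forest_.inbag_count, b.forest_.inbag_count)


class TestGrowth:
    def test_separable_data_trains_to_purity(self, perfect_binary):
        X, y = perfect_binary
        est = ShadowForestClassifier(n_estimators=30, min_node_size=1,
                                     random_state=0).fit(X, y)
        assert np.array_equal(est.predict(X), y)

    def test_min_node_size_n_gives_single_leaf_trees(self, perfect_binary):
        X, y = perfect_binary
        est = ShadowForestClassifier(n_estimators=10, min_node_size=len(y),
                                     random_state=0).fit(X, y)
        assert (est.forest_.sv == -1).all()
        assert np.all(est.feature_importances_ == 0.0)

    def test_original_pool_never_references_shadows(self):
        dm = simulate_null(NullScenario("C", seed=5))
        est = ShadowForestClassifier(n_estimators=30, random_state=1).fit(dm, dm.y)
        assert est.forest_.sv.max() < dm.p

    def test_augmented_pool_uses_shadows_and_stores_reordering(self):
        dm = simulate_null(NullScenario("A", seed=5))
        est = ShadowForestClassifier(n_estimators=30, candidate_pool="augmented",
                                     random_state=1).fit(dm, dm.y)
        assert est.forest_.sv.max() >= dm.p  # shadows do win splits under the null
        pi = est.reordering_
        assert sorted(pi) == list(range(dm.n))
        assert not np.array_equal(pi, np.arange(dm.n))

    def test_constant_outcome_gives_single_leaf_trees(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 4))
        est = ShadowForestClassifier(n_estimators=5, random_state=0).fit(
            X, np.zeros(30, dtype=int))
        assert (est.forest_.sv == -1).all()

    def test_augmented_predict_refused_without_force(self):
        dm = simulate_null(NullScenario("A", seed=5))
        est = ShadowForestClassifier(n_estimators=10, candidate_pool="augmented",
                                     random_state=1).fit(dm, dm.y)
        with pytest.raises(WrongMethodError):
            est.predict(dm)
        with pytest.warns(UserWarning):
            est.predict(dm, force=True)


class TestConservation:
    """The recorded decreases of a tree must sum exactly to the drop from
    in-bag root impurity to the summed leaf impurities."""

    @pytest.mark.parametrize("task", ["classification", "regression"])
    def test_per_tree_decrease_accounting(self, task):
        dm = simulate_null(NullScenario("C", seed=9, outcome_task=task))
        cls = (ShadowForestClassifier if task == "classification"
               else ShadowForestRegressor)
        for seed in range(5):
            est = cls(n_estimators=1, random_state=seed).fit(dm, dm.y)
            fa = est.forest_
            enc = est._enc
            # reconstruct the in-bag multiset and drop it through the tree
            rows = np.repeat(np.arange(fa.n), fa.inbag_count[0])
            leaves = {}
            for r in rows:
                node = 0
                while fa.sv[0][node] >= 0:
                    j = fa.sv[0][node]
                    col = j if j < fa.p else j - fa.p
                    row = r if j < fa.p else fa.perm[r]
                    val = enc.X[row, col]
                    if fa.smask[0][node] >= 0:
                        left = (int(fa.smask[0][node]) >> int(val)) & 1
                    else:
                        left = val <= fa.sval[0][node]
                    node = fa.lc[0][node] if left else fa.rc[0][node]
                leaves.setdefault(node, []).append(r)

            def weighted_impurity(rr):
                if task == "classification":
                    counts = np.bincount(enc.y_cls[rr], minlength=enc.J)
                    return len(rr) * gini_impurity(counts)
                return sse_impurity(enc.y_reg[rr])

            root = weighted_impurity(rows)
            leaf_sum = sum(weighted_impurity(np.array(rr)) for rr in leaves.values())
            assert fa.acc.sum() == pytest.approx(root - leaf_sum, abs=1e-8)


class TestOOB:
    def test_perfect_predictor_low_oob_error(self, perfect_binary):
        X, y = perfect_binary
        est = ShadowForestClassifier(n_estimators=100, random_state=2).fit(X, y)
        assert est.oob_error() < 0.05

    def test_null_data_oob_error_near_half(self):
        dm = simulate_null(NullScenario("A", seed=21))
        est = ShadowForestClassifier(n_estimators=100, random_state=2).fit(dm, dm.y)
        assert 0.35 < est.oob_error() < 0.65

    def test_per_tree_length_and_aggregate(self, perfect_binary):
        X, y = perfect_binary
        est = ShadowForestClassifier(n_estimators=25, random_state=2).fit(X, y)
        per_tree = est.oob_error(per_tree=True)
        assert per_tree.shape == (25,)
        assert np.nanmean(per_tree) >= 0.0

    def test_regression_oob_is_mse(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((120, 3))
        y = 2.0 * X[:, 0] + 0.1 * rng.standard_normal(120)
        est = ShadowForestRegressor(n_estimators=100, random_state=2).fit(X, y)
        assert est.oob_error() < np.var(y)  # explains most variance


class TestWrappers:
    def test_grow_forest_dispatches_on_outcome(self):
        dm = simulate_null(NullScenario("A", seed=4, outcome_task="regression"))
        est = grow_forest(dm, n_estimators=5, random_state=0)
        assert isinstance(est, ShadowForestRegressor)

    def test_sklearn_get_set_params_roundtrip(self):
        est = ShadowForestClassifier(n_estimators=12, mtry=4)
        est2 = ShadowForestClassifier(**est.get_params())
        assert est2.n_estimators == 12 and est2.mtry == 4

    def test_dataframe_with_factor_columns(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({
            "num": rng.standard_normal(60),
            "cat": pd.Categorical(rng.choice(list("abc"), 60)),
        })
        y = (X["cat"] == "a").astype(int)
        est = ShadowForestClassifier(n_estimators=40, random_state=0).fit(X, y)
        assert np.array_equal(est.predict(X), y)
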