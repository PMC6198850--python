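"""Impurity measures and single-variable split search, checked against
closed forms and brute-force enumeration."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from airforest import (DegenerateNodeError, ParameterError,
                       UnsupportedConfigurationError, best_split_for_variable,
                       draw_candidates, gini_impurity, resolve_candidate,
                       sse_impurity)


class TestImpurity:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 5], 0.5),
        ([10, 0], 0.0),
        ([3, 1], 0.375),
        ([1, 1, 1], 2 / 3),
    ])
    def test_gini_closed_form(self, counts, expected):
        assert gini_impurity(counts) == pytest.approx(expected)

    def test_gini_rejects_empty_node(self):
        with pytest.raises(DegenerateNodeError):
            gini_impurity([0, 0])

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=6).filter(lambda c: sum(c) > 0))
    @settings(max_examples=200, deadline=None)
    def test_gini_bounds(self, counts):
        J = len(counts)
        g = gini_impurity(counts)
        assert 0.0 <= g <= 1.0 - 1.0 / J + 1e-12
        pure = sum(c > 0 for c in counts) <= 1
        assert (g == 0.0) == pure

    @pytest.mark.parametrize("values,expected", [
        ([2, 2, 2], 0.0),
        ([0, 2], 2.0),
        ([1, 2, 3, 4], 5.0),
    ])
    def test_sse_closed_form(self, values, expected):
        assert sse_impurity(values) == pytest.approx(expected)

    def test_sse_rejects_empty_vector(self):
        with pytest.raises(DegenerateNodeError):
            sse_impurity([])

    @given(st.lists(st.floats(-10, 10), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_sse_nonnegative_zero_iff_constant(self, values):
        s = sse_impurity(values)
        assert s >= 0.0
        if len(set(values)) == 1:
            assert s == pytest.approx(0.0, abs=1e-9)


# ---------------------------------------------------------------------------
# brute-force oracles


def _weighted_decrease(y_left, y_right, task):
    """Node-size-weighted impurity decrease of a concrete bipartition."""
    nl, nr = len(y_left), len(y_right)
    n = nl + nr
    if task == "classification":
        J = int(max(np.max(y_left), np.max(y_right))) + 1

        def imp(y):
            return gini_impurity(np.bincount(y, minlength=J))

        parent = imp(np.concatenate([y_left, y_right]))
        return n * parent - nl * imp(y_left) - nr * imp(y_right)
    return (sse_impurity(np.concatenate([y_left, y_right]))
            - sse_impurity(y_left) - sse_impurity(y_right))


def brute_force_best(values, kind, y, task):
    """Enumerate every admissible split and return the best decrease."""
    values = np.asarray(values)
    y = np.asarray(y)
    best = 0.0
    if kind == "nominal":
        levels = sorted(set(values.tolist()))
        for r in range(1, len(levels)):
            for left in itertools.combinations(levels, r):
                mask = np.isin(values, left)
                d = _weighted_decrease(y[mask], y[~mask], task)
                best = max(best, d)
    else:
        for thr in np.unique(values)[:-1]:
            mask = values <= thr
            d = _weighted_decrease(y[mask], y[~mask], task)
            best = max(best, d)
    return best


@pytest.mark.parametrize("task", ["classification", "regression"])
@pytest.mark.parametrize("kind", ["continuous", "nominal"])
def test_best_split_matches_brute_force(task, kind, rng):
    """On every dataset with <= 8 rows and <= 4 levels the split search
    must agree with exhaustive enumeration of all admissible splits."""
    for trial in range(150):
        m = rng.integers(2, 9)
        if kind == "nominal":
            k = rng.integers(2, 5)
            v = rng.integers(0, k, m).astype(float)
        else:
            v = np.round(rng.standard_normal(m), 1)
        if task == "classification":
            y = rng.integers(0, rng.integers(2, 4), m)
        else:
            y = np.round(rng.standard_normal(m), 2)
        split = best_split_for_variable(v, kind, y, task,
                                        n_levels=4 if kind == "nominal" else None)
        expected = brute_force_best(v, kind, y, task)
        got = 0.0 if split is None else split.decrease
        assert got == pytest.approx(expected, abs=1e-9), \
            f"trial {trial}: v={v}, y={y}"


def test_split_examples_forced_by_formula():
    # perfectly separating threshold: parent Gini 0.5, both children pure
    s = best_split_for_variable([0, 0, 1, 1], "continuous", [0, 0, 1, 1],
                                "classification")
    assert s.decrease == pytest.approx(2.0)
    assert 0 < s.threshold < 1

    # constant covariate: no admissible split point
    assert best_split_for_variable([3, 3, 3, 3], "continuous", [0, 1, 0, 1],
                                   "classification") is None

    # nominal {a,b,c} with y=[A,A,B]: left {c} (or its complement) makes both
    # children pure; weighted decrease = 3 * Gini([2,1]) = 3 * 4/9
    s = best_split_for_variable([0, 1, 2], "nominal", [0, 0, 1],
                                "classification", n_levels=3)
    assert s.decrease == pytest.approx(3 * 4 / 9)
    assert s.left_levels in (frozenset({2}), frozenset({0, 1}))


def test_ordering_trick_equals_exhaustive_partitioning(rng):
    """For binary classification and regression, ordering nominal levels
    by outcome statistic and splitting as ordered finds the same optimal
    decrease as enumerating all 2-partitions."""
    for task in ("classification", "regression"):
        for _ in range(100):
            m = int(rng.integers(8, 40))
            k = int(rng.integers(4, 9))
            v = rng.integers(0, k, m).astype(float)
            y = (rng.integers(0, 2, m) if task == "classification"
                 else np.round(rng.standard_normal(m), 2))
            exh = best_split_for_variable(v, "nominal", y, task, n_levels=k,
                                          max_exhaustive_partition_levels=12)
            trick = best_split_for_variable(v, "nominal", y, task, n_levels=k,
                                            max_exhaustive_partition_levels=2)
            d_exh = 0.0 if exh is None else exh.decrease
            d_trick = 0.0 if trick is None else trick.decrease
            assert d_trick == pytest.approx(d_exh, abs=1e-9)


def test_multiclass_nominal_beyond_enumeration_rejected(rng):
    v = rng.integers(0, 6, 30).astype(float)
    y = rng.integers(0, 3, 30)
    with pytest.raises(UnsupportedConfigurationError):
        best_split_for_variable(v, "nominal", y, "classification", n_levels=6,
                                max_exhaustive_partition_levels=4)


# ---------------------------------------------------------------------------
# candidate drawing and shadow resolution


class TestCandidates:
    def test_exhaustive_draw_returns_all(self, rng):
        assert sorted(draw_candidates(10, 10, rng)) == list(range(10))

    def test_reproducible_and_distinct(self):
        a = draw_candidates(20, 3, np.random.default_rng(7))
        b = draw_candidates(20, 3, np.random.default_rng(7))
        assert np.array_equal(a, b)
        assert len(set(a)) == 3
        assert all(0 <= i < 20 for i in a)

    def test_mtry_larger_than_pool_rejected(self, rng):
        with pytest.raises(ParameterError):
            draw_candidates(5, 6, rng)

    def test_uniform_inclusion_frequency(self, rng):
        pool, mtry, draws = 20, 3, 4000
        freq = np.zeros(pool)
        for _ in range(draws):
            freq[draw_candidates(pool, mtry, rng)] += 1
        freq /= draws
        # each index appears with frequency mtry/pool
        assert np.allclose(freq, mtry / pool, atol=0.02)


class TestResolveCandidate:
    def test_original_index_unchanged(self, rng):
        X = rng.standard_normal((6, 10))
        assert np.array_equal(resolve_candidate(3, X), X[:, 3])

    def test_identity_reordering(self, rng):
        X = rng.standard_normal((6, 10))
        got = resolve_candidate(13, X, np.arange(6))
        assert np.array_equal(got, X[:, 3])

    def test_reversal_preserves_marginal(self, rng):
        X = rng.standard_normal((6, 10))
        got = resolve_candidate(13, X, np.arange(6)[::-1])
        assert np.array_equal(got, X[::-1, 3])
        assert np.array_equal(np.sort(got), np.sort(X[:, 3]))

    def test_shadow_without_reordering_rejected(self, rng):
        X = rng.standard_normal((6, 10))
        with pytest.raises(ParameterError):
            resolve_candidate(13, X)
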