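import numpy as np
import pandas as pd
import pytest

from airforest import DataMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def perfect_binary():
    """n=40 dataset whose outcome equals one binary covariate; 4 noise columns."""
    rng = np.random.default_rng(5)
    x0 = np.tile([0, 1], 20).astype(float)
    X = np.column_stack([x0] + [rng.standard_normal(40) for _ in range(4)])
    return X, x0.astype(int)


@pytest.fixture
def strong_signal():
    """Classification data with 5 informative covariates of decreasing
    strength and 5 pure-noise covariates."""
    rng = np.random.default_rng(11)
    n = 300
    y = rng.binomial(1, 0.5, n)
    cols = {}
    for i, eff in enumerate([2.0, 1.5, 1.0, 0.7, 0.4]):
        cols[f"s{i}"] = eff * (y - 0.5) + rng.standard_normal(n)
    for i in range(5):
        cols[f"n{i}"] = rng.standard_normal(n)
    X = pd.DataFrame(cols)
    return DataMatrix(X, pd.Series(y), outcome_kind="binary")
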