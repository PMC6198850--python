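"""Mirror-null significance testing for signed importance scores.

For an importance measure that is symmetric around zero for variables
unassociated with the outcome (AIR, holdout), the negative scores are a
sample from the lower half of the null distribution.  The empirical null
is therefore assembled from the observed scores themselves:

    M1 = { s : s < 0 },   M2 = { s : s = 0 },   M3 = { -s : s < 0 }

and M = M1 u M2 u M3.  The p-value of variable i is one minus the
empirical CDF of M at its score, p_i = 1 - F0(s_i), with the usual
right-continuous (non-strict, <=) ECDF convention.  The null hypothesis
is "the variable's true importance is <= 0"; it is rejected when
p_i <= alpha.

The construction needs many uninformative variables so that M1 is well
populated; with mostly informative variables it degenerates (see
:class:`~airforest.errors.DegenerateNullError`).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DegenerateNullError, WrongMethodError
from .importance import ImportanceResult, compute_importance

logger = logging.getLogger(__name__)


@dataclass
class NullDistribution:
    """The mirrored empirical null M = M1 u M2 u M3 and its ECDF."""

    m1: np.ndarray
    m2: np.ndarray
    m3: np.ndarray
    sorted_m: np.ndarray = field(init=False)

    def __post_init__(self):
        self.sorted_m = np.sort(np.concatenate([self.m1, self.m2, self.m3]))

    @property
    def size(self) -> int:
        return self.sorted_m.size

    def ecdf(self, x) -> np.ndarray:
        """F0(x) = #{m in M : m <= x} / |M| (right-continuous)."""
        x = np.asarray(x, dtype=np.float64)
        return np.searchsorted(self.sorted_m, x, side="right") / self.size


@dataclass
class TestResult:
    """Per-variable p-values and rejections at level alpha.

    ``p_adjusted`` is populated only when a multiple-testing correction
    was requested; rejections are then based on the adjusted values.
    """

    names: list
    scores: np.ndarray
    p_values: np.ndarray
    alpha: float
    rejected: np.ndarray
    null: NullDistribution
    method: str = ""
    p_adjusted: np.ndarray | None = None

    @property
    def null_size(self) -> int:
        return self.null.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"variable": self.names, "score": self.scores,
                             "p_value": self.p_values, "rejected": self.rejected})

    def to_tsv(self, path):
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {"alpha": self.alpha, "n_m1": int(self.null.m1.size),
                "n_m2": int(self.null.m2.size), "null_size": int(self.null_size),
                "n_rejected": int(self.rejected.sum())}


def mirror_null(scores) -> NullDistribution:
    """Assemble the mirrored empirical null from a full score vector.

    Zero scores enter once (via M2); in practice AIR produces exact
    zeros only for variables never selected in either role, which is the
    intended semantics, so zero detection uses exact equality.
    """
    s = np.asarray(scores, dtype=np.float64)
    m1 = s[s < 0.0]
    if m1.size == 0:
        raise DegenerateNullError(
            "no negative importance scores: the mirror null cannot be built. "
            "The test relies on many unassociated variables; consider a "
            "permutation-based test instead."
        )
    m2 = s[s == 0.0]
    return NullDistribution(m1=m1, m2=m2, m3=-m1)


def benjamini_hochberg(p_values) -> np.ndarray:
    """BH step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=np.float64)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def pvalues(scores, null: NullDistribution, alpha: float = 0.05,
            names=None, method: str = "", correction: str = "none") -> TestResult:
    """p_i = 1 - F0(score_i); reject when p_i <= alpha (alpha=0 rejects nothing).

    ``correction="bh"`` applies the Benjamini-Hochberg adjustment and
    rejects on the adjusted p-values instead (off by default: the
    studies report per-variable rejection rates at the nominal level).
    """
    s = np.asarray(scores, dtype=np.float64)
    p = 1.0 - null.ecdf(s)
    p_adj = None
    p_decide = p
    if correction not in ("none", "bh"):
        raise WrongMethodError(f"unknown correction {correction!r}")
    if correction == "bh":
        p_adj = benjamini_hochberg(p)
        p_decide = p_adj
    rejected = (p_decide <= alpha) if alpha > 0 else np.zeros(s.size, bool)
    if names is None:
        names = [f"x{i + 1}" for i in range(s.size)]
    return TestResult(list(names), s, p, float(alpha), rejected, null, method,
                      p_adjusted=p_adj)


def test_importance(result: ImportanceResult, alpha: float = 0.05,
                    correction: str = "none") -> TestResult:
    """Mirror-null test of an already-computed importance vector."""
    null = mirror_null(result.scores)
    return pvalues(result.scores, null, alpha, names=result.names,
                   method=result.method, correction=correction)


def run_importance_test(data, y=None, *, method: str = "air",
                        alpha: float = 0.05, correction: str = "none",
                        random_state=None, **forest_params) -> TestResult:
    """End to end: grow forest(s), compute importance, mirror-null test.

    Only sign-symmetric measures are admissible: AIR and holdout.  MDI
    is refused (always positive, the null would be empty by
    construction); MDA is allowed with a warning because its null is
    centred at zero but skewed, making the test conservative at best.
    """
    method = method.lower()
    if method == "mdi":
        raise WrongMethodError(
            "the impurity importance is always positive and has no negative "
            "null half; use method='air' or method='holdout'"
        )
    if method == "mda":
        warnings.warn("the permutation importance is not exactly symmetric "
                      "under the null (positive outliers are more likely); "
                      "p-values may be miscalibrated", stacklevel=2)
        logger.warning("mirror-null test requested for MDA, which is not "
                       "entirely unbiased")
    if method not in ("air", "holdout", "mda"):
        raise WrongMethodError(f"unknown importance method {method!r}")
    result = compute_importance(method, data, y, random_state=random_state,
                                **forest_params)
    return test_importance(result, alpha=alpha, correction=correction)
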