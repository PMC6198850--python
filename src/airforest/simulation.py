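"""Synthetic study designs: null-bias scenarios and logit-model power designs.

Null cases (no outcome-covariate association, used to measure importance
bias):

* **Case A** — 10 SNP-like covariates coded 0/1/2, drawn Binomial(2, MAF)
  with MAF = 0.05, 0.10, ..., 0.50.  The impurity importance grows with
  MAF; an unbiased measure should not.
* **Case B** — 10 nominal factors with k = 2,3,4,5,6,7,8,10,20,30
  equally likely categories.  The impurity importance grows with k.
* **Case C** — mixed types: four binary covariates with success
  probabilities 0.05/0.1/0.2/0.5, ordered factors with 5 and 10 levels,
  nominal factors with 5/8/10 levels, and one standard-normal continuous
  covariate; factor categories equally frequent.

The outcome is Bernoulli(0.5) for classification and standard normal for
regression, independent of all covariates.

Power designs draw independent covariates (standard normal
"expression-like" by default, Binomial(2, maf) for SNP-like designs),
assign effect sizes beta to a random subset of columns and draw the
outcome from the logit model logit P(Y=1) = sum_i beta_i x_i with
covariates standardized beforehand so that beta is comparable across
covariate types.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ColumnSchema, DataMatrix
from .errors import ParameterError
from .importance import compute_importance
from .testing import run_importance_test
from .errors import DegenerateNullError

logger = logging.getLogger(__name__)

_MAX_SEED = 2**31 - 1

MAF_GRID = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30, 0.35, 0.40, 0.45, 0.50)
CATEGORY_GRID = (2, 3, 4, 5, 6, 7, 8, 10, 20, 30)
DEFAULT_BETAS = (-1.0, 1.0, -2.0, 2.0, -3.0, 3.0, -4.0, 4.0)


@dataclass
class NullScenario:
    """One of the no-association designs (case A, B or C)."""

    case: str = "A"
    n: int = 100
    outcome_task: str = "classification"
    seed: int | None = None

    def __post_init__(self):
        self.case = self.case.upper()
        if self.case not in ("A", "B", "C"):
            raise ParameterError(f"unknown null case {self.case!r}")
        if self.outcome_task not in ("classification", "regression"):
            raise ParameterError(f"unknown task {self.outcome_task!r}")


@dataclass
class PowerScenario:
    """A logit-model design: independent covariates, a beta grid of effects.

    Defaults mirror a desk-scale version of an expression-like study:
    ``n_effect_each`` variables per effect size in ``effect_sizes`` (the
    default grid {+-1, +-2, +-3, +-4} with 10 each gives 80 effect
    variables), all remaining covariates unassociated.  An empty
    ``effect_sizes`` tuple gives a pure null design.
    """

    p_total: int = 500
    effect_sizes: tuple = DEFAULT_BETAS
    n_effect_each: int = 10
    n: int = 100
    replications: int = 200
    n_trees: int = 500
    mtry: int = 50
    alpha: float = 0.05
    covariate_model: str = "normal"  # "normal" | "snp"
    maf: float = 0.25
    seed: int | None = None

    def __post_init__(self):
        n_effect = len(self.effect_sizes) * self.n_effect_each
        if self.p_total < n_effect:
            raise ParameterError("p_total smaller than the number of effect variables")
        if self.covariate_model not in ("normal", "snp"):
            raise ParameterError(f"unknown covariate model {self.covariate_model!r}")


@dataclass
class StudySummary:
    """Tidy result table of a bias or power study plus raw scores."""

    kind: str                       # "bias" | "power"
    table: pd.DataFrame
    replications: int
    seed: int | None
    scores: dict = field(default_factory=dict)   # bias: method -> (reps, p)
    degenerate_replications: int = 0

    def to_tsv(self, path):
        self.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# data generation


def _null_outcome(task: str, n: int, rng: np.random.Generator) -> pd.Series:
    if task == "regression":
        return pd.Series(rng.standard_normal(n))
    return pd.Series(rng.binomial(1, 0.5, size=n))


def simulate_null(scenario: NullScenario) -> DataMatrix:
    """Generate one dataset under a null case; outcome independent of X."""
    rng = np.random.default_rng(scenario.seed)
    n = scenario.n
    cols = {}
    schema = []
    if scenario.case == "A":
        for maf in MAF_GRID:
            name = f"maf_{maf:.2f}"
            cols[name] = rng.binomial(2, maf, size=n)
            schema.append(ColumnSchema(name, "snp"))
    elif scenario.case == "B":
        for k in CATEGORY_GRID:
            name = f"k_{k}"
            codes = rng.integers(0, k, size=n)
            cols[name] = pd.Categorical(codes, categories=list(range(k)))
            schema.append(ColumnSchema(name, "nominal", levels=tuple(range(k))))
    else:  # case C
        for prob in (0.05, 0.1, 0.2, 0.5):
            name = f"B_{prob}"
            cols[name] = rng.binomial(1, prob, size=n)
            schema.append(ColumnSchema(name, "binary"))
        for k in (5, 10):
            name = f"O_{k}"
            codes = rng.integers(0, k, size=n)
            cols[name] = pd.Categorical(codes, categories=list(range(k)), ordered=True)
            schema.append(ColumnSchema(name, "ordered", levels=tuple(range(k))))
        for k in (5, 8, 10):
            name = f"N_{k}"
            codes = rng.integers(0, k, size=n)
            cols[name] = pd.Categorical(codes, categories=list(range(k)))
            schema.append(ColumnSchema(name, "nominal", levels=tuple(range(k))))
        cols["C"] = rng.standard_normal(n)
        schema.append(ColumnSchema("C", "continuous"))
    X = pd.DataFrame(cols)
    y = _null_outcome(scenario.outcome_task, n, rng)
    kind = "continuous" if scenario.outcome_task == "regression" else "binary"
    return DataMatrix(X, y, schema, outcome_kind=kind)


def simulate_power(scenario: PowerScenario, seed=None):
    """Generate one dataset under a logit-model power design.

    Returns ``(DataMatrix, effects)`` where ``effects`` is the length-p
    vector of true effect sizes (0 for unassociated variables).
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n, p = scenario.n, scenario.p_total
    if scenario.covariate_model == "snp":
        X = rng.binomial(2, scenario.maf, size=(n, p)).astype(np.float64)
        kind = "snp"
    else:
        X = rng.standard_normal((n, p))
        kind = "continuous"

    betas = np.repeat(np.asarray(scenario.effect_sizes, dtype=np.float64),
                      scenario.n_effect_each)
    effects = np.zeros(p)
    if betas.size:
        effect_idx = rng.choice(p, size=betas.size, replace=False)
        effects[effect_idx] = betas
        # standardize so beta is on a common scale across covariate types
        Z = X[:, effect_idx]
        sd = Z.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        Z = (Z - Z.mean(axis=0)) / sd
        eta = Z @ betas
    else:
        eta = np.zeros(n)
    prob = 1.0 / (1.0 + np.exp(-eta))
    y = rng.binomial(1, prob)

    names = [f"x{i + 1}" for i in range(p)]
    schema = [ColumnSchema(nm, kind) for nm in names]
    dm = DataMatrix(pd.DataFrame(X, columns=names), pd.Series(y), schema,
                    outcome_kind="binary")
    return dm, effects


# ---------------------------------------------------------------------------
# studies

QUANTILES = (0.025, 0.25, 0.5, 0.75, 0.975)


def run_bias_study(scenario: NullScenario, replications: int = 2000,
                   n_trees: int = 50, mtry: int | None = None,
                   min_node_size: int | None = None,
                   methods=("mdi", "mda", "holdout", "air"),
                   seed: int | None = None) -> StudySummary:
    """Replicate a null case and collect per-covariate score distributions.

    Per replication: fresh data, fresh forests, all requested importance
    measures.  The summary holds the 2.5/25/50/75/97.5% quantiles, the
    fraction of positive scores and the variance per covariate and
    method — the numeric content of the null-bias boxplots.
    """
    if replications < 1:
        raise ParameterError("replications must be >= 1")
    master = np.random.default_rng(scenario.seed if seed is None else seed)
    rep_seeds = master.integers(0, _MAX_SEED, size=(replications, 2))
    all_scores = {m: None for m in methods}
    names = None
    for r in range(replications):
        dm = simulate_null(NullScenario(scenario.case, scenario.n,
                                        scenario.outcome_task,
                                        seed=int(rep_seeds[r, 0])))
        sub = np.random.default_rng(int(rep_seeds[r, 1]))
        for m in methods:
            res = compute_importance(
                m, dm, random_state=int(sub.integers(0, _MAX_SEED)),
                n_estimators=n_trees, mtry=mtry, min_node_size=min_node_size)
            if all_scores[m] is None:
                all_scores[m] = np.empty((replications, dm.p))
                names = res.names
            all_scores[m][r] = res.scores
    rows = []
    for m in methods:
        sc = all_scores[m]
        qs = np.quantile(sc, QUANTILES, axis=0)
        for i, nm in enumerate(names):
            row = {"covariate": nm, "method": m,
                   "frac_positive": float(np.mean(sc[:, i] > 0)),
                   "variance": float(sc[:, i].var(ddof=1)) if replications > 1 else 0.0}
            for q, qv in zip(QUANTILES, qs[:, i]):
                row[f"q{q}"] = float(qv)
            rows.append(row)
    table = pd.DataFrame(rows)
    return StudySummary("bias", table, replications, seed, scores=all_scores)


def run_power_study(scenario: PowerScenario, methods=("air",),
                    seed: int | None = None) -> StudySummary:
    """Replicate a power design and aggregate rejection proportions.

    Power is the proportion of rejected hypotheses among variables
    sharing the same |beta|; the type I error is the rejection
    proportion among unassociated variables (reported as |beta| = 0).
    Replications whose mirror null degenerates are counted separately
    and excluded from the proportions.
    """
    if scenario.replications < 1:
        raise ParameterError("replications must be >= 1")
    master = np.random.default_rng(scenario.seed if seed is None else seed)
    rep_seeds = master.integers(0, _MAX_SEED, size=(scenario.replications, 2))
    abs_betas = sorted({abs(b) for b in scenario.effect_sizes}) if scenario.effect_sizes else []
    counts = {m: {b: [0, 0] for b in [0.0] + list(abs_betas)} for m in methods}
    degenerate = 0
    for r in range(scenario.replications):
        dm, effects = simulate_power(scenario, seed=int(rep_seeds[r, 0]))
        sub = np.random.default_rng(int(rep_seeds[r, 1]))
        rep_degenerate = False
        for m in methods:
            try:
                tr = run_importance_test(
                    dm, method=m, alpha=scenario.alpha,
                    random_state=int(sub.integers(0, _MAX_SEED)),
                    n_estimators=scenario.n_trees, mtry=scenario.mtry)
            except DegenerateNullError:
                rep_degenerate = True
                logger.warning("replication %d (%s): degenerate mirror null, "
                               "skipped", r, m)
                continue
            ab = np.abs(effects)
            for b in counts[m]:
                sel = ab == b
                counts[m][b][0] += int(tr.rejected[sel].sum())
                counts[m][b][1] += int(sel.sum())
        if rep_degenerate:
            degenerate += 1
    rows = []
    for m in methods:
        for b, (rej, tot) in counts[m].items():
            rows.append({"method": m, "abs_beta": b,
                         "rejection_proportion": rej / tot if tot else np.nan,
                         "n_tests": tot,
                         "role": "type_I_error" if b == 0.0 else "power"})
    table = pd.DataFrame(rows)
    return StudySummary("power", table, scenario.replications, seed,
                        degenerate_replications=degenerate)
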