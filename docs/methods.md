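# Methods

## The problem

Random-forest variable importance is the standard tool for ranking
covariates in high-dimensional life-science data (gene expression,
GWAS).  The cheapest measure, the impurity (Gini) importance or MDI,
sums the node-size-weighted impurity decreases of every split made on a
variable, divided by the number of trees.  It is biased: variables
offering more candidate split points — continuous variables, factors
with many categories, SNPs with high minor allele frequency — win more
and larger chance splits even when they carry no signal, so their MDI is
systematically inflated.  The permutation importance (MDA) avoids this
bias but costs one OOB re-evaluation per tree and variable, which is
prohibitive at GWAS scale.

## The AIR estimator

Write the impurity importance of covariate `X_i` as the sum of a signal
part (heterogeneity reduction genuinely attributable to `X_i`) and a
bias part (reduction due only to the structure of `X_i`).  A shadow copy
of `X_i` — the same column with rows rearranged by a permutation `pi` —
has the same structure, hence the same bias part, but no signal part.
Subtracting the shadow's importance from the original's therefore leaves
an estimate of the signal part alone, the *actual impurity reduction*:

    AIR_i = VIM_i(splits on the original column)
          - VIM_i(splits on its shadow)

The implementation makes this a single-forest, single-pass computation:

1. Before training, draw **one** permutation `pi` of the sample indices.
2. At every node, sample the `mtry` split candidates from the doubled
   pool `{1..2p}`.  An index `j <= p` is the original column `X_j`; an
   index `j > p` resolves to column `X_{j-p}` read through `pi`.  The
   shadow columns are never materialised.
3. Impurity decreases won by original indices accumulate positively into
   that variable's score, decreases won by shadow indices accumulate
   negatively.  Division by the tree count at the end gives AIR.

No replication, no second forest, no permutation re-predictions: the
overhead relative to plain MDI is only the doubled candidate pool.
Because a fraction of splits is deliberately wasted on shadows, an
augmented-pool forest is an importance estimator, not a prediction
model; `predict` refuses to run on one unless forced, and a separate
original-pool forest should be grown for prediction.

Under the null, original and shadow columns are exchangeable candidate
roles, so AIR is symmetric around zero for every covariate regardless of
its MAF, category count or type.  Both halves of the subtraction share
the same forest, which keeps the variance of the difference small.

## Splitting details

* Impurity: Gini `sum_j phi_j (1 - phi_j)` for classification, sum of
  squares for regression (variance differs only by a constant factor and
  leaves the node-size-weighted decreases unchanged).  Recorded node
  decreases are `n_parent * [Gamma(parent) - (nL/n) Gamma(L) - (nR/n)
  Gamma(R)]`, computed through the algebraically equivalent
  sum-of-squared-counts form, which is exact in floating point for
  integer counts.  Gains below a noise floor (1e-10 absolute for
  classification, 1e-9 relative for regression) count as zero, so
  homogeneous children never produce spurious splits.
* Numeric, binary/SNP (0/1/2 additive coding) and ordered-factor
  columns use threshold splits at midpoints between distinct sorted
  values.
* Nominal factors use level-subset splits.  All 2-partitions of the
  observed levels are enumerated up to
  `max_exhaustive_partition_levels` (default 12) observed levels.
  Beyond that, levels are ordered by class-1 frequency (binary
  classification) or outcome mean (regression) and split as if ordered —
  a classical result makes this exactly optimal for these two tasks, and
  the equivalence is property-tested against exhaustive enumeration.
  Multiclass outcomes with nominal factors beyond the exhaustive range
  are refused rather than approximated.
* Ties in gain: the first maximum in candidate-draw order wins; the draw
  order itself is seed-determined, so forests are bit-reproducible.
* Stopping: a node becomes a leaf when pure, at or below
  `min_node_size`, or when no candidate yields positive gain.  A
  bootstrap draw with constant outcome yields a single-leaf tree that
  contributes zero to every importance.

Defaults follow the common conventions: `mtry = floor(sqrt(p))` and
`min_node_size = 1` (grown to purity) for classification,
`mtry = floor(p/3)` and `min_node_size = 5` for regression; bootstrap
resampling of n with replacement (subsampling with fraction 0.632
available).  In augmented mode the pool doubles but the `mtry` count
does not (the candidate *range* changes, not the draw size);
`scale_mtry_with_pool=True` doubles it too for users who want candidate
pressure per original variable held constant.

## The other importance measures

* **MDA**: per tree, the OOB error is recomputed with one variable's
  OOB values freshly permuted; the error increases are averaged over
  trees.  Only OOB values are permuted (equivalent in effect on OOB
  predictions to permuting the full column).  Variables not used by a
  tree are skipped, which both saves time and guarantees an exact zero
  for variables no tree ever used.
* **Holdout**: the data are split into random halves; a forest grown on
  each half is scored on the other half, which plays the OOB role for
  every tree; the two direction scores are averaged.  A half containing
  a single outcome class triggers one resplit, then an error.

## Mirror-null testing

For a measure symmetric around zero under the null (AIR, holdout), the
observed negative scores are a sample of the null's lower half.  The
empirical null is assembled from the scores themselves — negatives (M1),
exact zeros (M2, produced only by variables never selected in either
role), and sign-flipped negatives (M3) — and the p-value of a score `s`
is `1 - F0(s)` with the right-continuous ECDF `F0` of `M = M1 u M2 u
M3`.  Rejection at `p <= alpha`, with `alpha = 0` rejecting nothing.
MDI is refused (no negative half exists); MDA is allowed with a warning
(its null is centred but positively skewed, so p-values can be
miscalibrated).  No multiple-testing correction is applied by default,
matching the per-variable rejection-rate convention of the simulation
studies.  The construction requires many unassociated variables; when no
score is negative a `DegenerateNullError` is raised, and a
permutation-of-outcome test (out of scope here) is the fallback.

## Synthetic designs

The simulation module is first-class, tested code; it defines the study
conditions under which the statistical claims are checked.

* **Null case A** — 10 SNP covariates, Binomial(2, MAF) additive coding,
  MAF = 0.05..0.50 in steps of 0.05.  (The genotype model is the
  standard additive-coding choice; a HWE 3-level factor would differ
  only in coding, not in the bias mechanism.)
* **Null case B** — 10 nominal factors with k = 2,3,4,5,6,7,8,10,20,30
  uniform categories.
* **Null case C** — mixed types: binaries with success probabilities
  0.05/0.1/0.2/0.5, ordered factors (5, 10 levels), nominal factors
  (5, 8, 10 levels), one standard normal.
* Outcomes: Bernoulli(0.5) factor (classification) or standard normal
  (regression), independent of all covariates.  Sample size 100, 50
  trees, node size 1 (classification) / 5 (regression).
* **Power designs** — p independent covariates (standard normal by
  default, Binomial(2, maf) for SNP-like designs), effect sizes
  beta = {±1, ±2, ±3, ±4} with 10 variables each (80 effect variables)
  assigned to a random column subset, outcome from the logit model
  `logit P(Y=1) = sum beta_i x_i` with covariates standardized first so
  beta is comparable across covariate types.  Generating independent
  columns replaces the original practice of permuting a real design
  matrix's columns; the two are statistically equivalent for
  decorrelated covariates.

What the generators deliberately do **not** emulate: correlation between
covariates (real expression/GWAS data are correlated; all importance
measures here are affected by correlation, and passing these tests says
nothing about correlated designs), linkage disequilibrium, missing
genotypes, batch effects, or survival outcomes.

## Study sizes and tolerances

The bias studies run at 2000 replications per null case and the power
study at 100–200 replications with 500 trees — the package's desk-scale
defaults, chosen so a full study completes in minutes on one core.  At
these sizes the Monte-Carlo standard error of a per-covariate median is
about `1.2533 * sd / sqrt(R)` and of a rejection proportion about
`sqrt(a(1-a)/R)`; the acceptance checks use two such standard errors as
their bands.  The type-I-error check uses 500 trees; with markedly fewer
trees the AIR null acquires discreteness (fewer selections per shadow)
and the test can run slightly anti-conservative, consistent with the
recommendation to increase the tree count for very high-dimensional
data.

## Numerical and design choices

* Per-tree seeds (and per-tree-per-variable permutation streams for
  MDA) are spawned from the master `random_state`, so results are
  independent of scheduling and bit-reproducible; the same seed yields
  byte-identical forests, importances and p-values.
* Nominal level subsets are stored as int64 bitmasks, capping nominal
  factors at 63 levels (far above the exhaustive-enumeration range).
* The ECDF uses the non-strict (`<=`) convention; zero detection for M2
  membership is exact equality, which is the intended semantics because
  AIR produces exact zeros only for never-selected variables.
* Single-threaded throughout; the tree kernels are numba-compiled, so
  the first call in a session pays a compilation cost of a few seconds.

## Known limitations

* The mirror-null test needs many unassociated variables; it is not
  usable for low-dimensional, mostly-informative designs.
* AIR shares the general sensitivity of forest importances to
  correlated predictors; no conditional or correlation-adjusted variant
  is provided.
* Survival outcomes, missing values, class weights and
  maximally-selected-rank splitting are out of scope.
* Augmented-pool forests are not prediction models (see above).
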