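# Methods

This note records the modeling choices behind `obecart`, in the spirit of
a statistical software methods appendix: what is computed, under which
assumptions, which knobs matter, and what the synthetic experiments do
and do not demonstrate.

## Ordinal target model

Targets are ordered classes c₁ < … < cₙ with integer values V(cᵢ) = i
(1-based). The integer-value convention makes |V(cᵢ) − V(cⱼ)| a
meaningful class distance and puts MSE-on-class-values and Kendall's τ_b
on a common scale. Files always store class *labels*; indices are an
in-memory detail. A non-negative numeric target (absence hours) is
binned by `HoursBinning`, default boundaries (0, 8, 40): class 1 is the
point mass at zero, then "hours" (0 < y < 8), "days" (8 ≤ y < 40, one
working day to one working week), "weeks" (y ≥ 40). The first boundary
is compared strictly, later ones inclusively; every non-negative value
maps to exactly one class. Missing values are rejected at read time with
a row/column-named error — explicit failure over silent imputation.

## Objective-based entropy

`OBE(c_s, D) = − Σ w(cᵢ) P(cᵢ) log₂ P(cᵢ)` with
`w(cᵢ) ∝ |V(cᵢ) − V(c_s)|^α`, normalized to sum to 1, so w(c_s) = 0.
Logarithms are base 2 (bits) throughout and 0·log 0 ≡ 0.

* **Selected class** (`entropy.statistic`): `max` (default), `min`, or
  `mode`. `max` targets detection of the highest-outcome class, which is
  the usual priority in absenteeism-style applications. For `mode` the
  **scope** matters: `per_node` (default) re-evaluates the mode on each
  tree node's own distribution and uses that single s in the node's
  parent and child terms; `global` fixes s once on the training
  distribution. Per-node is the default because after class balancing
  the global mode is a degenerate (tied) choice, while node-local modes
  still discriminate. Mode ties break toward the higher class value,
  consistent with prioritizing high-outcome detection.
* **α** (dimensionless, > 0; default 2): biases weights toward classes
  far from c_s. As α → 0⁺ the non-selected classes approach the uniform
  weight 1/(n−1), so OBE → (H − h_s)/(n−1) where h_s is the selected
  class's own entropy term — i.e. exact proportionality to Shannon
  entropy holds on the sub-simplex with p_s = 0, and the limit tests are
  formulated there. As α → ∞ all weight concentrates on the class
  maximizing |V(cᵢ) − V(c_s)| (when that argmax is unique; for odd n
  with s centered it is tied and the two extreme weights approach 1/2
  each). α is a per-problem hyperparameter; the `gridsearch` command
  selects it on a holdout criterion (macro-F by default, τ_b
  selectable).

## Tree induction

Greedy binary CART: at each node all candidate splits over all features
are scored by OBIG with the node's selected class held fixed across the
parent and child terms (which makes every candidate's gain ≥ 0, by
concavity of the fixed-weight OBE), and the maximizer is taken.

* Candidates: numeric — midpoints between consecutive distinct sorted
  values, condition `x ≤ t` routes left; categorical — one observed
  category vs rest, `x = a` routes left. Subset splits of categorical
  features are deliberately not searched.
* Tie-breaking: gains are compared with absolute tolerance 1e−12 (guards
  against float summation-order artifacts); ties go to the lowest schema
  feature index, then the smallest threshold / lexicographically first
  category. Fitting is therefore fully deterministic — byte-identical
  models on reruns.
* Stopping (`tree.*`): purity, `max_depth` (default unlimited),
  `min_samples_split` (default 2), `min_samples_leaf` (default 1), and
  best gain ≤ `min_gain` (default 0, i.e. any strictly positive gain
  splits). No pruning is applied; shallow interpretable trees are
  obtained via `max_depth`/`min_samples_leaf`.
* Prediction routes rows by the stored conditions; a category unseen in
  training fails its equality test and follows the "condition false"
  branch. Leaf prediction is the distribution argmax, ties toward the
  higher class.
* OBIGR (the gain divided by the split information of the full
  N_k-way partition) is implemented for completeness and for multiway
  analyses, but the binary CART path does not use it: with N_k = 2 the
  split-information correction mostly reorders balanced vs unbalanced
  splits, not features.
* A `uniform_weights` hook replaces the weight vector by 1/n, collapsing
  the criterion to classical Shannon-entropy CART; it exists so tests can
  verify that classical behavior is recovered exactly.
* Continuous features are used natively; equal-frequency discretization
  is unnecessary for threshold splits and is not performed.

## Preprocessing

* **Stratified holdout** (default test fraction 0.2): per-class test
  counts by largest-remainder rounding of `fraction · n_c` against an
  overall target of `round(fraction · T)`, seeded shuffles within class.
  Train/test class proportions differ from the parent's by less than one
  sample per class. Holdout (not k-fold) is the supported protocol, as
  oversampling inside CV folds is easy to get wrong and expensive.
* **SMOTE** (default k = 5 neighbors): every class is oversampled to the
  majority count. Neighbor search uses Euclidean distance on numeric
  features z-scored *within the minority class* (daily workload ~10⁵
  must not drown BMI ~10¹); synthetic rows interpolate numeric features
  uniformly on the sample–neighbor segment and copy categorical values
  from the seed sample (`"vote"`, SMOTE-NC style majority among the k
  neighbors, is available). Integer-valued numeric features may become
  fractional in synthetic rows; they are left unrounded. A singleton
  minority class cannot be interpolated and raises unless
  `duplicate_singletons` is set. Balanced input passes through
  unchanged. Note the consequence for interpretation: a tree fitted
  after SMOTE carries leaf distributions on the *balanced* scale; for
  subgroup reading on the original scale, fit with `--no-smote`.

## Patterns and subgroup comparison

One pattern per leaf (the exact root-to-leaf conjunction, its class
distribution, support and path id); patterns partition the feature
space. High-risk ranking sorts leaves with support ≥ `min_support` by
descending P(class ≥ target), ties by support then path id. The
complementary subgroup negates the final condition: the sibling leaf's
pattern when the sibling is a leaf, otherwise the sibling subtree's
aggregate (support-weighted mean of its leaves, which the subtree root
already stores).

Distribution comparison is a goodness-of-fit test of the subgroup's
counts against a reference (complementary subgroup or full dataset;
both are exposed because either reference can be scientifically
appropriate): Pearson chi-square when all expected counts ≥ 5,
otherwise a seeded Monte-Carlo multinomial p-value
(1 + #{simulated χ² ≥ observed}) / (B + 1) with B = 10,000 default —
valid at the single-digit supports deep trees produce, and well defined
when the reference has empty categories (an observed count there gives
an infinite statistic, hence the minimal p). Monte-Carlo p-values are
never exactly zero by construction. Feature influence is summarized as
depth of first use plus support-weighted total gain per feature.

## The synthetic generator

`SimSpec` draws independent uniform feature marginals (numeric ranges,
integer ranges, or uniform categories) and plants axis-aligned rules:
with probability `prevalence_r` a row is sampled inside rule r's region;
the *label* is then a deterministic function of the realized features —
first matching rule's class distribution, else the base distribution —
plus uniform label-flip noise. Because regions are boxes and marginals
independent, the expected class mixture has a closed form
(`expected_class_mixture`, inclusion–exclusion over first-match
precedence), which the generator's tests verify by the law of large
numbers at n = 50,000.

`absenteeism_like_spec` emulates the structure of the published
absenteeism data: 18 features (12 numeric, 6 categorical) with plausible
ranges, four classes, and three planted multi-feature rules echoing the
study's example subgroups (age × performance × month → low absence;
height × BMI × performance → high absence, the designated high-class
rule; workload × transport expense → days-level absence). The base
distribution is not hand-set: it is *solved* from the closed-form
mixture so that the generated class shares — label noise included —
equal the study's marginal (6%, 57%, 34%, 3%) exactly in expectation.
Two consequences are worth recording. First, the rule thresholds and
prevalences differ from the study's exemplar cutoffs: the marginal is a
hard budget (a rule concentrated on the 3%-share "weeks" class can
cover at most ~1.5% of rows once noise takes its cut, too little for
any learner to isolate reliably), so the high-class rule concentrates
on the two highest classes jointly (0, 0.05, 0.80, 0.15 over ~9% of
rows), which the 34% "days" share affords. Second, label noise above
~0.25 makes the solve infeasible (the pre-noise "weeks" budget goes
negative) and is rejected with an explanatory error. Default noise is
0.05.

What the generator does **not** emulate: feature correlations, the real
joint distribution, non-uniform marginals, or missingness. Passing
recovery tests therefore demonstrate that the pipeline isolates planted
axis-aligned subgroups at realistic class imbalance and mild label
noise — not that it reproduces any particular finding on the real data.

## Experiment sizes and verification choices

The test suite verifies the greedy splitter node-by-node against an
independent exhaustive scorer on 50 random mixed datasets of 30–120
rows (numeric values on coarse grids to keep candidate sets and trees
small), and the classical-entropy limit the same way with the uniform
hook. The subgroup-recovery experiment fits 20 seeds of n = 2,000
absenteeism-like rows (noise 0.05) with OBE(c_max), α = 1, depth ≤ 6,
min 10 samples per leaf, and requires the high-class rule's three
features to appear in a top-5 pattern (ranked by P(class ≥ weeks),
support ≥ 15) with Jaccard ≥ 0.6 in ≥ 90% of seeds. α = 1 follows a
grid search over {1, 2, 3, 4} on this data family — α is a per-problem
hyperparameter and large α, which concentrates weight on the classes
*far* from c_max, dilutes exactly the days/weeks distinctions subgroup
discovery needs; the shallow depth reflects that pattern extraction
wants interpretable paths, and unpruned trees flood the ranking with
tiny overfit leaves. Metric implementations are cross-checked against
scikit-learn/scipy and against O(n²) pair-enumeration oracles on
held-out fixtures; the null calibration of the subgroup test is checked
on 2,000 simulated null subgroups (rejection rate at 0.05 within
[0.03, 0.07]).

## Known limitations

* Greedy axis-aligned splits: interaction patterns not expressible as
  conjunctions of single-feature conditions are invisible.
* No pruning or honest (out-of-sample) leaf estimates: pattern
  distributions are training-set estimates and optimistically pure at
  small supports; the significance test mitigates but does not remove
  selection effects (p-values are not corrected for having searched the
  tree for extreme subgroups).
* SMOTE interpolation treats numeric features as continuous and
  interval-scaled; ordinal-coded categoricals stored as numbers will be
  interpolated as numbers.
* τ_b is undefined (reported as null) when either margin is constant,
  e.g. for single-leaf models.
* The synthetic generator's independence assumption makes planted-rule
  recovery easier than on correlated real data; treat recovery rates as
  an upper bound on real-data behavior.
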