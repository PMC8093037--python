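# Methods

## Problem setting

Two-class classification of expression matrices in the "small n, large p"
regime typical of cancer transcriptomics benchmarks: 50–250 samples,
4,000–15,000 genes, and class imbalance in which the clinically interesting
class (relapse, tumor subtype, poor outcome) is the rare one.  Two features
of this regime drive the design: almost all genes are irrelevant or redundant
for the class distinction, and a cost-blind classifier maximizing accuracy
will sacrifice the minority class.

The pipeline is: z-score standardization → FCBF feature selection → a
two-layer stacking ensemble whose metalearner is a cost-sensitive naive
Bayes (CSNB), evaluated by 5-fold-outer / 10-fold-inner nested
cross-validation.

## FCBF feature selection

Both feature relevance ("C-correlation", feature vs class) and redundancy
("F-correlation", feature vs feature) are measured by symmetric uncertainty

    SU(X, Y) = 2 IG(X|Y) / (H(X) + H(Y)),

a normalized information gain in [0, 1], computed from empirical joint
frequencies with entropies in bits.  The base of the logarithm cancels in
the ratio; bits are fixed for determinism.  SU of two constant variables is
defined as 0.  Computed values are clipped to [0, 1] to absorb rounding at
the boundaries.

SU needs discrete variables, so each continuous feature is discretized by
supervised entropy minimization: recursive binary splitting at the boundary
maximizing class information gain, each split accepted only if it passes the
Fayyad–Irani MDL test

    Gain > [log2(N-1) + log2(3^k - 2) - (k H(S) - k1 H(S1) - k2 H(S2))] / N.

Candidate cuts are midpoints between distinct adjacent values.  Two cuts
whose gains differ by less than 1e-12 are treated as tied and the smallest
cut wins; without the tolerance, mathematically tied boundaries would be
ranked by floating-point noise and the output would depend on summation
order.  A feature whose discretization stays a single bin carries no class
information and receives SU = 0.

Selection is the predominant-feature walk: rank features by descending
C-correlation (ties by ascending original index), drop those with
SU ≤ δ (default δ = 0, i.e. any nonzero relevance survives; configurable),
then remove every feature Fj for which an earlier retained feature Fi has
SU(Fi, Fj) ≥ SU(Fj, class).  Discretization and selection are recomputed on
whatever rows are passed in — per training fold when called inside
cross-validation.

## Cost-sensitive naive Bayes

Class 0 is the minority class, class 1 the majority.  Misclassification
costs form a 2×2 matrix C with zero diagonal; C01 (minority predicted as
majority) exceeds C10.  The default "auto" matrix is the inverse
class-frequency ratio, c01 = N_maj/N_min, c10 = 1 — the standard convention
when no domain costs are given — and is fully overridable.

Posteriors come from naive Bayes with Gaussian per-feature conditionals
(mean and n−1-denominator variance per class per feature).  The features the
model sees are standardized and continuous, which is what makes Gaussian
conditionals the defensible default; a categorical event model over
discrete codes is available behind `event_model="categorical"` for
sensitivity checks.  Variances are floored at
eps = max(1e-9 × largest feature variance, 1e-9) to avoid zero-variance
collapse, and likelihoods accumulate in log space so that thousands of
features cannot underflow.

Prediction minimizes the expected cost R(c_j|x) = Σ_i P(c_i|x) C_ij, i.e.
r0 = P(c1|x)·c10 and r1 = P(c0|x)·c01.  Ties go to the minority class,
consistent with the cost-sensitive intent; risks within 1e-9 relative are
treated as tied, because the degenerate-but-legitimate case "posteriors
equal priors under the auto cost matrix" is an exact mathematical tie that
exp/log round-trips would otherwise break arbitrarily.  With c01 = c10 the
rule reduces exactly to MAP naive Bayes, which serves as the cost-blind
baseline throughout.

## Primary learners and stacking

The first layer holds four heterogeneous classifiers in fixed order:
RBF-kernel SVM, K-nearest neighbors, a gain-ratio decision tree, and a
random forest.  The RBF kernel is K(x, xi) = exp(−‖x−xi‖²/σ²); note the σ²
denominator, i.e. gamma = 1/σ² with no factor of 2.  Defaults (all
configurable; none is prescribed by the problem): σ = median pairwise
training distance, SVM C = 1; K = 5 Euclidean neighbors; 100 forest trees;
tree pruning on.  SVM probabilities are a logistic link on decision values —
a monotone transform, so probability-based ROC equals decision-value ROC.
The tree uses binary threshold splits chosen by information gain ratio among
candidates with at least average gain, with pessimistic pruning based on an
upper 75% Clopper–Pearson bound on the leaf error; it is implemented here
because the backing library's trees only offer impurity criteria, not the
gain ratio.

Stacking trains these four on stratified inner folds (default 10, shuffled
once from the seed) and records their out-of-fold outputs as the
meta-feature matrix: one positive-class probability column per learner
(`mode="label"` thresholds at 0.5 instead; probability mode is the default
because it passes strictly more information to the metalearner).  One
column per learner, not two: the second binary-class column is redundant
and degenerate for a Gaussian metalearner.  CSNB is fit on the meta
matrix; the primary learners are then refit on the full training partition
for deployment.  The out-of-fold construction is what prevents the
metalearner from rewarding memorization — verified by the memorizing-1-NN
test, whose in-sample column is perfect but whose meta column carries the
planted label noise.

## Evaluation

Nested 5×10 cross-validation: stratified outer folds (shuffled once per
seed); within each outer training partition the standardizer is fit, FCBF
run, and the stacking ensemble trained — the held-out fold only ever passes
through transforms fit without it.  If FCBF selects nothing (possible under
a permutation null), the learners receive a single constant column and fall
back to the class prior rather than erroring.  A `paper_mode` switch
instead runs one global FCBF pass before the outer split, mimicking the
workflow of selecting features once on the full matrix; it logs a
selection-bias warning and exists for comparability, not as the default.

Metrics use the minority class as positive: accuracy, recall (sensitivity),
specificity, precision, F-score, all with 0/0 defined as 0.  Pooled
(micro-averaged) confusion counts across outer folds are the headline
numbers; per-fold metrics are retained in the report.  ROC/AUC come from
the pooled positive-class posterior scores; AUC is the Mann–Whitney pair
probability with ties counted 1/2.  Scores are cost-free: the cost matrix
moves the labeling threshold but never reorders posteriors.

## Synthetic data generator

The generator emulates the benchmark regime with known ground truth:
`n_samples=100`, `n_features=5000`, 10 informative features whose class
means differ by `effect_size=2` within-class standard deviations, 10
redundant features (informative column + N(0,1) noise), minority fraction
0.2 realized exactly as round(0.2·n), everything else N(0,1) noise, all
reproducible from one seed.  Effect size 2 puts single-gene separation in
the "clearly informative but individually imperfect" range
(single-feature Bayes error ≈ 16%), so that the ensemble and the filter
both have work to do.

Recovery of planted signal is judged at the group level (an informative
feature together with its redundant copies): FCBF is designed to keep one
representative per redundant group, so per-feature recall would be the
wrong oracle.

What the generator does not emulate: heavy-tailed intensities, gene–gene
correlation beyond the planted copies, batch effects, or probe-level
artifacts.  Passing tests on this data show the machinery is correct and
leakage-free under the stated noise model; they do not certify performance
on any real cohort.

## Study sizes used in the checks

The permutation-null study runs on balanced classes (majority fraction
0.5).  For an arbitrary classifier that is independent of the truth,
expected accuracy is q·π_maj + (1−q)·π_min where q is its majority-predict
rate; this equals the majority fraction for every classifier only when the
classes are balanced.  A cost-sensitive metalearner under the null
deliberately over-predicts the minority, so an imbalanced null would
conflate that intended behavior with a calibration failure.  Null
replicates use n = 80, p = 150, 5×5 folds, 20 permutations; the
cost-benefit comparison uses 20 replicates of 1:4-imbalanced data
(150 training samples, 200 held-out), effect size 0.8 — weak enough that
the decision threshold matters — and the separability check uses n = 100,
p = 500, effect 3.  The acceptance script runs the generator's default
regime (n = 100, p = 5000) end to end.

## Known limitations

- The cost matrix is 2×2 by construction; no multi-class generalization.
- Gaussian conditionals can be miscalibrated on strongly non-Gaussian meta
  features (e.g. saturated probabilities); the categorical variant is a
  partial check, not a fix.
- FCBF's greedy predominance walk has no optimality guarantee; with
  strongly correlated informative features it may keep a single
  representative where a wrapper method would keep several.
- AUC from pooled nested-CV scores mixes fold-specific models; this is the
  standard pooling convention but can differ from per-fold AUC averaging.
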