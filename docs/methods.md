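# Methods

`chemopercept` reimplements a molecular-perception classification
pipeline: molecules described by thousands of physicochemical
descriptors (Dragon-style tables) are classified into 12 color or 12
odor categories, the descriptors that carry the signal are identified,
and the overlap between color-coding and odor-coding descriptors is
quantified. This note records the models, the parameters that matter,
and the design choices made where the design was genuinely open.

## Preprocessing

Descriptor tables arrive as `cid,label,<descriptor...>` CSV with
missing entries written as `NaN` (also accepted: empty cells, `na`,
any case). The pipeline applies, in order:

1. **Exclusion** — molecules with strictly more than 2,000 missing
   descriptor values are dropped (`filter_high_missing`; a molecule
   with exactly 2,000 is retained). The rule runs before imputation.
2. **Imputation** — every remaining missing entry becomes 0
   (`impute_zero`). `mean_missing_count` reports the pre-imputation
   mean number of missing entries per molecule, computed after the
   exclusion step.
3. **Folds** — stratified k-fold cross-validation (k = 4 by default),
   without oversampling. Stratification is a deliberate choice: with
   12 classes whose sizes range from hundreds down to single digits,
   unstratified folds can lose a class from a training set entirely. A
   class with fewer than k members appears in only some folds; overall
   fold sizes differ by at most one. A flag restores unstratified
   assignment.

## Random forest

A Breiman forest: `n_trees` = 100 trees, each grown on a bootstrap
sample of the training molecules with `m_try` candidate descriptors
per split, prediction by majority vote (ties break toward the lowest
vocabulary index, since plain forests give no rule). The convention
`m_try = floor(sqrt(p))` gives 72 for a 5,270-descriptor table.
Individual trees are scikit-learn decision trees; bagging, voting and
per-tree bootstrap records are kept in-package because out-of-bag
(OOB) permutation importance is defined on each tree's own OOB
molecules:

> importance(j) = mean over trees of
>   [tree's OOB error after permuting column j − tree's OOB error]

The raw mean is used (no SD normalization), negatives are clamped to 0,
and a descriptor is "needed" iff its clamped importance is strictly
positive. A descriptor never split on by any tree scores exactly 0.

## Deep belief network

A stack of restricted Boltzmann machines (RBMs) pretrained greedily by
CD-1 contrastive divergence, then fine-tuned end-to-end with a softmax
read-out by backpropagation on cross-entropy. Since descriptors are
unbounded reals, inputs are min–max scaled per feature to [0, 1] using
training-set statistics (test values clipped; constant features map to
0) and treated as Bernoulli probabilities — the standard practice for
real-valued visible units.

Hyperparameter defaults (none of which are canonical): CD-1, batch
size 32, pretraining learning rate 0.05 with momentum 0.5, 50
pretraining epochs, 100 fine-tuning epochs at learning rate 0.1,
momentum 0.5. Weights initialize from N(0, 0.01²); biases at zero.
Training raises an error if weights explode (non-finite or |w| > 1e4).
`grid_search` maps the cross-validated accuracy surface over a
learning-rate × momentum grid (defaults lr ∈ {0.001, 0.01, 0.05, 0.1},
momentum ∈ {0, 0.5, 0.9}); a grid point that diverges scores 0.

The three compared architectures, parameterized by input dimension p,
are `[p,500]`, `[p,2000,500]` and `[p,2000,1000,500]`; the single-RBM
stack is the reference default.

The CD-1 update uses hidden probabilities for the positive statistics,
a sampled hidden state for the reconstruction, and visible/hidden
probabilities thereafter. `RBM.cd_gradient` takes the hidden sample as
an argument so that the exact expectation of the gradient over the
(enumerable) hidden states of a tiny machine can be tested against
closed-form sigmoid arithmetic, without Monte Carlo noise.

## Feature selection

**Wrapper GA.** Binary chromosomes of length p switch descriptors on or
off; fitness is the k-fold CV accuracy of a forest restricted to the
active descriptors, minus a small parsimony term λ·|mask|/p (λ = 0.01)
so that equal-accuracy masks prefer fewer descriptors. Operators:
tournament selection (size 3), uniform crossover (rate 0.9), per-bit
mutation at 1/p, elitism of 1. An all-zero chromosome is repaired by
forcing one random bit on (logged). Fitness is cached by mask and
deterministic per run, so the elitist best trace is non-decreasing.

By default a quarter of the initial population is seeded from the
forest's OOB-importance "needed" mask (bit-jittered at 2%), the rest
uniform random. This hybrid forest+GA initialization is what makes
repeated runs agree on the signal-carrying descriptors: informative
bits enter the population at high frequency and selection retains
them, while with purely random initialization bits that the
accuracy plateau cannot distinguish stay near their initial frequency
of 0.5 and a high cross-run consensus threshold retains almost
nothing.

**Consensus.** The search is repeated R = 20 times; descriptors present
in at least `min_count` of the R final best masks form the consensus
set (18/20 and 16/20 are the reference thresholds for the color and
odor tasks). Raising `min_count` never grows the set.

**Ranking.** For a trained classifier with baseline validation accuracy
acc1, each descriptor's indicator is |acc2 − acc1|, where acc2 is the
validation accuracy after randomly permuting that descriptor's column
across validation molecules, averaged over repeated runs (default 20).
By default each repetition refits the classifier, absorbing the
forest's own randomness into the average; a fixed-model mode permutes
only. Note that a descriptor that is fully redundant with others can
carry an indicator of exactly 0 at the accuracy ceiling — permutation
importance splits between correlated copies — so rankings are best
read per class group, and smaller forests with more refit repetitions
are more sensitive to individually-redundant descriptors.

## Evaluation and association

Cohen's κ is computed from the confusion matrix as
(p_o − p_e)/(1 − p_e); a diagonal-only matrix scores exactly 1, and
the degenerate single-occupied-class perfect case returns 1 by
convention. Cross-validation reports per-fold accuracy and κ, their
mean ± SD (sample SD over folds), and the pooled confusion matrix; a
fold whose training complement lacks two classes is skipped with a
warning.

Feature–class heat maps use the point-biserial correlation between a
descriptor and each class's one-hot indicator (the correlation
statistic itself is an interpretation choice; constant descriptors
yield 0 with a warning). Two-way hierarchical clustering uses
Euclidean distance with average linkage (the linkage is likewise our
choice; only the distance is canonical).

The cross-modal analysis restricts the color and odor key-descriptor
matrices to the molecules present in both datasets (≥ 3 required),
z-scores each descriptor with sample (n−1) SD, and connects every
color-key × odor-key pair whose Pearson |r| meets the threshold
(default 0.300552). A descriptor present in both key sets is tagged
`shared`. The edge set is monotone non-increasing in the threshold.
The color/odor co-occurrence test collapses colors to
{white/colorless, other} and odors to {odorless, other} and applies
Pearson's χ² (1 dof) via expected counts; the Yates continuity
correction is off by default and available by flag.

## Synthetic data

The generator plants known structure so every downstream stage can be
scored against ground truth. Background descriptors are drawn from a
heavy-tailed scale mixture — per-feature scale s_j ~ exp(N(0, 1.5)),
offset ~ N(0, s_j²), noise ~ N(0, s_j²) — mimicking the wildly
heterogeneous scales of real descriptor blocks and exercising the
z-scoring and [0,1]-scaling paths; 30% of background columns are
rounded to integers (count-like descriptors). Each class receives
`informative_per_class` dedicated columns whose mean shifts by
`effect_size`·s_j for that class's molecules; informative columns are
disjoint across classes. Missingness is uniform MCAR at `nan_rate`
(no mechanism is documented for the real tables); masked values are
recoverable only from the ground-truth record. Named profiles
replicate the real class imbalances (12 colors summing to 1,267
molecules, 12 odors summing to 598). Paired generation draws two label
partitions over the same molecules with separate informative sets,
except for `shared_feature_count` columns informative in both
modalities — the true shared nodes of the cross-modal network.

What the generator does **not** emulate: correlated descriptor blocks,
chemically meaningful structure, non-random missingness, or label
noise. Passing recovery tests therefore demonstrates that the
machinery identifies additively mean-shifted signal under heavy-tailed
noise and imbalance — not that it would resolve collinear descriptor
families on real tables.

## Problem sizes used in the checks

The shipped checks run on scaled-down instances chosen to keep a
single-CPU run comfortable: recovery experiments use n = 400
molecules, p = 500 descriptors, 4 classes with 5 informative
descriptors each at effect size 3; the GA uses population 20 over 12
generations with 2-fold, 15-tree fitness forests, repeated 20 times at
consensus threshold 18; ranking uses 15-tree forests refit over 10
repetitions; the DBN check uses a [500, 50] single-RBM stack. Under
these conditions the consensus recovers ≥ 80% of planted descriptors
(typically 18/20 with no background false positives), forest CV
accuracy exceeds 0.95, and the DBN exceeds 0.9 held-out accuracy.

## Known limitations

- The GA at full Dragon scale (p ≈ 5,270) is computationally heavy;
  runs at that scale should raise the population/generation budget and
  expect hours, not minutes.
- Permutation importance of strictly redundant descriptors is diluted
  (see above); the consensus mechanism, not the raw indicator, is the
  reliable selector under redundancy.
- The DBN treats [0,1]-scaled descriptors as Bernoulli probabilities;
  a Gaussian-visible RBM variant is not implemented.
- Reported κ/accuracy SDs are over folds of a single CV pass, not over
  repeated CV replications.
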