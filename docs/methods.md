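# Methods

## Estimand and estimator

Two files A (smaller, size N_A) and B (size N_B) contain records of
overlapping populations described by categorical linkage variables. A
linkage engine assigns each cross-file pair (i, j) a score d_ij in [0, 1];
pairs with d_ij > ξ, ξ in [0.5, 1), are declared linked subject to a
one-to-one constraint. The false discovery proportion of the declared set,
FDP(ξ) = FP/(TP+FP), is the estimand.

The decoy procedure augments B with N_synth = α·N_B records sampled from
B's estimated empirical distribution. Decoys cannot truly link, so links
made to them are certain false positives. With FP_synth the number of
decoy links and N_real_linked the number of links to real records,

    FDP_hat(ξ) = FP_synth(ξ) · (N_B / N_synth) / N_real_linked(ξ).

Unbiasedness needs two conditions: (i) decoys are exchangeable with B's
non-linking records, which holds when link status is independent of the
observed variables ("links at random") and the synthesizer is faithful;
(ii) decoys minimally perturb the linkage. Condition (i) implies
FP_synth/N_synth ≤ N_real_linked/N_B in expectation, i.e. FDP_hat ≤ 1; an
estimate above one therefore flags bias (`exceeds_one`). Two comparison
estimators are also computed: the augmented-task variant
FP_synth·(1 + N_B/N_synth)/N_all_linked (biased for the real-data FDP, kept
for reference) and the naive model-based estimate
Σ(1−d_ij)/#retained over retained real pairs, which inherits any
miscalibration of the linkage model.

The procedure is repeated R times with fresh decoy draws (the linker seed
is held fixed, so synthesis is the only randomness source); per-threshold
replicates are aggregated by a capped mean (default: average of
min(estimate, 1); truncated mean and median are selectable) with the plain
sample standard error. `tune_threshold` returns the smallest grid threshold
whose aggregate meets a target FDP, or an explicit not-achievable result.

## Synthesizer

The joint distribution of the linkage variables is factorized sequentially:
columns are ordered by decreasing cardinality (ties by declaration order),
the first column is sampled from its marginal frequency table, later
columns from conditional frequency tables given all earlier columns.

Numerical choices:

* **Smoothing.** Each table is a Dirichlet posterior with 0.5 pseudo-count
  per category (configurable). For conditionals the prior mass is centred
  on the column *marginal*, not the uniform, so sparse parent combinations
  shrink toward the marginal and unseen parent combinations back off to it
  entirely. A uniform prior would drag high-cardinality conditionals toward
  the uniform distribution and make decoys artificially unique.
* **Model choice per column.** A column's conditional model is kept only if
  it beats the marginal-only model by BIC on the observed data; otherwise
  the column is synthesized from its marginal. With mostly-singleton parent
  combinations the raw conditional tables memorise individual source rows,
  and decoys that replicate the exact variable combination of a *linked*
  record get linked to that record's true partner, inflating FP_synth.
  The BIC guard mirrors tree-based synthesizers, which only model
  dependence the data support, while deterministic relationships (and any
  dependence strong enough to matter) are retained.
* **Missing values** are dropped per column during fitting and never
  generated.
* **Decoy placement.** `augment_file` interleaves decoys at seeded-random
  row positions instead of appending them. Agreement-pattern scores produce
  exact ties, and the greedy one-to-one assignment breaks ties by record
  position; appended decoys would then lose every tie against a real
  record, suppressing FP_synth roughly ten-fold. Provenance travels in the
  `source` column, so counting is unaffected by row order.

Synthesis quality is certified by `synth_quality_auc`: a logistic
regression on one-hot-encoded variables, 5-fold stratified CV, scoring
real-vs-synthetic; an AUC near 0.5 certifies indistinguishability. The
classifier family is a pragmatic choice — any well-calibrated
discriminative model would serve.

## Built-in linker

The test-bed linker is the classical Fellegi–Sunter two-class mixture on
binary agreement vectors: per variable, m_k = P(agree | link),
u_k = P(agree | non-link), λ = P(link), assuming conditional independence
of comparisons given class. Comparisons involving a missing value
contribute no likelihood factor. Fitting is plain EM on the pattern counts
(tolerance 1e-6 on the log-likelihood, max 500 iterations, initialised at
u = observed agreement rates, m = 0.9, λ = min(0.1, N_A/#pairs)); a global
class swap guards against label switching. Posterior scores are
per-pattern Bayes ratios. `link_set` keeps pairs above ξ and enforces
one-to-one greedily in descending score order (ties by lower i, then lower
j) — deterministic and auditable; optimal assignment is out of scope. Any
external engine can replace this module by returning `ScoredPairs`
(serializable as CSV) for a pair of files.

## Simulation harness

`simulate_files` draws an entity population with n_vars independent
multinomial variables. Default cardinalities (2, 6, 12, 30, 60) with
geometric-decay category probabilities p_i ∝ exp(−3i/K) are rescaled by a
bisection search until the *expected* proportion of unique variable
combinations in the larger file matches the target discrimination level
(Monte-Carlo expectation with common random numbers; realized values land
within ±0.02, otherwise an infeasibility error reports the achievable
range). These distributions are a documented stand-in: real linkage
variables are neither independent nor geometric.

round(overlap·N_A) entities appear in both files — chosen uniformly under
`at_random`, or proportional to exp(Σ w_k z_k) of standardized category
scores under `depends_on_variables` (Gumbel top-k sampling). Registration
error miscodes each variable independently per file with probability
`error_rate` (default 0.02) by resampling from the generating marginal, so
the marginal distribution is unchanged. Duplicates, when requested, are
copies of existing records with fresh ids, split between linking and
non-linking records, and marked non-links in the truth (the truth stays
one-to-one). Files are returned in shuffled row order.

The outcome model for inference demonstrations is
Y = −5 + X1 + X2 + 20·X3 + ε with X1 ~ N(0,1), X2 ~ N(0, 3) (scale 3),
X3 ~ Beta(0.2, 0.1) − 2/3 (bimodal), ε ~ N(0,1); non-linked records
receive outcomes by inverse-transform sampling from the right-continuous
empirical CDF of the linked outcomes (ties toward the smaller value), so
linked and non-linked outcomes share a marginal distribution.

What passing simulations do **not** show: robustness to dependent linkage
variables, to informative missingness, to string-valued identifiers, or to
error mechanisms correlated with link status — none of which the generator
emulates.

## Problem sizes and known limitations

* The bias study and the acceptance computation use N_A = 2000,
  N_B = 5000, five variables, 10 procedure repetitions — large enough for
  stable pattern-count EM yet a desk-scale run of a few minutes.
* With a one-to-one linker at high overlap, the estimator carries a
  structural upward tilt: real B-records that form links are consumed by
  their true partners during assignment, while decoys remain available as
  false-link candidates throughout, so FP_synth/N_synth slightly exceeds
  FP/N_B even for perfect decoys (raw thresholded counts, without the
  one-to-one step, are exchangeable). The effect scales roughly with
  TP/(N_B − TP) and is conservative — the FDP is over-, never
  under-estimated by it.
* When the linkage task is accurate (tiny FDP), FP_synth counts are small
  and the relative error of the estimator is dominated by Poisson noise;
  more repetitions or a larger α (within (0, 0.2]) tighten it at the cost
  of more linkage runs.
* Estimating the false negative proportion, augmenting file A (or both
  files), and confidence intervals beyond the SE over repetitions are out
  of scope.
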