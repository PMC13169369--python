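# Methods

This note documents the models and procedures `apdkit` implements, the
choices made where the design was genuinely open, and what the synthetic
generators do and do not emulate.

## Alignment and the performance-gap bound

Two feature matrices `X` (n × p) and `Z` (n × q) describing the same n
samples are compared with linear centered kernel alignment (CKA):

    align(X, Z) = ‖Xᵀ H Z‖²_F / (‖Xᵀ H X‖_F · ‖Zᵀ H Z‖_F),
    H = I − (1/n) 1 1ᵀ.

The implementation works in feature space (O(n·p·q)); tests verify it
against an independent Gram-matrix (HSIC-form) oracle to 1e-10, along with
the defining invariances (orthogonal transforms, positive isotropic
scaling), symmetry, range, and CKA(X, X) = 1. A matrix that is all-zero
after centering makes the statistic 0/0; `linear_cka` raises an error
rather than silently returning a number.

For centered designs and a response y the squared-residual gap of the two
least-squares fits obeys

    ‖XW − y‖² − ‖ZV − y‖²  ≤  rank X + rank Z − 2·align(X, Z).

Interpretation choices, made once and recorded here:

* **"Normalized response"** is read as: center y, then scale to unit L2
  norm. Centering matches the centered designs and makes residual norms
  comparable across instances; the alternative (normalize only) is not
  asserted to be wrong, just not what this package does.
* **W, V** are minimum-norm (pseudoinverse) least-squares solutions, so the
  bound is well-defined at any rank. `numpy.linalg.lstsq` provides them.
* **Ranks** are numerical: singular values above
  `max(n_rows, n_cols) · eps · σ_max` (the standard SVD cutoff), giving
  reproducible integers.
* The left side is **signed** (X's residual minus Z's), matching the
  one-sided statement; the randomized harness checks both orientations of
  every instance. `bound_experiment` draws Gaussian X, Z, y with
  n ∈ {10..200} and feature dimensions ∈ {1..50} and reports the violation
  count (zero in 10,000 trials) and quantiles of the slack rhs − lhs.

## Fingerprints and the MMCD margin statistic

Molecules are represented as Morgan fingerprints (radius 2, 2048 bits,
computed with RDKit); the distance between two fingerprints is the Tanimoto
distance 1 − |a∧b|/|a∨b|. Two all-zero fingerprints have undefined
similarity; it is taken as 0 (distance 1), matching common toolkit
behavior, with a logged warning.

The mean minimum class distance (MMCD) summarizes the margin between the
two classes of a binary dataset. The name and the verbal definition pull in
different directions, so both readings are implemented and every result
records which one produced it:

* `mean_of_min` (default): per compound, the minimum Tanimoto distance to
  any opposite-class compound, averaged over the compounds of **both**
  classes pooled. This matches the expansion of the name and the
  margin intuition (an interleaved dataset scores near 0).
* `min_of_mean`: per compound, the mean distance to all opposite-class
  compounds, minimized over compounds.

Pooling both classes (rather than treating one class as the query side)
yields a single value symmetric in the labels; label-swap invariance is a
tested property. Distances are computed exactly with blocked integer matrix
products — at the 5000-compound cap an all-pairs computation is cheap, and
exactness beats approximate nearest neighbors for reproducibility.

Dataset preparation mirrors the benchmark conventions: molecules with
average molecular weight ≥ 600 Da are dropped (structure standardization is
assumed done upstream), then datasets larger than 5000 records are reduced
to exactly 5000 by seeded uniform sampling, preserving record order.

## MLP benchmarking and APD points

Every representation is scored by the same predictive model: a three-layer
MLP — input → 128 → 128 → output, counting weight layers — with ReLU
activations, trained with Adam for exactly 30 epochs (no early stopping, no
schedule) at learning rate 1e-4, L2 weight decay 5e-4, batch size 1000.
The backend is scikit-learn's `MLPClassifier`; its `alpha` penalty is the
classic coupled-L2 reading of "weight decay". Continuous features are
standard-scaled on the training split; binary fingerprints are left as-is.

"Final hidden layer" embeddings are taken **post-activation** (the
representation actually feeding the linear readout); the reading of
"three-layer" as two hidden layers is recorded in `MLPConfig.n_layers` so
the one-hidden-layer alternative is a one-line change. Embeddings are
extracted by replaying the forward pass through the fitted weights, which a
test checks against an independent layer-by-layer replay.

An APD point for a representation pair on one dataset is
(alignment, |ΔMCC|): linear CKA between the two models' embeddings on a
shared evaluation set, against the absolute difference in Matthews
correlation coefficient (zero-denominator MCC is 0 by convention). On
synthetic data the evaluation set is a stratified 20% holdout seeded from
the model config. Per-dataset aggregation uses the sample standard
deviation, with std 0 for a single pair.

## Exclusion-zone inference

Given a scatter of (alignment, perf_diff) points, the quantile grid places
one cell at every pair of marginal quantile levels (q_a, q_p), in steps of
0.05 from 0 to 0.95. A cell's region is the upper-right set
{alignment > Q(q_a), perf_diff > Q(q_p)}; under independence of the axes
its expected occupancy is p₀ = (1 − q_a)(1 − q_p), and the cell's p-value
is the exact binomial lower tail P(K ≤ observed | N, p₀) — small when the
region is underpopulated. Quantiles use the median-unbiased (type 8)
estimator; at level 0 the cutoff is −∞ so the strict inequality keeps all
N points.

The cluster-based permutation test controls for the many correlated cells:
cells with p below 0.05 are merged into 4-connected clusters (neighbors
differ by one threshold step along one axis) scored by the summed −log10 p;
the maximum cluster mass is compared with the null distribution obtained by
shuffling the pairing of perf_diff against alignment across points —
preserving both marginals, hence the grid cutoffs, while destroying joint
structure. The p-value is (1 + #{null ≥ observed})/(1 + B). The default
B = 9999 gives 1e-4 resolution; the cell-forming threshold, connectivity
and cluster statistic are this package's declared defaults. Calibration and
power are tested empirically: under an independence null the rejection rate
at α = 0.05 stays within Monte-Carlo slack of the nominal level, and a
planted exclusion zone (perf_diff bounded by 1 − alignment) at 200 points
is detected with power ≥ 0.8.

## APD regions and MMCD-based assignment

Region structure in APD space is modeled by k-means on z-scored axes, with
k ∈ {2..10} chosen to maximize the silhouette score over the best of 100
seeded initializations per k (ties prefer smaller k). Each cluster gets a
mean ± sd of the MMCDs of its member datasets; a new dataset is assigned to
the cluster with the nearest mean MMCD (ties to the lowest cluster index),
and agreement with APD-space assignment (nearest centroid) is scored by
balanced accuracy — the unweighted mean of per-class recalls.

## Decision simulations

**p_better.** Given an ensemble of representations with performances m_i
and a pairwise alignment matrix, each Monte-Carlo repetition samples n
reference representations without replacement plus one extra, and counts a
success when the newcomer exceeds C · max(reference) with C a multiplier
(1.10 = +10%). The multiplicative reading follows the formal statement
p(m_{n+1} > C·max); the additive-percent alternative is noted but not
implemented. Repetitions whose reference maximum is ≤ 0 are excluded when
C > 1 (a multiplicative threshold on a nonpositive best is ill-behaved)
and their count reported. Sweeps share random draws across C for a fixed n,
so estimates are exactly monotone in C. Alignment grouping uses terciles of
the per-repetition mean pairwise alignment by default, with data-scale bin
edges as an option — the bin edges behind "low/high alignment" regimes are
a free choice. The i.i.d. sanity point: with exchangeable performances and
C = 1 the probability is exactly 1/(n + 1).

**Data scaling.** `scaling_analysis` trains at fractions 0.75–0.95 (step
0.05) of the training data, 30 repeats each with fresh derived seeds, and
reports the Spearman rank correlation (average ranks on ties) between
fraction and performance over all 150 pairs with a percentile bootstrap
95% CI from 1000 paired resamples (the bootstrap method and count are this
package's choices). Constant performances return r_s = 0 with a degeneracy
flag. Subset draws for real training functions should be stratified to
preserve class balance; the synthetic oracle abstracts the trained model as
performance(f) = base + slope·f + noise.

## Synthetic generators: what they emulate, and what they don't

* `gen_fp_dataset` — two prototype bit vectors sharing a tunable fraction
  of their set bits, each record a prototype with independent bit flips.
  Separation (1 − overlap) tunes the expected MMCD monotonically: overlap 1
  with no flips gives MMCD 0, overlap 0 gives MMCD 1. Defaults (50 per
  class, 64 set bits of 2048, flip 0.01) give margins spanning the [0, 1]
  range smoothly. These are not molecules: real fingerprint bit statistics
  (bit frequency skew, substructure correlation) are not reproduced, so
  passing tests show the statistic behaves as designed, not that real
  datasets have a particular MMCD distribution.
* `gen_representations` — noisy orthogonal views r = L·M_r + σ_r·ε of a
  shared standard-normal latent matrix, with labels from a logistic rule on
  L plus optional flips. Square noiseless views are exactly CKA-1; CKA
  falls monotonically with σ. Real learned representations differ in ways
  (nonlinearity, low-rank structure) this linear family does not capture.
* `gen_apd_points` — the independence null draws alignment ~ U(0,1) and
  perf_diff ~ U(0, 0.6) independently; exclusion mode draws perf_diff
  uniformly below the envelope s·(1 − alignment), directly encoding the
  empirical ceiling the analysis reports. Strength 1 therefore plants zero
  envelope violations by construction.
* `gen_apd_clusters` — three Gaussian clusters at the populated APD
  regions (low/low, high-alignment/low-gap, low-alignment/high-gap) with
  per-cluster MMCD levels; the high-alignment region carries the lowest
  MMCD, mirroring the margin hypothesis. Used for k-selection and
  assignment tests.
* `gen_blobs` — two 6-σ-separated Gaussian blobs of 5000 samples
  (the benchmark's dataset-size cap): a genuinely linearly separable
  sanity task on which the fixed MLP recipe must score high MCC.
* `gen_learning_curves` — performance(f) = base + slope·f + N(0, σ²),
  seeded per call.

All generators are pure functions of their configs; a single seeded stream
per call makes output independent of consumption order.

## Numerical conventions and problem sizes

Tolerances: CKA–oracle agreement 1e-10; bound slack 1e-8; centering checked
at 1e-8·n per column. Determinism: every stochastic routine takes a seed;
derived seeds come from `numpy.random.SeedSequence` and stay below 2³¹.

The test and acceptance runs use desk-scale problem sizes chosen to make
the Monte-Carlo assertions sharp while keeping the whole suite fast on one
CPU: 10,000 bound instances; 200 null scatters × 199 permutations for
calibration and 100 planted scatters for power; 100 seeds for k-selection;
100,000 p_better repetitions; 200 coverage runs for the scaling CI.

## Known limitations

* The bound verification is numerical, not a proof; it covers Gaussian
  instances in the stated size ranges.
* MMCD ignores label noise and within-class structure; two datasets with
  equal MMCD can behave differently.
* The permutation test's power figure is specific to the planted-envelope
  generator; weaker or differently-shaped exclusion patterns will show
  different power.
* The MLP backend reads "weight decay" as a coupled L2 penalty; decoupled
  weight-decay Adam would train slightly differently.
* p_better conditions on the observed ensemble; it does not model the cost
  of evaluating the extra representation.
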