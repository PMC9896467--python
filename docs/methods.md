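# Methods

This note records the model, the numerical choices, and what the test
suite does and does not establish.

## Negative screening

The screening score of an unlabeled pair (drug *k*, target *j*) is the
average of two similarity-weighted interaction profiles:

- target side: `SPC_jk = Σ_{l≠j} PS_jl·y_kl / Σ_{l≠j} PS_jl`, the
  weighted fraction of target *j*'s similarity neighborhood already
  targeted by drug *k*;
- drug side: `SCP_kj = Σ_{i≠k} CS_ki·y_ij / Σ_{i≠k} CS_ki`, mirrored.

The self-pair is excluded from both sums, so a known positive's own
label never enters its score.  Both sides are convex combinations of
binary labels, hence bounded in [0, 1], and adding an interaction with
a positively-similar neighbor can only raise the corresponding side
(monotonicity; property-tested).

A side is *undefined* when its denominator vanishes (an entity with
zero similarity mass) or when its entity has no known interactions at
all; an undefined side contributes 0, and a pair is flagged in
`undefined_mask` only when both sides are undefined.  Undefined-side
zeros are deliberate rather than imputed: under the dissimilarity rule,
total absence of supporting evidence is the strongest indication of
non-interaction, and such pairs remain eligible — indeed preferred —
as negatives.

Negatives are the `ceil(ratio · n_pos)` lowest-scoring unlabeled pairs
(`ratio` defaults to 1, a class-balanced set).  Ties break by row-major
pair index so the selection is deterministic.  Only *known*
interactions seed the score; no self-training iteration augments the
positive set.

A real subtlety, found while validating the generator: a positive whose
drug (or target) has no *other* interaction scores 0 — its own label is
excluded — so "every planted positive outscores every cross-cluster
pair" holds only for positives supported on both sides.  The tests
assert exactly that, plus mean dominance over all positives.

## Features and the ELM

Pair (k, j) is represented as `[PS_j,: ‖ CS_k,:]` (length m + n): the
similarity profiles are the features, no further engineering.  The ELM
has one hidden layer of L nodes (default L = 100; the desk-scale
benchmark uses L = 20 to keep the search dimension L(d+1) moderate),
sigmoid activation by default, scalar 0/1 targets, and output weights
solved as the minimum-norm least-squares solution of `Hβ = T` via
SVD-based `lstsq` (numerically the Moore–Penrose pseudoinverse; no
ridge term).  With L ≥ N distinct rows the network interpolates the
training labels, which the tests verify to 1e-6.

## Spherical search

Minimization over a box, fully seeded.  Per iteration:

1. **Control parameters** per individual from a 2×H success-history
   memory (H = 5): `rank_i ~ Binomial(D, mem_rank)` clamped to
   [1, D−1]; `c_i ~ Cauchy(mem_step, 0.1)` resampled while ≤ 0 and
   truncated at 1.  Memory initialized at rank probability 0.5 and step
   0.7.
2. **Directions**: the better half of the population (median joins the
   worse half when N is odd) moves towards-rand
   (`z = x_p + x_q − x_r − x_i`), the worse half towards-best with the
   attractor drawn from the top ⌈0.11·N⌉ solutions.
3. **Projection**: one random orthogonal matrix A per iteration (QR of
   a standard-normal matrix with sign fix), one random binary mask per
   individual with `rank_i` ones; the step is
   `y = x + c·(Aᵀ diag(b) A) z`, applied batched as two N×D·D matmuls.
   Per-iteration (rather than per-individual) refresh of A is a cost
   choice; the per-individual masks preserve step diversity.
4. **Bound repair** by midpoint reflection: a violated coordinate moves
   to the midpoint of parent value and bound.
5. **Greedy selection** with ≤ (equal-fitness trials replace their
   parents); improvements feed the memory as weighted Lehmer means,
   ranks first normalized to rank/D.  A zero-improvement-only iteration
   leaves the memory unchanged.  Infinite parent fitnesses (from
   non-finite objective values, which are warned about and treated as
   +∞) are capped before weight normalization.
6. **Population reduction** from `pop_init` = 100 to `pop_min` = 4:
   linear in evaluations by default; an exponential schedule
   `round(N_init·(N_min/N_init)^(nfes/nfes_max))` is available.  The
   worst-ranked members are dropped.

The per-iteration trial batch is truncated at the remaining budget, so
a run uses exactly `nfes_max` evaluations and ends at `pop_min`.
Defaults follow the published configuration (budget 10⁴, population
100, pbest 0.11, memory 5).  No archive is maintained: the published
parameter list mentions an archive rate, but no archive mechanism is
defined anywhere, so none is implemented.

On the 10-D sphere with these defaults the optimizer reaches ~1e-19
(the acceptance threshold is 1e-2).

## Fitness

The fitness of a flat parameter vector (first L·d entries the input
weights row-major, last L the biases, box [−1, 1]) is stratified
10-fold CV: per fold, β is solved on the training split, the held-out
split is scored, and the fold contributes (AUC_i + AUPR_i)/2.  We
report the *mean* over folds so the fitness is a bounded [0, 1] score;
the literal fold-sum (k times the mean, monotonically equivalent for
optimization) is exposed as `fitness_sum`.  The fold split uses a fixed
seed across all evaluations of one search so the objective is
stationary; `DTIResults.reevaluate(fold_seed)` quantifies the selection
optimism of that choice with a fresh split.  Maximization is
implemented as minimization of the negated fitness, leaving the ≤
selection rule unchanged.

AUC is the Mann–Whitney rank statistic (ties count 1/2).  AUPR is
average precision with ties ordered negatives-first — a pessimistic
estimator chosen over trapezoidal PR interpolation, whose linear
segments are known to overestimate.  Confusion-matrix quantities, when
a hard label is needed, threshold the ELM score at 0.5.

## Friedman test

Methods are ranked within each dataset column ascending by score (best
method = rank k, ties share average positions; this orientation matches
the published rank tables).  The statistic
`12/(nk(k+1))·ΣR_j² − 3n(k+1)` is divided by the tie-correction factor
`1 − Σ(t³−t)/(n(k³−k))`; the correction is mandatory — the published
chi-squares are reproducible only with it — and complete ties in every
column raise an error.  p-values come from the χ²(k−1) upper tail.

## Synthetic benchmark

The generator emulates the structure the screening rule needs from the
gold-standard data: drugs and targets fall into matched clusters
(sizes as equal as possible, remainder to the first clusters),
similarity is `within_cluster_sim` inside a cluster and
`between_cluster_sim` outside (defaults 0.8 / 0.2, a clear but not
caricatural separation), and interactions are planted in matched blocks
at `interaction_density` (default 0.3, comparable to the denser
gold-standard classes' within-neighborhood rates), optionally flipped
with probability `label_noise`.  A ±0.02 uniform symmetric jitter makes
similarity ranks almost surely unique (set to 0 for exact-value tests);
the diagonal is forced to 1.  Defaults are 40 drugs × 40 targets with
4 clusters — the desk-scale study condition used by the end-to-end
tests and the acceptance script.

What it does *not* emulate: realistic SIMCOMP/sequence-similarity
distributions (heavy-tailed, asymmetric), hub drugs and promiscuous
targets, or correlation between similarity and interaction degree.
Passing tests therefore demonstrate correctness of the machinery and
recoverability of clean planted structure, not gold-standard-level
performance; runs on the real benchmarks use the same code path via
`DTIModel.from_directory`/`--network-dir`.

## Problem sizes in the tests

The end-to-end checks run the 40×40 benchmark with L = 20: one
headline run at budget 2,000 evaluations, and a 20-seed paired
comparison at budget 600 per seed, where the SS optimum is required to
be at least the best of 20 random hidden-layer draws evaluated on the
same folds in ≥ 18/20 seeds.  The paired comparison uses the smaller
budget because the property it checks — greedy SS never falls below
the best random draw it effectively contains — is budget-insensitive,
and 600 evaluations keep the 20-seed loop desk-scale.

## Known limitations

- Screening assumes complete similarity matrices; missing entries are
  rejected rather than imputed, since the score is undefined under
  missingness.
- Pair-level CV shares drugs and targets across folds; cold-start
  (new-drug / new-target) splits are out of scope.
- The ELM is unregularized; for near-rank-deficient hidden matrices the
  minimum-norm pseudoinverse is the only implicit regularizer.
- Similarity values are consumed as stored; no rescaling or kernel
  correction is applied.
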