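# Methods

## The optimization problem

A campaign optimizes the activity of a protein of length L over point
mutants of its wild-type sequence under a hard measurement budget
(default 3 rounds × 16 mutants). Decisions in one round shape the data
available to the next, so the workflow is evaluated as a closed loop: what
matters is the quality of the mutants found by the end, not intermediate
prediction accuracy.

## Naturalness scoring

A protein language model conditioned on the unmasked wild type yields
per-position amino-acid distributions P(y | x). The naturalness of a
mutant x′ with mutated positions T is the summed log-likelihood ratio
Σ_{i∈T} [log P(x′_i|x) − log P(x_i|x)]. Mutations are treated as
independent and additive in log space; a single forward pass suffices.
Masked-marginal variants are deliberately out of scope. Because the score
is a within-row ratio, any per-position additive shift of the
log-probabilities cancels — the softmax normalizer never matters.

Zero-shot selection takes the top of the naturalness ranking. Ties break
lexicographically by (position, mutant letter): deterministic and
seed-free. The at-most-3-per-locus cap is exposed (`max_per_locus`) and
off by default in simulation, matching how the workflow is used in
practice versus in benchmarks.

## The ranking ensemble

Each ensemble member maps a fixed-length sequence embedding (960 for
ESMC-300M mean pooling; smaller for the synthetic oracle) through
100 → 50 → 1 with batch normalization after each hidden linear layer,
ReLU, dropout 0.2, and no bias in the final layer — a Bradley-Terry score
is only identified up to translation, so a final bias would be pure noise.
Training uses Adam (lr 3e-4, weight decay 1e-5 on weight matrices) on the
pairwise loss BCE(σ(s_w − s_l), 1) over winner-first directed pairs; ties
in the targets produce no pair. The network and optimizer are implemented
directly on numpy; the analytic gradients are verified against central
finite differences in the test suite.

**Pair split.** All directed pairs are split 80–20 into train/validation
under a no-transitive-leakage rule: a pair (a, b) can enter validation
only if b is not reachable from a through the remaining train digraph
(breadth-first search, with a two-hop screen first). Rejected pairs stay
in train; dense tournaments under-fill the quota, which is logged. The
exact BFS-checked procedure is applied to pair universes up to
`max_split_pairs` (default 4000); larger universes — warm-start over all
L×19 singles generates O((L·19)²/2) pairs — are first seeded-subsampled
to that size, so the leakage guarantee is exact on the split universe and
approximate with respect to the full tournament. Minibatch training pairs
are all comparable pairs within a minibatch of records minus the
validation pairs; the split is computed once per training phase.

**Two-phase training.** Warm-start: at most 50 epochs on naturalness
targets of all single mutants (early stopping patience 20, validation
every 5 epochs), distilling the PLM prior into the compact top model.
Activity fine-tuning: at most 200 epochs on the measured activities
(patience 40, validation every 10). Early stopping restores the
best-validation weights. Degenerate inputs (fewer than five pairs) train
without validation for the full epoch budget. Warm-start depends only on
the naturalness table, so a campaign computes the five warm-started
snapshots once and fine-tunes from them in every later round.

**Ensemble.** Five members seeded base+k (k = 0..4); all member
stochasticity — initialization, shuffles, dropout, split — flows from the
member seed. Predictions over a candidate set are demeaned per member,
the consensus is their mean, and Σ is the across-member sample covariance
of deviations from the consensus (1/(K−1) normalization; identical
members give Σ = 0, rank(Σ) ≤ K−1).

## Constant-liar acquisition

The consensus/covariance pair is treated as a Gaussian belief. Once, up
front, `α · median(diag Σ)` is added to the diagonal — the lie's
observation noise. The lie value is fixed for the whole batch at the
minimum of the initial consensus. Each of the 16 greedy steps picks the
arg-max of the current posterior mean (an optional UCB term `β·σ` is
exposed, default β = 0; ties break by candidate order), then conditions
mean and covariance on the lied observation by the standard rank-one
updates. The covariance update is independent of the lie's value; the
mean update is not. With a zero-variance diagonal the selector falls back
to top-N with a warning. Small α yields confident lies and diverse
batches; α → ∞ recovers top-N exactly. At α = 100 the batch is within a
single boundary swap of top-N on random 5-member ensembles but not
identical: the mean perturbation scales as (y_i − y_lie)·corr/α, and
5-member sample covariances carry spurious correlations of order 0.5, so
exact-set agreement is a limit property (it is exact by α ≈ 1e5), not an
α = 100 property. The default campaign schedule applies α = 6 in round 2
and α = 100 (pure exploitation) afterwards.

## Campaigns and benchmarks

Each replicate holds out 50% of the landscape (seeded); selection and
training see only the accessible half, while the held-out half provides
the ranking diagnostic (Spearman of model scores versus truth on up to
2000 held-out mutants, subsampled, from round 2 on). The candidate pool
starts as all accessible single mutants and expands each round with
single-mutation extensions of any measured "hit" (default rule: activity
strictly above the wild type's 0; top-quartile and top-k rules are
configurable). Previously measured mutants never re-enter.

Strategies: `folde` (zero-shot round 1, warm-started BT ensemble +
constant-liar afterwards), `zero_shot` (successive disjoint naturalness
batches), `random` (uniform), and `random_forest` (random round 1, then a
default-parameter scikit-learn RandomForestRegressor on embeddings with
top-N selection — the EVOLVEpro-style baseline).

Metrics: cumulative count of selected mutants at or above the 90th
activity percentile, and whether any selection reaches the 99th.
Percentiles (also the 99.375th used by the engineering-difficulty
statistic (A_q − A_min)/(A_max − A_min)) use linear interpolation between
order statistics; thresholds are computed over the accessible half by
default (`metrics_on="full"` switches to the whole landscape). Replicates
share holdout and selection seeds across strategies, so per-landscape
comparisons are paired; the one-sided Wilcoxon signed-rank test runs on
log-transformed hit-count differences (zeros shift both sides by +1
first, flagged; zero differences are dropped; exact null for n ≤ 25
without ties, normal approximation otherwise — delegated to scipy, with
an exact 2^n enumeration oracle in the tests).

## The synthetic oracle

The generator emulates the statistical structure the method assumes, not
any real protein:

- **Landscape.** Per-(position, amino-acid) effects ~ N(0, effect_scale²),
  wild-type letters pinned at 0 so "above wild type" is a meaningful hit
  rule. All L×19 singles are enumerated; an optional sample of doubles
  adds pairwise interaction terms on a seeded subset of position pairs,
  sized so that `epistasis_weight` is the interaction share of
  double-mutant variance. Measurement noise N(0, noise_sd²) is added to
  every recorded activity. Defaults: effect_scale 1, noise_sd 0.1,
  no epistasis, L 48.
- **Log-probabilities.** Row p is a log-softmax of (effects + η). Since
  naturalness is a within-row ratio, the normalizer cancels and the
  naturalness of single (p, a) is effect(p, a) + η(p, a) − η(p, wt). The
  noise scale is solved in closed form (Spearman→Pearson conversion for
  bivariate normals, measurement noise included) so that
  Spearman(naturalness, activity) over singles lands at `naturalness_rho`
  (default 0.5, the level real PLMs show); the calibration is validated
  to ±0.1 in the tests.
- **Embeddings.** `n_sig = round(signal_fraction · dim)` coordinates are
  linear reads of the per-position effect vector through a projection
  with rows 1 + 2·N(0, 1): a shared fitness direction plus a dominant
  locus-specific spread. The constant 2 sets the regime the method is
  designed for — most fitness information lives in locus-specific
  directions, so models trained only on mutants from a few
  high-naturalness loci generalize poorly (the round-2 collapse that
  warm-starting repairs), while a few dozen *randomly* spread
  measurements still identify the shared direction. The remaining
  coordinates are a seeded random projection of the one-hot sequence
  content. Everything is bit-reproducible under the config seed, and the
  oracle implements the same contract a real-PLM adapter would.

What passing tests on this oracle do **not** show: performance on real
landscapes with epistasis beyond pairwise terms, realistic PLM embedding
geometry, assay-specific noise, or multi-mutation search spaces at
ProteinGym scale. The benchmark numbers here are qualitative analogues
(direction and mechanism), not predictions of real-data effect sizes.

## Numerical and design choices

- Positions are 1-based everywhere in the API (ProteinGym convention).
- Holdout size is round(fraction·N) (banker's rounding via Python's
  float rounding); splits, campaigns, and benchmarks are deterministic
  given their seeds, with sub-seeds spawned from numpy `SeedSequence`.
- Batch-norm uses running statistics (momentum 0.1) in eval mode;
  dropout is disabled at prediction time.
- Covariance posteriors are symmetrized after each rank-one update;
  positive-semidefiniteness is maintained by the up-front jitter, and a
  non-positive pick variance raises rather than silently pseudo-inverting.
- DMS tables: rows with missing scores are skipped with a warning and
  counted in the load report; the wild type resolves from an explicit
  FASTA sidecar, then an explicit argument, then reconstruction from the
  per-row wild-type letters (gaps are an error).
- Desk-scale problem sizes used throughout the tests and the acceptance
  script (L 24–40, dim 24–32, 5-member ensembles) were chosen so the
  statistical phenomena of interest are measurable with comfortable
  margins at these dimensions; the architecture and training protocol are
  unchanged from the 960-dimensional configuration.

## Known limitations

- Only the wild-type-marginal naturalness formulation is implemented.
- The warm-start pair split at full L×19 scale protects against
  transitive leakage on a subsampled pair universe, not the complete
  tournament.
- The random-forest baseline uses library defaults; no hyper-parameter
  search is attempted for it or for the MLP.
- Constant-liar assumes the ensemble covariance is a meaningful
  similarity signal; with fewer than ~3 members it degenerates.
- Real-PLM adapters are specified by contract (`folde.plm.Embedder`,
  `PrecomputedEmbedder` + HDF5 cache for replay) but no network-backed
  model is bundled.
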