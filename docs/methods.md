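# Methods

## The model

The package learns a symmetric weight matrix `W` (A×A, unit Frobenius norm)
over the features of a binary classification problem. Its diagonal entries
weight single features; its off-diagonal entries weight *pairs* of
features, so `W` is a directly interpretable map of main effects and
pairwise interactions. Distances between instances are measured with the
quadratic-Manhattan form

    q(x_i, x_j) = |x_i − x_j|ᵀ W |x_i − x_j|,

where the absolute value is element-wise. Because `|d|_a |d|_b ≥ 0`, the
entry `w_ab` acts as a nonnegative-basis coefficient for the joint
displacement of features `a` and `b`.

Each training instance `n` carries two probability distributions: `α_n`
over its *hit set* (same-class samples) and `β_n` over its *miss set*
(opposite-class samples), interpreted as "probability of being the nearest
hit/miss". The fitted objective is

    C(α, β, W) = Σ_n D_n [ Σ_h α_nh q(x_n, x_h) − Σ_m β_nm q(x_n, x_m) ]
               + σ Σ_n D_n [ E_miss(n) − E_hit(n) ],

with Shannon entropies in natural log and per-sample weights `D` (uniform
`1/N` outside boosting; the `1/N` factor rescales the objective without
moving any argmin). Minimizing the first bracket maximizes the
probabilistic hypothesis-margin. The entropy bracket implements a max–min
entropy principle: margins are considered *stable* when same-class
neighbors are spread evenly (high hit entropy) while opposite-class mass is
concentrated (low miss entropy). `σ > 0` is the single tunable
hyperparameter; it is both the softmin temperature of the probability
updates and the weight of the stabilization term.

## The optimizer

Fitting alternates two exact closed-form steps:

1. **Probabilities.** With `W` fixed, the stationary distributions are
   softmins of the q-distances, `α_nh ∝ exp(−q(x_n, x_h)/σ)` (same for β
   over misses). The objective is a local minimum in α and a local maximum
   in β there — a saddle in the joint probability space; the package's
   tests verify this by simplex perturbation.
2. **Weight matrix.** With probabilities fixed the margin bracket equals
   `tr(W Σ)` for the hit-minus-miss scatter
   `Σ = Σ_n D_n (Σ_h α_nh d_nh d_nhᵀ − Σ_m β_nm d_nm d_nmᵀ)`,
   `d_ij = |x_i − x_j|`. Over symmetric PSD matrices of unit Frobenius
   norm the minimizer is spectral: with eigenpairs `(μ_i, ψ_i)` of Σ,
   `W = Σ_i η_i ψ_i ψ_iᵀ` where `η_i = (−μ_i)₊ / ‖(−μ)₊‖₂`, attaining
   `tr(WΣ) = −‖(−μ)₊‖₂`. When Σ is diagonal this reduces exactly to the
   closed-form Relief weighting applied to the diagonal, which anchors the
   implementation against the Relief baseline in tests.

Iteration stops when `|ΔC| < tol` (default `1e-4` on the `1/N`-normalized
objective) or after `max_iter` rounds (default 10). `W(0)` is a seeded
random symmetric PSD unit-Frobenius matrix (Gaussian symmetrized, negative
eigenvalues clipped, renormalized). On well-asymmetric problems the
alternation settles in a handful of rounds; on the deliberately symmetric
two-Gaussian benchmark the two mirror-image solutions (feature-1- vs
feature-2-dominant) produce a damped two-phase oscillation, so a minority
of runs need a few dozen rounds. The converged `W` is a self-consistent
joint fixed point of both updates.

Degenerate spectra (no negative eigenvalue of Σ — no direction in which
hits are closer than misses) raise an error on the first round and
otherwise stop the fit keeping the previous `W`, flagged on the model.

Element-wise nonnegativity of `W` is a nominal constraint of the model
statement; the spectral step guarantees symmetry and positive
semidefiniteness but not element-wise sign, and no projection is applied
during iteration. Small entries (default threshold `1/A`, strict `<`) can
be pruned afterwards, with Frobenius renormalization of the survivors.

## Prediction

A query `x'` is standardized with the training scaler and scored per class
by the softmin-weighted mean q-distance to that class's training members:

    score(c) = Σ_{y_n = c} α_nᶜ(x') q(x', x_n),
    α_nᶜ(x') ∝ exp(−q(x', x_n)/σ).

The smaller score wins (the class maximizing the query's margin). As
σ → 0 this reduces to 1-nearest-neighbor under q. Exact ties go to the
larger training class, then to the first label in the stored class order.

## Hyperparameter tuning

σ is selected on the halving grid {4, 2, 1, 0.5, 0.25} (halved from 4
while strictly above 0.2), crossed with pruning on/off, by internal
stratified 5-fold cross-validation accuracy; ties prefer the larger σ,
then no pruning. Fold counts and repetitions for the internal loop are
package choices — the selection protocol requires only "internal
cross-validation".

## High-dimensional two-stage fit

Modelling all A² pairs is wasteful for wide tables. Stage 1 runs the same
alternation restricted to diagonal `W` (main effects only; the diagonal
closed form `w = (−diag Σ)₊/‖·‖₂`), producing a nonnegative unit-L2
feature-weight vector. Features with weight strictly above `2/A` (A the
original feature count) are kept; the rest are recorded as discarded and
can be added back by the caller. Stage 2 fits the full interaction model
on the kept features, initializing `W(0)` with the renormalized diagonal
of the kept weights. The model stores the kept indices so full-width
queries are projected correctly. Note that the `2/A` default is meaningful
only for large A: at A = 2 it equals 1.0, which a unit-norm weight vector
cannot strictly exceed, so low-dimensional uses should pass an explicit
threshold.

## Boosting

The boosted variant is standard AdaBoost with the interaction-margin
learner as base classifier. Sample weights `D_t` enter the objective by
multiplying both brackets per sample; consequently the per-instance
probability updates are unchanged and `D_t` acts only through the weighted
scatter. The temperature anneals geometrically from `σ_max = 4` to
`σ_min = 0.2` with ratio `(σ_min/σ_max)^{1/T}` per stored round, so early
learners see smooth global structure and later ones focus locally.
Defaults: `T = 100` rounds, base learner capped at 10 inner iterations.
Rounds with weighted training error `ε_t ≥ 1/2` or `ε_t = 0` are discarded
and retried with a fresh initialization (the schedule does not advance on
discarded rounds); attempts are capped at `2T` to guarantee termination,
and if only perfect learners were seen a single one is returned with vote
1. Stored rounds vote with `α_t = ½ log((1−ε_t)/ε_t)`.

## Synthetic benchmark

The generator emulates a two-feature interaction problem: class 1 is
Gaussian with mean (4, 2), class 2 with mean (6, 0), shared covariance
[[1, 0.5], [0.5, 1]] — the separating direction is the anti-diagonal
x₁ − x₂, carried jointly by the two correlated features. Contamination
replaces `round(ρ·100)` of each class's 100 samples with draws from a wide
class-specific noise Gaussian (means (8, −2) and (2, 4), covariance
[[8, 4], [4, 8]]) placed to disrupt the interaction signal; ρ sweeps 5% to
50% in 5% steps in `noise_sweep`. Optional independent standard-normal
nuisance columns support screening studies and default to zero. Noise
*replaces* clean samples so class sizes stay exactly 100 each.

A Monte-Carlo oracle reports the accuracy of the exact likelihood-ratio
classifier under the configured mixture. For the uncontaminated default
the value is also available in closed form — equal-prior Gaussians with
shared covariance give Bayes accuracy Φ(Δ/2) with Mahalanobis distance
Δ = 4, i.e. Φ(2) ≈ 0.9772 — which the tests use as a frozen regression
baseline for the Monte-Carlo estimate and as the ceiling against which
cross-validated accuracy is compared.

What the generator does *not* emulate: heavy-tailed or discrete features,
class imbalance, label noise, correlated nuisance features, and
higher-order (beyond pairwise) interactions. Passing tests therefore
demonstrate correctness of the machinery and qualitative robustness of the
interaction weight under contamination, not performance on real
gene-expression data.

## Evaluation protocol

Two learners are compared by repeated stratified 10-fold cross-validation,
ten repetitions (100 paired trials), with standardization and any nested
tuning fitted inside each training fold. Fold membership derives only from
the seed and the labels, so competing learners see identical splits and
their per-trial accuracies are paired. The comparison is a two-stage
paired Student's t-test at α = 0.05: a non-significant two-sided test is a
tie; otherwise a one-sided test in the direction of the observed mean
difference declares win or loss. Zero-variance difference vectors are
decided by sign (all-zero → tie). Stratification is a package choice made
because small classes make plain 10-fold splits degenerate.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run entirely on generated data:
50 seeded fits of the 200-sample benchmark for the convergence-speed
check; 20 seeds per contamination level for the interaction-recovery
trend; single-repetition tuned 10-fold CV against the analytic Bayes
ceiling; 10-round boosted ensembles for the AdaBoost bound; and 1000
simulated null resamples for the type-I-error rate of the comparison test.
These sizes were chosen to exercise every code path at the benchmark's
native scale (N = 200, A = 2) while keeping the default run fast on a
single CPU.

## Known limitations

- Binary classification only; multi-class problems must be reduced to two
  classes by the caller.
- Exact alternation can converge slowly on problems with symmetric
  competing solutions (see above); the iteration cap bounds the cost.
- The prediction rule stores the full standardized training table in the
  model (its score is a weighted distance to training members), so model
  files grow linearly with N.
- Pruning can break positive semidefiniteness of `W`; pruned matrices are
  treated as scoring weights, not metrics.
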