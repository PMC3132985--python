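# Methods

## The model

`mcbr` implements a Gaussian linear observation model with a K-component
scale-mixture prior on the weights:

    y = X w + b + ε,    ε ~ N(0, α⁻¹ Iₙ),        α ~ Γ(α₁, α₂)
    wⱼ | zⱼ, λ ~ N(0, λ_{zⱼ}⁻¹)
    λₖ ~ Γ(λ₁ₖ, λ₂ₖ)
    zⱼ | π ~ Categorical(π),     π ~ Dirichlet(η) (symmetric)

All Gamma distributions use the shape/rate convention,
Γ(x; a, b) = bᵃ x^{a−1} e^{−bx} / Γ(a).  Every feature in class k shares
the precision λₖ, so shrinkage is pooled within classes: the model
interpolates between a single global ridge penalty (K = 1, "BRR") and a
penalty per feature (K = p with zⱼ = j frozen, "ARD").  Marginalizing λₖ
makes each class prior a heavy-tailed Student-t on the weights at a
class-specific scale.  `mcbr.joint_log_density` is the single executable
definition of the joint; both inference engines are derived from it and
tested against it.

Integrating the class structure out, the weight prior is a mixture of
zero-mean Gaussians at K different scales — the mechanism by which
relevant features (assigned to weak-shrinkage classes) and irrelevant
ones (strong-shrinkage classes) are regularized differently, and the
reason the fitted `z` is a relevance clustering of features.

**Class labels are 0-based** (0..K−1) throughout the API.

## Hyperparameter presets

* `universal_hyperparams(K=9)`: λ₁ₖ = 10^(k−3) for k = 0..8 (10⁻³…10⁵),
  λ₂ₖ = 10⁻², α₁ = α₂ = 1.  Prior mean precisions therefore ladder
  through 10⁻¹…10⁷ — prior weight scales from ~3 down to ~3·10⁻⁴ — in
  √10 steps.  The heterogeneous shapes double as a label-symmetry
  breaker, so class identities are stable during sampling.  These priors
  assume the target is roughly unit-scale; a warning is emitted when
  var(y) falls outside [10⁻², 10³], and `standardize_y=True` opts into
  unit-variance scaling (undone at prediction time).  Note the top
  classes' shapes (10⁴, 10⁵) make those priors effectively delta
  functions: their precisions are pinned near 10⁶–10⁷ whatever the data
  say.  That is intended (they are the "kill" classes for noise
  features) but has consequences for VB (below).
* `brr_hyperparams()`: K = 1, all four Gamma constants 10⁻⁶ (essentially
  flat), matching the standard weakly informative Bayesian ridge setup.
* `ard_hyperparams(p)`: K = p, constants 10⁻⁶, assignments frozen at
  zⱼ = j and never updated.

η is never prescribed by the construction; the default is the uniform
symmetric Dirichlet η = 1, exposed in `MCBRHyperparams`.  The intercept
carries no prior: fitting runs on column-centered X and mean-centered y,
and b is recovered as mean(y) − mean-row(X)·w.

## Gibbs engine

One sweep draws, in the fixed order **z, λ, π, α, w**:

* zⱼ | · ∝ πₖ √λₖ exp(−λₖ wⱼ²/2), vectorized in log space with row-max
  subtraction;
* λₖ | · ~ Γ(λ₁ₖ + nₖ/2, λ₂ₖ + Sₖ/2), nₖ the class count, Sₖ the sum of
  squared member weights (empty classes redraw from their prior, which
  is what lets pruned classes repopulate);
* π | · ~ Dirichlet(η + n₁, …, η + nₖ);
* α | · ~ Γ(α₁ + n/2, α₂ + ‖y − Xw‖²/2);
* w | · ~ N(α P⁻¹ Xᵀy, P⁻¹) with P = α XᵀX + diag(λ_z), drawn via a
  Cholesky factor of P (on failure the diagonal is jittered once by
  10⁻¹⁰ × its mean; a second failure raises).

Any fixed sweep order leaves the stationary distribution unchanged; this
one is simply documented.  Initialization: z uniform at random, w = 0,
α and λ at prior means, π uniform.  Point estimates are post-burn-in
means of w, α, λ, π (defaults 5000 sweeps / 4000 burn-in); the reported
class assignment is the final sweep's z (so `z_prob` is one-hot), which
keeps the weight/assignment pair coherent for map readouts.  π is
sampled explicitly rather than collapsed.

Mixing note: the √10 spacing of the universal ladder is what makes the
sampler mix — a feature's assignment random-walks between adjacent
classes (odds ratios O(1)) rather than having to jump from the strongest
shrinkage class to the weakest in one step.

## Variational engine

Mean-field factorization q(w)q(α)q(λ)q(z)q(π) (Gaussian, Gamma, Gamma,
categorical, Dirichlet).  Updates cycle in the order qz, qλ, qπ, qα, qw;
each is the exact stationary point of the free energy
F = E_q[log p(y, Θ)] − E_q[log q], so F is non-decreasing after every
single update — the engine's master regression test, and F equals the
log evidence exactly when the posterior factorizes (verified against a
quadrature oracle on a pinned conjugate model).  Responsibilities are
initialized as uniform-random normalized rows; other factors start at
their priors.  The loop stops at 500 cycles or when |ΔF| ≤ 10⁻⁸ |F|
(configurable `tol`).  The full p×p posterior covariance of w is
maintained (intended for p up to ~500 post-screening); no factorized
approximation is used.

With the ARD preset the responsibilities are frozen at the identity and
the updates reduce exactly to variational ARD (each λⱼ update touches
only feature j).

**Known limitation (by design honest, not fixed):** with the universal
ladder, VB deterministically collapses to a one-class solution.  The
initial mixed responsibilities give every feature an effective precision
of order 10⁶, the weights shrink to ≈ 0, and the qz update then prefers
large-E[log λ] classes, which locks the collapse in; the near-delta top
priors cannot be moved by the data.  On the sparse benchmark this yields
ζ ≈ 0 — the documented failure mode that motivates the Gibbs engine.
The two engines do agree (weight correlation > 0.95) on well-conditioned
n ≫ p problems when the class priors are moderate enough to adapt.

## Synthetic benchmarks

`make_sparse_regression(n_train=50, n_test=50, p=200)`: X i.i.d. N(0,1),
y = 2(X₁+X₂−X₃−X₄) + 0.5(X₅+X₆−X₇−X₈) + ε, ε ~ N(0,1).  var(y) = 18,
noise ceiling ζ = 17/18.  Defaults are the study conditions used by the
benchmark harness and the acceptance script.

`make_volumetric(n=100)`: 12×12×12 standard-normal volumes, smoothed
with an isotropic Gaussian kernel (sd 2 voxels, zero padding, truncation
at 4 sd) to mimic fMRI spatial correlation; four 2×2×2 ROIs with weights
(−0.5, +0.5, −0.5, +0.5) placed deterministically one per octant, offset
2 voxels from the faces (origins (2,2,2), (8,8,2), (8,2,8), (2,8,8));
per image exactly half of the 32 ROI weights are dropped (reading "50%
randomly chosen" as exactly 16), emulating inter-image spatial
variability; y is computed from the *smoothed* in-support voxels; noise
sd is set from the empirical variance of the n noiseless targets to hit
a 5 dB SNR (no closed form exists after smoothing + dropout).  Features
are flattened x-fastest (index = x + 12y + 144z) with coordinates
attached.

What the generators do not emulate: hemodynamics, session/run structure,
scanner drift, subject variability beyond the dropout mechanism, or GLM
preprocessing.  Passing tests on them demonstrates correctness of the
machinery and qualitative behavior (adaptive shrinkage, feature
clustering, screening enrichment), not real-data performance.

## Evaluation protocol

* ζ uses population variances (divide by n) in numerator and
  denominator; the ratio is invariant to that convention, ζ = 1 is
  perfect, 0 is any constant prediction.
* `anova_select` ranks features by the one-way F statistic across the
  target's levels; for a continuous target with no repeated levels it
  falls back to squared-correlation ranking (documented, equivalent
  ordering to univariate regression F).  Ties break toward lower index.
* `cross_validate` supports k-fold and leave-one-condition / subject /
  session-out schemes; any screening-size or hyperparameter selection
  runs as a nested CV strictly inside each training fold (an
  information-leak test asserts that corrupting a held-out fold's
  targets cannot change the selection made for it).
* `run_benchmark` draws a fresh dataset per trial (trial t seeds the
  generator and every method with seed + t, so methods see identical
  data), reports mean, sample std (ddof = 1) and two-sided paired
  t-test p-values against a reference method.  The default six-method
  roster: Gibbs-MCBR and VB-MCBR (universal priors); BRR and ARD with
  all Gamma constants 10⁻⁶ via scikit-learn's evidence-maximization
  `BayesianRidge`/`ARDRegression` (the classical implementations of
  those two special cases); elastic net with the data-dependent grids
  λ₁ ∈ {0.2, 0.1, 0.05, 0.01}·‖Xᵀy‖∞ (L1) × λ₂ ∈ {0.1, 0.5, 1, 10, 100}
  (L2) on the objective ½‖y − Xw‖² + λ₁‖w‖₁ + ½λ₂‖w‖², tuned by inner
  5-fold CV; and linear-kernel SVR with C ∈ {10⁻³…10} tuned the same
  way.  No screening is applied on the sparse benchmark.
* `class_purity` reports per-class size and purity (% of truly
  informative members); the "informative class" is the one maximizing
  mean |w| over members.

Why scikit-learn for the BRR/ARD rows: a Gibbs chain under the 10⁻⁶
ridge prior is essentially immobile — the single λ's conditional has
shape p/2, making log λ a near-driftless random walk with step sd
√(2/p) that starts around 10⁸ when w is initialized at zero — so
sampling is not a practical estimator for that degenerate preset, while
evidence maximization is the standard one.  The in-repo engines still
accept both presets, and VB with the BRR preset is cross-checked against
`BayesianRidge` in the tests.

## Numerical choices and degenerate inputs

* All categorical/responsibility computations run in log space with
  max-subtraction (Gibbs) or log-sum-exp (VB); precision draws that
  underflow to zero contribute probability zero rather than NaN.
* Cholesky factorizations jitter once (10⁻¹⁰ × mean diagonal) and then
  raise; non-finite sampler states or free energies abort with the
  iteration index.
* Centering requires n ≥ 2; ζ requires var(y) > 0 (a zero-variance CV
  fold is scored missing and flagged).
* Dataset invariants (finite entries, matching lengths, unique voxel
  coordinates) are validated at construction.
* With a single class, π ≡ (1) without sampling; empty classes keep
  their prior and may be recolonized.

## Problem sizes in the shipped checks

The test-suite and acceptance runs use the study-scale benchmark (15
trials, p = 200, n = 50 + 50, 5000 Gibbs sweeps) — under a minute total —
plus small instances for the engine-level oracles: the brute-force joint
check enumerates all assignments at p = 3, n = 8, K = 2 and integrates
the precisions on dense log grids; moment checks for each conditional
use 10⁴–3·10⁴ draws; the free-energy monotonicity property runs 100
random small instances.
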