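# Methods

This note records the modelling choices, defaults, and numerical decisions
behind `mklconn`, and what the synthetic experiments do and do not
establish about real data.

## Graph spectrum and kernels

Structural connectomes are symmetrized as `(W + Wᵀ)/2` with the diagonal
zeroed before validation, because tractography-derived matrices are near-
but not exactly symmetric; asymmetry beyond a relative `1e-6` is treated
as a data error rather than silently averaged away. The Laplacian is the
symmetric normalized form `I − D^{-1/2} W D^{-1/2}` by default (the
unnormalized `D − W` is available via `normalization=`): normalization
makes diffusion scales comparable across subjects whose overall connection
strength differs, which matters because the co-activation stack is shared
cohort-wide. Eigenvalues are clipped at zero (round-off) and each
eigenvector's sign is fixed so its largest-magnitude entry is positive.
The sign convention makes serialized decompositions reproducible; every
kernel `H(γ) = Ψ e^{−Λγ} Ψᵀ` is provably invariant to it, and a test
asserts this. The matrix exponential is evaluated spectrally, which is
exact for symmetric Laplacians — no series truncation is involved.

### Scale placement

The number of scales `m` is a user choice (default 16; the synthetic
experiments use 4 to keep problems desk-sized). Scale *placement* is
data-driven: `γ_min` is found by bisection as the scale whose kernel
deviates from the identity by Frobenius norm `0.01·n` (smaller scales are
numerically indistinguishable from "no diffusion") and `γ_max` as the
scale within `0.01·n` of the rank-1 stationary projector (larger scales
add nothing). Scales are log-spaced between the endpoints, so refining
`m` nests coarser grids. Both deviation functionals are computed from the
spectrum alone, making the bisection cheap and deterministic. A
disconnected graph has no unique stationary projector and is rejected.

## The multi-kernel fit

The training objective separates over the `n` region columns, and each
column problem `min ‖XΠ^j − Y_j‖² + λ‖Π^j‖₁` is solved by
coordinate-descent LASSO (scikit-learn backend; objective mapped via
`alpha = λ/(2·pn)`), with **no intercept and no column standardization** —
the kernels already share a spectral footing, and standardization would
distort the meaning of the scales. `λ = 0` falls back to least squares.
The solver runs to a relative duality-gap tolerance of `1e-7`
(comfortably inside the `1e-5` KKT tolerance the tests assert);
non-convergence raises a diagnostic warning and returns the best iterate.
`λ = "auto"` selects the penalty on a logarithmic grid spanning
`[1e-4, 1] × λ_max` (with `λ_max = max_j ‖2XᵀY_j‖_∞`, the smallest fully
shrinking penalty) by 3-fold cross-validation over *subjects* (never rows
of one subject), with folds drawn deterministically from a seed; ties
prefer the sparser model. The chosen `λ` is serialized with the model.

The fit targets the full FC including its unit diagonal (the Frobenius
objective taken verbatim), while all evaluation correlations exclude the
diagonal; see "Identifiability" below for a consequence. Predictions
`Σ H_i π_i` are not symmetric for general `π_i`, so predicted FCs are
symmetrized to `(C_f + C_fᵀ)/2` by default — empirical FC is symmetric and
scatter/score computations need one value per region pair.

## Baselines

**SDK.** The sweep grid defaults to 50 log-spaced scales spanning the same
data-driven endpoints as the kernel bank. Per-subject optima are found by
maximizing the off-diagonal Pearson correlation between `H(γ)` and the
empirical FC; the cohort optimum is the mode over the shared grid points
(ties toward the smaller scale — the more local, conservative kernel).

**DMF.** Regional synaptic gating follows
`dS_i/dt = −S_i/τ_S + (1−S_i) γ H(x_i) + σ ν_i(t)` with the sigmoid-like
transfer `H(x) = (ax−b)/(1−e^{−d(ax−b)})` (the removable singularity at
`ax = b` is evaluated analytically as `1/d`) and input
`x_i = w J_N S_i + G J_N Σ_j C_ij S_j + I_0`. Local constants are the
reduced-model standards of the mean-field lineage (`a = 270 nC⁻¹`,
`b = 108 Hz`, `d = 0.154 s`, `γ = 0.641`, `τ_S = 0.1 s`,
`J_N = 0.2609 nA`, `w = 0.9`, `I_0 = 0.3 nA`, `σ = 0.001 nA`), all
overridable. Integration is Euler–Maruyama at `dt = 1 ms` with noise
`σ√dt·N(0,1)` per node per step and `S` clipped to `[0,1]` (gating is a
channel fraction). The SC is normalized by its maximum entry before
simulation (flag to disable) so that `G ∈ [0,3]` spans a comparable regime
across cohorts. BOLD uses the Balloon–Windkessel model with
Friston-lineage constants (`κ = 0.65 s⁻¹`, `γ_h = 0.41 s⁻¹`,
`τ_h = 0.98 s`, `α = 0.32`, `ρ = 0.34`, `V₀ = 0.02`), integrated at the
same `dt`, with a 20 s burn-in discarded and samples every `tr = 2 s`;
an 8-minute post-burn-in window therefore yields exactly 240 samples.
G-fitting reruns each candidate with the same noise stream so candidates
differ only in coupling.

## Synthetic cohorts

The generator emulates a small SC–FC cohort: a modular weighted template
(4 communities; intra/inter edge densities 0.85/0.25; lognormal weights
with location 0 intra and −1.5 inter, scale 0.5 — heavy-tailed, hub-like
weights), per-subject multiplicative jitter `exp(0.1·N(0,1))` on the
shared support, redrawn until connected. FCs come from the forward model
itself: `FC^s = sym(Σ H_i^s π_i*) + symmetric N(0, sd)` from a sparse
ground-truth `Π*` (Bernoulli support, standard-normal values), then mapped
into `[−1,1]` by a **single cohort-level** max-abs off-diagonal scalar
with the diagonal set to 1. A per-subject scalar would silently break the
shared-`Π` linear structure that recovery experiments rely on; the
cohort-level scalar folds into `Π` as one number. The pre-noise matrices
are returned for oracle tests. All randomness flows through named
substreams of one seed (template, jitter, `Π*`, FC noise), so cohorts are
bit-reproducible.

What the generator does **not** emulate: distance-dependent connection
probability, hemispheric organization, tractography biases, and —
importantly — realistic inter-subject variability. Jittered copies of one
template produce functional matrices that are much more similar across
subjects (off-diagonal correlation ≈ 0.99) than real cohorts, so synthetic
scores overstate how much of a real subject's FC is predictable, and
SC-destruction experiments understate degradation (see below).

## Identifiability and the limits of the synthetic experiments

Two structural facts shape what parameter-recovery experiments can show:

1. **The symmetrized target is outside the model's raw range.** The
   generator must symmetrize `Σ H_i π_i*` and force a unit diagonal to
   produce a valid FC, but the regression fits the *unsymmetrized* model.
   The fitted `Π` therefore reproduces predictions essentially perfectly
   while differing substantially from `Π*` entry-wise — even a noiseless
   least-squares fit on a full-rank design does not return `Π*`.
2. **Kernel columns are coherent across scales.** Log-spaced heat kernels
   share their low-frequency structure; column coherences reach ≈ 0.998,
   far beyond any sparse-recovery regime, so LASSO cannot re-identify the
   generating support among near-collinear alternatives.

Consequently, held-out *prediction* on synthetic cohorts is excellent
(≈ 0.99) and robust, but *support recovery* of `Π*` at matched sparsity
plateaus around 0.3–0.45 over the whole `λ` path. Prediction quality is
insensitive to this non-identifiability; interpretation of individual `Π`
entries is not, and should be done with care on real data too.

For the same reason, shuffling SC weights costs little on these cohorts:
the smallest scale's kernel is within `0.01·n` of the identity *by
construction of the scale set*, so a fitted `Π` can realize an almost
SC-invariant cohort-mean predictor, and near-identical subjects leave that
predictor scoring ≈ 0.99. Row-permuting `Π` — which destroys the learned
structure itself — collapses the score by ≈ 0.9, and the no-swap /
full-retention controls reproduce intact scores exactly.

## Problem sizes and determinism

The shipped tests and the acceptance script run cohorts of 15 subjects
with `n = 20` regions and `m = 4` scales, 250-draw perturbation and
permutation nulls, and mean-field demonstrations on 6-node graphs with
short horizons (the 240-sample BOLD check integrates a 500 s window at
`dt = 10 ms`); these sizes were chosen so the whole battery completes in
minutes while every property remains sharply testable. Every stochastic
component (cohort synthesis, fold splits, λ-selection, perturbation and
permutation nulls, mean-field noise) is driven by explicit seeds or named
substreams, and identical configuration plus seed reproduces `Π`, folds,
perturbations, and trajectories bit-for-bit — a property the test suite
asserts.

## Known limitations

- Scale count `m` and placement are fixed before fitting, not estimated.
- Structure recovery (SC from FC) is out of scope.
- Static FC only; no functional connectivity dynamics.
- Directed or signed structural graphs are not supported.
- `Π` entries should be interpreted as a predictive representation, not as
  uniquely identified physiological couplings (see "Identifiability").
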