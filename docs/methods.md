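# Methods

## The model

A trial-structured population recording is arranged as a dense tensor
`X ∈ R^{N×T×K}` (neurons × time points × trials).  Classical matrix
factorizations approximate an unfolding of `X` by a sum of rank-1 terms
and therefore commit to a single *covariability class*: patterns shared
across neurons, across time, or across trials.  `slicerank` instead
approximates the tensor by a small number of **slice-rank-1** terms, the
outer product of a loading vector along one axis and a full matrix
("slice") over the other two:

```
X̂[n,t,k] = Σ_r u_n^(r) A^(r)[t,k]  +  Σ_r v_t^(r) B^(r)[n,k]  +  Σ_r w_k^(r) C^(r)[n,t]
```

with `R = (R_neuron, R_time, R_trial)` components of the three slice
types.  A neuron-slicing term is a fixed neural pattern with an
arbitrary time-by-trial activation; a time-slicing term is a stereotyped
temporal profile whose neural encoding drifts over trials; a
trial-slicing term is a stereotyped spatiotemporal pattern (e.g. a
sequence) rescaled per trial.  The CP/TCA decomposition is the special
case in which every slice is itself rank 1; a single slice type reduces
exactly to a matrix factorization of the corresponding unfolding.
Both reductions are exploited as oracles in the test suite.

Assumptions: trials share a common time base (warp or trim first — see
`preprocess`), the data are dense and finite, and structure is
(multi)linear.  Chaotic or unalignable dynamics are out of model.

## Fitting

The loss is the mean squared error over unmasked entries.  Parameters
(loadings and slices) are initialized uniformly on [−1, 1] (or [0, 1]
under non-negativity) and optimized with Adam (β₁ = 0.9, β₂ = 0.999),
learning rate 0.02 by default.  Two masks multiply: a fixed train mask
(cross-validation holdout) and a stochastic mask that hides a scheduled
fraction of trainable entries to inject gradient noise.  The fraction
starts at 80% and halves per block of iterations (5 blocks × 200
iterations by default, stochastic subset redrawn every 20 iterations).
An endpoint-mode preset (`toy_config`) interpolates the fraction
geometrically from 0.8 to 0.05 and the learning rate from 0.2 to
0.0125 across five blocks, redrawing the mask every iteration; it is
the schedule used for the feedforward simulation experiments.
Non-negativity is enforced by projection (clamping at zero after each
step), which pairs naturally with the uniform [0, 1] initialization.
There is no early stopping; divergence (non-finite loss) raises an
error carrying the loss trace.  `multi_seed_fit` repeats the fit
(default ten restarts) and keeps the lowest train loss.  The optimizer's
moment parameters and the restart-seed derivation are package choices —
only the learning rate, schedule shape and restart count are inherent
to the procedure.

## Cross-validated model selection

Held-out entries are contiguous time blocks on randomly drawn
(neuron, trial) fibers — not salt-and-pepper — so temporal
autocorrelation cannot leak across the split; a margin trimmed from
both block ends belongs to neither set, and only block interiors are
scored.  The held-out fraction (default 20%) is counted before
trimming.  Blocks are placed by rejection sampling without wrapping;
geometry that cannot fit raises a usage error.

The grid search fits every rank tuple under identical per-repetition
splits and initialization seeds.  Selection uses a scale-free skill
score, `perf = 1 − RMSE_test / RMS(X)`; all ranks with
`perf ≥ θ · max perf` are admissible (θ = 0.80 unconstrained, 0.95
non-negative) and the smallest total rank wins, ties broken
lexicographically on (R_neuron, R_time, R_trial).  The performance
definition makes the thresholds dimensionless; it is the package's
concrete reading of "performance relative to the RMS of the data", and
an explicit `theta` enables elbow-style near-optimal selection.

## Invariances and the hierarchical optimization

Two transformation families preserve the fit:

1. **Within a slice type** — mixing the R components by any invertible
   `F` (loadings by `F`, slices by `F⁻¹`) leaves that type's partial
   reconstruction unchanged.
2. **Between slice types** — a rank-1 tensor built from one loading of
   each of two types and an arbitrary vector along the third axis can
   be subtracted from one type's slices and added to the other's,
   changing both partials but not their sum.

These classes commute, and they are resolved hierarchically:

* **Stage 1** minimizes the masked MSE (the fit above).
* **Stage 2** minimizes the summed squared entries of the three partial
  reconstructions over the between-type transfer parameters
  `x ∈ R^{R_time×R_trial×N}`, `y ∈ R^{R_neuron×R_trial×T}`,
  `z ∈ R^{R_neuron×R_time×K}` — a convex quadratic on the transfer
  orbit, so the optimized partials are unique regardless of which orbit
  member stage 1 produced.  It is minimized with Adam (learning rate
  0.02, budget 3000 iterations) with two stopping rules: RMS gradient
  below 1e-8, or no relative improvement of the best objective value
  beyond 1e-12 over 50 iterations.  The best-seen parameters are
  returned, which makes repeated application a no-op.  The full
  reconstruction is preserved exactly (the transfer identity is applied
  to the slices in closed form, not re-fitted).
* **Stage 3** recomputes each slice type's components from the
  truncated SVD of its partial reconstruction unfolded along the
  loading axis: orthonormal loadings, mutually orthogonal slices,
  ordered by captured variance, each loading oriented so its
  largest-magnitude entry is positive.  Operating on the partial
  reconstruction (rather than rotating stored factors) makes the stage
  exactly idempotent and numerically stable; degenerate singular-value
  ties fall back to the SVD's stable ordering with a warning.

Non-negative models skip stages 2–3: the gauge-fixing argument relies
on the unconstrained invariance classes, and the constraint already
restricts the solution set.  The CLI refuses `optimize --nonnegative`
with an explanatory message.

## Model similarity

Components of two equal-rank models are compared per slice type.  Each
pair scores the mean of |cos∠(loadings)| and |cos∠(vectorized slices)|;
the Hungarian algorithm maximizes the summed score, and the overall
similarity is the mean of matched scores (range [0, 1]).  The absolute
value absorbs the sign ambiguity of unconstrained factorizations — a
signed angle would report spurious disagreement for sign-flipped but
identical components.  The chance baseline permutes entries within each
weight vector of one model (default 100 repetitions) before rescoring.
Note that because slices are typically much higher-dimensional than the
transfer degrees of freedom, two stage-1-only fits of the same data can
already score well above the shuffle baseline; the pipeline's
contribution is pushing the score to ≈1.

## Synthetic ground truth

### Feedforward go/no-go model (default N=80, T=90, K=100)

Linear neurons sum two inputs.  (i) *Sensory*: a Gaussian-bump drive
`s_t = exp(−(t−4)²)` on each trial, weighted per neuron by go/no-go
weights that evolve across trials as independent Ornstein–Uhlenbeck
processes (targets μ_go = 2, μ_no = 0, diffusion σ = 1.3, per-neuron
rates α ~ U[0.2, 0.8], initialized at 1, clamped to [0, 2] after each
exact-discretization step, sampled at K evenly spaced points in
[0, 10]); the presented stimulus repeats the previous trial's with
probability 0.5.  (ii) *Top-down*: a rectified zero-mean Gaussian
process over time (squared-exponential kernel, lengthscale √0.5, fresh
draw per trial, 1e-8 diagonal jitter before Cholesky) through fixed
weights w ~ U[0, 1].  The tensor is the exact sum of a time-slicing
source (sensory) and a neuron-slicing source (top-down), hence slice
rank 2.  The time grid is T points on [0, 10] (the bump's interval is
not inherent to the model; this choice contains it comfortably) and
the trial grid includes both endpoints of [0, 10].

### Linear RNN with embedded sequences (default N=T=K=200; desk preset 60)

Connectivity `W = U S Uᵀ` with `U` the left singular vectors of a
random normal matrix and `S` two identical blocks
`(λ+ε)I₋ − λI` (sub-diagonal shift chains).  A trial's initial state
`cos θ · U₁ + sin θ · U_{N/2+1}` launches one or both sequences; a 2-D
input with per-trial linear dynamics (`A` entries ~ N(0, 1/2), initial
condition standard normal — the input's initial distribution is a
package choice) enters through the chain-tail columns `U_{N/2}` and
`U_N`, so input-driven activity stays in that 2-D subspace.  Noiseless
activity therefore decomposes exactly into two trial-slicing components
(loadings cos θ, sin θ) plus two neuron-slicing components — planted
rank (2 neuron, 0 time, 2 trial).  Integration is Euler–Maruyama with
`dt = horizon/T`.

Free numeric choices (no values are inherent to the construction):
`ε = 1` makes the chain-mode peak amplitudes approximately constant
(the amplitude ratio per mode is `(λ+ε)/(1+λ)`); the horizon is 5
membrane time constants — long enough for both sequences yet short
enough that the per-trial input dynamics, which are unstable with
probability ≈ 1/2, stay bounded; `λ` then sets the sequence speed so
the last chain mode peaks inside the trial (24 at N=200, 6.5 at the
desk preset).  Instability (norm blow-up) raises an error naming λ, ε
and dt.  Condition angles default to alternating {0, π/2}; a continuous
U[0, π/2] option exists.  Intrinsic (σ₁), input (σ₂) and observation
(σ₃) noise are independent; with the identity readout E[Y] = X, and a
separate `noise_seed` lets noisy repetitions share their structure.
`sigma3_for_zeta` calibrates σ₃ to a target noise fraction
ζ = ‖Y−X‖²/‖Y−ȳ‖², against which the variance explained
κ = 1 − ‖Ŷ−Y‖²/‖Y−ȳ‖² is judged (optimal denoiser: κ = 1 − ζ).

### What the generators do and do not emulate

They produce exactly-low-slice-rank structure plus controlled noise:
ideal for validating recovery, selection and uniqueness.  They do not
emulate spiking statistics, nonlinear readouts, non-negative rates with
baseline offsets, ragged trials, or slow nonstationarities other than
the modeled ones — passing tests demonstrate correctness of the
machinery, not that real recordings are low slice rank.

## Diagnostics

Per-neuron goodness of fit `1 − Σ(X−X̂)²/ΣX²` (undefined for silent
neurons, reported as NaN).  Per-neuron slice-type contributions use
*raw, unsquared* sums `f_n^type = Σ X̂^type / Σ X̂`; under sign
cancellation these can leave [0, 1] — they are reported as computed,
and the test suite pins the behavior with a constructed counterexample.
Slice spectra are singular values after removing each slice's
second-axis means (configurable), matching covariance-eigenspectrum
usage.

## Preprocessing

Piecewise linear warping maps each trial's event anchors onto shared
targets (helper: median inter-anchor intervals), resampling by linear
interpolation on a fixed-length output grid.  Gaussian temporal
smoothing uses reflect padding; scaling is per-neuron min-max over the
whole experiment (constant neurons map to 0 with a warning) or
z-scoring.

## Problem sizes and numerics

All computation is float64.  Equality-style assertions are phrased as
relative Frobenius errors.  The validation suite runs the feedforward
model at its default (80, 90, 100) scale with single-restart fits for
the composition sweep, the RNN at the 60³ desk preset with two
restarts, uniqueness at 30³, and cross-validated rank recovery at 30³
with ten independent single-seed repetitions over the {0..2}³ grid —
sizes chosen so the whole suite completes in a few minutes on one CPU
while leaving every effect far from its threshold.  The acceptance
script sweeps compositions with two restarts each at the full toy
scale.  Zero-rank models are legal everywhere and reconstruct to zeros
(the grid's origin).  Seeds propagate through `numpy` SeedSequence
substreams; every randomized stage is bit-reproducible given its seed.

## Known limitations

* The masked-SGD fit has no convergence guarantee; pathological ranks
  or learning rates can stall below the SVD bound (the 1%-of-oracle
  check in the tests guards the configured defaults only).
* Stage 2 is first-order; extremely ill-conditioned loading sets could
  leave a residual gradient (a warning reports the final RMS gradient).
* The similarity score is blind to component scale by construction and
  compares equal ranks only.
* The comparison-curve enumeration of rank compositions is exhaustive
  only up to total rank 6 (configurable), then greedy.
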