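# Methods

## Model and assumptions

The coding chain is linear and gaussian: an original signal s (zero mean,
covariance Σₛ) is degraded by a linear distortion A and additive white
sensory noise (variance σₙ²), encoded by M linear units with additive white
neural noise (variance σ_δ²), and read out by the optimal linear (Wiener)
estimator.  Key idealizations:

* **Co-diagonal structure.**  The blur A shares the signal eigenbasis E.
  For stationary image statistics E is the real 2-D Fourier basis and A a
  circular convolution; everything is then carried in per-component arrays
  (λᵢ, aᵢ, gains), and dense N×N matrices are materialized only on demand.
  This is what makes 121×121 (N = 14,641) problems cheap.
* **Second-order sufficiency.**  Encoder, decoder and expected error depend
  on the signal only through Σₛ; signals need not be gaussian (the sparse
  texture family exploits this for the response-sparsity cost).
* **Power-constrained capacity.**  Neural precision enters as a fixed
  per-unit SNR; the total response-power budget P = M·σ_δ²·10^(SNR/10)
  grows linearly with the population, which is the entire mechanism by
  which extra neurons help.

## Optimal allocation (water-filling)

Minimizing the closed-form MSE over per-component response powers pᵢ is a
convex problem whose KKT conditions give pᵢ = max(0, √(sᵢσ_δ²/μ) − σ_δ²),
with sᵢ = λᵢ²aᵢ²/(aᵢ²λᵢ+σₙ²) the recoverable power.  Implementation
choices:

* At most min(M, N) components are active; the active candidates are the
  top components ranked by sᵢ (descending), ties broken by ascending
  frequency then component index.  The ranking is provably optimal here
  because the per-component value functions sᵢ·p/(p+σ_δ²) are pointwise
  ordered by sᵢ.
* The water level μ is found by bisection on the monotone budget function
  (400 iterations, far past the 1e-10 relative tolerance), after which p
  is rescaled by P/Σp — a ≤1e-10 relative correction that makes the budget
  hold exactly, which downstream invariants (trace of the encoded
  covariance) rely on.
* Degenerate inputs: components with aᵢ²λᵢ + σₙ² = 0 are unobservable and
  get sᵢ = 0; a problem with no recoverable component raises an explicit
  infeasibility error.

The whitening baseline uses the same machinery with gains c/√(aᵢ²λᵢ) on
the top-M blurred-signal components and c chosen to spend P exactly.  With
a zero-variance component in the spectrum (the DC mode of a zero-mean
image model) complete whitening is undefined and reported as an error; the
abstract `make_powerlaw_components` constructor (all components positive)
is the configuration used for complete-case spectral comparisons.

## Shaping the orthogonal factor

All encoders W = VΛ̃Eᵀ with orthogonal V are MSE-equal; V is chosen by
minimizing

    Σⱼ (vⱼ/(P/M) − 1)²  +  γ · C(W)/C₀

where vⱼ is unit j's response variance (the individual power constraint),
C the selected resource cost and C₀ its value at initialization.  The
normalization — deviations measured relative to P/M, cost relative to C₀ —
is a design choice that makes γ (default 0.1) comparable across constraint
kinds and problem scales; the gradient is otherwise the straightforward
one, with the individual-power term ∇_W Σⱼ(vⱼ−P/M)² ∝ diag(vⱼ−P/M)·WΣₓ.

Each iteration takes a gradient step on W and projects back onto the
solution manifold by orthogonal Procrustes (SVD of the cross-product with
Λ̃Eᵀ), so the total power constraint is satisfied *exactly* at every
iterate and the expected MSE never changes.  The step size backtracks by
halving (≤30 times) whenever the objective would increase and grows by
1.3× after accepted steps.  Convergence requires violation ≤ 1% (the
documented tolerance of the individual constraint) and, when a cost is
active, relative cost change ≤ 1e-6 over 50 iterations; non-convergence
returns the best iterate with a warning — the procedure is a local one and
is genuinely susceptible to local minima.

Numerical details: |w| is smoothed as √(w²+ε²) and |z|^q as
(z²+ε²σ²)^{q/2} (ε = 1e-6·rms and 1e-3·σ respectively) so gradients exist
at zero; the response-sparsity scale σⱼ uses the model variance √vⱼ and is
held fixed within an iteration; the locality peak is the maximum-|w| entry,
ties to the lowest pixel index, recomputed every iteration.  The
generalized-gaussian shape parameter defaults to q = 0.5 and the
alternative locality reading Σ d·(w²)² sits behind `locality_quartic`.

Initialization matters.  Random orthogonal starts (QR of a seeded gaussian
matrix, optional restarts) balance power reliably but rarely escape to
spatially localized optima — consistent with the local-minima caveat
above.  For the locality kind a warm start is therefore provided
(`init="target"`): project a spatially local target onto the manifold —
the identity when M = N (yielding the symmetric, ZCA-like solution, which
for stationary statistics is circulant and balances individual power
essentially exactly), else M gaussian bumps of width κ·√(N/(πM)) (κ
default 0.5, `kappa_scan` explores the range) centered on k-means
centroids of uniform samples of the visual field.  The localized
populations shown in the examples come from this route plus gradient
refinement.

## Synthetic data

The texture generator draws s = E·diag(√λ)·u with u i.i.d. unit-variance
coefficients — gaussian, or generalized-gaussian with exponent 0.7 for the
sparse family (the minimal higher-order structure that makes the
response-sparsity cost non-degenerate).  Default study conditions follow
the retinal setting: 1/f² spectrum with the DC variance set to zero and
tr(Σₛ) = N (unit pixel variance), gaussian blur MTF exp(−2π²σ²f²) with
σ = 1 px standing in for measured eye optics, sensory SNR swept over
−10…20 dB, neural SNR 10 dB (≈1.7 bits/unit), cell ratios 1:1 (fovea) and
16:1 (periphery), grids of 15×15 for shaping studies and 121×121 / 14,641
components for scaling checks.  What the generator does *not* emulate:
calibrated luminances, cone spectral sensitivity and nonlinearity,
measured point-spread functions, and the non-stationarity of real scenes —
so passing tests demonstrate the mechanics of the code, not quantitative
retinal predictions; quantities that depend on measured optics and
empirical image covariances (e.g. exact cone counts inside RF centers) are
checked only as orderings, not values.

## Diagnostics

Stage spectra report per-component variances and gains at every pipeline
stage.  Receptive-field centers are the 8-connected half-height region
around the maximum-|w| pixel, counted on raw weights (smoothing, σ=0.5 px,
is applied only to displayed cross-sections).  The center-surround
classifier requires a positive peak and a negative mean weight in every
populated quadrant of the annulus two dilations beyond the center —
satisfied by difference-of-gaussians structure, failed by oriented or
delocalized fields.  Light adaptation is the percent change of mean center
pixel count between low- and high-SNR populations.

## Problem sizes in the test-suite and acceptance runs

Shaping studies run on 15×15 grids (M = 225), spectral comparisons on 100
abstract components, oracle cross-checks on N ≤ 8 with exhaustive
active-set enumeration plus SLSQP — sizes chosen to keep each study a
desk-scale computation while preserving every qualitative regime
(complete/under/overcomplete, low/high SNR).

## Known limitations

* The shaping objective is non-convex in V; different seeds give different
  (equally optimal in MSE, differently costed) populations.
* Whitening is undefined for overcomplete populations and for complete
  populations over rank-deficient spectra — both reported as errors rather
  than patched.
* The locality cost's printed form admits two readings (quadratic vs
  quartic in w); both are implemented, quadratic by default.
* Periodic (circulant) boundary conditions: receptive fields near the grid
  edge wrap around, which inflates distance-based costs for edge units.
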