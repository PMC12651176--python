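# Methods

## Model and scope

The package implements the linearized stochastic Amari neural field on a
periodic one-dimensional lattice.  The nonlinear equation is used only to
locate the homogeneous fixed point u0 (root of u0 = w̃ f[u0], with
w̃ = ∫ w(x,y) dy the constant row integral); all dynamics are the linear
Langevin equation for the fluctuations, d eta/dt = Lambda eta + xi, with
additive Gaussian noise white in time.  One spatial dimension is chosen
because every formula involved (Lyapunov equation, trace formula, spectral
decomposition, path functional) is dimension-agnostic at the matrix level;
the ring keeps the Fourier route exact and desk-scale.  Multiplicative,
non-Gaussian or time-correlated noise, higher-dimensional grids, and
simulation of the full nonlinear equation are out of scope.

## Discretization contract

A single convention is used everywhere so that the three sigma routes agree
exactly on the discrete system:

- Operators are matrices acting directly on field vectors; a smooth kernel
  k(x,y) enters as `k(x_i, x_j) * dx`, a Dirac delta as `delta_ij / dx`.
  Hence `Lambda = -I/tau + (f'[u0]/tau) W dx`.
- Covariances (noise Gamma, stationary C) hold plain kernel values at grid
  points; space-time white noise of amplitude T is `(T/dx) I`.  With these
  choices the Lyapunov equation, the trace formula, and the Onsager-Machlup
  quadratic form are dx-free matrix algebra.
- Mode transform: `eta_k = dx * Σ_j eta_j exp(-i k x_j)`, k = 2πm/L,
  m ∈ [-N/2, N/2).  The kernel transform `w_hat_k = dx * FFT(profile)` (first
  kernel column, i.e. the profile w(x_j)) makes `lambda_k = (-1 + f'[u0]
  w_hat_k)/tau` exactly the eigenvalues of the circulant drift matrix.  The
  per-mode noise amplitude consistent with this transform is `gamma_k = L *
  dx * FFT(noise profile)_k`; it appears in the stationary mode correlators
  but never in sigma_k.

The noise convention is `<xi(t) xi(t')> = Gamma delta(t-t')`, i.e. Gamma is
the full noise amplitude (diffusion matrix Gamma/2).  The Lyapunov equation
is written accordingly as `Lambda C + C Lambdaᵀ = -Gamma`; comparisons with
texts using `... = -2D` must respect this factor.

## Numerical choices

- **Lyapunov solve**: dense Bartels-Stewart (`scipy.linalg.
  solve_continuous_lyapunov`), symmetrized, residual checked against
  `1e-10 ||Gamma||_F`; precision via Cholesky solves, never an explicit
  inverse of an ill-conditioned matrix.
- **Trace formula**: evaluated with Cholesky-based applications of
  Gamma⁻¹.  The algebraically equivalent form `Tr[2 Lambdaᵀ Gamma⁻¹ Lambda C
  + Lambda]` is computed alongside; disagreement beyond 1e-8 (relative to
  the term magnitudes) raises an internal-consistency error.  Note the
  equivalent forms involve cancellation of O(Tr Lambda) terms, so near
  equilibrium sigma is accurate only to ~1e-12 × that scale — hence the
  "numerical zero" floor of 1e-10 used in equilibrium assertions.
- **Stability**: all drift eigenvalues must satisfy Re < -1e-10; violations
  raise rather than warn, because every stationary formula assumes strict
  stability.
- **Equilibrium verdict**: relative Frobenius asymmetry of h = Lambda Gamma,
  default tolerance 1e-8 (configurable).  The composition h = Lambda_mat
  Gamma_mat is convention-independent for the symmetry test.
- **Fixed point**: sign-change scan (4001 points) of w̃ f[u] - u on
  [min(0,w̃)-1, max(0,w̃)+1] — analytically safe since 0 < f < 1 — polished
  by Brent to |residual| ≤ 1e-12.  With a steep sigmoid the equation is
  bistable; the default selector takes the stable root with largest u0
  (configurable by index or nearest-value).
- **Integrator**: Euler-Maruyama with Cholesky noise factor.  Additive noise
  means the SDE needs no Ito/Stratonovich choice; the midpoint rule is
  applied only in the entropy functional, where it is what produces the
  equal-time noise-field correlation Gamma/2.  Accuracy guard:
  dt·max|eigenvalue| > 0.1 warns, > 0.5 errors.
- **Path estimator**: Sigma(t) is computed both as the backward-minus-forward
  Onsager-Machlup action and as the Stratonovich sum
  `2 Σ_n Δeta_nᵀ Gamma⁻¹ Lambda eta_bar_n`.  The two are algebraically
  identical; the gap is accumulated per time step (differencing per-step
  quadratic forms, not two large totals) so it stays at rounding level
  (≲1e-12) even on 10⁶-step runs, and is checked against
  1e-9·(1+|Sigma|).  Path normalization constants are direction-independent
  and never computed.
- **Error bars**: non-overlapping block bootstrap (200 resamples), block
  length max(10 slowest relaxation times, 100 steps), at least 20 blocks
  required.  Bootstrap RNG seeds derive from the trajectory seed, so results
  are reproducible.
- **Finite-run and finite-step bias**: the estimator bias is O(dt) (first
  order, consistent with the weak order of the scheme) and the correlator
  bias from a finite run is O(exp(-2|Re lambda| t)); both are documented
  rather than corrected, and the study runs choose dt and t so they sit well
  inside the statistical errors.

## Synthetic inputs

Kernels and noise covariances are generated from parametric families on the
ring (minimum-image distances, so every matrix is circulant): an even
Gaussian profile (equilibrium branch), a shifted Gaussian whose displacement
breaks w(x,y) = w(y,x) (the sole source of irreversibility under translation
invariance), a mexican-hat difference of Gaussians, a pure shift, and
explicit user matrices.  The correlated-noise family is a *wrapped* Gaussian
(summed over periodic images): plain truncation of a Gaussian profile is not
positive definite on a ring, while the wrapped profile has strictly positive
Fourier coefficients, needing only a 1e-10·T diagonal jitter.

Default study conditions used by the tests and the acceptance script:
sigmoid gain beta = 2, threshold u* = 0.5, relaxation time tau = 1, kernels
normalized to row integral w̃ = 1.  These give u0 = 0.5 (by threshold
symmetry), f'[u0] = beta/4 = 0.5, and slowest eigenvalue -0.5, i.e. a
comfortably stable, moderately correlated field.  Problem sizes: N = 64
(equilibrium null, 10⁶ steps at dt = 1e-3), N = 32 (trace/spectral
equivalence), N = 16 with runs of several thousand relaxation times for
statistics recovery, and the 2-dimensional rotation drift -aI + bJ (a = b =
1; sigma = 2b²/a = 2) as the exactly solvable nonequilibrium benchmark.

What the generator does *not* emulate: real cortical connectivity is neither
translation invariant nor one-dimensional, activity is nonstationary, and
empirical recordings add measurement noise and coarse-graining — passing
tests show the estimators recover the model's own sigma, not that the model
describes any particular dataset.

## Open design points resolved here

- The stationary mode correlator is taken as `<eta_dot_k eta_k*> = gamma_k
  (lambda_k* - lambda_k)/(4 Re lambda_k)` — the grouping under which the
  correlator combination reproduces sigma_k exactly.  It is independently
  confirmed by a direct Stratonovich calculation (`<eta_dot eta*> = lambda
  <|eta|^2> + gamma/2`) and by simulation; e.g. lambda = -1+i, gamma = 2
  gives +i.
- `mode_epr` accepts arbitrary strictly stable eigenvalues (not only
  circulant-model modes): for any normal drift with scalar noise the sum of
  -Im²/Re over the spectrum equals the trace formula, which is how the
  rotation benchmark is cross-checked without a 2×2 circulant (a real 2×2
  circulant is symmetric and has no complex modes).
- For kernels whose transform does not decay (pure shift), sigma grows with
  N; the CLI spectrum command warns when the highest-|k| mode contributes
  more than 1% of the total.  The per-mode spectrum, not the total, is the
  resolution-independent object.

## Known limitations

Dense linear algebra limits grids to a few hundred sites (ample here).
Trajectories are stored in memory (a 10⁶ × 64 run is ~0.5 GB).  The path
estimator requires the generating (Lambda, Gamma) — model-mismatch and
data-driven (inference) entropy estimation are out of scope, as are
partial-observation/coarse-graining bounds.
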