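"""Three independent routes to the same entropy production rate.

For a nonequilibrium model (shifted-Gaussian coupling, white noise) we compute
sigma by (1) the analytic trace formula on the Lyapunov covariance, (2) the
per-Fourier-mode closed form summed over modes, and (3) the Lebowitz-Spohn
path estimator applied to a simulated trajectory (log-ratio of forward to
backward path probabilities per unit time).  The first two agree to machine
precision; the third agrees within its statistical error.
"""

from amari_epr import (
    DiscreteGrid, KernelSpec, NoiseSpec, SigmoidActivation, SimulationConfig,
    build_kernel, build_model, build_noise, entropy_production_trace,
    lebowitz_spohn_estimate, simulate, spectral_entropy_production,
)

grid = DiscreteGrid(n_points=32, length=10.0)
act = SigmoidActivation(gain=2.0, threshold=0.5)
W = build_kernel(KernelSpec("shifted_gaussian", width=1.0,
                            shift=grid.length / 8, normalization=1.0), grid)
model = build_model(grid, tau=1.0, act=act, kernel_matrix=W)
noise = build_noise(NoiseSpec("white", amplitude=1.0), grid)
L, G = model.drift_matrix, noise.covariance_matrix

sigma_trace = entropy_production_trace(L, G)
sigma_spectral = spectral_entropy_production(model, noise).total_epr

traj = simulate(model, noise,
                SimulationConfig(dt=1e-3, n_steps=500_000, seed=1,
                                 burn_in=5_000))
est = lebowitz_spohn_estimate(traj, L, G)

print(f"trace formula      sigma = {sigma_trace:.10f}")
print(f"spectral sum       sigma = {sigma_spectral:.10f}")
print(f"path estimator     sigma = {est.sigma_hat:.4f} +/- {est.standard_error:.4f}"
      f"   ({est.n_blocks} blocks, OM gap {est.om_consistency_gap:.2e})")
print("\nThe OM gap is the difference between the action-difference and")
print("Stratonovich-sum evaluations of Sigma(t) - identical up to rounding.")
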