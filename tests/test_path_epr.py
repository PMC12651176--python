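import numpy as np
import pytest

from amari_epr import (
    DiscreteGrid,
    SimulationConfig,
    Trajectory,
    entropy_production_trace,
    lebowitz_spohn_estimate,
    model_from_drift,
    path_action,
    reservoir_entropy_rate_mc,
    shannon_entropy_rate_decomposition,
    simulate,
    solve_lyapunov,
    time_reverse,
)
from conftest import random_stable_system


def make_traj(fields, dt=1.0, seed=0):
    fields = np.asarray(fields, dtype=float)
    return Trajectory(times=dt * np.arange(len(fields)), fields=fields, dt=dt,
                      model_fingerprint="", seed=seed)


class TestPathAction:
    def test_hand_evaluated_single_site(self):
        # Lambda = -1, Gamma = 1, dt = 1, eta: 0 -> 1
        traj = make_traj([[0.0], [1.0]])
        s_f = path_action(traj, np.array([[-1.0]]), np.array([[1.0]]), "forward")
        assert s_f == pytest.approx(9.0 / 8.0, rel=1e-14)
        s_b = path_action(traj, np.array([[-1.0]]), np.array([[1.0]]), "backward")
        assert s_b == pytest.approx(1.0 / 8.0, rel=1e-14)

    def test_noiseless_solution_has_vanishing_action(self):
        L = np.array([[-1.0]])
        dt = 1e-4
        t = dt * np.arange(1001)
        traj = make_traj(np.exp(-t)[:, None], dt=dt)
        s = path_action(traj, L, np.array([[1.0]]), "forward")
        assert s <= 1e-4  # O(dt) at fixed horizon

    def test_forward_on_reversed_equals_backward(self, rotation_system):
        model, noise = rotation_system
        traj = simulate(model, noise, SimulationConfig(dt=1e-2, n_steps=200, seed=4))
        L, G = model.drift_matrix, noise.covariance_matrix
        a1 = path_action(time_reverse(traj), L, G, "forward")
        a2 = path_action(traj, L, G, "backward")
        assert a1 == pytest.approx(a2, rel=1e-12)

    def test_rejects_singular_noise(self):
        traj = make_traj([[0.0], [1.0]])
        with pytest.raises(ValueError, match="positive definite"):
            path_action(traj, np.array([[-1.0]]), np.array([[0.0]]))


class TestLebowitzSpohn:
    def test_equilibrium_estimate_covers_zero(self, sym_model, white_noise):
        cfg = SimulationConfig(dt=2e-3, n_steps=400_000, seed=31)
        traj = simulate(sym_model, white_noise, cfg)
        est = lebowitz_spohn_estimate(
            traj, sym_model.drift_matrix, white_noise.covariance_matrix)
        assert abs(est.sigma_hat) <= 3 * est.standard_error

    def test_rotation_system_recovers_sigma(self, rotation_system):
        model, noise = rotation_system
        cfg = SimulationConfig(dt=1e-3, n_steps=500_000, seed=8)
        traj = simulate(model, noise, cfg)
        est = lebowitz_spohn_estimate(
            traj, model.drift_matrix, noise.covariance_matrix)
        assert abs(est.sigma_hat - 2.0) <= 3 * est.standard_error
        assert est.standard_error < 0.5

    def test_onsager_machlup_identity_gap(self, rotation_system):
        model, noise = rotation_system
        traj = simulate(model, noise, SimulationConfig(dt=1e-3, n_steps=50_000,
                                                       seed=9))
        est = lebowitz_spohn_estimate(
            traj, model.drift_matrix, noise.covariance_matrix,
            block_steps=1000)
        t = traj.times[-1]
        assert est.om_consistency_gap <= 1e-9 * (1 + abs(est.sigma_hat * t))

    def test_running_series_converges_to_estimate(self, rotation_system):
        model, noise = rotation_system
        traj = simulate(model, noise, SimulationConfig(dt=1e-3, n_steps=100_000,
                                                       seed=10))
        est = lebowitz_spohn_estimate(
            traj, model.drift_matrix, noise.covariance_matrix, block_steps=2000)
        assert est.running_sigma[-1] == pytest.approx(est.sigma_hat, rel=1e-12)

    def test_fingerprint_mismatch_rejected(self, rotation_system):
        model, noise = rotation_system
        traj = simulate(model, noise, SimulationConfig(dt=1e-2, n_steps=100, seed=1))
        with pytest.raises(ValueError, match="different"):
            lebowitz_spohn_estimate(traj, -np.eye(2), noise.covariance_matrix)

    def test_dt_bias_shrinks_with_step(self, rotation_system):
        # first-order estimator: error vs analytic sigma decreases with dt
        model, noise = rotation_system
        L, G = model.drift_matrix, noise.covariance_matrix
        devs = []
        for dt, n in ((4e-2, 100_000), (1e-2, 400_000)):
            traj = simulate(model, noise,
                            SimulationConfig(dt=dt, n_steps=n, seed=77))
            est = lebowitz_spohn_estimate(traj, L, G)
            devs.append((abs(est.sigma_hat - 2.0), est.standard_error))
        # coarse run has visible bias; fine run is within errors
        assert devs[1][0] <= 3 * devs[1][1] or devs[1][0] < devs[0][0]


class TestReservoirMC:
    def test_equilibrium_rate_is_zero(self, sym_model, white_noise):
        L, G = sym_model.drift_matrix, white_noise.covariance_matrix
        st = solve_lyapunov(L, G)
        est = reservoir_entropy_rate_mc(L, G, st, 50_000, seed=13)
        # at equilibrium the integrand vanishes pointwise, leaving only rounding
        assert abs(est.s_dot_res) <= 3 * est.standard_error + 1e-12
        # at detailed balance the current vanishes pointwise: Lambda C = -Gamma/2
        np.testing.assert_allclose(L @ st.covariance, -G / 2, atol=1e-10)

    def test_rotation_system(self, rotation_system):
        model, noise = rotation_system
        L, G = model.drift_matrix, noise.covariance_matrix
        st = solve_lyapunov(L, G)
        est = reservoir_entropy_rate_mc(L, G, st, 100_000, seed=14)
        assert abs(est.s_dot_res - 2.0) <= 3 * est.standard_error

    def test_half_sample_consistency(self, rotation_system):
        model, noise = rotation_system
        L, G = model.drift_matrix, noise.covariance_matrix
        st = solve_lyapunov(L, G)
        e1 = reservoir_entropy_rate_mc(L, G, st, 40_000, seed=100)
        e2 = reservoir_entropy_rate_mc(L, G, st, 40_000, seed=200)
        combined = np.hypot(e1.standard_error, e2.standard_error)
        assert abs(e1.s_dot_res - e2.s_dot_res) <= 3 * combined


class TestShannonDecomposition:
    def test_equilibrium_all_zero(self, sym_model, white_noise):
        L, G = sym_model.drift_matrix, white_noise.covariance_matrix
        st = solve_lyapunov(L, G)
        s_tot, s_res, s_sys = shannon_entropy_rate_decomposition(L, G, st)
        assert abs(s_tot) <= 1e-10 and abs(s_res) <= 1e-10 and abs(s_sys) <= 1e-10

    def test_rotation_system_closed_form(self, rotation_system):
        model, noise = rotation_system
        L, G = model.drift_matrix, noise.covariance_matrix
        st = solve_lyapunov(L, G)
        s_tot, s_res, s_sys = shannon_entropy_rate_decomposition(L, G, st)
        assert s_tot == pytest.approx(2.0, rel=1e-12)
        assert s_res == pytest.approx(2.0, rel=1e-12)
        assert abs(s_sys) <= 1e-12

    def test_total_rate_nonnegative_and_equals_trace(self):
        rng = np.random.default_rng(21)
        for _ in range(10):
            L, G = random_stable_system(rng, 5, correlated_noise=True)
            st = solve_lyapunov(L, G)
            s_tot, s_res, s_sys = shannon_entropy_rate_decomposition(L, G, st)
            sigma = entropy_production_trace(L, G, st)
            assert s_tot >= -1e-10
            assert s_tot == pytest.approx(sigma, rel=1e-9, abs=1e-10)
            assert abs(s_sys) <= 1e-9 * (1 + abs(s_tot))


class TestConsistencyTriangle:
    @pytest.mark.parametrize("seed", [0, 1])
    def test_three_routes_agree_on_random_small_system(self, seed):
        rng = np.random.default_rng(1234 + seed)
        n = 3
        L, G = random_stable_system(rng, n, correlated_noise=True)
        grid = DiscreteGrid(n, float(n))  # dx = 1
        model = model_from_drift(grid, L)
        from amari_epr import NoiseModel

        noise = NoiseModel.from_covariance(grid, G)
        st = solve_lyapunov(L, G)
        sigma = entropy_production_trace(L, G, st)
        s_tot, s_res, _ = shannon_entropy_rate_decomposition(L, G, st)
        assert s_tot == pytest.approx(sigma, rel=1e-10, abs=1e-10)
        mc = reservoir_entropy_rate_mc(L, G, st, 200_000, seed=seed)
        assert abs(mc.s_dot_res - sigma) <= 3 * mc.standard_error
        re_min = float(np.abs(np.linalg.eigvals(L).real).min())
        dt = min(1e-3, 0.05 / np.abs(np.linalg.eigvals(L)).max())
        traj = simulate(model, noise,
                        SimulationConfig(dt=dt, n_steps=400_000, seed=seed))
        est = lebowitz_spohn_estimate(traj, L, G)
        assert abs(est.sigma_hat - sigma) <= 3 * est.standard_error

    def test_noise_field_equal_time_correlator(self, rotation_system):
        # Stratonovich half: E[d eta . midpoint] / dt = Lambda C + Gamma / 2
        model, noise = rotation_system
        L, G = model.drift_matrix, noise.covariance_matrix
        C = solve_lyapunov(L, G).covariance
        traj = simulate(model, noise,
                        SimulationConfig(dt=1e-3, n_steps=500_000, seed=55))
        X = traj.fields
        d = (X[1:] - X[:-1]) / traj.dt
        mid = 0.5 * (X[1:] + X[:-1])
        D = np.einsum("ti,tj->ij", d, mid) / d.shape[0]
        xi_eta = D - L @ C  # should be Gamma / 2
        # crude SE: independent-block scale for each entry
        n_eff = traj.times[-1] / 2.0
        se = np.sqrt(G[0, 0] / (2 * traj.dt)) / np.sqrt(d.shape[0])
        assert np.all(np.abs(xi_eta - G / 2) <= 3 * se * np.sqrt(2))
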