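"""Euler-Maruyama integration of the linear Langevin field dynamics.

The update is ``eta_{n+1} = eta_n + dt * Lambda eta_n + sqrt(dt) * B z_n``
with ``B Bᵀ = Gamma`` (Cholesky factor) and i.i.d. standard-normal ``z_n``.
Additive noise means the SDE itself has no Ito/Stratonovich ambiguity; the
Stratonovich subtlety enters only in the entropy-production functional
(module ``path_epr``).
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np

from .field_model import DiscreteGrid, NeuralFieldModel, NoiseModel
from .spectral_epr import _mode_grid

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "ModeCorrelatorEstimates",
    "simulate",
    "time_reverse",
    "empirical_mode_correlators",
    "model_fingerprint",
]


@dataclass(frozen=True)
class SimulationConfig:
    """Integrator settings; all randomness flows from the single ``seed``."""

    dt: float
    n_steps: int
    burn_in: int = 0
    seed: int = 0
    initial_field: np.ndarray | str = "stationary"
    save_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.n_steps <= 0:
            raise ValueError("n_steps must be positive")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")
        if self.save_stride <= 0:
            raise ValueError("save_stride must be positive")


@dataclass(frozen=True)
class Trajectory:
    """Chronologically ordered field configurations at uniform spacing."""

    times: np.ndarray = field(repr=False)
    fields: np.ndarray = field(repr=False)  # shape (n_saved, n_points)
    dt: float = 0.0  # spacing between saved frames
    model_fingerprint: str = ""
    seed: int = 0


def model_fingerprint(drift: np.ndarray, noise_cov: np.ndarray) -> str:
    """Hash identifying the (Lambda, Gamma) pair a trajectory was generated with."""
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(drift, dtype=float).tobytes())
    h.update(np.ascontiguousarray(noise_cov, dtype=float).tobytes())
    return h.hexdigest()[:16]


def _check_dt(dt: float, drift: np.ndarray) -> None:
    from scipy import linalg

    rho = float(np.max(np.abs(linalg.eigvals(drift))))
    if dt * rho > 0.5:
        raise ValueError(
            f"dt * max|eigenvalue| = {dt * rho:.3g} > 0.5: integration unstable"
        )
    if dt * rho > 0.1:
        warnings.warn(
            f"dt * max|eigenvalue| = {dt * rho:.3g} > 0.1: results may be "
            "inaccurate", stacklevel=3,
        )


def simulate(
    model: NeuralFieldModel, noise: NoiseModel, config: SimulationConfig
) -> Trajectory:
    """Integrate ``eta_dot = Lambda eta + xi`` and return the saved trajectory.

    ``initial_field`` may be a vector, ``"zero"``, or ``"stationary"`` (draw
    from the Lyapunov covariance — the right choice for stationary entropy
    estimates, avoiding transient bias).  Bit-reproducible for a given seed.
    """
    if model.grid.n_points != noise.grid.n_points:
        raise ValueError("model and noise grids do not match")
    L = model.drift_matrix
    n = model.grid.n_points
    _check_dt(config.dt, L)
    rng = np.random.default_rng(config.seed)

    if isinstance(config.initial_field, str):
        if config.initial_field == "zero":
            eta = np.zeros(n)
        elif config.initial_field == "stationary":
            from scipy import linalg

            from .stationary_epr import solve_lyapunov

            C = solve_lyapunov(L, noise.covariance_matrix).covariance
            eta = linalg.cholesky(C, lower=True) @ rng.standard_normal(n)
        else:
            raise ValueError(f"unknown initial_field {config.initial_field!r}")
    else:
        eta = np.array(config.initial_field, dtype=float)
        if eta.shape != (n,):
            raise ValueError("initial_field has wrong shape")

    dt = config.dt
    sqdt = np.sqrt(dt)
    A = np.eye(n) + dt * L
    B = noise.factor
    stride = config.save_stride
    n_saved = config.n_steps // stride + 1
    out = np.empty((n_saved, n), dtype=float)
    out[0] = eta

    # burn-in (discarded)
    chunk = 16384
    for start in range(0, config.burn_in, chunk):
        m = min(chunk, config.burn_in - start)
        z = rng.standard_normal((m, n)) @ B.T
        for i in range(m):
            eta = A @ eta + sqdt * z[i]
    out[0] = eta

    saved = 1
    for start in range(0, config.n_steps, chunk):
        m = min(chunk, config.n_steps - start)
        z = rng.standard_normal((m, n)) @ B.T
        for i in range(m):
            eta = A @ eta + sqdt * z[i]
            if (start + i + 1) % stride == 0:
                out[saved] = eta
                saved += 1
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("trajectory diverged; reduce dt")
    dts = dt * stride
    times = dts * np.arange(n_saved)
    return Trajectory(
        times=times, fields=out, dt=dts,
        model_fingerprint=model_fingerprint(L, noise.covariance_matrix),
        seed=config.seed,
    )


def time_reverse(traj: Trajectory) -> Trajectory:
    """Backward trajectory ``eta_bar(s) = eta(t - s)``; an involution."""
    return Trajectory(
        times=traj.times.copy(), fields=traj.fields[::-1].copy(), dt=traj.dt,
        model_fingerprint=traj.model_fingerprint, seed=traj.seed,
    )


@dataclass(frozen=True)
class ModeCorrelatorEstimates:
    """Empirical per-mode stationary correlators with bootstrap errors."""

    mode_index: np.ndarray
    wavenumbers: np.ndarray
    variance: np.ndarray  # <|eta_k|^2>
    variance_se: np.ndarray
    deriv_corr: np.ndarray  # <eta_dot_k eta_k*> (complex)
    deriv_corr_se: np.ndarray  # SE of (Re, Im) combined in quadrature
    n_blocks: int = 0


def empirical_mode_correlators(
    traj: Trajectory, grid: DiscreteGrid,
    block_steps: int | None = None, slowest_rate: float | None = None,
    n_boot: int = 200,
) -> ModeCorrelatorEstimates:
    """Estimate per-mode stationary correlators from a trajectory.

    Fields are transformed to mode amplitudes ``eta_k = dx * sum_j eta_j
    exp(-i k x_j)``; ``<eta_dot_k eta_k*>`` uses the Stratonovich midpoint
    pairing ``(Delta eta_k / dt) * conj(midpoint)``.  Standard errors come
    from a non-overlapping block bootstrap; pass ``slowest_rate =
    min|Re lambda_k|`` so the block length covers >= 10 relaxation times, or
    set ``block_steps`` directly.
    """
    X = traj.fields
    n_frames, n = X.shape
    if n != grid.n_points:
        raise ValueError("trajectory and grid dimensions differ")
    if block_steps is None:
        if slowest_rate is not None:
            block_steps = max(int(np.ceil(10.0 / (slowest_rate * traj.dt))), 100)
        else:
            block_steps = max((n_frames - 1) // 50, 100)
    n_incr = n_frames - 1
    n_blocks = n_incr // block_steps
    if n_blocks < 20:
        raise ValueError(
            f"trajectory too short: {n_blocks} blocks of {block_steps} steps "
            "(need >= 20)"
        )
    m, k = _mode_grid(n, grid.length)
    order = np.argsort(m)
    # eta_k(t) for all frames: dx * FFT along space
    modes = grid.spacing * np.fft.fft(X, axis=1)
    d = (modes[1:] - modes[:-1]) / traj.dt
    mid = 0.5 * (modes[1:] + modes[:-1])
    var_samples = np.abs(modes[:-1]) ** 2
    dc_samples = d * np.conj(mid)

    used = n_blocks * block_steps
    vb = var_samples[:used].reshape(n_blocks, block_steps, n).mean(axis=1)
    db = dc_samples[:used].reshape(n_blocks, block_steps, n).mean(axis=1)
    variance = vb.mean(axis=0)
    deriv = db.mean(axis=0)

    rng = np.random.default_rng(traj.seed + 0x5EED)
    idx = rng.integers(0, n_blocks, size=(n_boot, n_blocks))
    v_boot = vb[idx].mean(axis=1)  # (n_boot, n)
    d_boot = db[idx].mean(axis=1)
    variance_se = v_boot.std(axis=0, ddof=1)
    deriv_se = np.sqrt(
        d_boot.real.std(axis=0, ddof=1) ** 2 + d_boot.imag.std(axis=0, ddof=1) ** 2
    )
    return ModeCorrelatorEstimates(
        mode_index=m[order], wavenumbers=k[order],
        variance=variance[order].real, variance_se=variance_se[order],
        deriv_corr=deriv[order], deriv_corr_se=deriv_se[order],
        n_blocks=n_blocks,
    )
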