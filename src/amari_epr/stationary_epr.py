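"""Stationary covariance, analytic entropy production and equilibrium checks.

For the stable linear Langevin system ``eta_dot = Lambda eta + xi`` with
``<xi xi'> = Gamma delta(t - t')`` the stationary covariance ``C`` solves the
Lyapunov equation ``Lambda C + C Lambdaᵀ = -Gamma``.  The stationary entropy
production rate has the closed form

    sigma = Tr[(Lambdaᵀ Gamma⁻¹ - Gamma⁻¹ Lambda) Lambda C]

which vanishes iff the detailed-balance condition ``Lambda Gamma = Gamma
Lambdaᵀ`` holds, i.e. iff ``h = Lambda Gamma`` is symmetric.  The equivalent
form ``Tr[2 Lambdaᵀ Gamma⁻¹ Lambda C + Lambda]`` is computed alongside as an
internal consistency check.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .field_model import StabilityError

__all__ = [
    "StationaryState",
    "EquilibriumReport",
    "solve_lyapunov",
    "entropy_production_trace",
    "equilibrium_check",
    "gaussian_shannon_entropy",
]


@dataclass(frozen=True)
class StationaryState:
    """Stationary Gaussian state: covariance, precision, Lyapunov residual."""

    covariance: np.ndarray = field(repr=False)
    precision: np.ndarray = field(repr=False)
    lyapunov_residual: float = 0.0


def _as_square(a, name) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"{name} must be a square matrix")
    return a


def _require_stable(drift: np.ndarray) -> None:
    eigs = linalg.eigvals(drift)
    worst = eigs[np.argmax(eigs.real)]
    if worst.real >= -1e-10:
        raise StabilityError(f"drift not strictly stable (eigenvalue {worst})")


def solve_lyapunov(drift: np.ndarray, noise_cov: np.ndarray) -> StationaryState:
    """Solve ``Lambda C + C Lambdaᵀ = -Gamma`` for the stationary covariance.

    The Bartels-Stewart solution is symmetrized, its residual recorded, and
    the precision ``C⁻¹`` computed by Cholesky-based solves.
    """
    L = _as_square(drift, "drift")
    G = _as_square(noise_cov, "noise_cov")
    if L.shape != G.shape:
        raise ValueError("drift and noise_cov dimensions differ")
    _require_stable(L)
    C = linalg.solve_continuous_lyapunov(L, -G)
    C = 0.5 * (C + C.T)
    resid = float(np.linalg.norm(L @ C + C @ L.T + G, "fro"))
    g_norm = float(np.linalg.norm(G, "fro"))
    if resid > 1e-10 * g_norm:
        raise RuntimeError(
            f"Lyapunov residual {resid:g} exceeds 1e-10 * ||Gamma|| = {1e-10 * g_norm:g}"
        )
    cf = linalg.cho_factor(C, lower=True)
    precision = linalg.cho_solve(cf, np.eye(C.shape[0]))
    precision = 0.5 * (precision + precision.T)
    return StationaryState(covariance=C, precision=precision,
                           lyapunov_residual=resid)


def entropy_production_trace(
    drift: np.ndarray, noise_cov: np.ndarray, state: StationaryState | None = None
) -> float:
    """Analytic stationary entropy production rate.

    Evaluates ``Tr[(Lambdaᵀ Gamma⁻¹ - Gamma⁻¹ Lambda) Lambda C]`` with
    ``Gamma⁻¹`` applied through Cholesky solves, and cross-checks against the
    algebraically equivalent ``Tr[2 Lambdaᵀ Gamma⁻¹ Lambda C + Lambda]``.
    Independent of the overall noise amplitude (C scales with Gamma,
    Gamma⁻¹ inversely).
    """
    L = _as_square(drift, "drift")
    G = _as_square(noise_cov, "noise_cov")
    if state is None:
        state = solve_lyapunov(L, G)
    C = state.covariance
    if C.shape != L.shape:
        raise ValueError("state dimension does not match drift")
    gf = linalg.cho_factor(0.5 * (G + G.T), lower=True)
    ginv_L = linalg.cho_solve(gf, L)  # Gamma^{-1} Lambda
    LC = L @ C
    # Tr[Lambdaᵀ Gamma⁻¹ Lambda C] = sum((Gamma⁻¹Lambda) * (Lambda C)), as
    # Tr[Aᵀ B] with A = Gamma⁻¹Lambda (Gamma⁻¹ symmetric)
    t1 = float(np.sum(ginv_L * LC))
    t2 = float(np.trace(ginv_L @ LC))  # Tr[Gamma⁻¹ Lambda Lambda C]
    sigma = t1 - t2
    form1 = 2.0 * t1 + float(np.trace(L))
    scale = 1.0 + abs(t1) + abs(float(np.trace(L)))
    if abs(sigma - form1) > 1e-8 * scale:
        raise RuntimeError(
            f"entropy-production forms disagree: {sigma:g} vs {form1:g}"
        )
    return sigma


@dataclass(frozen=True)
class EquilibriumReport:
    """Detailed-balance diagnostics for a (drift, noise) pair."""

    h_matrix: np.ndarray = field(repr=False)
    asymmetry_norm: float = 0.0
    is_equilibrium: bool = False
    sigma_analytic: float = 0.0


def equilibrium_check(
    drift: np.ndarray, noise_cov: np.ndarray, tolerance: float = 1e-8
) -> EquilibriumReport:
    """Check the generalized detailed-balance condition ``Lambda Gamma = Gamma Lambdaᵀ``.

    Computes ``h = Lambda Gamma`` (discrete form of ``h(x,y) = integral
    lambda(x,z) gamma(z,y) dz``), its relative asymmetry
    ``||h - hᵀ||_F / ||h||_F``, and the analytic sigma.  Symmetric h is
    equivalent to zero entropy production; for space-time white noise it
    reduces to symmetry of the synaptic kernel.
    """
    L = _as_square(drift, "drift")
    G = _as_square(noise_cov, "noise_cov")
    h = L @ G
    h_norm = np.linalg.norm(h, "fro")
    asym = float(np.linalg.norm(h - h.T, "fro") / h_norm) if h_norm > 0 else 0.0
    sigma = entropy_production_trace(L, G)
    return EquilibriumReport(
        h_matrix=h, asymmetry_norm=asym,
        is_equilibrium=bool(asym <= tolerance), sigma_analytic=sigma,
    )


def gaussian_shannon_entropy(state: StationaryState) -> float:
    """Differential entropy ``(1/2) log det(2 pi e C)`` of the stationary Gaussian."""
    C = state.covariance
    sign, logdet = np.linalg.slogdet(C)
    if sign <= 0:
        raise ValueError("covariance must be positive definite")
    n = C.shape[0]
    return 0.5 * (n * np.log(2.0 * np.pi * np.e) + logdet)
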