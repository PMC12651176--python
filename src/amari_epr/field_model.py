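"""Discretized linearized Amari neural field model.

The Amari equation describes a coarse-grained neural activity field
``u(x, t)`` on a spatial domain through a leak term ``-u/tau`` and synaptic
input ``(1/tau) * integral w(x, y) f[u(y)] dy``, with a sigmoid firing-rate
function ``f``.  Around a homogeneous fixed point ``u0`` the fluctuations
``eta = u - u0`` obey the linear Langevin equation ``eta_dot = Lambda eta + xi``
where ``Lambda`` has kernel ``lambda(x, y) = -delta(x - y)/tau +
f'[u0] w(x, y)/tau``.

Discretization contract (used consistently across the package): the domain is
a periodic 1-D ring sampled at ``n`` points with spacing ``dx``; integral
operators become matrices that act on field vectors directly, i.e. the smooth
part of a kernel carries a quadrature weight ``dx`` while a Dirac delta maps
to ``delta_ij / dx`` (so the delta in ``lambda`` contributes ``-1/tau`` on the
diagonal with no ``dx`` factor).  Covariance matrices (noise ``Gamma``,
stationary ``C``) hold plain kernel values at the grid points; with these
conventions the Lyapunov equation, the entropy-production trace formula and
the Onsager-Machlup action are all plain matrix algebra with no stray ``dx``
factors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize

__all__ = [
    "DiscreteGrid",
    "SigmoidActivation",
    "NeuralFieldModel",
    "NoiseModel",
    "StabilityError",
    "sigmoid_activation",
    "activation_gain",
    "solve_homogeneous_fixed_point",
    "build_linear_operator",
    "build_model",
    "model_from_drift",
    "potential_energy",
]

#: strict-stability margin: all drift eigenvalues must satisfy Re < -STABILITY_TOL
STABILITY_TOL = 1e-10


class StabilityError(ValueError):
    """Raised when a drift operator is not strictly stable."""


@dataclass(frozen=True)
class DiscreteGrid:
    """Periodic 1-D lattice: ``n_points`` sites on a ring of length ``length``."""

    n_points: int
    length: float

    def __post_init__(self) -> None:
        if self.n_points <= 0:
            raise ValueError("n_points must be positive")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def spacing(self) -> float:
        return self.length / self.n_points

    @property
    def positions(self) -> np.ndarray:
        return self.spacing * np.arange(self.n_points)

    def min_image(self, d: np.ndarray) -> np.ndarray:
        """Signed minimum-image displacement on the ring, in [-L/2, L/2)."""
        L = self.length
        return (np.asarray(d) + L / 2) % L - L / 2


@dataclass(frozen=True)
class SigmoidActivation:
    """Sigmoid firing-rate function ``f[u] = 1 / (exp(beta (u_star - u)) + 1)``."""

    gain: float  # beta > 0
    threshold: float  # u* > 0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("sigmoid gain beta must be > 0")
        if self.threshold <= 0:
            raise ValueError("sigmoid threshold u* must be > 0")


def sigmoid_activation(u, act: SigmoidActivation):
    """Evaluate the sigmoid ``f[u]``; stable for large ``|beta (u* - u)|``."""
    z = act.gain * (act.threshold - np.asarray(u, dtype=float))
    # exp(-|z|) never overflows; the two branches are algebraically identical
    ez = np.exp(-np.abs(z))
    out = np.where(z >= 0, ez / (1.0 + ez), 1.0 / (1.0 + ez))
    return out if out.ndim else float(out)


def activation_gain(u, act: SigmoidActivation):
    """Slope ``f'[u] = beta f (1 - f)``; strictly positive, maximal at u = u*."""
    f = sigmoid_activation(u, act)
    return act.gain * f * (1.0 - f)


def solve_homogeneous_fixed_point(
    row_integral: float, act: SigmoidActivation
) -> list[tuple[float, bool]]:
    """All homogeneous fixed points ``u0`` solving ``u0 = w_tilde f[u0]``.

    Roots are located by sign-change scanning of ``g(u) = w_tilde f[u] - u`` on
    the analytically safe bracket ``[min(0, w) - 1, max(0, w) + 1]`` (since
    0 < f < 1 confines u0 between 0 and w_tilde), then polished with Brent's
    method.  Each root carries a stability flag for the homogeneous ODE:
    ``-1 + w_tilde f'[u0] < 0``.
    """
    w = float(row_integral)
    if not np.isfinite(w):
        raise ValueError("row_integral must be finite")
    if w == 0.0:
        return [(0.0, True)]

    def g(u):
        return w * sigmoid_activation(u, act) - u

    lo, hi = min(0.0, w) - 1.0, max(0.0, w) + 1.0
    grid = np.linspace(lo, hi, 4001)
    vals = g(grid)
    roots: list[float] = []
    for i in range(len(grid) - 1):
        a, b = vals[i], vals[i + 1]
        if a == 0.0:
            roots.append(float(grid[i]))
        elif a * b < 0:
            roots.append(float(optimize.brentq(g, grid[i], grid[i + 1],
                                               xtol=1e-14, rtol=8.9e-16)))
    if vals[-1] == 0.0:
        roots.append(float(grid[-1]))
    # dedupe near-identical roots from grid-point hits
    uniq: list[float] = []
    for r in sorted(roots):
        if not uniq or abs(r - uniq[-1]) > 1e-9:
            uniq.append(r)
    if not uniq:
        warnings.warn("no homogeneous fixed point found in bracket", stacklevel=2)
        return []
    return [(r, bool(-1.0 + w * activation_gain(r, act) < 0)) for r in uniq]


def _check_stable(mat: np.ndarray) -> np.ndarray:
    eigs = linalg.eigvals(mat)
    worst = eigs[np.argmax(eigs.real)]
    if worst.real >= -STABILITY_TOL:
        raise StabilityError(
            f"drift operator not strictly stable: eigenvalue {worst} has "
            f"Re >= -{STABILITY_TOL:g}"
        )
    return eigs


def build_linear_operator(
    grid: DiscreteGrid, tau: float, kernel_matrix: np.ndarray, gain_at_fp: float
) -> np.ndarray:
    """Matrix form of the linearized drift ``Lambda``.

    ``Lambda[i, j] = -delta_ij / tau + (gain_at_fp / tau) * w[i, j] * dx``;
    the Dirac delta contributes ``-1/tau`` on the diagonal with no quadrature
    weight, the smooth synaptic kernel carries ``dx``.
    """
    W = np.asarray(kernel_matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("kernel_matrix must be square")
    if W.shape[0] != grid.n_points:
        raise ValueError("kernel_matrix not conformable with grid")
    if tau <= 0:
        raise ValueError("tau must be positive")
    lam = (gain_at_fp / tau) * W * grid.spacing
    lam[np.diag_indices_from(lam)] -= 1.0 / tau
    _check_stable(lam)
    return lam


@dataclass(frozen=True)
class NeuralFieldModel:
    """Linearized stochastic Amari model on a periodic grid.

    Holds the ingredients of the drift operator: relaxation time ``tau``, the
    synaptic kernel matrix ``w(x_i, x_j)``, the homogeneous fixed point ``u0``
    with the sigmoid slope there, and the assembled drift matrix ``Lambda``.
    """

    grid: DiscreteGrid
    tau: float
    activation: SigmoidActivation
    kernel_matrix: np.ndarray
    row_integral: float
    fixed_point: float
    gain_at_fp: float
    drift_matrix: np.ndarray = field(repr=False)

    @property
    def drift_eigenvalues(self) -> np.ndarray:
        return linalg.eigvals(self.drift_matrix)


def build_model(
    grid: DiscreteGrid,
    tau: float,
    act: SigmoidActivation,
    kernel_matrix: np.ndarray,
    fixed_point_selector: str | int | float = "largest_stable",
) -> NeuralFieldModel:
    """Assemble a :class:`NeuralFieldModel` from its nonlinear ingredients.

    Requires constant kernel row integrals (a homogeneous fixed point must
    exist).  ``fixed_point_selector`` picks among multiple roots of
    ``u0 = w_tilde f[u0]``: ``"largest_stable"`` (default), an integer index
    into the sorted root list, or a float selecting the root nearest a value.
    """
    W = np.asarray(kernel_matrix, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1] or W.shape[0] != grid.n_points:
        raise ValueError("kernel_matrix must be square and conformable with grid")
    row_sums = W.sum(axis=1) * grid.spacing
    w_tilde = float(row_sums.mean())
    scale = max(1.0, abs(w_tilde))
    if np.max(np.abs(row_sums - w_tilde)) > 1e-8 * scale:
        raise ValueError(
            "no homogeneous fixed point: kernel row integrals are not constant"
        )
    roots = solve_homogeneous_fixed_point(w_tilde, act)
    if not roots:
        raise ValueError("no homogeneous fixed point found")
    u0 = _select_root(roots, fixed_point_selector)
    gain = float(activation_gain(u0, act))
    drift = build_linear_operator(grid, tau, W, gain)
    resid = abs(u0 - w_tilde * sigmoid_activation(u0, act))
    if resid > 1e-12:
        raise ValueError(f"fixed-point residual {resid:g} exceeds 1e-12")
    return NeuralFieldModel(
        grid=grid, tau=tau, activation=act, kernel_matrix=W,
        row_integral=w_tilde, fixed_point=u0, gain_at_fp=gain, drift_matrix=drift,
    )


def _select_root(roots: list[tuple[float, bool]], selector) -> float:
    if selector == "largest_stable":
        stable = [r for r, s in roots if s]
        if not stable:
            raise ValueError("no stable homogeneous fixed point")
        return max(stable)
    if isinstance(selector, bool):
        raise ValueError(f"invalid fixed_point_selector {selector!r}")
    if isinstance(selector, int):
        return sorted(r for r, _ in roots)[selector]
    if isinstance(selector, float):
        return min((r for r, _ in roots), key=lambda r: abs(r - selector))
    raise ValueError(f"invalid fixed_point_selector {selector!r}")


def model_from_drift(
    grid: DiscreteGrid, drift: np.ndarray, tau: float = 1.0
) -> NeuralFieldModel:
    """Wrap an explicit stable drift matrix as a :class:`NeuralFieldModel`.

    Useful for benchmark systems specified directly at the matrix level (the
    rotation drift, random stable drifts).  The synaptic kernel is recovered
    from the operator convention with unit gain: ``W = (Lambda + I/tau) * tau
    / dx``; the fixed point is the origin of the linear fluctuation dynamics.
    """
    L = np.asarray(drift, dtype=float)
    if L.ndim != 2 or L.shape[0] != L.shape[1] or L.shape[0] != grid.n_points:
        raise ValueError("drift must be square and conformable with grid")
    _check_stable(L)
    W = (L + np.eye(grid.n_points) / tau) * tau / grid.spacing
    return NeuralFieldModel(
        grid=grid, tau=tau, activation=SigmoidActivation(1.0, 0.5),
        kernel_matrix=W, row_integral=float(W.sum(axis=1).mean() * grid.spacing),
        fixed_point=0.0, gain_at_fp=1.0, drift_matrix=L,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Spatial noise covariance ``Gamma`` with factor ``B`` s.t. ``B Bᵀ = Gamma``.

    The noise field is white in time with ``<xi(x,t) xi(y,t')> =
    gamma(x,y) delta(t-t')``; ``covariance_matrix`` holds the kernel values
    ``gamma(x_i, x_j)`` (a space-time-white noise ``T delta(x-y)`` therefore
    appears as ``(T/dx) I``).  ``white_amplitude`` records ``T`` when the
    covariance is of that form, else ``None``.
    """

    grid: DiscreteGrid
    covariance_matrix: np.ndarray = field(repr=False)
    factor: np.ndarray = field(repr=False)
    white_amplitude: float | None = None

    def __post_init__(self) -> None:
        G = self.covariance_matrix
        if not np.allclose(G, G.T, rtol=0, atol=1e-12 * max(1.0, np.abs(G).max())):
            raise ValueError("noise covariance must be symmetric")
        # positive definiteness is enforced by the Cholesky in the constructor

    @classmethod
    def from_covariance(
        cls, grid: DiscreteGrid, covariance: np.ndarray,
        white_amplitude: float | None = None,
    ) -> "NoiseModel":
        G = np.asarray(covariance, dtype=float)
        G = 0.5 * (G + G.T)
        try:
            B = linalg.cholesky(G, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError("noise covariance must be positive definite") from exc
        return cls(grid=grid, covariance_matrix=G, factor=B,
                   white_amplitude=white_amplitude)


def potential_energy(model: NeuralFieldModel, eta: np.ndarray) -> float:
    """Quadratic potential ``U[eta] = -(dx^2/2) sum_ij eta_i lambda_ij eta_j``.

    Only defined for self-adjoint drift (symmetric synaptic kernel), where the
    Langevin equation is gradient flow in ``U`` and, with space-time white
    noise of amplitude T, the stationary density is Boltzmann
    ``exp(-U/T)``.  With the operator convention ``Lambda = lambda * dx`` this
    is ``-(dx/2) etaᵀ Lambda eta``; it is >= 0 for stable symmetric drift.
    """
    L = model.drift_matrix
    if not np.allclose(L, L.T, rtol=0, atol=1e-10 * np.abs(L).max()):
        raise ValueError("potential undefined for non-self-adjoint Lambda")
    eta = np.asarray(eta, dtype=float)
    return float(-0.5 * model.grid.spacing * eta @ L @ eta)
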