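"""Parametric synaptic-kernel and noise-covariance families on the ring.

All profiles are evaluated at the minimum-image displacement ``x_i - x_j`` on
the periodic domain, so every generated matrix is circulant (translation
invariant).  A nonzero ``shift`` displaces the Gaussian profile and breaks the
``w(x,y) = w(y,x)`` symmetry — the sole source of irreversibility under
translation invariance — while leaving the row integrals constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .field_model import DiscreteGrid, NoiseModel

__all__ = ["KernelSpec", "NoiseSpec", "build_kernel", "build_noise"]

KERNEL_FAMILIES = (
    "zero", "gaussian", "shifted_gaussian", "mexican_hat", "pure_shift",
    "explicit_matrix",
)
NOISE_FAMILIES = ("white", "gaussian_correlated", "explicit_matrix")


@dataclass(frozen=True)
class KernelSpec:
    """Parametric synaptic kernel.

    families:
      zero              w = 0
      gaussian          amplitude * exp(-d^2 / (2 width^2))
      shifted_gaussian  amplitude * exp(-(d - shift)^2 / (2 width^2))
      mexican_hat       amplitude * (exp(-d^2/(2 w^2)) - ratio * exp(-d^2/(2 (2w)^2)))
      pure_shift        delta-like coupling to the site a distance `shift` away
      explicit_matrix   user-supplied square matrix (validated)

    ``normalization``, when given, rescales so the row integral
    ``dx * sum_j w[i, j]`` equals that target w_tilde.
    """

    family: str
    amplitude: float = 1.0
    width: float = 1.0
    shift: float = 0.0
    ratio: float = 0.5
    normalization: float | None = None
    matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in KERNEL_FAMILIES:
            raise ValueError(f"unknown kernel family {self.family!r}")
        if self.family not in ("zero", "explicit_matrix", "pure_shift") and self.width <= 0:
            raise ValueError("kernel width must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Noise covariance family.

    white:               gamma(x,y) = T delta(x-y), realized as (T/dx) I
    gaussian_correlated: circulant squared-exponential profile, amplitude T,
                         correlation length ell (diagonal jitter <= 1e-10 T
                         enforces positive definiteness)
    explicit_matrix:     user-supplied symmetric positive-definite matrix
    """

    family: str
    amplitude: float = 1.0  # T
    correlation_length: float = 1.0  # ell_gamma
    matrix: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.family not in NOISE_FAMILIES:
            raise ValueError(f"unknown noise family {self.family!r}")
        if self.amplitude <= 0:
            raise ValueError("noise amplitude T must be positive")


def _circulant_from_profile(grid: DiscreteGrid, profile_fn) -> np.ndarray:
    x = grid.positions
    d = grid.min_image(x[:, None] - x[None, :])
    return profile_fn(d)


def build_kernel(spec: KernelSpec, grid: DiscreteGrid) -> np.ndarray:
    """Materialize the kernel matrix ``w(x_i, x_j)`` for a spec."""
    n = grid.n_points
    if spec.family == "zero":
        W = np.zeros((n, n))
    elif spec.family == "gaussian":
        W = _circulant_from_profile(
            grid, lambda d: spec.amplitude * np.exp(-d**2 / (2 * spec.width**2)))
    elif spec.family == "shifted_gaussian":
        W = _circulant_from_profile(
            grid,
            lambda d: spec.amplitude
            * np.exp(-grid.min_image(d - spec.shift) ** 2 / (2 * spec.width**2)),
        )
    elif spec.family == "mexican_hat":
        W = _circulant_from_profile(
            grid,
            lambda d: spec.amplitude
            * (np.exp(-d**2 / (2 * spec.width**2))
               - spec.ratio * np.exp(-d**2 / (8 * spec.width**2))),
        )
    elif spec.family == "pure_shift":
        # couples site i to site i - shift/dx (delta kernel carries 1/dx)
        k = int(round(spec.shift / grid.spacing)) % n
        W = spec.amplitude / grid.spacing * np.roll(np.eye(n), -k, axis=1)
    elif spec.family == "explicit_matrix":
        if spec.matrix is None:
            raise ValueError("explicit_matrix kernel requires a matrix")
        W = np.asarray(spec.matrix, dtype=float)
        if W.shape != (n, n):
            raise ValueError("explicit kernel matrix not conformable with grid")
    else:  # pragma: no cover
        raise ValueError(spec.family)
    if spec.normalization is not None and spec.family != "zero":
        row = W.sum(axis=1).mean() * grid.spacing
        if row == 0:
            raise ValueError("cannot normalize a kernel with zero row integral")
        W = W * (spec.normalization / row)
    return W


def build_noise(spec: NoiseSpec, grid: DiscreteGrid) -> NoiseModel:
    """Materialize a :class:`NoiseModel` (covariance + Cholesky factor)."""
    n = grid.n_points
    if spec.family == "white":
        G = (spec.amplitude / grid.spacing) * np.eye(n)
        return NoiseModel.from_covariance(grid, G, white_amplitude=spec.amplitude)
    if spec.family == "gaussian_correlated":
        ell = spec.correlation_length
        if ell <= 0:
            raise ValueError("correlation length must be positive")

        # wrapped Gaussian: summing over periodic images keeps the profile
        # positive definite on the ring (plain truncation does not)
        def wrapped(d):
            return spec.amplitude * sum(
                np.exp(-((d + m * grid.length) ** 2) / (2 * ell**2))
                for m in range(-5, 6)
            )

        G = _circulant_from_profile(grid, wrapped)
        G = G + 1e-10 * spec.amplitude * np.eye(n)
        return NoiseModel.from_covariance(grid, G)
    if spec.family == "explicit_matrix":
        if spec.matrix is None:
            raise ValueError("explicit_matrix noise requires a matrix")
        G = np.asarray(spec.matrix, dtype=float)
        if G.shape != (n, n):
            raise ValueError("explicit noise matrix not conformable with grid")
        return NoiseModel.from_covariance(grid, G)
    raise ValueError(spec.family)  # pragma: no cover
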