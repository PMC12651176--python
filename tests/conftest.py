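import numpy as np
import pytest

from amari_epr import (
    DiscreteGrid,
    KernelSpec,
    NoiseModel,
    NoiseSpec,
    SigmoidActivation,
    build_kernel,
    build_model,
    build_noise,
    model_from_drift,
)


@pytest.fixture(scope="session")
def grid():
    return DiscreteGrid(n_points=32, length=10.0)


@pytest.fixture(scope="session")
def sigmoid():
    return SigmoidActivation(gain=2.0, threshold=0.5)


@pytest.fixture(scope="session")
def sym_model(grid, sigmoid):
    """Even Gaussian kernel, w_tilde = 1: self-adjoint drift (equilibrium)."""
    W = build_kernel(KernelSpec("gaussian", width=1.0, normalization=1.0), grid)
    return build_model(grid, 1.0, sigmoid, W)


@pytest.fixture(scope="session")
def asym_model(grid, sigmoid):
    """Shifted Gaussian kernel: asymmetric circulant drift (nonequilibrium)."""
    W = build_kernel(
        KernelSpec("shifted_gaussian", width=1.0, shift=grid.length / 8,
                   normalization=1.0),
        grid,
    )
    return build_model(grid, 1.0, sigmoid, W)


@pytest.fixture(scope="session")
def white_noise(grid):
    return build_noise(NoiseSpec("white", amplitude=1.0), grid)


@pytest.fixture(scope="session")
def rotation_system():
    """Rotation drift -aI + bJ (a = b = 1), identity noise: sigma = 2b^2/a = 2."""
    grid2 = DiscreteGrid(n_points=2, length=2.0)  # dx = 1: matrices pass through
    L = np.array([[-1.0, -1.0], [1.0, -1.0]])
    model = model_from_drift(grid2, L)
    noise = NoiseModel.from_covariance(grid2, np.eye(2))
    return model, noise


def random_stable_system(rng, n, correlated_noise=False):
    """Random strictly stable drift plus symmetric PD noise covariance."""
    A = rng.standard_normal((n, n))
    shift = max(np.linalg.eigvals(A).real.max(), 0.0) + 0.5 + rng.uniform(0, 1)
    L = A - shift * np.eye(n)
    if correlated_noise:
        B = rng.standard_normal((n, n))
        G = B @ B.T + n * np.eye(n)
    else:
        G = np.eye(n)
    return L, G


def random_stable_circulant(rng, n):
    """Random circulant strictly stable drift (translation-invariant system)."""
    from scipy.linalg import circulant

    prof = rng.standard_normal(n)
    M = circulant(prof)
    shift = np.linalg.eigvals(M).real.max() + 0.5 + rng.uniform(0, 1)
    return M - shift * np.eye(n)
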