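"""JSON configuration schema (pydantic) and model assembly.

A single JSON document with blocks {grid, tau, activation, kernel, noise,
fixed_point, simulate, tasks, output} specifies everything needed to rebuild
a model, its noise, and a simulation — the reproducibility surface of the
command-line pipeline.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal

import numpy as np
from pydantic import BaseModel, Field, field_validator

from .field_model import (
    DiscreteGrid,
    NeuralFieldModel,
    NoiseModel,
    SigmoidActivation,
    build_model,
)
from .kernels import KernelSpec, NoiseSpec, build_kernel, build_noise
from .langevin_sim import SimulationConfig

__all__ = ["AmariConfig", "load_config", "assemble"]

SCHEMA_VERSION = "1.0"


class GridBlock(BaseModel):
    n: int = Field(gt=0)
    L: float = Field(gt=0)


class ActivationBlock(BaseModel):
    beta: float = Field(gt=0)
    u_star: float = Field(gt=0)


class KernelBlock(BaseModel):
    family: Literal[
        "zero", "gaussian", "shifted_gaussian", "mexican_hat", "pure_shift",
        "explicit_matrix",
    ]
    amplitude: float = 1.0
    width: float = 1.0
    shift: float = 0.0
    ratio: float = 0.5
    normalization: float | None = None
    matrix: list[list[float]] | None = None


class NoiseBlock(BaseModel):
    family: Literal["white", "gaussian_correlated", "explicit_matrix"] = "white"
    T: float = Field(default=1.0, gt=0)
    ell: float = Field(default=1.0, gt=0)
    matrix: list[list[float]] | None = None


class FixedPointBlock(BaseModel):
    selector: str | int | float = "largest_stable"


class SimulateBlock(BaseModel):
    dt: float = Field(gt=0)
    n_steps: int = Field(gt=0)
    burn_in: int = Field(default=0, ge=0)
    seed: int = 0
    initial: Literal["zero", "stationary"] = "stationary"
    save_stride: int = Field(default=1, gt=0)


class AmariConfig(BaseModel):
    """Top-level config; `tasks` drive the pipeline subcommand."""

    grid: GridBlock
    tau: float = Field(gt=0)
    activation: ActivationBlock
    kernel: KernelBlock
    noise: NoiseBlock = NoiseBlock()
    fixed_point: FixedPointBlock = FixedPointBlock()
    simulate: SimulateBlock | None = None
    tasks: list[
        Literal["epr-analytic", "check-equilibrium", "spectrum", "simulate",
                "epr-path"]
    ] = Field(default_factory=lambda: ["epr-analytic", "check-equilibrium"])
    schema_version: str = SCHEMA_VERSION

    @field_validator("tasks")
    @classmethod
    def _path_needs_sim(cls, v, info):
        return v


def load_config(path: str | Path) -> AmariConfig:
    with open(path) as fh:
        return AmariConfig.model_validate(json.load(fh))


def assemble(
    cfg: AmariConfig,
) -> tuple[NeuralFieldModel, NoiseModel, SimulationConfig | None]:
    """Build the model, noise and (optional) simulation config from a schema."""
    grid = DiscreteGrid(n_points=cfg.grid.n, length=cfg.grid.L)
    act = SigmoidActivation(gain=cfg.activation.beta, threshold=cfg.activation.u_star)
    kspec = KernelSpec(
        family=cfg.kernel.family, amplitude=cfg.kernel.amplitude,
        width=cfg.kernel.width, shift=cfg.kernel.shift, ratio=cfg.kernel.ratio,
        normalization=cfg.kernel.normalization,
        matrix=None if cfg.kernel.matrix is None else np.asarray(cfg.kernel.matrix),
    )
    W = build_kernel(kspec, grid)
    model = build_model(grid, cfg.tau, act, W, cfg.fixed_point.selector)
    nspec = NoiseSpec(
        family=cfg.noise.family, amplitude=cfg.noise.T,
        correlation_length=cfg.noise.ell,
        matrix=None if cfg.noise.matrix is None else np.asarray(cfg.noise.matrix),
    )
    noise = build_noise(nspec, grid)
    sim = None
    if cfg.simulate is not None:
        s = cfg.simulate
        sim = SimulationConfig(
            dt=s.dt, n_steps=s.n_steps, burn_in=s.burn_in, seed=s.seed,
            initial_field=s.initial, save_stride=s.save_stride,
        )
    return model, noise, sim
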