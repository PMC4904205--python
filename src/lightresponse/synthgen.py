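"""Synthetic light-response curves with known ground truth.

Emulates a realistic gas-exchange measurement campaign: a model family, a
plausible parameter vector, an increasing irradiance ladder starting at
darkness, and additive homoscedastic Gaussian noise (the simplest error
structure consistent with ordinary least-squares fitting).  Ground-truth
parameters travel with every generated curve so that parameter-recovery
experiments are well-posed.

Parameter sub-ranges are deliberately narrower than the optimizer's [0,1] /
[0,100] search box: the box is a bound for optimization, not a realistic
species distribution.  The defaults (quantum efficiency 0.02-0.09, Amax
3-35 µmol m-2 s-1, dark respiration 0.2-3 µmol m-2 s-1, noise sd 0.1-0.5
µmol m-2 s-1) span herbaceous through woody plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .models import ModelSpec, get_model, MODEL_NAMES
from .pipeline import LightResponseDataset

__all__ = [
    "DEFAULT_GRID",
    "PLAUSIBLE_RANGES",
    "ScenarioConfig",
    "SyntheticCurve",
    "generate_curve",
    "generate_suite",
]

#: Standard 13-step irradiance ladder (µmol photons m-2 s-1), darkness first.
DEFAULT_GRID = np.array(
    [0, 20, 50, 100, 200, 400, 600, 800, 1000, 1200, 1400, 1700, 2000], dtype=float
)

#: Plausible generating sub-ranges per parameter (narrower than the search box).
PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "a": (0.02, 0.09),
    "amax": (3.0, 35.0),
    "rd": (0.2, 3.0),
    "theta": (0.2, 0.95),
    "beta": (0.0, 0.001),
    "gamma": (0.0, 0.01),
}

#: Noise standard deviation drawn per curve (µmol m-2 s-1).
NOISE_SD_RANGE = (0.1, 0.5)


@dataclass(frozen=True)
class ScenarioConfig:
    """One generating scenario: model, true parameters, grid, noise, seed."""

    model: str
    params: tuple[float, ...]
    irradiance_grid: np.ndarray = field(default_factory=lambda: DEFAULT_GRID.copy())
    noise_sd: float = 0.0
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        grid = np.asarray(self.irradiance_grid, dtype=float).ravel()
        object.__setattr__(self, "irradiance_grid", grid)
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise ValueError("irradiance grid must start at 0 and be strictly increasing")
        spec = get_model(self.model)
        if len(self.params) != spec.n_params:
            raise ValueError(f"{self.model} needs {spec.n_params} parameters")
        for value, (lo, hi) in zip(self.params, spec.default_bounds):
            if not lo <= value <= hi:
                raise ValueError(
                    f"generating parameter {value} outside the {self.model} "
                    f"search bounds [{lo}, {hi}]"
                )


@dataclass(frozen=True)
class SyntheticCurve:
    """A generated dataset together with its generating truth."""

    dataset: LightResponseDataset
    model: str
    true_params: tuple[float, ...]
    noise_sd: float


def generate_curve(config: ScenarioConfig) -> list[SyntheticCurve]:
    """Generate ``n_replicates`` noisy curves from one scenario.

    ``a_net = model.predict(true_params, grid) + N(0, noise_sd^2)`` per
    point, with an independent noise draw per replicate; identical seeds
    give identical data.
    """
    spec = get_model(config.model)
    clean = spec.predict(config.params, config.irradiance_grid)
    rng = np.random.default_rng(config.seed)
    curves = []
    for rep in range(config.n_replicates):
        noise = rng.normal(0.0, config.noise_sd, size=clean.size) if config.noise_sd > 0 else 0.0
        ds = LightResponseDataset(
            species_id=f"sim_{config.model}_{config.seed}",
            replicate_id=str(rep + 1),
            irradiance=config.irradiance_grid,
            a_net=clean + noise,
        )
        curves.append(
            SyntheticCurve(dataset=ds, model=config.model, true_params=config.params,
                           noise_sd=config.noise_sd)
        )
    return curves


def _draw_params(model: ModelSpec, rng: np.random.Generator) -> tuple[float, ...]:
    vals = []
    for name in model.param_names:
        lo, hi = PLAUSIBLE_RANGES[name]
        vals.append(float(lo + rng.random() * (hi - lo)))
    return tuple(vals)


def generate_suite(
    n_datasets: int = 42,
    seed: int = 0,
    noise_sd: Optional[float] = None,
    irradiance_grid: Optional[Sequence[float]] = None,
    models: Sequence[str] = MODEL_NAMES,
) -> list[SyntheticCurve]:
    """A campaign-sized collection of curves with stored ground truth.

    Cycles through the four generating model families, draws each curve's
    parameters from the plausible sub-ranges and (unless ``noise_sd`` is
    fixed) its noise level uniformly from 0.1-0.5 µmol m-2 s-1.  The default
    size (42) mirrors a typical multi-species campaign of two replicates for
    each of 21 species.
    """
    if n_datasets < 1:
        raise ValueError("n_datasets must be >= 1")
    grid = DEFAULT_GRID if irradiance_grid is None else np.asarray(irradiance_grid, dtype=float)
    rng = np.random.default_rng(seed)
    curves: list[SyntheticCurve] = []
    for i in range(n_datasets):
        model_name = models[i % len(models)]
        spec = get_model(model_name)
        params = _draw_params(spec, rng)
        sd = noise_sd if noise_sd is not None else float(
            NOISE_SD_RANGE[0] + rng.random() * (NOISE_SD_RANGE[1] - NOISE_SD_RANGE[0])
        )
        clean = spec.predict(params, grid)
        noise = rng.normal(0.0, sd, size=grid.size) if sd > 0 else np.zeros(grid.size)
        ds = LightResponseDataset(
            species_id=f"sim{i + 1:02d}_{model_name}",
            replicate_id="1",
            irradiance=grid,
            a_net=clean + noise,
        )
        curves.append(SyntheticCurve(dataset=ds, model=model_name, true_params=params, noise_sd=sd))
    return curves
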