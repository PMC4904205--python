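"""Photosynthetic light-response models.

Four classical models of net photosynthetic rate ``A_n`` (µmol CO2 m-2 s-1)
as a function of irradiance ``I`` (µmol photons m-2 s-1):

* ``exponential``            A_n = Amax * (1 - exp(-a*I/Amax)) - Rd
* ``rectangular``            A_n = a*I*Amax / (a*I + Amax) - Rd
* ``nonrectangular``         A_n = [a*I + Amax - sqrt((a*I+Amax)^2 - 4*theta*a*I*Amax)] / (2*theta) - Rd
* ``modified_rectangular``   A_n = a*I*(1 - beta*I) / (1 + gamma*I) - Rd

Common parameters: ``a`` is the initial quantum efficiency (the initial slope
of the curve, µmol CO2 per µmol photons), ``Amax`` the net light-saturated
photosynthetic rate, and ``Rd`` the dark respiration rate; all four models
predict ``A_n = -Rd`` at ``I = 0``.  ``theta`` in [0, 1] is the curvature of
the nonrectangular hyperbola: theta -> 0 recovers the rectangular hyperbola
and theta = 1 gives the Blackman broken-stick response ``min(a*I, Amax) - Rd``.
``beta`` and ``gamma`` are dimensionless shape constants of the modified
rectangular hyperbola, which unlike the other three models can bend downward
at high irradiance (photoinhibition).

Units are documented, not enforced: datasets from different instruments and
digitized figures mix sources, so the functions only require consistency
between the fitted data and the reported parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "InvalidParameterError",
    "ModelSpec",
    "MODEL_NAMES",
    "get_model",
    "predict_exponential",
    "predict_rectangular",
    "predict_nonrectangular",
    "predict_modified_rectangular",
    "THETA_LIMIT_THRESHOLD",
]

#: Below this curvature the nonrectangular hyperbola is evaluated through its
#: analytic theta -> 0 limit (the rectangular hyperbola); the 2*theta
#: denominator otherwise divides by ~0.
THETA_LIMIT_THRESHOLD = 1e-8


class InvalidParameterError(ValueError):
    """Raised when a parameter vector makes a model prediction undefined."""


def _check_finite(params: np.ndarray) -> None:
    if not np.all(np.isfinite(params)):
        raise InvalidParameterError(f"non-finite parameters: {params!r}")


def _as_params(params: Sequence[float], n: int) -> np.ndarray:
    p = np.asarray(params, dtype=float).ravel()
    if p.size != n:
        raise InvalidParameterError(f"expected {n} parameters, got {p.size}")
    _check_finite(p)
    return p


def predict_exponential(params: Sequence[float], irradiance) -> np.ndarray:
    """Exponential model, parameters ``(a, Amax, Rd)``.

    ``Amax = 0`` is handled as the limit ``A_n = -Rd``.
    """
    a, amax, rd = _as_params(params, 3)
    I = np.asarray(irradiance, dtype=float)
    if amax == 0.0:
        return np.full_like(I, -rd)
    with np.errstate(over="ignore"):  # extreme a/Amax ratios -> inf, callers reject
        return amax * (1.0 - np.exp(-a * I / amax)) - rd


def predict_rectangular(params: Sequence[float], irradiance) -> np.ndarray:
    """Rectangular hyperbola, parameters ``(a, Amax, Rd)``.

    Requires ``a*I + Amax > 0`` elementwise (the hyperbola's denominator).
    """
    a, amax, rd = _as_params(params, 3)
    I = np.asarray(irradiance, dtype=float)
    denom = a * I + amax
    if np.any(denom <= 0.0):
        raise InvalidParameterError(
            f"rectangular hyperbola denominator a*I + Amax <= 0 (a={a}, Amax={amax})"
        )
    return a * I * amax / denom - rd


def predict_nonrectangular(params: Sequence[float], irradiance) -> np.ndarray:
    """Nonrectangular hyperbola, parameters ``(theta, a, Amax, Rd)``.

    Lower root of ``theta*A^2 - (a*I + Amax)*A + a*I*Amax = 0``, shifted by
    ``-Rd``.  For ``theta < THETA_LIMIT_THRESHOLD`` the analytic limit (the
    rectangular hyperbola) is used, keeping the prediction continuous in
    theta.  The discriminant is clipped at zero to absorb rounding when
    ``theta`` is exactly 1 and ``a*I = Amax``.
    """
    theta, a, amax, rd = _as_params(params, 4)
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"curvature theta={theta} outside [0, 1]")
    I = np.asarray(irradiance, dtype=float)
    if theta < THETA_LIMIT_THRESHOLD:
        return predict_rectangular((a, amax, rd), I)
    s = a * I + amax
    disc = s * s - 4.0 * theta * a * I * amax
    return (s - np.sqrt(np.clip(disc, 0.0, None))) / (2.0 * theta) - rd


def predict_modified_rectangular(params: Sequence[float], irradiance) -> np.ndarray:
    """Modified rectangular hyperbola, parameters ``(a, beta, gamma, Rd)``.

    Requires ``1 + gamma*I > 0`` elementwise.
    """
    a, beta, gamma, rd = _as_params(params, 4)
    I = np.asarray(irradiance, dtype=float)
    denom = 1.0 + gamma * I
    if np.any(denom <= 0.0):
        raise InvalidParameterError(
            f"modified rectangular denominator 1 + gamma*I <= 0 (gamma={gamma})"
        )
    return a * I * (1.0 - beta * I) / denom - rd


@dataclass(frozen=True)
class ModelSpec:
    """A light-response model: prediction function plus parameter metadata.

    ``default_bounds`` are the standard per-parameter search boxes used by the
    bound-constrained global optimizers ([0, 1] for the dimensionless
    parameters a, theta, beta, gamma; [0, 100] µmol m-2 s-1 for Amax and Rd).
    """

    name: str
    param_names: tuple[str, ...]
    predict: Callable[[Sequence[float], np.ndarray], np.ndarray] = field(repr=False)
    default_bounds: tuple[tuple[float, float], ...]

    @property
    def n_params(self) -> int:
        return len(self.param_names)

    def __post_init__(self) -> None:
        if len(self.default_bounds) != len(self.param_names):
            raise ValueError("default_bounds must align with param_names")


_MODELS: dict[str, ModelSpec] = {
    "exponential": ModelSpec(
        name="exponential",
        param_names=("a", "amax", "rd"),
        predict=predict_exponential,
        default_bounds=((0.0, 1.0), (0.0, 100.0), (0.0, 100.0)),
    ),
    "rectangular": ModelSpec(
        name="rectangular",
        param_names=("a", "amax", "rd"),
        predict=predict_rectangular,
        default_bounds=((0.0, 1.0), (0.0, 100.0), (0.0, 100.0)),
    ),
    "nonrectangular": ModelSpec(
        name="nonrectangular",
        param_names=("theta", "a", "amax", "rd"),
        predict=predict_nonrectangular,
        default_bounds=((0.0, 1.0), (0.0, 1.0), (0.0, 100.0), (0.0, 100.0)),
    ),
    "modified_rectangular": ModelSpec(
        name="modified_rectangular",
        param_names=("a", "beta", "gamma", "rd"),
        predict=predict_modified_rectangular,
        default_bounds=((0.0, 1.0), (0.0, 1.0), (0.0, 1.0), (0.0, 100.0)),
    ),
}

MODEL_NAMES: tuple[str, ...] = tuple(_MODELS)


def get_model(name: str) -> ModelSpec:
    """Look up a model by name.

    Raises ``KeyError`` listing the valid names for an unknown model.
    """
    try:
        return _MODELS[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        ) from None
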