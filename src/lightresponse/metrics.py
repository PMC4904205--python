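"""Goodness-of-fit and model-comparison statistics.

RSS, the coefficient of determination R^2 = 1 - RSS/TSS (which can be
negative for fits worse than the mean predictor), and the Akaike information
criterion.  Because different statistical packages print AIC under different
conventions, the convention is an explicit switch:

* ``gaussian_full`` (default): the full Gaussian log-likelihood form
  ``n*[ln(2*pi) + ln(RSS/n) + 1] + 2*(k + 1)``, counting the error variance
  as a fitted parameter.  This is what R's ``AIC()`` reports for a
  least-squares model with ``k`` regression parameters.
* ``ls_simple``: the reduced least-squares form ``n*ln(RSS/n) + 2*k``.

Both orderings agree when comparing models with equal ``k`` on the same data;
they differ by a constant plus ``2`` per parameter otherwise, so every report
records which convention produced it.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = [
    "AIC_CONVENTIONS",
    "FitMetrics",
    "UndefinedMetricError",
    "aic",
    "compute_metrics",
    "r_squared",
    "rank_models",
    "residual_sum_of_squares",
]

AIC_CONVENTIONS = ("gaussian_full", "ls_simple")


class UndefinedMetricError(ValueError):
    """Raised when a metric is undefined for the given data (e.g. TSS = 0)."""


@dataclass(frozen=True)
class FitMetrics:
    rss: float
    r_squared: float
    aic: float
    n_obs: int
    n_params: int
    aic_convention: str = "gaussian_full"


def residual_sum_of_squares(model, params, dataset) -> float:
    """Sum of squared residuals of ``model(params)`` on ``dataset``.

    Returns ``+inf`` when the prediction is undefined or non-finite for
    ``params``, so that optimizers reject the candidate instead of crashing.
    """
    from .models import InvalidParameterError

    try:
        pred = model.predict(params, dataset.irradiance)
    except InvalidParameterError:
        return math.inf
    with np.errstate(over="ignore", invalid="ignore"):
        resid = dataset.a_net - pred
        rss = float(np.dot(resid, resid))
    return rss if math.isfinite(rss) else math.inf


def r_squared(model, params, dataset) -> float:
    """Coefficient of determination 1 - RSS/TSS."""
    obs = np.asarray(dataset.a_net, dtype=float)
    tss = float(np.sum((obs - obs.mean()) ** 2))
    if tss == 0.0:
        raise UndefinedMetricError("R^2 undefined: observations have zero variance")
    return 1.0 - residual_sum_of_squares(model, params, dataset) / tss


def aic(rss: float, n_obs: int, n_params: int, convention: str = "gaussian_full") -> float:
    """Akaike information criterion for a Gaussian least-squares fit.

    ``rss = 0`` (a perfect fit) makes the log-likelihood unbounded; a
    ``-inf`` sentinel is returned with a warning.
    """
    if convention not in AIC_CONVENTIONS:
        raise ValueError(f"unknown AIC convention {convention!r}; use one of {AIC_CONVENTIONS}")
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    if rss < 0:
        raise ValueError("rss must be non-negative")
    if rss == 0.0:
        warnings.warn("AIC is -inf for a zero-residual fit", RuntimeWarning, stacklevel=2)
        return -math.inf
    n = n_obs
    if convention == "gaussian_full":
        return n * (math.log(2.0 * math.pi) + math.log(rss / n) + 1.0) + 2.0 * (n_params + 1)
    return n * math.log(rss / n) + 2.0 * n_params


def compute_metrics(model, params, dataset, convention: str = "gaussian_full") -> FitMetrics:
    """RSS, R^2 and AIC of one fit, bundled."""
    rss = residual_sum_of_squares(model, params, dataset)
    n = len(dataset.a_net)
    return FitMetrics(
        rss=rss,
        r_squared=r_squared(model, params, dataset),
        aic=aic(rss, n, model.n_params, convention) if rss > 0 else -math.inf,
        n_obs=n,
        n_params=model.n_params,
        aic_convention=convention,
    )


def rank_models(fit_results: Iterable) -> list:
    """Order fits by ascending AIC (lower is better).

    Ties are broken by fewer parameters, then by model name.  All results
    must carry the same AIC convention; mixing conventions is refused because
    their absolute values are not comparable.
    """
    results = list(fit_results)
    conventions = {_get(r, "aic_convention") for r in results}
    conventions.discard(None)
    if len(conventions) > 1:
        raise ValueError(f"cannot rank fits with mixed AIC conventions: {sorted(conventions)}")
    return sorted(
        results,
        key=lambda r: (_get(r, "aic"), _get(r, "n_params"), str(_get(r, "model"))),
    )


def _get(result, name):
    """Field access tolerant of FitResult, FitMetrics or plain mappings."""
    if isinstance(result, dict):
        return result.get(name)
    if hasattr(result, name):
        return getattr(result, name)
    metrics = getattr(result, "metrics", None)
    if metrics is not None and hasattr(metrics, name):
        return getattr(metrics, name)
    return None
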