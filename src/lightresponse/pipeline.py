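"""Fitting orchestration: one curve, one model — or the full batch.

The central entry points are :func:`fit` (one dataset x one model x one
optimizer), :func:`refine_with_lm` (the recommended hybrid: polish a DE
solution with Levenberg-Marquardt, keeping whichever has lower RSS) and
:func:`fit_all` (the Cartesian product over datasets and models, emitting a
long-format table plus a wide R^2/AIC pivot).

Seeding: a batch run takes one master seed; each (dataset, model) cell gets
an independent child seed derived deterministically through
``numpy.random.SeedSequence``, so re-running a batch reproduces it
bit-identically while cells stay statistically independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .models import ModelSpec, get_model, MODEL_NAMES
from .optimizers import (
    Bounds,
    DEConfig,
    GAConfig,
    LMConfig,
    OptResult,
    SAConfig,
    de_minimize,
    ga_minimize,
    lm_fit,
    sa_minimize,
)

__all__ = [
    "FitResult",
    "LightResponseDataset",
    "METHODS",
    "fit",
    "fit_all",
    "pivot_report",
    "refine_with_lm",
    "rss_objective",
]

METHODS = ("de", "lm", "ga", "sa", "de+lm")

#: Columns of the long-format report CSV, in order.
REPORT_COLUMNS = [
    "species_id", "replicate_id", "model", "optimizer", "converged",
    "a", "amax", "rd", "theta", "beta", "gamma", "rss", "r2", "aic", "seed",
]

_ALL_PARAM_COLUMNS = ("a", "amax", "rd", "theta", "beta", "gamma")


@dataclass(frozen=True)
class LightResponseDataset:
    """One light-response curve: paired irradiance / net-assimilation arrays.

    ``irradiance`` in µmol photons m-2 s-1 (non-negative), ``a_net`` in
    µmol CO2 m-2 s-1; at least 5 points per curve.
    """

    species_id: str
    replicate_id: str
    irradiance: np.ndarray
    a_net: np.ndarray

    def __post_init__(self) -> None:
        I = np.asarray(self.irradiance, dtype=float).ravel()
        A = np.asarray(self.a_net, dtype=float).ravel()
        object.__setattr__(self, "irradiance", I)
        object.__setattr__(self, "a_net", A)
        if I.size != A.size:
            raise ValueError("irradiance and a_net must have equal length")
        if I.size < 5:
            raise ValueError("a light-response curve needs at least 5 points")
        if not (np.all(np.isfinite(I)) and np.all(np.isfinite(A))):
            raise ValueError("irradiance and a_net must be finite")
        if np.any(I < 0):
            raise ValueError("irradiance must be non-negative")

    @property
    def key(self) -> tuple[str, str]:
        return (self.species_id, self.replicate_id)

    @property
    def n_obs(self) -> int:
        return int(self.irradiance.size)


@dataclass(frozen=True)
class FitResult:
    """One fitted curve: parameters, metrics and optimizer provenance."""

    species_id: str
    replicate_id: str
    model: str
    optimizer: str
    params: np.ndarray
    metrics: _metrics.FitMetrics
    converged: bool
    failure_reason: str = "none"
    seed: Optional[int] = None
    refinement_failed: bool = False
    r2_before_refinement: Optional[float] = None

    @property
    def param_dict(self) -> dict[str, float]:
        spec = get_model(self.model)
        return dict(zip(spec.param_names, np.asarray(self.params, dtype=float)))

    @property
    def delta_r2(self) -> Optional[float]:
        """R^2 improvement contributed by LM refinement, if any."""
        if self.r2_before_refinement is None:
            return None
        return self.metrics.r_squared - self.r2_before_refinement


def rss_objective(model: ModelSpec, dataset: LightResponseDataset):
    """RSS objective closure; returns +inf where the model is undefined."""

    def objective(params: np.ndarray) -> float:
        return _metrics.residual_sum_of_squares(model, params, dataset)

    return objective


def _sample_init(bounds: Bounds, rng: np.random.Generator) -> np.ndarray:
    return bounds.lower + rng.random(bounds.dim) * bounds.span


def fit(
    dataset: LightResponseDataset,
    model: ModelSpec | str,
    method: str = "de",
    config=None,
    init_params: Optional[Sequence[float]] = None,
    seed: int = 0,
    aic_convention: str = "gaussian_full",
) -> FitResult:
    """Fit one model to one curve with the chosen optimizer.

    ``method`` is one of ``de``, ``lm``, ``ga``, ``sa`` or ``de+lm`` (the
    recommended hybrid).  Global methods search the model's default bound
    box; ``lm`` needs ``init_params``, or samples a start uniformly from
    that box when none is given.  ``config`` overrides the optimizer's
    default hyperparameters (a DEConfig/LMConfig/... matching the method;
    for ``de+lm`` a DEConfig configures the DE stage).
    """
    spec = get_model(model) if isinstance(model, str) else model
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}; valid: {', '.join(METHODS)}")
    if dataset.n_obs < spec.n_params + 1:
        raise ValueError(
            f"dataset {dataset.key} has {dataset.n_obs} points; "
            f"fitting {spec.name} needs at least {spec.n_params + 1}"
        )
    bounds = Bounds.from_model(spec)
    objective = rss_objective(spec, dataset)

    if method in ("de", "de+lm"):
        de_cfg = config if isinstance(config, DEConfig) else DEConfig(seed=seed)
        res = de_minimize(objective, bounds, de_cfg)
    elif method == "ga":
        ga_cfg = config if isinstance(config, GAConfig) else GAConfig(seed=seed)
        res = ga_minimize(objective, bounds, ga_cfg)
    elif method == "sa":
        sa_cfg = config if isinstance(config, SAConfig) else SAConfig(seed=seed)
        res = sa_minimize(objective, bounds, sa_cfg)
    else:  # lm
        lm_cfg = config if isinstance(config, LMConfig) else LMConfig()
        if init_params is None:
            init_params = _sample_init(bounds, np.random.default_rng(seed))
        res = lm_fit(spec, dataset, init_params, lm_cfg)

    result = _to_fit_result(dataset, spec, method, res, aic_convention)
    if method == "de+lm":
        result = refine_with_lm(result, dataset)
    return result


def _to_fit_result(
    dataset: LightResponseDataset,
    spec: ModelSpec,
    method: str,
    res: OptResult,
    aic_convention: str,
) -> FitResult:
    if math.isfinite(res.best_objective):
        m = _metrics.compute_metrics(spec, res.best_params, dataset, aic_convention)
    else:
        m = _metrics.FitMetrics(
            rss=math.inf, r_squared=-math.inf, aic=math.inf,
            n_obs=dataset.n_obs, n_params=spec.n_params, aic_convention=aic_convention,
        )
    return FitResult(
        species_id=dataset.species_id,
        replicate_id=dataset.replicate_id,
        model=spec.name,
        optimizer=method,
        params=np.asarray(res.best_params, dtype=float),
        metrics=m,
        converged=res.converged,
        failure_reason=res.failure_reason,
        seed=res.seed_used,
    )


def refine_with_lm(
    de_result: FitResult,
    dataset: LightResponseDataset,
    config: LMConfig = LMConfig(),
) -> FitResult:
    """Polish a DE fit with LM started at the DE parameter estimates.

    Returns whichever of the two fits has the lower RSS; the pre-refinement
    R^2 is kept so the improvement ``delta_r2`` is reportable.  If LM fails
    outright the DE result is returned unchanged with ``refinement_failed``
    set.
    """
    if not math.isfinite(de_result.metrics.rss):
        return replace(de_result, refinement_failed=True)
    spec = get_model(de_result.model)
    res = lm_fit(spec, dataset, de_result.params, config)
    r2_de = de_result.metrics.r_squared
    if not math.isfinite(res.best_objective):
        return replace(de_result, refinement_failed=True, r2_before_refinement=r2_de)
    if res.best_objective < de_result.metrics.rss:
        m = _metrics.compute_metrics(
            spec, res.best_params, dataset, de_result.metrics.aic_convention
        )
        return replace(
            de_result,
            optimizer="de+lm",
            params=np.asarray(res.best_params, dtype=float),
            metrics=m,
            refinement_failed=False,
            r2_before_refinement=r2_de,
        )
    return replace(de_result, optimizer="de+lm", r2_before_refinement=r2_de)


def result_to_row(result: FitResult) -> dict:
    """Flatten one FitResult into a report row (shared CSV schema)."""
    row = {
        "species_id": result.species_id,
        "replicate_id": result.replicate_id,
        "model": result.model,
        "optimizer": result.optimizer,
        "converged": result.converged,
    }
    pd_params = result.param_dict
    for col in _ALL_PARAM_COLUMNS:
        row[col] = pd_params.get(col, np.nan)
    row["rss"] = result.metrics.rss
    row["r2"] = result.metrics.r_squared
    row["aic"] = result.metrics.aic
    row["seed"] = result.seed
    return row


def fit_all(
    datasets: Iterable[LightResponseDataset],
    models: Iterable[ModelSpec | str] = MODEL_NAMES,
    method: str = "de",
    config=None,
    master_seed: int = 0,
    aic_convention: str = "gaussian_full",
) -> tuple[list[FitResult], pd.DataFrame]:
    """Fit every dataset x model cell; failures are recorded, never raised.

    Returns the list of FitResults plus the long-format report DataFrame
    (columns ``species_id,replicate_id,model,optimizer,converged,a,amax,rd,
    theta,beta,gamma,rss,r2,aic,seed``).  Cell seeds derive from
    ``master_seed`` deterministically.
    """
    datasets = list(datasets)
    specs = [get_model(m) if isinstance(m, str) else m for m in models]
    if not datasets or not specs:
        raise ValueError("datasets and models must be non-empty")

    seeds = np.random.SeedSequence(master_seed).spawn(len(datasets) * len(specs))
    results: list[FitResult] = []
    rows: list[dict] = []
    idx = 0
    for ds in datasets:
        for spec in specs:
            seed = int(seeds[idx].generate_state(1)[0] % (2**31))
            idx += 1
            try:
                cfg = config
                if method in ("de", "de+lm") and config is None:
                    cfg = DEConfig(seed=seed)
                elif method == "ga" and config is None:
                    cfg = GAConfig(seed=seed)
                elif method == "sa" and config is None:
                    cfg = SAConfig(seed=seed)
                elif isinstance(config, (DEConfig, GAConfig, SAConfig)):
                    cfg = replace(config, seed=seed)
                res = fit(ds, spec, method, cfg, seed=seed, aic_convention=aic_convention)
            except Exception as exc:  # a single bad cell must not kill a batch
                res = FitResult(
                    species_id=ds.species_id, replicate_id=ds.replicate_id,
                    model=spec.name, optimizer=method,
                    params=np.full(spec.n_params, np.nan),
                    metrics=_metrics.FitMetrics(
                        rss=math.inf, r_squared=-math.inf, aic=math.inf,
                        n_obs=ds.n_obs, n_params=spec.n_params,
                        aic_convention=aic_convention,
                    ),
                    converged=False, failure_reason=f"error: {exc}", seed=seed,
                )
            results.append(res)
            rows.append(result_to_row(res))
    table = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    return results, table


def pivot_report(table: pd.DataFrame) -> pd.DataFrame:
    """Wide per-curve view: one row per (species, replicate), R^2 and AIC
    column blocks per model — the layout used for side-by-side model
    comparison tables."""
    wide = table.pivot_table(
        index=["species_id", "replicate_id"],
        columns="model",
        values=["r2", "aic"],
        aggfunc="first",
        sort=False,
    )
    wide = wide.swaplevel(axis=1)
    model_order = [m for m in MODEL_NAMES if m in table["model"].unique()]
    wide = wide.reindex(
        columns=pd.MultiIndex.from_product([model_order, ["r2", "aic"]]),
    )
    return wide
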