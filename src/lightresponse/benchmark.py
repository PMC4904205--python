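"""Initial-value sensitivity and optimizer-comparison experiments.

Two experiments quantify why a global optimizer is worth the extra
evaluations:

1. **Initial-value sweep** — Levenberg-Marquardt started from many initial
   parameter vectors drawn uniformly from the optimizer search box (the same
   box the global methods use).  Failed convergence — singular system,
   non-finite objective, or iteration exhaustion — is the measurement, along
   with the R^2 distribution of the successful runs.  The nonrectangular
   hyperbola, whose curvature parameter confines the model to a slab of the
   box, is the classic failure champion.

2. **Optimizer comparison** — every (dataset, model) cell fitted with DE,
   the baselines (GA, SA) and best-of-N-starts LM at a shared iteration
   budget and identical bounds; reported as Delta R^2 = R^2(DE) - R^2(other).

Both experiments derive all randomness from one master seed through
per-trial child seeds, so reports are bit-reproducible.  Trials run
sequentially; any parallel execution must preserve the per-trial child
seeds to keep that guarantee.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from . import metrics as _metrics
from .models import get_model, MODEL_NAMES
from .optimizers import Bounds, DEConfig, GAConfig, LMConfig, SAConfig, lm_fit
from .pipeline import LightResponseDataset, fit_all

__all__ = [
    "SweepResult",
    "compare_optimizers",
    "initial_value_sweep",
    "sensitivity_report",
]


@dataclass(frozen=True)
class SweepResult:
    """LM initial-value sweep outcome for one (dataset, model) cell."""

    species_id: str
    replicate_id: str
    model: str
    n_trials: int
    n_failed: int
    r2_values: np.ndarray  # successes only
    seed: int

    def __post_init__(self) -> None:
        if self.n_failed + len(self.r2_values) != self.n_trials:
            raise ValueError("n_failed + successes must equal n_trials")

    @property
    def best_r2(self) -> float:
        return float(np.max(self.r2_values)) if len(self.r2_values) else -math.inf


def initial_value_sweep(
    dataset: LightResponseDataset,
    model,
    n_trials: int = 100,
    seed: int = 0,
    lm_config: LMConfig = LMConfig(),
    bounds: Optional[Bounds] = None,
) -> SweepResult:
    """Run LM from ``n_trials`` uniform random starts inside the bound box.

    Draws each start uniformly within the model's optimizer bounds (LM
    itself remains unbounded once started) and records the convergence flag
    and, for successes, the R^2.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    spec = get_model(model) if isinstance(model, str) else model
    box = bounds if bounds is not None else Bounds.from_model(spec)
    rng = np.random.default_rng(seed)
    starts = box.lower + rng.random((n_trials, box.dim)) * box.span

    n_failed = 0
    r2s: list[float] = []
    for start in starts:
        res = lm_fit(spec, dataset, start, lm_config)
        if res.converged:
            r2s.append(_metrics.r_squared(spec, res.best_params, dataset))
        else:
            n_failed += 1
    return SweepResult(
        species_id=dataset.species_id,
        replicate_id=dataset.replicate_id,
        model=spec.name,
        n_trials=n_trials,
        n_failed=n_failed,
        r2_values=np.array(r2s),
        seed=seed,
    )


def sensitivity_report(
    datasets: Iterable[LightResponseDataset],
    models: Sequence[str] = MODEL_NAMES,
    n_trials: int = 100,
    master_seed: int = 0,
    lm_config: LMConfig = LMConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """LM sweep over every (dataset, model) cell.

    Returns (per-cell table, per-model aggregate).  The aggregate's
    ``n_failed`` column is the sweep-failure count summed over datasets —
    with 42 curves and 100 draws each, 4200 LM runs per model.
    """
    datasets = list(datasets)
    seeds = np.random.SeedSequence(master_seed).spawn(len(datasets) * len(models))
    rows = []
    idx = 0
    for ds in datasets:
        for model in models:
            seed = int(seeds[idx].generate_state(1)[0] % (2**31))
            idx += 1
            sweep = initial_value_sweep(ds, model, n_trials, seed, lm_config)
            rows.append(
                {
                    "species_id": sweep.species_id,
                    "replicate_id": sweep.replicate_id,
                    "model": sweep.model,
                    "n_trials": sweep.n_trials,
                    "n_failed": sweep.n_failed,
                    "best_r2": sweep.best_r2,
                    "median_r2": float(np.median(sweep.r2_values)) if len(sweep.r2_values) else np.nan,
                    "seed": seed,
                }
            )
    table = pd.DataFrame(rows)
    aggregate = (
        table.groupby("model", sort=False)
        .agg(n_trials=("n_trials", "sum"), n_failed=("n_failed", "sum"),
             best_r2=("best_r2", "max"))
        .reset_index()
    )
    return table, aggregate


def compare_optimizers(
    datasets: Iterable[LightResponseDataset],
    models: Sequence[str] = MODEL_NAMES,
    optimizers: Sequence[str] = ("de", "ga", "sa"),
    master_seed: int = 0,
    max_iterations: int = 500,
    lm_best_of: int = 0,
) -> pd.DataFrame:
    """Fit every cell with each optimizer at a shared budget and bounds.

    DE is the reference: the output carries one ``r2_<opt>`` column per
    optimizer and ``delta_r2_<opt> = r2_de - r2_<opt>`` for the others.
    With ``lm_best_of=N > 0`` an extra ``r2_lm_best`` column reports the
    best R^2 of N uniform random LM starts per cell.  Failed fits appear as
    NaN with their reason, never silently dropped.
    """
    if "de" not in optimizers:
        raise ValueError("DE must be included as the reference optimizer")
    datasets = list(datasets)
    models = list(models)

    r2 = {}
    reasons = {}
    for k, opt in enumerate(optimizers):
        cfg = {
            "de": DEConfig(max_iterations=max_iterations),
            "ga": GAConfig(max_iterations=max_iterations),
            "sa": SAConfig(max_iterations=max_iterations),
        }[opt]
        results, table = fit_all(
            datasets, models, method=opt, config=cfg,
            master_seed=int(np.random.SeedSequence([master_seed, k]).generate_state(1)[0] % (2**31)),
        )
        r2[opt] = table.set_index(["species_id", "replicate_id", "model"])["r2"]
        reasons[opt] = [r.failure_reason for r in results]

    rows = []
    sweep_seeds = np.random.SeedSequence([master_seed, 999]).spawn(len(datasets) * len(models))
    idx = 0
    for ds in datasets:
        for model in models:
            key = (ds.species_id, ds.replicate_id, model)
            row = {"species_id": ds.species_id, "replicate_id": ds.replicate_id, "model": model}
            for opt in optimizers:
                val = float(r2[opt].loc[key])
                row[f"r2_{opt}"] = val if math.isfinite(val) else np.nan
            for opt in optimizers:
                if opt != "de":
                    row[f"delta_r2_{opt}"] = row["r2_de"] - row[f"r2_{opt}"]
            if lm_best_of > 0:
                seed = int(sweep_seeds[idx].generate_state(1)[0] % (2**31))
                sweep = initial_value_sweep(ds, model, n_trials=lm_best_of, seed=seed)
                row["r2_lm_best"] = sweep.best_r2 if len(sweep.r2_values) else np.nan
                row["delta_r2_lm_best"] = row["r2_de"] - row["r2_lm_best"]
            idx += 1
            rows.append(row)
    return pd.DataFrame(rows)
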