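"""Bound-constrained global and local optimizers for curve fitting.

Local least-squares methods (Levenberg-Marquardt and friends) are fast but
hyper-sensitive to their starting point: a badly drawn initial parameter
vector makes them diverge or stall.  Global, population-based methods search
a bound box instead of a neighbourhood and need no initial guess.  This
module provides, under one minimization contract:

* ``de_minimize``  — classic Differential Evolution, strategy rand/1/bin,
  the recommended fitter;
* ``lm_fit``       — a damped Gauss-Newton (Levenberg-Marquardt) local
  least-squares optimizer with finite-difference Jacobian, used to refine a
  DE solution or to study initial-value sensitivity;
* ``ga_minimize``  — a simplified real-coded genetic algorithm (tournament
  selection, blend crossover, uniform mutation, single-member elitism), a
  reduced-fidelity baseline;
* ``sa_minimize``  — single-chain simulated annealing with geometric cooling
  and bounded Gaussian proposals, a reduced-fidelity baseline for
  generalized simulated annealing.

All optimizers are deterministic under a fixed seed, tolerate objectives
that return ``+inf`` in undefined regions, and report failures explicitly
through ``OptResult.failure_reason``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = [
    "Bounds",
    "DEConfig",
    "GAConfig",
    "LMConfig",
    "SAConfig",
    "OptResult",
    "de_minimize",
    "ga_minimize",
    "lm_fit",
    "sa_minimize",
]

Objective = Callable[[np.ndarray], float]


@dataclass(frozen=True)
class Bounds:
    """Per-parameter box constraints, lower < upper elementwise."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float).ravel()
        hi = np.asarray(self.upper, dtype=float).ravel()
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape:
            raise ValueError("lower and upper must have the same length")
        if not np.all(np.isfinite(lo)) or not np.all(np.isfinite(hi)):
            raise ValueError("bounds must be finite")
        if not np.all(lo < hi):
            raise ValueError("lower bounds must be strictly below upper bounds")

    @property
    def dim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    @classmethod
    def from_model(cls, model) -> "Bounds":
        lo, hi = zip(*model.default_bounds)
        return cls(np.array(lo), np.array(hi))


@dataclass(frozen=True)
class DEConfig:
    """Differential Evolution hyperparameters.

    ``population_size=None`` means 10x the problem dimension, the canonical
    sizing.  F and CR are the canonical rand/1/bin defaults; the 500-iteration
    cap is the standard budget for light-response fits.
    """

    population_size: Optional[int] = None
    F: float = 0.8
    CR: float = 0.9
    max_iterations: int = 500
    seed: int = 0
    bound_repair: str = "reflect"

    def __post_init__(self) -> None:
        if not 0.0 < self.F <= 2.0:
            raise ValueError("F must be in (0, 2]")
        if not 0.0 <= self.CR <= 1.0:
            raise ValueError("CR must be in [0, 1]")
        if self.population_size is not None and self.population_size < 4:
            raise ValueError("population_size must be >= 4 (mutation needs 3 donors plus target)")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.bound_repair not in ("reflect", "clip", "resample"):
            raise ValueError("bound_repair must be one of: reflect, clip, resample")


@dataclass(frozen=True)
class GAConfig:
    """Simplified real-coded genetic algorithm hyperparameters."""

    population_size: Optional[int] = None
    crossover_prob: float = 0.9
    mutation_prob: Optional[float] = None  # default 1/dim per gene
    blend_alpha: float = 0.5
    tournament_size: int = 3
    max_iterations: int = 500
    seed: int = 0


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing hyperparameters.

    The evaluation budget defaults to ``max_iterations * 10 * dim`` single
    moves, matching the total number of objective evaluations DE spends at
    its default population size.
    """

    max_iterations: int = 500
    step_scale: float = 0.1
    t_initial: Optional[float] = None  # default: |f(x0)| + 1
    t_final_ratio: float = 1e-6
    seed: int = 0


@dataclass(frozen=True)
class LMConfig:
    """Levenberg-Marquardt hyperparameters (unbounded local search)."""

    max_iterations: int = 100
    ftol: float = 1e-8
    xtol: float = 1e-8
    lambda0: float = 1e-3
    lambda_up: float = 10.0
    lambda_down: float = 0.1
    jacobian: str = "forward_difference"

    def __post_init__(self) -> None:
        if self.ftol <= 0 or self.xtol <= 0 or self.lambda0 <= 0:
            raise ValueError("tolerances and lambda0 must be positive")
        if self.jacobian not in ("forward_difference", "central_difference"):
            raise ValueError("jacobian must be forward_difference or central_difference")


@dataclass(frozen=True)
class OptResult:
    """Outcome of one optimizer run.

    ``trajectory`` records the best objective after each iteration (for DE,
    GA, SA) or the RSS after each accepted step (for LM); it is
    non-increasing by construction.  ``converged=False`` always carries a
    ``failure_reason`` other than ``"none"``.
    """

    best_params: np.ndarray
    best_objective: float
    converged: bool
    failure_reason: str = "none"
    n_evaluations: int = 0
    trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))
    seed_used: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.converged and self.failure_reason == "none":
            raise ValueError("non-converged result must carry a failure_reason")


def _safe_eval(objective: Objective, x: np.ndarray) -> float:
    v = objective(x)
    return float(v) if math.isfinite(v) else math.inf


def _repair(trial: np.ndarray, bounds: Bounds, mode: str, rng: np.random.Generator) -> np.ndarray:
    lo, hi = bounds.lower, bounds.upper
    out_lo = trial < lo
    out_hi = trial > hi
    if not (out_lo.any() or out_hi.any()):
        return trial
    if mode == "clip":
        return np.clip(trial, lo, hi)
    if mode == "resample":
        bad = out_lo | out_hi
        trial = trial.copy()
        trial[bad] = lo[bad] + rng.random(int(bad.sum())) * (hi - lo)[bad]
        return trial
    # reflect: mirror across the violated bound, then clip (a step larger
    # than the box span would otherwise reflect out the other side)
    trial = trial.copy()
    trial[out_lo] = (2 * lo - trial)[out_lo]
    trial[out_hi] = (2 * hi - trial)[out_hi]
    return np.clip(trial, lo, hi)


def de_minimize(objective: Objective, bounds: Bounds, config: DEConfig = DEConfig()) -> OptResult:
    """Minimize ``objective`` over ``bounds`` with DE/rand/1/bin.

    One generation: for every target vector ``x_i`` draw three distinct
    donors ``r1, r2, r3 != i``, form the mutant ``v = x_r1 + F*(x_r2 -
    x_r3)``, cross it binomially into ``x_i`` with probability CR (one
    coordinate forced from the mutant), repair out-of-bounds coordinates,
    and keep the trial iff its objective does not exceed the target's.
    Runs exactly ``max_iterations`` generations; ``converged`` is True iff
    the final best objective is finite.
    """
    d = bounds.dim
    np_size = config.population_size or 10 * d
    if np_size < 4:
        raise ValueError("population_size must be >= 4")
    rng = np.random.default_rng(config.seed)

    pop = bounds.lower + rng.random((np_size, d)) * bounds.span
    fitness = np.array([_safe_eval(objective, x) for x in pop])
    n_evals = np_size

    trajectory = np.empty(config.max_iterations)
    for gen in range(config.max_iterations):
        # donor indices: 3 distinct members != target, drawn per member
        donors = np.empty((np_size, 3), dtype=int)
        for i in range(np_size):
            choices = rng.choice(np_size - 1, size=3, replace=False)
            donors[i] = choices + (choices >= i)
        mutants = pop[donors[:, 0]] + config.F * (pop[donors[:, 1]] - pop[donors[:, 2]])

        cross = rng.random((np_size, d)) < config.CR
        cross[np.arange(np_size), rng.integers(0, d, size=np_size)] = True
        trials = np.where(cross, mutants, pop)

        for i in range(np_size):
            trial = _repair(trials[i], bounds, config.bound_repair, rng)
            f_trial = _safe_eval(objective, trial)
            n_evals += 1
            if f_trial <= fitness[i]:
                pop[i] = trial
                fitness[i] = f_trial
        trajectory[gen] = fitness.min()

    best = int(np.argmin(fitness))
    finite = math.isfinite(fitness[best])
    return OptResult(
        best_params=pop[best].copy(),
        best_objective=float(fitness[best]),
        converged=finite,
        failure_reason="none" if finite else "nonfinite_objective",
        n_evaluations=n_evals,
        trajectory=trajectory,
        seed_used=config.seed,
    )


def ga_minimize(objective: Objective, bounds: Bounds, config: GAConfig = GAConfig()) -> OptResult:
    """Simplified real-coded GA under the same contract as ``de_minimize``.

    A reduced-fidelity baseline: tournament selection, BLX-alpha blend
    crossover, per-gene uniform mutation and elitism of one.  Not a replica
    of any production GA library.
    """
    d = bounds.dim
    np_size = config.population_size or 10 * d
    pm = config.mutation_prob if config.mutation_prob is not None else 1.0 / d
    rng = np.random.default_rng(config.seed)

    pop = bounds.lower + rng.random((np_size, d)) * bounds.span
    fitness = np.array([_safe_eval(objective, x) for x in pop])
    n_evals = np_size

    trajectory = np.empty(config.max_iterations)
    for gen in range(config.max_iterations):
        elite = int(np.argmin(fitness))
        new_pop = [pop[elite].copy()]
        while len(new_pop) < np_size:
            # tournament selection of two parents
            idx = rng.integers(0, np_size, size=(2, config.tournament_size))
            p1 = pop[idx[0][np.argmin(fitness[idx[0]])]]
            p2 = pop[idx[1][np.argmin(fitness[idx[1]])]]
            if rng.random() < config.crossover_prob:
                lo = np.minimum(p1, p2)
                hi = np.maximum(p1, p2)
                spread = config.blend_alpha * (hi - lo)
                child = lo - spread + rng.random(d) * (hi - lo + 2 * spread)
            else:
                child = p1.copy()
            mutate = rng.random(d) < pm
            if mutate.any():
                child[mutate] = bounds.lower[mutate] + rng.random(int(mutate.sum())) * bounds.span[mutate]
            new_pop.append(np.clip(child, bounds.lower, bounds.upper))
        pop = np.array(new_pop)
        fitness = np.array([_safe_eval(objective, x) for x in pop])
        n_evals += np_size
        trajectory[gen] = fitness.min()

    # elitism makes the best-so-far monotone
    trajectory = np.minimum.accumulate(trajectory)
    best = int(np.argmin(fitness))
    finite = math.isfinite(fitness[best])
    return OptResult(
        best_params=pop[best].copy(),
        best_objective=float(fitness[best]),
        converged=finite,
        failure_reason="none" if finite else "nonfinite_objective",
        n_evaluations=n_evals,
        trajectory=trajectory,
        seed_used=config.seed,
    )


def sa_minimize(objective: Objective, bounds: Bounds, config: SAConfig = SAConfig()) -> OptResult:
    """Single-chain simulated annealing under the same contract.

    Bounded Gaussian proposals (sd = ``step_scale`` x box span, reflected
    into the box) with Metropolis acceptance and geometric cooling from
    ``t_initial`` down by a factor ``t_final_ratio`` over the run.  A
    reduced-fidelity stand-in for generalized simulated annealing, whose
    Tsallis visiting distribution is not reproduced here.
    """
    d = bounds.dim
    rng = np.random.default_rng(config.seed)
    n_steps = config.max_iterations * 10 * d

    x = bounds.lower + rng.random(d) * bounds.span
    fx = _safe_eval(objective, x)
    n_evals = 1
    t0 = config.t_initial if config.t_initial is not None else (abs(fx) if math.isfinite(fx) else 1.0) + 1.0
    cooling = config.t_final_ratio ** (1.0 / max(n_steps - 1, 1))

    best_x, best_f = x.copy(), fx
    trajectory = np.empty(config.max_iterations)
    temp = t0
    steps_per_iter = n_steps // config.max_iterations
    for it in range(config.max_iterations):
        for _ in range(steps_per_iter):
            prop = x + rng.normal(0.0, config.step_scale, size=d) * bounds.span
            prop = _repair(prop, bounds, "reflect", rng)
            fp = _safe_eval(objective, prop)
            n_evals += 1
            accept = fp <= fx or (
                math.isfinite(fp) and rng.random() < math.exp(min((fx - fp) / max(temp, 1e-300), 0.0))
            )
            if accept:
                x, fx = prop, fp
                if fp < best_f:
                    best_x, best_f = prop.copy(), fp
            temp *= cooling
        trajectory[it] = best_f

    finite = math.isfinite(best_f)
    return OptResult(
        best_params=best_x,
        best_objective=float(best_f),
        converged=finite,
        failure_reason="none" if finite else "nonfinite_objective",
        n_evaluations=n_evals,
        trajectory=trajectory,
        seed_used=config.seed,
    )


def _fd_jacobian(residual_fn, params: np.ndarray, r0: np.ndarray, scheme: str) -> np.ndarray:
    """Finite-difference Jacobian of the residual vector.

    Step per parameter is ``max(1e-6, 1e-6*|p|)`` — scale-aware across
    parameters spanning [0, 1] and [0, 100].
    """
    n, p = r0.size, params.size
    J = np.empty((n, p))
    for j in range(p):
        h = max(1e-6, 1e-6 * abs(params[j]))
        xp = params.copy()
        xp[j] += h
        rp = residual_fn(xp)
        if scheme == "central_difference":
            xm = params.copy()
            xm[j] -= h
            rm = residual_fn(xm)
            J[:, j] = (rp - rm) / (2.0 * h)
        else:
            J[:, j] = (rp - r0) / h
    return J


def lm_fit(model, dataset, init_params: Sequence[float], config: LMConfig = LMConfig()) -> OptResult:
    """Levenberg-Marquardt least-squares fit of ``model`` to ``dataset``.

    Iterates the damped normal equations ``(J^T J + lambda*diag(J^T J)) delta
    = J^T r`` with a finite-difference Jacobian.  A step is accepted iff it
    decreases the RSS (then ``lambda`` shrinks); otherwise ``lambda`` grows
    and the step is retried.  Stops when the relative RSS change falls below
    ``ftol`` or the relative step below ``xtol`` (``converged=True``), or
    with an explicit failure: non-finite objective at the start, a damped
    system still singular after retries, or iteration exhaustion.  The search
    is unbounded, as is conventional for LM.
    """
    from .models import InvalidParameterError

    obs = np.asarray(dataset.a_net, dtype=float)
    n_evals = 0

    def residuals(p: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        n_evals += 1
        try:
            pred = model.predict(p, dataset.irradiance)
        except InvalidParameterError:
            return np.full(obs.shape, np.nan)
        return obs - pred

    params = np.asarray(init_params, dtype=float).copy()
    if params.size != model.n_params:
        raise ValueError(f"init_params must have length {model.n_params}")

    r = residuals(params)
    with np.errstate(over="ignore"):
        rss = float(np.dot(r, r)) if np.all(np.isfinite(r)) else math.inf
    if not math.isfinite(rss):
        return OptResult(
            best_params=params,
            best_objective=math.inf,
            converged=False,
            failure_reason="nonfinite_objective",
            n_evaluations=n_evals,
            trajectory=np.empty(0),
        )
    if rss == 0.0:  # already at an exact least-squares optimum
        return OptResult(
            best_params=params, best_objective=0.0, converged=True,
            failure_reason="none", n_evaluations=n_evals, trajectory=np.array([0.0]),
        )

    lam = config.lambda0
    accepted = [rss]
    max_lambda = 1e12
    for _ in range(config.max_iterations):
        J = _fd_jacobian(residuals, params, r, config.jacobian)
        if not np.all(np.isfinite(J)):
            return OptResult(
                best_params=params, best_objective=rss, converged=False,
                failure_reason="nonfinite_objective", n_evaluations=n_evals,
                trajectory=np.array(accepted),
            )
        JTJ = J.T @ J
        g = J.T @ r
        diag = np.clip(np.diag(JTJ), 1e-14, None)

        step_taken = False
        while lam <= max_lambda:
            try:
                delta = np.linalg.solve(JTJ + lam * np.diag(diag), -g)
            except np.linalg.LinAlgError:
                lam *= config.lambda_up
                continue
            if not np.all(np.isfinite(delta)):
                lam *= config.lambda_up
                continue
            trial = params + delta
            r_trial = residuals(trial)
            with np.errstate(over="ignore"):
                rss_trial = float(np.dot(r_trial, r_trial)) if np.all(np.isfinite(r_trial)) else math.inf
            if not math.isfinite(rss_trial):
                lam *= config.lambda_up
                continue
            if rss_trial < rss:
                step_rel = float(np.linalg.norm(delta)) / (float(np.linalg.norm(params)) + config.xtol)
                rss_rel = (rss - rss_trial) / max(rss, 1e-300)
                params, r, rss = trial, r_trial, rss_trial
                accepted.append(rss)
                lam = max(lam * config.lambda_down, 1e-12)
                step_taken = True
                if rss_rel <= config.ftol or step_rel <= config.xtol or rss == 0.0:
                    return OptResult(
                        best_params=params, best_objective=rss, converged=True,
                        failure_reason="none", n_evaluations=n_evals,
                        trajectory=np.array(accepted),
                    )
                break
            lam *= config.lambda_up
        if not step_taken:
            # damping exhausted without an acceptable step: flat or singular
            return OptResult(
                best_params=params, best_objective=rss, converged=False,
                failure_reason="singular_system", n_evaluations=n_evals,
                trajectory=np.array(accepted),
            )

    return OptResult(
        best_params=params, best_objective=rss, converged=False,
        failure_reason="max_iterations", n_evaluations=n_evals,
        trajectory=np.array(accepted),
    )
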