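# Methods

## The estimation problem

A light-response curve is a small dataset — typically 10–15 points — of net
photosynthetic rate `A_n` (µmol CO₂ m⁻² s⁻¹) measured across an increasing
irradiance ladder `I` (µmol photons m⁻² s⁻¹). Each of the four supported
models is fitted by ordinary (unweighted) least squares: minimize
`RSS(p) = Σᵢ (A_nᵢ − f(p, Iᵢ))²` over the model's parameter vector `p`.
Homoscedastic errors are assumed; no weighting or robust loss is offered.

The difficulty is not the objective but the start. The least-squares
surface of these models has narrow curved valleys, plateaus (e.g. in θ when
`aI ≪ A_max`), and — for the nonrectangular and modified families — regions
where the model is simply undefined. Local derivative-based optimizers
started from a poor guess stall or diverge. The package's position is to
make the fit a function of the data and a search box only.

## Model evaluation details

* **Parameter order** is fixed per model — exponential/rectangular
  `(a, amax, rd)`, nonrectangular `(theta, a, amax, rd)`, modified
  `(a, beta, gamma, rd)` — so bounds, serialized reports and parameter
  vectors always align.
* **θ → 0 limit.** The nonrectangular prediction divides by `2θ`; below
  `θ = 1e−8` it is evaluated through its analytic limit, the rectangular
  hyperbola, keeping the prediction continuous in θ (verified to 1e−8
  relative in tests). The discriminant is clipped at zero to absorb
  rounding at θ = 1 where it forms a perfect square.
* **Undefined regions** (θ outside [0, 1], non-positive hyperbola
  denominators, non-finite parameters) raise a typed error at the model
  layer; the RSS objective converts that to `+inf` so population-based
  optimizers can traverse bad regions without crashing, while direct users
  still get a diagnosis.
* **Units** are documented but not enforced; datasets digitized from
  heterogeneous sources must simply be self-consistent.

## Optimizers

All four optimizers are implemented in this package in plain NumPy and
share one contract: minimize a scalar objective over a bound box,
deterministic under a fixed seed, explicit failure reporting.

* **Differential Evolution** (the recommended fitter): strategy
  rand/1/bin — uniform initialization in the box, mutation
  `v = x_{r1} + F(x_{r2} − x_{r3})` with distinct donors, binomial
  crossover with one forced coordinate, greedy selection. Defaults
  `NP = 10×d`, `F = 0.8`, `CR = 0.9`, 500 generations: the canonical
  settings for this strategy, all config-overridable. Bound repair defaults
  to *reflect* (mirror across the violated bound, then clip), which
  preserves search diffusion near bounds better than plain clipping; *clip*
  and *resample* are available. The best-objective trajectory is monotone
  by construction (greedy selection) and is asserted in tests. DE runs its
  full generation budget; "converged" means a finite best objective, since
  a global method has no gradient-based stopping criterion at these
  problem sizes.
* **Levenberg–Marquardt**: damped normal equations
  `(JᵀJ + λ·diag(JᵀJ))δ = −Jᵀr` with a finite-difference Jacobian
  (forward by default, central optional), step accepted only if RSS
  decreases (λ ×0.1 on accept, ×10 on reject). Convergence = relative RSS
  change ≤ `ftol` (1e−8) or relative step ≤ `xtol` (1e−8). *Failed
  convergence* is explicitly one of: non-finite objective at the start, a
  damped system still unusable after escalating λ to 1e12 (flat or singular
  curvature), or exhausting 100 iterations — a deliberate, testable
  definition, since failure accounting is one of the package's
  measurements. The Jacobian step is `max(1e−6, 1e−6·|p|)`, scale-aware
  across parameters living on [0, 1] and [0, 100]. LM itself is unbounded,
  as is conventional; only its starting points are drawn from the box.
* **GA and SA baselines** are deliberately simplified, reduced-fidelity
  comparators: a real-coded GA (tournament of 3, BLX-0.5 blend crossover,
  per-gene uniform mutation at rate 1/d, elitism of one) and a single-chain
  simulated annealing (Gaussian proposals at 0.1× the box span reflected
  into bounds, Metropolis acceptance, geometric cooling over a budget of
  `500 × 10d` evaluations to match DE's). They exist so local-vs-global and
  global-vs-global comparisons can be run inside one deterministic
  framework; they are not replicas of any production GA or generalized-SA
  package, whose heavy-tailed visiting distributions and adaptive operators
  are out of scope.

## Seeding

Every stochastic experiment flows from one master seed. Batch runs spawn
per-(dataset, model) child seeds via `numpy.random.SeedSequence`, so a
42-curve table, a 4200-run LM sweep, or an optimizer comparison is
bit-reproducible while cells remain statistically independent. Trials run
sequentially; a parallel executor must preserve the per-trial child seeds
to keep the guarantee.

## Goodness of fit and model choice

`R² = 1 − RSS/TSS` (not a squared correlation), so a fit worse than the
mean predictor is honestly negative — which the GA baseline does produce on
hard curves. AIC defaults to the full Gaussian log-likelihood convention
`n[ln 2π + ln(RSS/n) + 1] + 2(k+1)`, verified in tests against R's `AIC()`
on a frozen linear-model oracle; a reduced `n·ln(RSS/n) + 2k` convention is
a switch, and reports refuse to rank fits across conventions. No AICc:
with n ≈ 13 and k = 3–4 the small-sample correction would change rankings,
but plain AIC is what this class of analyses conventionally reports, and
the ranking function is deliberately transparent. Ties break toward fewer
parameters, then model name.

## The synthetic campaign

The generator emulates a multi-species gas-exchange campaign: a 13-step
irradiance ladder `{0, 20, 50, 100, 200, 400, 600, 800, 1000, 1200, 1400,
1700, 2000}`, parameters drawn per curve from plausible sub-ranges
(a ∈ [0.02, 0.09], A_max ∈ [3, 35], R_d ∈ [0.2, 3], θ ∈ [0.2, 0.95],
β ∈ [0, 0.001], γ ∈ [0, 0.01]) cycling through all four generating
families, additive homoscedastic Gaussian noise with sd drawn from
[0.1, 0.5] µmol m⁻² s⁻¹, and 42 curves per campaign (21 species × 2
replicates is the typical shape). The sub-ranges are intentionally narrower
than the optimizer's search box: the box is a bound for optimization, not a
species distribution.

What the generator does **not** emulate: instrument-specific error
structure (flow drift, leak artifacts), variance growing with irradiance,
digitization noise of figure-extracted data, or temperature/CO₂ covariates.
Passing tests therefore demonstrate optimizer and pipeline correctness
under clean statistical conditions, not robustness to every field dataset.

## Problem sizes and numerical choices

The test suite and the acceptance script run the campaign at 42 curves;
the LM sensitivity experiment uses 100 uniform random starts per
(curve, model) — 4200 LM runs per model — and optimizer comparisons share a
500-iteration budget and identical bounds. Smaller slices of the same
experiments appear in unit tests.

Known limitations, measured rather than hidden:

* At noise sd = 0.3 the median parameter-recovery error of the *global
  least-squares optimum itself* slightly exceeds 5% (θ and γ are weakly
  identified on a 13-point ladder); at sd ≤ 0.2 it is well under 5%. This
  is an identifiability property of the data, not an optimizer failure —
  DE with and without LM polish lands on the same optimum, and at zero
  noise recovers every parameter to ~1e−8 relative.
* LM failure *counts* depend on the failure definition and optimizer
  internals; what is stable, and what the package asserts, is the ordering
  (the nonrectangular model fails most, the 4-parameter families fail far
  more than the 3-parameter ones) and that DE searching the same box never
  fails.
* The exhaustive-grid cross-check of DE localizes the continuous optimum
  only to about one grid cell; the test tolerance is 1.5 cells.
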