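# Methods

## The classifier

The core model is a two-class soft-margin SVM. For training data
`(xᵢ, yᵢ)` with `yᵢ ∈ {+1, −1}`, the primal problem

```
min  ½‖w‖² + C Σᵢ ξᵢ    s.t.  yᵢ(w·φ(xᵢ) + b) ≥ 1 − ξᵢ,  ξᵢ ≥ 0
```

trades margin width against slack through the box penalty `C`. We solve
the Lagrangian dual

```
max_α  Σᵢ αᵢ − ½ αᵀHα    s.t.  0 ≤ αᵢ ≤ C,  Σᵢ αᵢ yᵢ = 0,
H_ij = yᵢ yⱼ k(xᵢ, xⱼ),
```

which involves the data only through the kernel `k`. Supported kernels:
linear, polynomial `(x·z + a)^b`, RBF `exp(−‖x−z‖²/2σ²)` and sigmoid
`tanh(a x·z − b)`. The sigmoid kernel is not positive semi-definite for
general `(a, b)`; training proceeds with a warning, using an
endpoint-objective rule for non-convex pair subproblems, and may return
a local solution.

### SMO solver

The dual is solved by sequential minimal optimization over pairs of
multipliers. Working-set selection: the first index is the point with
the **maximal KKT violation** (margin shortfall given its bound status);
the second maximizes `|E₁ − E₂|` over the candidates, preferring
non-bound points, with a seeded-random fallback when no progress is
possible. The run stops when the largest KKT violation drops below the
tolerance (default `1e-3`; tests use down to `1e-8`), or after
`max_passes × n` pair updates.

- A point counts as a support vector when `αᵢ > 1e-8·C` (relative rank
  threshold).
- The bias is recomputed after convergence as the average of
  `y_v − Σᵢ αᵢ yᵢ k(xᵢ, x_v)` over support vectors, preferring the
  unbounded ones (`0 < α_v < C`) because they sit exactly on the margin;
  if every support vector is at the box bound the average runs over all
  of them.
- Prediction breaks the tie `f(x) = 0` toward `+1`.
- `solve_dual_reference` is an independent brute-force check: SLSQP on
  the boxed, equality-constrained QP from multiple feasible starts. It
  is only intended for instances of ≲10 points and is used by the test
  suite to confirm SMO optimality to `1e-5` relative.

## Hyperparameter search

Two dimensions are tuned: `C ∈ [2⁻⁵, 2¹⁵]` and the kernel parameter
(RBF width `σ ∈ [2⁻⁴, 2⁴]`), both searched in log₂ coordinates so a
step means a multiplicative change. The fitness of a candidate is the
mean **stratified k-fold cross-validation accuracy** (percent, k = 5 by
default) of an SVM trained at that point on the training split; folds
are drawn once per search so every candidate sees the same partition,
which makes the objective deterministic. Resubstitution (training)
accuracy is available as an alternative fitness mode. A fold whose SVM
training fails scores 0 and the search continues.

All four optimizers are elitist (the best-so-far never degrades), clamp
every position to the search box, are deterministic under a seed, and
record a per-generation trace of best fitness, mean population fitness
and best position. Ties keep the incumbent.

### Particle swarm (PSO)

Canonical update `v ← w·v + c₁r₁(pbest − x) + c₂r₂(gbest − x)`,
`x ← x + v`, with `c₁ = 1.5`, `c₂ = 1.7`, population 20, 100
generations. The inertia weight decays linearly 0.9 → 0.4 over the run
(a fixed weight can be passed instead); velocities are clamped to 20% of
each dimension's range. Budget: `pop × (iters + 1)` objective calls.

### Cuckoo search (CS)

Population of nests, one solution per nest. Per generation each nest
emits a Lévy-flight proposal `x' = x + α·step⊙(x − best)` with
per-dimension scale `α = 0.01 × range`; the proposal replaces a
*randomly chosen* nest if fitter. Then the worst `P_a = 0.25` fraction
of nests is abandoned and re-seeded uniformly (never the current best).
Step lengths come from Mantegna's algorithm: `step = u/|v|^{1/β}` with
`u ~ N(0, σ_u²)`, `v ~ N(0,1)`. We parameterize by the power-law
exponent of the step density, `λ = 1.5` with stability index
`β = λ − 1 = 0.5`, which gives very heavy tails (occasional long jumps
across the whole box). Because the drift term vanishes at the best nest,
its own proposal uses an undirected Lévy perturbation instead, so the
incumbent region keeps being explored. Budget:
`pop + iters × (pop + round(P_a·pop))`.

### Real-coded GA

Roulette selection on quadratically scaled, min-shifted fitness
(uniform fallback when all fitness values are equal), arithmetic
crossover with probability `p_c = 0.5` using per-gene blend weights
`u ~ U(0,1)`, per-gene Gaussian mutation with probability `p_m = 0.005`
whose standard deviation starts at 10% of the range and halves every 25
generations (coarse early, fine late), one random immigrant per
generation to guard against premature convergence of the blend-only
recombination, and 1-elitism (the previous best replaces the worst
child). The quadratic fitness scaling, annealing schedule and immigrant
slot were chosen because a plain roulette/fixed-σ variant stalls on
smooth objectives: blending alone cannot leave the population's convex
hull, so without late-stage fine mutation and sustained selection
pressure about 40% of runs plateau 0.1–0.4 away from a quadratic
optimum at this population size. Budget: `pop × (iters + 1)`.

### CS-PSO hybrid

Stage 1 runs cuckoo search for `round(cs_fraction × total)` generations
(default fraction 0.5) — the Lévy flights give broad, restart-resistant
exploration of the log-scaled box. Stage 2 initializes a particle swarm
from the final nest **population** (default; a best-plus-random transfer
mode exists), sets the swarm's global best to the CS best, zeroes all
velocities, and refines for the remaining generations. The trace is the
concatenation of both stages and the returned best is the better of the
two stage bests, so the hybrid can never end below its CS stage.

A single iteration budget (100) covers the whole hybrid; the 50/50 split
is a package default, configurable via `cs_fraction`.

## Data handling

- **I/O**: UCI-style delimited text, label in a configurable column
  (default last), raw labels mapped to `{+1, −1}` (default `1 → +1`
  benign, `2 → −1` malignant). Missing-value tokens (`?`) raise by
  default; a drop-rows policy is available. Writing uses full `repr`
  precision so read-back is exact.
- **Normalization**: per-feature min-max to `[0, 1]`, fitted on the
  training rows only and then applied to the test rows (test values may
  fall outside `[0, 1]`; no clipping). Fitting on the training split
  avoids information leaking from the test set into the scaling;
  constant features map to 0.
- **Splitting**: stratified random split of a stated size under a seed
  (default), or `first-n` file order for users who want a deterministic
  prefix split. The canonical clinical-table sizes are 270 → 190/80 and
  699 → 549/150.

## Synthetic data generator

`generate_synthetic` draws two isotropic unit-variance Gaussian clusters
in `d` dimensions whose means sit `separation` apart along the diagonal
direction, then shuffles rows and encodes raw labels as `{1, 2}`. The
Bayes error is `Φ(−separation/2)` independent of `d`, so the difficulty
dial is direct: the default `separation = 2.5` gives ≈10.6% Bayes error —
test accuracies in the high 80s, comparable to real clinical tables of
this size — while `separation = 10` is separable for practical purposes
and `separation = 0` is pure chance.

What the generator does **not** emulate: correlated or heterogeneous
features, class-conditional covariance differences, label noise, missing
values, and discrete/ordinal attributes — all present in real clinical
tables. Passing tests on this generator therefore demonstrates that the
pipeline optimizes and classifies correctly under known geometry, not
that any particular accuracy will transfer to a specific real dataset.

## Numerical choices and degenerate cases

- KKT tolerance `1e-3` for tuning-time fits (speed), `≤1e-6` where
  optimality itself is asserted; `max_passes` bounds runaway fits at
  extreme `C`.
- Undefined precision/recall (zero denominator) reports 0 with a
  warning; `F = 0` when `P + R = 0`.
- Equality-constraint residual `|Σαᵢyᵢ|` is kept at numerical zero by
  construction (pair updates preserve it exactly).
- Optimizer tie-breaks keep the incumbent, which makes best-fitness
  traces constant (not drifting) on flat objectives.
- Seeds: every stochastic component (generator, splits, folds, all four
  optimizers, SMO fallback choice) consumes an explicit integer seed;
  the hybrid derives independent stage seeds via a seed sequence.

## Default experiment sizes

Full-budget searches (population 20, 100 generations, 5-fold CV) are the
package defaults and match the comparison protocol this package
implements. The bundled acceptance script and the worked example use a
demo scale — population 10, 20 generations, 3-fold CV on the 270×13
synthetic table — which reaches within a point or two of the
full-budget result on this generator because the CV-accuracy surface
over `(log C, log σ)` has a broad plateau near its optimum.

## Known limitations

- Binary classification only; no multi-class scheme, no probability
  calibration, no SVM regression.
- The SMO implementation stores the full kernel matrix (O(n²) memory),
  appropriate for the few-hundred-row tables it targets.
- CV-accuracy fitness is piecewise constant in the hyperparameters, so
  many search points tie; optimizers rely on elitism rather than
  gradient-like progress near the optimum.
- The GA meets a weaker recovery tolerance than PSO/CS on smooth
  benchmarks (0.1 vs 0.01 at equal budgets); it is included as a
  baseline, not as the recommended tuner.
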