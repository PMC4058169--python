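"""Population metaheuristics for hyperparameter search.

Four engines share one interface: particle swarm optimization (PSO),
cuckoo search (CS) with Lévy-flight proposals, a real-coded genetic
algorithm (GA), and the two-stage hybrid that runs CS first and hands its
final population to PSO.  All maximize a scalar objective over a bounded
:class:`SearchSpace`, are elitist (the recorded best-fitness trace is
non-decreasing), clamp every position to the bounds, and are fully
deterministic under a seed.

Evaluation budgets (asserted in the test suite):

- PSO, GA: ``pop * (iters + 1)`` (initial population + one evaluation per
  particle per generation).
- CS: ``pop + iters * (pop + round(Pa * pop))`` (initial nests, then one
  Lévy proposal per nest plus the abandoned-nest refills per generation).
- Hybrid: CS budget for the CS stage + ``pop * iters_pso`` (the PSO stage
  inherits already-evaluated positions).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("swarmsvm")

__all__ = [
    "Dimension",
    "SearchSpace",
    "Candidate",
    "ConvergenceTrace",
    "SwarmState",
    "NestSet",
    "ParticleSwarm",
    "CuckooSearch",
    "RealCodedGA",
    "HybridCSPSO",
    "levy_flight",
    "mantegna_steps",
    "optimize_hybrid",
]


# --------------------------------------------------------------------------
# search space
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Dimension:
    """One search dimension; log-scaled dimensions search in log2 space."""

    name: str
    lower: float
    upper: float
    scale: str = "linear"  # "linear" | "log"

    def __post_init__(self) -> None:
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: lower must be < upper")
        if self.scale not in ("linear", "log"):
            raise ValueError(f"{self.name}: scale must be 'linear' or 'log'")
        if self.scale == "log" and self.lower <= 0:
            raise ValueError(f"{self.name}: log scale requires lower > 0")


class SearchSpace:
    """Bounded box of named dimensions with optional log scaling.

    Optimizers move in internal (scaled) coordinates; ``decode`` maps a
    scaled point back to natural units.  The default space for SVM tuning
    is ``C in [2^-5, 2^15]`` and RBF width ``sigma in [2^-4, 2^4]``, both
    log-scaled.
    """

    def __init__(self, dims: list[Dimension]):
        if not dims:
            raise ValueError("search space needs at least one dimension")
        self.dims = list(dims)
        self.lower = np.array(
            [math.log2(d.lower) if d.scale == "log" else d.lower for d in dims]
        )
        self.upper = np.array(
            [math.log2(d.upper) if d.scale == "log" else d.upper for d in dims]
        )

    @classmethod
    def for_svm(cls, kernel_kind: str = "rbf") -> "SearchSpace":
        dims = [Dimension("C", 2.0**-5, 2.0**15, "log")]
        if kernel_kind == "rbf":
            dims.append(Dimension("sigma", 2.0**-4, 2.0**4, "log"))
        elif kernel_kind in ("polynomial", "sigmoid"):
            dims.append(Dimension("a", 2.0**-4, 2.0**4, "log"))
        return cls(dims)

    @property
    def n_dims(self) -> int:
        return len(self.dims)

    @property
    def ranges(self) -> np.ndarray:
        return self.upper - self.lower

    def names(self) -> list[str]:
        return [d.name for d in self.dims]

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.uniform(self.lower, self.upper, size=(n, self.n_dims))

    def clip(self, z: np.ndarray) -> np.ndarray:
        return np.clip(z, self.lower, self.upper)

    def decode(self, z: np.ndarray) -> np.ndarray:
        """Scaled coordinates -> natural units."""
        z = np.asarray(z, dtype=float)
        out = z.copy()
        for j, d in enumerate(self.dims):
            if d.scale == "log":
                out[..., j] = 2.0 ** z[..., j]
        return out

    def decode_dict(self, z: np.ndarray) -> dict:
        vals = self.decode(z)
        return {d.name: float(vals[j]) for j, d in enumerate(self.dims)}


@dataclass
class Candidate:
    """A point in scaled search coordinates with its fitness."""

    position: np.ndarray
    fitness: float = -np.inf
    evaluated: bool = False


@dataclass
class ConvergenceTrace:
    """Per-generation best/mean fitness and best position (scaled coords)."""

    best_fitness: list[float] = field(default_factory=list)
    mean_fitness: list[float] = field(default_factory=list)
    best_position: list[np.ndarray] = field(default_factory=list)

    def append(self, best: float, mean: float, position: np.ndarray) -> None:
        self.best_fitness.append(float(best))
        self.mean_fitness.append(float(mean))
        self.best_position.append(np.array(position, copy=True))
        logger.info("generation %d: best fitness %.6g (mean %.6g)",
                    len(self.best_fitness), best, mean)

    def extend(self, other: "ConvergenceTrace") -> None:
        self.best_fitness += other.best_fitness
        self.mean_fitness += other.mean_fitness
        self.best_position += other.best_position

    def __len__(self) -> int:
        return len(self.best_fitness)

    def is_monotone(self) -> bool:
        b = self.best_fitness
        return all(b[i + 1] >= b[i] for i in range(len(b) - 1))

    def to_dataframe(self, space: SearchSpace | None = None):
        import pandas as pd

        d = {
            "generation": np.arange(1, len(self) + 1),
            "best_fitness": self.best_fitness,
            "mean_fitness": self.mean_fitness,
        }
        pos = np.array(self.best_position)
        if space is not None:
            pos = space.decode(pos)
            names = space.names()
        else:
            names = [f"z{j}" for j in range(pos.shape[1])]
        for j, name in enumerate(names):
            d[f"best_{name}"] = pos[:, j]
        return pd.DataFrame(d)

    def write_csv(self, path, space: SearchSpace | None = None) -> None:
        self.to_dataframe(space).to_csv(path, index=False)


# --------------------------------------------------------------------------
# Lévy flights (Mantegna's algorithm)
# --------------------------------------------------------------------------

def mantegna_steps(rng: np.random.Generator, lam: float, size) -> np.ndarray:
    """Heavy-tailed step lengths approximating a Lévy-stable law.

    ``lam`` is the power-law exponent of the step-length density,
    ``P(s) ~ |s|^-lam`` with ``lam in (1, 3]``; Mantegna's stability index
    is ``beta = lam - 1``.  Steps are ``u / |v|^(1/beta)`` with
    ``u ~ N(0, sigma_u^2)``, ``v ~ N(0, 1)``.
    """
    if not 1.0 < lam <= 3.0:
        raise ValueError("Levy exponent lam must lie in (1, 3]")
    beta = lam - 1.0
    sigma_u = (
        math.gamma(1.0 + beta) * math.sin(math.pi * beta / 2.0)
        / (math.gamma((1.0 + beta) / 2.0) * beta * 2.0 ** ((beta - 1.0) / 2.0))
    ) ** (1.0 / beta)
    u = rng.normal(0.0, sigma_u, size=size)
    v = rng.normal(0.0, 1.0, size=size)
    return u / np.abs(v) ** (1.0 / beta)


def levy_flight(
    current: np.ndarray,
    best: np.ndarray,
    rng: np.random.Generator,
    alpha: float | np.ndarray,
    lam: float = 1.5,
    bounds: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """One Lévy-flight proposal:  x' = x + alpha * step * (x - best).

    The drift term vanishes when ``current == best`` (the proposal equals
    the current point) and when ``alpha == 0``; callers that need the best
    point to keep moving must add their own perturbation (see
    :meth:`CuckooSearch.step`).
    """
    current = np.asarray(current, dtype=float)
    step = mantegna_steps(rng, lam, current.shape)
    proposal = current + alpha * step * (current - np.asarray(best, dtype=float))
    if bounds is not None:
        proposal = np.clip(proposal, bounds[0], bounds[1])
    return proposal


# --------------------------------------------------------------------------
# optimizer base
# --------------------------------------------------------------------------

class _Optimizer:
    """Shared bookkeeping: evaluation counting, elitist best, tracing."""

    def __init__(self, space: SearchSpace, pop_size: int, n_iters: int, seed: int):
        if pop_size < 2:
            raise ValueError("population size must be >= 2")
        self.space = space
        self.pop_size = pop_size
        self.n_iters = n_iters
        self.seed = seed
        self.n_evaluations = 0
        self.state_ = None

    def _make_objective(self, objective):
        def f(z):
            self.n_evaluations += 1
            return float(objective(self.space.decode(z)))

        return f

    @staticmethod
    def _improves(new: float, old: float) -> bool:
        # ties keep the incumbent
        return new > old


@dataclass
class SwarmState:
    """PSO population: positions/velocities plus personal and global bests."""

    positions: np.ndarray
    velocities: np.ndarray
    fitness: np.ndarray
    pbest_positions: np.ndarray
    pbest_fitness: np.ndarray
    gbest_position: np.ndarray
    gbest_fitness: float


class ParticleSwarm(_Optimizer):
    """Canonical PSO:  v <- w v + c1 r1 (pbest - x) + c2 r2 (gbest - x).

    Inertia ``w`` decays linearly 0.9 -> 0.4 over the run by default
    (pass a float for a fixed weight).  Velocities are clamped to
    ``vmax_frac`` of each dimension's range and positions to the bounds.
    """

    def __init__(self, space, pop_size=20, n_iters=100, c1=1.5, c2=1.7,
                 inertia="linear", vmax_frac=0.2, seed=0):
        super().__init__(space, pop_size, n_iters, seed)
        self.c1, self.c2 = c1, c2
        self.inertia = inertia
        self.vmax = vmax_frac * space.ranges

    def _inertia_at(self, gen: int) -> float:
        if self.inertia == "linear":
            if self.n_iters <= 1:
                return 0.9
            return 0.9 - (0.9 - 0.4) * gen / (self.n_iters - 1)
        return float(self.inertia)

    def init_state_from(self, positions: np.ndarray, fitness: np.ndarray,
                        gbest: Candidate) -> SwarmState:
        """Seed the swarm from an evaluated population (hybrid hand-off).

        Velocities start at zero and the supplied global best becomes the
        swarm's global best.
        """
        positions = self.space.clip(np.array(positions, dtype=float))
        fitness = np.array(fitness, dtype=float)
        state = SwarmState(
            positions=positions,
            velocities=np.zeros_like(positions),
            fitness=fitness,
            pbest_positions=positions.copy(),
            pbest_fitness=fitness.copy(),
            gbest_position=positions[int(np.argmax(fitness))].copy(),
            gbest_fitness=float(fitness.max()),
        )
        if self._improves(gbest.fitness, state.gbest_fitness) or gbest.fitness == state.gbest_fitness:
            state.gbest_position = gbest.position.copy()
            state.gbest_fitness = gbest.fitness
        return state

    def step(self, state: SwarmState, objective, rng, w: float) -> SwarmState:
        """One synchronous PSO generation, in place."""
        shape = state.positions.shape
        r1 = rng.uniform(size=shape)
        r2 = rng.uniform(size=shape)
        state.velocities = (
            w * state.velocities
            + self.c1 * r1 * (state.pbest_positions - state.positions)
            + self.c2 * r2 * (state.gbest_position - state.positions)
        )
        np.clip(state.velocities, -self.vmax, self.vmax, out=state.velocities)
        state.positions = self.space.clip(state.positions + state.velocities)
        state.fitness = np.array([objective(z) for z in state.positions])
        improved = state.fitness > state.pbest_fitness
        state.pbest_positions[improved] = state.positions[improved]
        state.pbest_fitness[improved] = state.fitness[improved]
        k = int(np.argmax(state.pbest_fitness))
        if self._improves(state.pbest_fitness[k], state.gbest_fitness):
            state.gbest_fitness = float(state.pbest_fitness[k])
            state.gbest_position = state.pbest_positions[k].copy()
        return state

    def run(self, objective, init_positions=None, init_fitness=None,
            init_gbest: Candidate | None = None) -> tuple[Candidate, ConvergenceTrace]:
        rng = np.random.default_rng(self.seed)
        f = self._make_objective(objective)
        if init_positions is not None:
            gbest = init_gbest or Candidate(init_positions[0], -np.inf, True)
            state = self.init_state_from(init_positions, init_fitness, gbest)
        else:
            positions = self.space.sample(rng, self.pop_size)
            fitness = np.array([f(z) for z in positions])
            state = self.init_state_from(positions, fitness,
                                         Candidate(positions[0], -np.inf, True))
        trace = ConvergenceTrace()
        for gen in range(self.n_iters):
            self.step(state, f, rng, self._inertia_at(gen))
            trace.append(state.gbest_fitness, state.fitness.mean(), state.gbest_position)
        self.state_ = state
        best = Candidate(state.gbest_position.copy(), state.gbest_fitness, True)
        return best, trace


@dataclass
class NestSet:
    """Cuckoo-search population: one egg (solution) per nest, plus the
    best nest ever seen (elitism) and the discovery probability Pa."""

    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    pa: float


class CuckooSearch(_Optimizer):
    """Cuckoo search with Lévy flights.

    Per generation: each nest emits a Lévy-flight proposal biased by the
    best nest; the proposal replaces a *randomly chosen* nest if fitter.
    Then a fraction ``Pa`` of the worst nests is abandoned and re-seeded
    uniformly at random.  The best solution ever seen is preserved.
    """

    def __init__(self, space, pop_size=20, n_iters=100, pa=0.25,
                 levy_lambda=1.5, step_scale=0.01, seed=0):
        super().__init__(space, pop_size, n_iters, seed)
        if not 0.0 < pa < 1.0:
            raise ValueError("Pa must lie in (0, 1)")
        self.pa = pa
        self.levy_lambda = levy_lambda
        self.alpha = step_scale * space.ranges  # per-dimension step scale
        self.n_abandoned = int(round(pa * pop_size))

    def init_state(self, objective, rng) -> NestSet:
        positions = self.space.sample(rng, self.pop_size)
        fitness = np.array([objective(z) for z in positions])
        k = int(np.argmax(fitness))
        return NestSet(positions, fitness, positions[k].copy(), float(fitness[k]), self.pa)

    def step(self, nests: NestSet, objective, rng) -> NestSet:
        """One CS generation, in place."""
        bounds = (self.space.lower, self.space.upper)
        n = self.pop_size
        for i in range(n):
            if np.allclose(nests.positions[i], nests.best_position):
                # zero drift: perturb with a plain Lévy step so the best
                # region keeps being explored
                step = mantegna_steps(rng, self.levy_lambda, nests.positions[i].shape)
                proposal = np.clip(
                    nests.positions[i] + self.alpha * step, *bounds
                )
            else:
                proposal = levy_flight(
                    nests.positions[i], nests.best_position, rng,
                    alpha=self.alpha, lam=self.levy_lambda, bounds=bounds,
                )
            fit = objective(proposal)
            j = int(rng.integers(n))
            if self._improves(fit, nests.fitness[j]):
                nests.positions[j] = proposal
                nests.fitness[j] = fit
            if self._improves(fit, nests.best_fitness):
                nests.best_position = proposal.copy()
                nests.best_fitness = fit
        # abandonment: re-seed the worst Pa fraction (never the current best)
        m = self.n_abandoned
        if m > 0:
            order = np.argsort(nests.fitness)  # worst first
            worst = order[: min(m, n - 1)]
            fresh = self.space.sample(rng, len(worst))
            fresh_fit = np.array([objective(z) for z in fresh])
            nests.positions[worst] = fresh
            nests.fitness[worst] = fresh_fit
            k = int(np.argmax(fresh_fit))
            if self._improves(fresh_fit[k], nests.best_fitness):
                nests.best_position = fresh[k].copy()
                nests.best_fitness = float(fresh_fit[k])
        return nests

    def run(self, objective) -> tuple[Candidate, ConvergenceTrace]:
        rng = np.random.default_rng(self.seed)
        f = self._make_objective(objective)
        nests = self.init_state(f, rng)
        trace = ConvergenceTrace()
        for _ in range(self.n_iters):
            self.step(nests, f, rng)
            trace.append(nests.best_fitness, nests.fitness.mean(), nests.best_position)
        self.state_ = nests
        best = Candidate(nests.best_position.copy(), nests.best_fitness, True)
        return best, trace


class RealCodedGA(_Optimizer):
    """Real-coded GA: roulette selection, arithmetic crossover, Gaussian
    per-gene mutation, 1-elitism.

    Selection is roulette on quadratically scaled, min-shifted fitness
    (an all-equal population falls back to uniform).  Crossover blends
    each parent pair gene-wise with fresh uniform weights with probability
    ``p_c``.  Mutation adds ``N(0, sigma_g^2)`` per gene with probability
    ``p_m``, where ``sigma_g`` starts at ``sigma_frac * range`` and halves
    every ``anneal_halflife`` generations (coarse early, fine late).  One
    random immigrant per generation guards against premature collapse,
    and 1-elitism re-inserts the previous best over the worst child.
    """

    def __init__(self, space, pop_size=20, n_iters=100, p_c=0.5, p_m=0.005,
                 mutation_sigma_frac=0.1, anneal_halflife=25, seed=0):
        super().__init__(space, pop_size, n_iters, seed)
        if pop_size % 2:
            raise ValueError("population size must be even for pairing")
        self.p_c, self.p_m = p_c, p_m
        self.mut_sigma = mutation_sigma_frac * space.ranges
        self.anneal_halflife = anneal_halflife

    def _select(self, fitness: np.ndarray, rng) -> np.ndarray:
        w = (fitness - fitness.min()) ** 2
        total = w.sum()
        if total <= 0:
            p = np.full(len(fitness), 1.0 / len(fitness))
        else:
            p = w / total
        return rng.choice(len(fitness), size=len(fitness), p=p)

    def step(self, positions: np.ndarray, fitness: np.ndarray, objective, rng,
             generation: int = 0) -> tuple[np.ndarray, np.ndarray]:
        elite_idx = int(np.argmax(fitness))
        elite_pos, elite_fit = positions[elite_idx].copy(), float(fitness[elite_idx])
        parents = positions[self._select(fitness, rng)]
        children = parents.copy()
        n_dims = positions.shape[1]
        for a in range(0, self.pop_size, 2):
            if rng.uniform() < self.p_c:
                u = rng.uniform(size=n_dims)
                p1, p2 = parents[a].copy(), parents[a + 1].copy()
                children[a] = u * p1 + (1.0 - u) * p2
                children[a + 1] = (1.0 - u) * p1 + u * p2
        sigma = self.mut_sigma * 0.5 ** (generation / self.anneal_halflife)
        mutate = rng.uniform(size=children.shape) < self.p_m
        noise = rng.normal(0.0, 1.0, size=children.shape) * sigma
        children = self.space.clip(children + mutate * noise)
        children[-1] = self.space.sample(rng, 1)[0]  # random immigrant
        child_fit = np.array([objective(z) for z in children])
        # 1-elitism: the previous best replaces the worst child
        worst = int(np.argmin(child_fit))
        if self._improves(elite_fit, child_fit[worst]):
            children[worst] = elite_pos
            child_fit[worst] = elite_fit
        return children, child_fit

    def run(self, objective) -> tuple[Candidate, ConvergenceTrace]:
        rng = np.random.default_rng(self.seed)
        f = self._make_objective(objective)
        positions = self.space.sample(rng, self.pop_size)
        fitness = np.array([f(z) for z in positions])
        best = Candidate(positions[int(np.argmax(fitness))].copy(), float(fitness.max()), True)
        trace = ConvergenceTrace()
        for gen in range(self.n_iters):
            positions, fitness = self.step(positions, fitness, f, rng, gen)
            k = int(np.argmax(fitness))
            if self._improves(float(fitness[k]), best.fitness):
                best = Candidate(positions[k].copy(), float(fitness[k]), True)
            trace.append(best.fitness, fitness.mean(), best.position)
        self.state_ = (positions, fitness)
        return best, trace


class HybridCSPSO(_Optimizer):
    """Two-stage search: cuckoo search seeds a particle swarm.

    Stage 1 runs CS for ``round(cs_fraction * total_iters)`` generations to
    locate promising hyperparameter regions with Lévy-flight exploration.
    Stage 2 initializes a PSO swarm from the final nest positions
    (``transfer="population"``, default) or from the single best nest plus
    fresh random particles (``transfer="best"``), sets the swarm's global
    best to the CS best, zeroes all velocities, and refines for the
    remaining generations.  The returned trace concatenates both stages.
    """

    def __init__(self, space, pop_size=20, n_iters=100, cs_fraction=0.5,
                 pa=0.25, c1=1.5, c2=1.7, levy_lambda=1.5, step_scale=0.01,
                 inertia="linear", vmax_frac=0.2, transfer="population", seed=0):
        super().__init__(space, pop_size, n_iters, seed)
        if not 0.0 < cs_fraction < 1.0:
            raise ValueError("cs_fraction must lie in (0, 1)")
        if transfer not in ("population", "best"):
            raise ValueError("transfer must be 'population' or 'best'")
        self.cs_iters = max(1, int(round(cs_fraction * n_iters)))
        self.pso_iters = n_iters - self.cs_iters
        seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
        self.cs = CuckooSearch(space, pop_size, self.cs_iters, pa=pa,
                               levy_lambda=levy_lambda, step_scale=step_scale,
                               seed=int(seeds[0]))
        self.pso = ParticleSwarm(space, pop_size, self.pso_iters, c1=c1, c2=c2,
                                 inertia=inertia, vmax_frac=vmax_frac,
                                 seed=int(seeds[1]))
        self.transfer = transfer

    def run(self, objective) -> tuple[Candidate, ConvergenceTrace]:
        cs_best, trace = self.cs.run(objective)
        self.n_evaluations += self.cs.n_evaluations
        nests = self.cs.state_

        if self.transfer == "population":
            positions = nests.positions.copy()
            fitness = nests.fitness.copy()
        else:
            rng = np.random.default_rng(self.pso.seed + 1)
            positions = self.space.sample(rng, self.pop_size)
            positions[0] = cs_best.position
            fitness = np.full(self.pop_size, -np.inf)
            fitness[0] = cs_best.fitness
            for i in range(1, self.pop_size):
                self.n_evaluations += 1
                fitness[i] = float(objective(self.space.decode(positions[i])))

        if self.pso_iters > 0:
            pso_best, pso_trace = self.pso.run(
                objective, init_positions=positions,
                init_fitness=fitness, init_gbest=cs_best,
            )
            self.n_evaluations += self.pso.n_evaluations
            trace.extend(pso_trace)
            best = pso_best if pso_best.fitness >= cs_best.fitness else cs_best
        else:
            best = cs_best
        self.state_ = self.pso.state_
        return best, trace


def optimize_hybrid(space: SearchSpace, objective, pop_size=20, total_iters=100,
                    cs_fraction=0.5, pa=0.25, c1=1.5, c2=1.7, seed=0,
                    transfer="population") -> tuple[Candidate, ConvergenceTrace]:
    """Functional wrapper around :class:`HybridCSPSO`."""
    opt = HybridCSPSO(space, pop_size=pop_size, n_iters=total_iters,
                      cs_fraction=cs_fraction, pa=pa, c1=c1, c2=c2,
                      transfer=transfer, seed=seed)
    return opt.run(objective)
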