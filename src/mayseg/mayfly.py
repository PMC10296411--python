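"""Mayfly optimization (MFO): a swarm metaheuristic for continuous maximization.

The swarm holds equal numbers of male and female agents.  Every agent moves by

    loc(t+1) = loc(t) + velocity(t+1)

Males are attracted to their personal best and the global best with an
exponentially decaying visibility term ``exp(-beta * r^2)``; the current best
male instead performs a "nuptial dance" — a uniform random velocity kick that
sustains exploration.  Each female is paired with the same-ranked male and
flies toward him when he is fitter, otherwise she takes a random walk.  After
the move, the better half of the ranked male/female pairs mate: offspring are
convex combinations of the parents with a Gaussian mixing weight, and replace
the worst agents of each sex.  The dance and random-walk amplitudes decay
geometrically so the swarm settles.

Everything is seeded and deterministic; positions are clamped to the search
box after every move.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["MFOConfig", "MayflyPopulation", "Offspring", "initialize", "mate", "step", "optimize"]


@dataclass(frozen=True)
class MFOConfig:
    """Mayfly-swarm hyperparameters.

    ``bounds`` is a sequence of (lower, upper) pairs, one per dimension.
    The male and female swarms have equal size by construction.
    """

    bounds: tuple[tuple[float, float], ...]
    n_males: int = 20
    n_females: int = 20
    n_iterations: int = 100
    a1: float = 1.0  # attraction to personal best
    a2: float = 1.5  # attraction to global best
    a3: float = 1.5  # female attraction to paired male
    beta: float = 2.0  # visibility exponent
    dance: float = 5.0  # nuptial-dance amplitude (best male)
    fl: float = 1.0  # female random-walk amplitude
    gravity: float = 0.8  # velocity damping
    dance_damp: float = 0.99
    fl_damp: float = 0.99
    mating_p_mean: float = 0.5
    mating_p_std: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_males != self.n_females:
            raise ValueError("male and female swarms must be the same size")
        if not (0 < self.gravity <= 1):
            raise ValueError("gravity must be in (0, 1]")
        for damp in (self.dance_damp, self.fl_damp):
            if not (0 < damp <= 1):
                raise ValueError("damping factors must be in (0, 1]")
        for lo, hi in self.bounds:
            if not lo < hi:
                raise ValueError(f"degenerate bound ({lo}, {hi})")

    @property
    def n_dims(self) -> int:
        return len(self.bounds)

    def lower(self) -> np.ndarray:
        return np.array([b[0] for b in self.bounds])

    def upper(self) -> np.ndarray:
        return np.array([b[1] for b in self.bounds])


@dataclass
class MayflyPopulation:
    male_positions: np.ndarray  # (n_males, dims)
    female_positions: np.ndarray
    male_velocities: np.ndarray
    female_velocities: np.ndarray
    male_values: np.ndarray  # (n_males,)
    female_values: np.ndarray
    pbest_positions: np.ndarray  # per-male personal best
    pbest_values: np.ndarray
    gbest_position: np.ndarray
    gbest_value: float
    rng: np.random.Generator
    dance: float
    fl: float


@dataclass(frozen=True)
class Offspring:
    child1: np.ndarray
    child2: np.ndarray


def mate(male: np.ndarray, female: np.ndarray, P: float) -> Offspring:
    """Convex-combination crossover: each child lies between its parents
    coordinate-wise when ``P`` is in [0, 1]."""
    male = np.asarray(male, dtype=float)
    female = np.asarray(female, dtype=float)
    if male.shape != female.shape:
        raise ValueError(f"parent dimension mismatch: {male.shape} vs {female.shape}")
    child1 = P * male + (1.0 - P) * female
    child2 = P * female + (1.0 - P) * male
    return Offspring(child1=child1, child2=child2)


def _evaluate(objective, positions: np.ndarray) -> np.ndarray:
    vals = np.array([float(objective(x)) for x in positions])
    if not np.all(np.isfinite(vals)):
        bad = positions[~np.isfinite(vals)][0]
        raise ValueError(f"objective not finite at {bad}")
    return vals


def initialize(config: MFOConfig, objective) -> MayflyPopulation:
    """Uniform random positions in the box, zero velocities, bests evaluated.

    The global best is the best initial male (males lead the search; females
    are pulled toward them)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.lower(), config.upper()
    shape = (config.n_males, config.n_dims)
    males = rng.uniform(lo, hi, size=shape)
    females = rng.uniform(lo, hi, size=shape)
    mv = _evaluate(objective, males)
    fv = _evaluate(objective, females)
    best = int(np.argmax(mv))
    return MayflyPopulation(
        male_positions=males,
        female_positions=females,
        male_velocities=np.zeros(shape),
        female_velocities=np.zeros(shape),
        male_values=mv,
        female_values=fv,
        pbest_positions=males.copy(),
        pbest_values=mv.copy(),
        gbest_position=males[best].copy(),
        gbest_value=float(mv[best]),
        rng=rng,
        dance=config.dance,
        fl=config.fl,
    )


def _clamp(x: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> np.ndarray:
    return np.clip(x, lo, hi)


def _truncated_gauss(rng: np.random.Generator, mean: float, std: float) -> float:
    # resampling truncation to [0, 1]; keeps offspring on the parent segment
    for _ in range(100):
        p = rng.normal(mean, std)
        if 0.0 <= p <= 1.0:
            return float(p)
    return float(np.clip(p, 0.0, 1.0))


def step(pop: MayflyPopulation, config: MFOConfig, objective, iteration: int = 0) -> MayflyPopulation:
    """One MFO generation: velocity updates, moves, mating, replacement.

    Mutates and returns ``pop``.  The global best never degrades (elitism:
    the best record is only overwritten by a better value).
    """
    rng = pop.rng
    lo, hi = config.lower(), config.upper()
    n, d = pop.male_positions.shape
    g = config.gravity
    span = hi - lo  # attraction distances in box-normalized coordinates,
    # so the visibility term exp(-beta r^2) is scale-invariant

    # --- male velocities ---
    best_male = int(np.argmax(pop.male_values))
    for i in range(n):
        x = pop.male_positions[i]
        v = pop.male_velocities[i]
        if i == best_male:
            r = rng.uniform(-1.0, 1.0, size=d)
            v_new = g * v + pop.dance * r
        else:
            rp = (x - pop.pbest_positions[i]) / span
            rg = (x - pop.gbest_position) / span
            v_new = (
                g * v
                + config.a1 * np.exp(-config.beta * (rp @ rp)) * (pop.pbest_positions[i] - x)
                + config.a2 * np.exp(-config.beta * (rg @ rg)) * (pop.gbest_position - x)
            )
        pop.male_velocities[i] = v_new

    # --- female velocities: ranked pairing, fly to the male if he is fitter ---
    male_rank = np.argsort(-pop.male_values, kind="stable")
    female_rank = np.argsort(-pop.female_values, kind="stable")
    for k in range(n):
        i_m, i_f = int(male_rank[k]), int(female_rank[k])
        xf = pop.female_positions[i_f]
        vf = pop.female_velocities[i_f]
        if pop.male_values[i_m] > pop.female_values[i_f]:
            rmf = (xf - pop.male_positions[i_m]) / span
            v_new = g * vf + config.a3 * np.exp(-config.beta * (rmf @ rmf)) * (
                pop.male_positions[i_m] - xf
            )
        else:
            v_new = g * vf + pop.fl * rng.uniform(-1.0, 1.0, size=d)
        pop.female_velocities[i_f] = v_new

    # --- moves (loc <- loc + velocity), clamped to the box ---
    pop.male_positions = _clamp(pop.male_positions + pop.male_velocities, lo, hi)
    pop.female_positions = _clamp(pop.female_positions + pop.female_velocities, lo, hi)
    pop.male_values = _evaluate(objective, pop.male_positions)
    pop.female_values = _evaluate(objective, pop.female_positions)

    # --- mating: top half of ranked pairs produce offspring ---
    male_rank = np.argsort(-pop.male_values, kind="stable")
    female_rank = np.argsort(-pop.female_values, kind="stable")
    n_pairs = n // 2
    sons, daughters = [], []
    for k in range(n_pairs):
        P = _truncated_gauss(rng, config.mating_p_mean, config.mating_p_std)
        off = mate(pop.male_positions[male_rank[k]], pop.female_positions[female_rank[k]], P)
        sons.append(off.child1)
        daughters.append(off.child2)

    # offspring replace the worst-ranked agents of each sex
    if n_pairs:
        sons = _clamp(np.array(sons), lo, hi)
        daughters = _clamp(np.array(daughters), lo, hi)
        son_vals = _evaluate(objective, sons)
        daughter_vals = _evaluate(objective, daughters)
        worst_males = male_rank[::-1][:n_pairs]
        worst_females = female_rank[::-1][:n_pairs]
        pop.male_positions[worst_males] = sons
        pop.male_velocities[worst_males] = 0.0
        pop.male_values[worst_males] = son_vals
        pop.female_positions[worst_females] = daughters
        pop.female_velocities[worst_females] = 0.0
        pop.female_values[worst_females] = daughter_vals

    # --- refresh bests ---
    improved = pop.male_values > pop.pbest_values
    pop.pbest_positions[improved] = pop.male_positions[improved]
    pop.pbest_values[improved] = pop.male_values[improved]
    best = int(np.argmax(pop.male_values))
    if pop.male_values[best] > pop.gbest_value:
        pop.gbest_value = float(pop.male_values[best])
        pop.gbest_position = pop.male_positions[best].copy()

    # --- damp exploration amplitudes ---
    pop.dance *= config.dance_damp
    pop.fl *= config.fl_damp
    return pop


def optimize(config: MFOConfig, objective) -> tuple[np.ndarray, float, np.ndarray]:
    """Run the full MFO loop.

    Returns the best position, its objective value, and the per-iteration
    trace of best values (monotone non-decreasing, length ``n_iterations``).
    """
    pop = initialize(config, objective)
    trace = np.empty(config.n_iterations)
    for it in range(config.n_iterations):
        step(pop, config, objective, iteration=it)
        trace[it] = pop.gbest_value
    return pop.gbest_position.copy(), pop.gbest_value, trace
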