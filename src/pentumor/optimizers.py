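"""Population metaheuristics: emperor penguin optimizer and multileader optimizer.

Both algorithms minimize a bounded continuous objective and share one
contract (:class:`ObjectiveSpec`): a total evaluation function over an
axis-aligned box.  Positions are clamped to the box after every update, a
single seeded generator drives each run with a documented draw order
(member-major, dimension-minor), and the best-so-far trace is
non-increasing by construction.

Emperor penguin optimizer (EPO)
    Models huddling: a temperature profile theta' grows over iterations, a
    social-force function ``S(x) = (f e^(-x/l) - e^(-x))^2`` modulates the
    pull toward the best agent, and each member moves to
    ``X_best - U * D`` where ``U`` mixes the temperature term with the
    member's distance grid to the best and ``D`` is the force-weighted
    distance.

Multileader optimizer (MLO)
    The population is sorted by fitness; the best nL members act as
    leaders.  Each member updates each coordinate toward a roulette-chosen
    leader, then makes a shrinking random move proportional to its own
    coordinate; both phases use greedy acceptance, so a member's fitness
    never worsens.

The MLT wrapper (:func:`mlt_objective`) negates the between-class variance
so threshold search fits the minimization convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .mlt import Histogram, decode_thresholds, otsu_objective


class ObjectiveError(ValueError):
    """Raised for invalid objective specifications or non-finite fitness."""


@dataclass
class ObjectiveSpec:
    """A bounded continuous minimization problem.

    evaluate : callable mapping a length-``dimension`` vector to a float
    bounds : (low, high) per dimension, shape (dimension, 2)
    """

    evaluate: Callable[[np.ndarray], float]
    bounds: np.ndarray
    dimension: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bounds, dtype=float)
        if b.shape != (self.dimension, 2):
            raise ObjectiveError(
                f"bounds must have shape ({self.dimension}, 2), got {b.shape}"
            )
        if np.any(b[:, 0] >= b[:, 1]):
            raise ObjectiveError("each lower bound must be below its upper bound")
        self.bounds = b

    @property
    def low(self) -> np.ndarray:
        return self.bounds[:, 0]

    @property
    def high(self) -> np.ndarray:
        return self.bounds[:, 1]


@dataclass(frozen=True)
class EPOParams:
    population_size: int = 30
    max_iterations: int = 500
    movement: float = 2.0  # M, fixed to 2 in the source formulation
    social_f: float = 2.0
    social_l: float = 1.5
    theta_max: float = 50.0  # cap on the temperature profile near its pole
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ObjectiveError("population_size must be >= 2")
        if self.max_iterations < 1:
            raise ObjectiveError("max_iterations must be >= 1")
        if self.social_f <= 1:
            raise ObjectiveError("social_f must exceed 1")


@dataclass(frozen=True)
class MLOParams:
    population_size: int = 30
    n_leaders: int = 3
    max_iterations: int = 200
    seed: int = 0

    def validate(self) -> None:
        if self.population_size < 2:
            raise ObjectiveError("population_size must be >= 2")
        if not (1 <= self.n_leaders <= self.population_size):
            raise ObjectiveError("n_leaders must lie in [1, population_size]")
        if self.max_iterations < 1:
            raise ObjectiveError("max_iterations must be >= 1")


@dataclass
class OptimizeResult:
    """Best solution plus per-iteration best/mean fitness traces."""

    best_position: np.ndarray
    best_fitness: float
    best_trace: np.ndarray
    mean_trace: np.ndarray

    def trace_rows(self) -> list[tuple[int, float, float]]:
        return [
            (i, float(b), float(m))
            for i, (b, m) in enumerate(zip(self.best_trace, self.mean_trace))
        ]


def _evaluate_population(obj: ObjectiveSpec, positions: np.ndarray) -> np.ndarray:
    fits = np.empty(positions.shape[0])
    for i, x in enumerate(positions):
        fits[i] = _evaluate_one(obj, x)
    return fits


def _evaluate_one(obj: ObjectiveSpec, x: np.ndarray) -> float:
    val = float(obj.evaluate(x))
    if not math.isfinite(val):
        raise ObjectiveError(f"objective returned non-finite value {val} at {x}")
    return val


def social_force(x: np.ndarray, f: float = 2.0, l: float = 1.5) -> np.ndarray:
    """EPO social force ``S(x) = (f e^(-x/l) - e^(-x))^2``, elementwise."""
    x = np.abs(x)
    return (f * np.exp(-x / l) - np.exp(-x)) ** 2


def temperature_profile(theta: float, iteration: int, max_iterations: int,
                        theta_max: float = 50.0) -> float:
    """EPO temperature profile ``theta' = theta - Itermax / (C - Itermax)``.

    Implemented literally for ``C < Itermax`` and capped at ``theta_max``
    to sidestep the pole at ``C = Itermax``.
    """
    if iteration >= max_iterations:
        return theta_max
    value = theta - max_iterations / (iteration - max_iterations)
    return min(value, theta_max)


def epo_optimize(obj: ObjectiveSpec, params: EPOParams) -> OptimizeResult:
    """Minimize ``obj`` with the emperor penguin optimizer.

    Per iteration C: one uniform draw R sets theta (0 if R > 0.5 else 1),
    theta' follows the temperature profile, and every member moves to
    ``X_best - U * D`` with
    ``U = M * (theta' + |X_best - X|) * Rand() - theta'``
    (per-dimension draws), ``V = Rand()``,
    ``D = |S(U) * X_best - V * X|``.  Positions are clamped to the box and
    the global best is tracked across iterations.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, m = params.population_size, obj.dimension
    pos = rng.uniform(obj.low, obj.high, size=(n, m))
    fits = _evaluate_population(obj, pos)
    best_i = int(np.argmin(fits))
    best_pos, best_fit = pos[best_i].copy(), float(fits[best_i])
    best_trace, mean_trace = [best_fit], [float(fits.mean())]

    for c in range(1, params.max_iterations + 1):
        r = rng.uniform()
        theta = 0.0 if r > 0.5 else 1.0
        theta_p = temperature_profile(theta, c, params.max_iterations, params.theta_max)
        x_grid = np.abs(best_pos - pos)
        u = (
            params.movement * (theta_p + x_grid) * rng.uniform(size=(n, m))
            - theta_p
        )
        v = rng.uniform(size=(n, m))
        s = social_force(u, params.social_f, params.social_l)
        d = np.abs(s * best_pos - v * pos)
        pos = np.clip(best_pos - u * d, obj.low, obj.high)
        fits = _evaluate_population(obj, pos)
        it_best = int(np.argmin(fits))
        if fits[it_best] < best_fit:
            best_fit = float(fits[it_best])
            best_pos = pos[it_best].copy()
        best_trace.append(best_fit)
        mean_trace.append(float(fits.mean()))

    return OptimizeResult(best_pos, best_fit, np.array(best_trace), np.array(mean_trace))


def normalized_fitness(fitnesses: np.ndarray) -> np.ndarray:
    """MLO normalized fitness ``(fit_i - max fit) / sum_j (fit_j - max fit)``.

    Larger values mark better (smaller-fitness) members; the worst member
    gets 0.  When every fitness is equal the normalization is undefined and
    a uniform vector is returned (limit behavior).
    """
    fits = np.asarray(fitnesses, dtype=float)
    shifted = fits - fits.max()
    denom = shifted.sum()
    if denom == 0.0:
        return np.full(fits.shape, 1.0 / fits.size)
    return shifted / denom


def leader_probabilities(
    sorted_fitnesses: np.ndarray, n_leaders: int
) -> tuple[np.ndarray, np.ndarray]:
    """Selection probabilities and cumulative bands for the top-nL leaders.

    ``sorted_fitnesses`` is the ascending population fitness vector; the
    first ``n_leaders`` entries are the leaders.  Returns ``(P, C)`` with
    ``P_l`` proportional to the leader's normalized fitness and ``C`` its
    cumulative sum (last entry 1).  Degenerate cases (all-equal fitness,
    or all leaders tied at the population maximum) fall back to uniform.
    """
    fits = np.asarray(sorted_fitnesses, dtype=float)
    if not (1 <= n_leaders <= fits.size):
        raise ObjectiveError("n_leaders must lie in [1, population size]")
    norm = normalized_fitness(fits)
    leader_norm = norm[:n_leaders]
    total = leader_norm.sum()
    if total <= 0.0 or not np.isfinite(total):
        p = np.full(n_leaders, 1.0 / n_leaders)
    else:
        p = leader_norm / total
    return p, np.cumsum(p)


def roulette_select(cumulative: np.ndarray, r: float) -> int:
    """Roulette-wheel pick: the 1-based rank of the smallest l with r <= C_l."""
    c = np.asarray(cumulative, dtype=float)
    if c.ndim != 1 or c.size == 0:
        raise ObjectiveError("cumulative vector must be non-empty and 1-D")
    if np.any(np.diff(c) < 0):
        raise ObjectiveError("cumulative vector must be non-decreasing")
    if abs(c[-1] - 1.0) > 1e-9:
        raise ObjectiveError(f"cumulative vector must end at 1, got {c[-1]}")
    if not (0.0 <= r <= 1.0):
        raise ObjectiveError(f"r must lie in [0, 1], got {r}")
    return int(min(np.searchsorted(c, r, side="left"), c.size - 1)) + 1


def mlo_optimize(
    obj: ObjectiveSpec,
    params: MLOParams,
    initial_positions: Optional[np.ndarray] = None,
) -> OptimizeResult:
    """Minimize ``obj`` with the multileader optimizer.

    Per iteration t: the population is sorted ascending by fitness and the
    first nL members become leaders with roulette bands from their
    normalized fitness.  Each member then (1) proposes, per dimension, a
    move toward a roulette-chosen leader,
    ``x_new = x + rand * (leader - 2x)``, accepted only if fitness does not
    worsen, and (2) makes a local move
    ``x_new = x + 2(1 - t/T) * (-0.2 + 0.4 rand) * x`` under the same
    greedy rule.  ``initial_positions`` may seed the first rows of the
    population (e.g. a gradient warm start).
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, m = params.population_size, obj.dimension
    pos = rng.uniform(obj.low, obj.high, size=(n, m))
    if initial_positions is not None:
        init = np.atleast_2d(np.asarray(initial_positions, dtype=float))
        if init.shape[1] != m:
            raise ObjectiveError("initial_positions dimension mismatch")
        k = min(init.shape[0], n)
        pos[:k] = np.clip(init[:k], obj.low, obj.high)
    fits = _evaluate_population(obj, pos)
    best_i = int(np.argmin(fits))
    best_pos, best_fit = pos[best_i].copy(), float(fits[best_i])
    best_trace, mean_trace = [best_fit], [float(fits.mean())]
    t_max = params.max_iterations

    for t in range(1, t_max + 1):
        order = np.argsort(fits, kind="stable")
        leaders = pos[order[: params.n_leaders]]
        _, cum = leader_probabilities(fits[order], params.n_leaders)

        # phase 1: per-dimension roulette move toward a leader
        for i in range(n):
            r_sel = rng.uniform(size=m)
            step = rng.uniform(size=m)
            idx = np.minimum(
                np.searchsorted(cum, r_sel, side="left"), params.n_leaders - 1
            )
            lam = leaders[idx, np.arange(m)]
            proposal = np.clip(pos[i] + step * (lam - 2.0 * pos[i]), obj.low, obj.high)
            f_new = _evaluate_one(obj, proposal)
            if f_new <= fits[i]:
                pos[i], fits[i] = proposal, f_new

        # phase 2: shrinking local move proportional to the coordinate
        scale = local_step_scale(t, t_max)
        for i in range(n):
            u = rng.uniform(size=m)
            proposal = np.clip(
                pos[i] + scale * (-0.2 + 0.4 * u) * pos[i], obj.low, obj.high
            )
            f_new = _evaluate_one(obj, proposal)
            if f_new <= fits[i]:
                pos[i], fits[i] = proposal, f_new

        it_best = int(np.argmin(fits))
        if fits[it_best] < best_fit:
            best_fit = float(fits[it_best])
            best_pos = pos[it_best].copy()
        best_trace.append(best_fit)
        mean_trace.append(float(fits.mean()))

    return OptimizeResult(best_pos, best_fit, np.array(best_trace), np.array(mean_trace))


def local_step_scale(t: int, t_max: int) -> float:
    """MLO local-move shrink factor ``2 (1 - t / T)``; zero at the final step."""
    return 2.0 * (1.0 - t / t_max)


# --------------------------------------------------------------------------
# benchmark objectives (analytic minima; used by tests and the CLI)

def sphere(dim: int, half_width: float = 5.0) -> ObjectiveSpec:
    """``sum x_i^2`` on ``[-half_width, half_width]^dim``; minimum 0 at 0."""
    bounds = np.tile([-half_width, half_width], (dim, 1))
    return ObjectiveSpec(lambda x: float(np.dot(x, x)), bounds, dim)


def rastrigin(dim: int, half_width: float = 5.12) -> ObjectiveSpec:
    """Multimodal Rastrigin function; minimum 0 at the origin."""
    bounds = np.tile([-half_width, half_width], (dim, 1))

    def f(x: np.ndarray) -> float:
        return float(10.0 * dim + np.sum(x**2 - 10.0 * np.cos(2 * np.pi * x)))

    return ObjectiveSpec(f, bounds, dim)


def shifted_quadratic(dim: int, shift: float = 1.5, half_width: float = 5.0) -> ObjectiveSpec:
    """``sum (x_i - shift)^2``; minimum 0 at the shift vector."""
    bounds = np.tile([-half_width, half_width], (dim, 1))
    return ObjectiveSpec(lambda x: float(np.sum((x - shift) ** 2)), bounds, dim)


def benchmark_objectives(dim: int = 5) -> dict[str, ObjectiveSpec]:
    """Named suite of analytic test objectives."""
    return {
        "sphere": sphere(dim),
        "rastrigin": rastrigin(dim),
        "shifted_quadratic": shifted_quadratic(dim),
    }


def mlt_objective(hist: Histogram, k: int) -> ObjectiveSpec:
    """Threshold search as a minimization problem: negated Otsu criterion.

    A candidate vector of K reals in ``[1, L-1]`` decodes (sort, round,
    de-collide) to a valid threshold set; fitness is ``-F``.
    """
    bounds = np.tile([1.0, float(hist.levels - 1)], (k, 1))

    def f(x: np.ndarray) -> float:
        ts = decode_thresholds(x, hist.levels)
        return -otsu_objective(hist, ts).between_class_variance

    return ObjectiveSpec(f, bounds, k)
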