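"""Hybrid grey-wolf / particle-swarm binary feature selection.

The optimizer searches the space of nonempty binary feature masks for
the subset maximizing the wrapper fitness

    F = 0.9 * Acc + 0.1 * (1 - Fr)

where ``Acc`` is the internal cross-validated accuracy of the downstream
classifier on the selected columns and ``Fr = |mask| / d`` is the
fraction of features kept, so the second term rewards parsimony.

The hybridization keeps the grey-wolf elitist leader hierarchy — the
three best agents (alpha, beta, delta) are re-ranked every iteration and
retained unless strictly beaten — while movement follows the PSO
velocity rule

    V(t+1) = w V(t) + c1 r1 (Pbest - X) + c2 r2 (Gbest - X)
    X(t+1) = X(t) + V(t+1)

with per-dimension uniform r1, r2, inertia w annealed linearly from 0.8
to 0.4, and Gbest the mean of the three leader positions (the grey-wolf
"follow the leaders' centroid" behavior; set ``leader_combine="alpha"``
to follow the alpha alone).  Positions are continuous scores; masks are
drawn per dimension with the S-shaped transfer probability sigmoid(x),
velocities clamped to +-6 so the sigmoid stays responsive.  Initial
positions sit at a softened logit (+-init_scale) of the random initial
mask rather than the saturated +-inf logit, which keeps early bit-flip
probabilities high enough for genuine exploration.  Leaders are frozen
within an iteration; fitness is cached per mask so it is a pure
function of the mask for a fixed evaluator seed.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Protocol

import numpy as np

from .exceptions import ConfigError, FitnessError


@dataclasses.dataclass(frozen=True)
class HgwoPsoConfig:
    """Optimizer hyperparameters (defaults follow the benchmark setting)."""

    n_wolves: int = 10
    iterations: int = 100
    w_start: float = 0.8
    w_end: float = 0.4
    c1: float = 2.0
    c2: float = 2.0
    acc_weight: float = 0.9
    parsimony_weight: float = 0.1
    v_clamp: float = 6.0
    init_scale: float = 1.0
    leader_combine: str = "mean3"  # or "alpha"
    binarize: str = "stochastic"  # or "threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wolves < 4:
            raise ConfigError("need >= 4 wolves (alpha, beta, delta + followers)")
        if self.iterations < 1:
            raise ConfigError("iterations must be >= 1")
        if abs(self.acc_weight + self.parsimony_weight - 1.0) > 1e-12:
            raise ConfigError("acc_weight + parsimony_weight must equal 1")
        if self.leader_combine not in ("alpha", "mean3"):
            raise ConfigError("leader_combine must be 'alpha' or 'mean3'")
        if self.binarize not in ("stochastic", "threshold"):
            raise ConfigError("binarize must be 'stochastic' or 'threshold'")


@dataclasses.dataclass(frozen=True)
class FitnessResult:
    """Wrapper-fitness components for one mask."""

    acc: float
    frac_selected: float
    fitness: float
    valid: bool = True


class AccuracyEvaluator(Protocol):
    """Anything exposing ``accuracy(mask) -> float`` on training rows only."""

    def accuracy(self, mask: np.ndarray) -> float: ...


@dataclasses.dataclass
class Wolf:
    """One search agent: continuous position/velocity plus binary mask."""

    position: np.ndarray
    velocity: np.ndarray
    mask: np.ndarray
    fitness: FitnessResult | None = None
    pbest_position: np.ndarray | None = None
    pbest_mask: np.ndarray | None = None
    pbest_fitness: FitnessResult | None = None


@dataclasses.dataclass
class HgwoPsoResult:
    """Outcome of one optimizer run."""

    mask: np.ndarray
    fitness: FitnessResult
    history: list[float]
    n_evaluations: int


def fitness(
    mask: np.ndarray,
    evaluator: AccuracyEvaluator,
    acc_weight: float = 0.9,
    parsimony_weight: float = 0.1,
    cache: dict[bytes, FitnessResult] | None = None,
) -> FitnessResult:
    """Evaluate F = acc_weight * Acc + parsimony_weight * (1 - Fr).

    An empty mask is never sent to the evaluator; it yields fitness 0
    flagged invalid.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return FitnessResult(acc=0.0, frac_selected=0.0, fitness=0.0, valid=False)
    key = np.packbits(mask).tobytes()
    if cache is not None and key in cache:
        return cache[key]
    acc = float(evaluator.accuracy(mask))
    if not 0.0 <= acc <= 1.0:
        raise FitnessError(f"evaluator accuracy {acc} outside [0, 1]")
    fr = float(mask.sum()) / mask.size
    res = FitnessResult(
        acc=acc,
        frac_selected=fr,
        fitness=acc_weight * acc + parsimony_weight * (1.0 - fr),
    )
    if cache is not None:
        cache[key] = res
    return res


def inertia(t: int, T: int, w_start: float = 0.8, w_end: float = 0.4) -> float:
    """Linearly annealed inertia weight: w_start at t=0, w_end at t=T."""
    return w_start + (w_end - w_start) * t / T


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _sample_mask(
    position: np.ndarray, rng: np.random.Generator, binarize: str
) -> np.ndarray:
    """S-shaped transfer: select each dimension with probability sigmoid(x).

    An all-zero draw is resampled once, then the dimension with the
    largest selection probability is forced on.
    """
    prob = _sigmoid(position)
    if binarize == "threshold":
        mask = prob >= 0.5
    else:
        mask = rng.random(position.size) < prob
        if not mask.any():
            mask = rng.random(position.size) < prob
    if not mask.any():
        mask = np.zeros(position.size, dtype=bool)
        mask[int(np.argmax(prob))] = True
    return mask


def update_wolf(
    wolf: Wolf,
    gbest_position: np.ndarray,
    w: float,
    cfg: HgwoPsoConfig,
    rng: np.random.Generator,
) -> None:
    """PSO velocity/position update plus stochastic re-binarization."""
    d = wolf.position.size
    r1 = rng.random(d)
    r2 = rng.random(d)
    pbest = wolf.pbest_position if wolf.pbest_position is not None else wolf.position
    v = (
        w * wolf.velocity
        + cfg.c1 * r1 * (pbest - wolf.position)
        + cfg.c2 * r2 * (gbest_position - wolf.position)
    )
    wolf.velocity = np.clip(v, -cfg.v_clamp, cfg.v_clamp)
    wolf.position = wolf.position + wolf.velocity
    wolf.mask = _sample_mask(wolf.position, rng, cfg.binarize)
    wolf.fitness = None


def _initial_position(mask: np.ndarray, scale: float) -> np.ndarray:
    """Softened logit of the binary mask: +-scale (sigmoid(+-1) ~ 0.73/0.27).

    The exact logit of a 0/1 mask is +-inf; a mild score keeps the
    S-shaped transfer stochastic during early iterations.
    """
    return np.where(mask, scale, -scale).astype(np.float64)


def run(
    evaluator: AccuracyEvaluator,
    d: int,
    cfg: HgwoPsoConfig | None = None,
    callback: Callable[[int, float], None] | None = None,
) -> HgwoPsoResult:
    """Run HGWO-PSO over nonempty masks of ``d`` features.

    Returns the alpha wolf's mask after the final iteration together
    with the per-iteration best-fitness history, which is non-decreasing
    by elitist retention of the leaders.
    """
    if cfg is None:
        cfg = HgwoPsoConfig()
    if d < 1:
        raise ConfigError("feature dimension d must be >= 1")
    rng = np.random.default_rng(cfg.seed)
    cache: dict[bytes, FitnessResult] = {}

    def fit(mask: np.ndarray) -> FitnessResult:
        return fitness(mask, evaluator, cfg.acc_weight, cfg.parsimony_weight, cache)

    wolves: list[Wolf] = []
    for _ in range(cfg.n_wolves):
        mask = rng.random(d) < 0.5
        while not mask.any():
            mask = rng.random(d) < 0.5
        wolves.append(
            Wolf(
                position=_initial_position(mask, cfg.init_scale),
                velocity=np.zeros(d),
                mask=mask,
            )
        )

    # Elite leaders (alpha, beta, delta) persist across iterations and are
    # replaced only by strictly better agents.
    leaders: list[tuple[FitnessResult, np.ndarray, np.ndarray]] = []
    history: list[float] = []

    for t in range(cfg.iterations):
        for wolf in wolves:
            if wolf.fitness is None:
                wolf.fitness = fit(wolf.mask)
            if (
                wolf.pbest_fitness is None
                or wolf.fitness.fitness > wolf.pbest_fitness.fitness
            ):
                wolf.pbest_fitness = wolf.fitness
                wolf.pbest_mask = wolf.mask.copy()
                wolf.pbest_position = wolf.position.copy()

        # Re-rank leaders over current agents plus retained elites.
        pool = leaders + [
            (w.fitness, w.position.copy(), w.mask.copy()) for w in wolves  # type: ignore[misc]
        ]
        pool.sort(key=lambda item: item[0].fitness, reverse=True)
        dedup: list[tuple[FitnessResult, np.ndarray, np.ndarray]] = []
        seen: set[bytes] = set()
        for item in pool:
            key = np.packbits(item[2]).tobytes()
            if key not in seen:
                seen.add(key)
                dedup.append(item)
            if len(dedup) == 3:
                break
        leaders = dedup
        history.append(leaders[0][0].fitness)
        if callback is not None:
            callback(t, leaders[0][0].fitness)

        if cfg.leader_combine == "mean3":
            gbest = np.mean([pos for _, pos, _ in leaders], axis=0)
        else:
            gbest = leaders[0][1]

        # Current top wolves are frozen this iteration (leader hierarchy);
        # all other agents move.
        ranked = sorted(
            range(len(wolves)),
            key=lambda i: wolves[i].fitness.fitness,  # type: ignore[union-attr]
            reverse=True,
        )
        frozen = set(ranked[:3])
        w = inertia(t, cfg.iterations, cfg.w_start, cfg.w_end)
        for i, wolf in enumerate(wolves):
            if i in frozen:
                continue
            update_wolf(wolf, gbest, w, cfg, rng)

    alpha = leaders[0]
    return HgwoPsoResult(
        mask=alpha[2].copy(),
        fitness=alpha[0],
        history=history,
        n_evaluations=len(cache),
    )
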