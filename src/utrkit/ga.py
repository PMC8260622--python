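"""Genetic algorithm for designing high-fitness 100-bp, AUG-free 5' UTRs.

Each run samples 100 endogenous (standardized) 5' UTRs as the initial
population and evolves them by fitness-ranked tournament selection (size 3
by default), single-point crossover, and per-nucleotide substitution mutation, with
elitism; every variant is repaired to stay AUG-free.  After at most 50
generations the top 5 evaluated sequences with pairwise Hamming distance of
at least 5 bp are kept, restricted to those scoring at least 0.05 fitness
units above the best of the run's initial naturally occurring sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.base import BaseEstimator

from .io import UtrRecord, UtrkitError
from .prep import strip_augs

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GAConfig:
    """Population / variation / selection parameters of one GA run."""

    pop_size: int = 100
    max_generations: int = 50
    n_keep: int = 5
    min_hamming: int = 5
    min_improvement: float = 0.05
    mutation_rate: float = 0.02
    crossover_rate: float = 0.5
    elitism_count: int = 2
    tournament_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pop_size < 2:
            raise UtrkitError("pop_size must be >= 2")
        for rate in (self.mutation_rate, self.crossover_rate):
            if not 0.0 <= rate <= 1.0:
                raise UtrkitError("rates must be in [0, 1]")
        if self.min_hamming < 0:
            raise UtrkitError("min_hamming must be >= 0")
        if self.elitism_count < 0 or self.elitism_count > self.pop_size:
            raise UtrkitError("elitism_count must be in [0, pop_size]")
        if self.tournament_size < 1:
            raise UtrkitError("tournament_size must be >= 1")


@dataclass
class GAResult:
    """Kept designs plus the audit trail of one GA run."""

    kept: list[tuple[str, float, int]]  # (sequence, fitness, generation found)
    best_fitness_trajectory: list[float]
    initial_best: float
    seed_pool_ids: list[str]
    n_evaluated: int = 0
    config: dict = field(default_factory=dict)


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise UtrkitError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independently substitute each position with probability ``rate``.

    A substituted base becomes one of the three other bases uniformly; the
    result is then AUG-repaired.  Length is preserved.
    """
    if not 0.0 <= rate <= 1.0:
        raise UtrkitError("mutation rate must be in [0, 1]")
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = rng.random(arr.shape[0]) < rate
    if hit.any():
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[int(rng.integers(3))]
    out = arr.tobytes().decode()
    if "ATG" in out:
        out = strip_augs(out, rng)
    return out


def recombine(a: str, b: str, rng: np.random.Generator) -> str:
    """Single-point crossover at a uniform cut in [1, L-1], AUG-repaired."""
    if len(a) != len(b):
        raise UtrkitError(f"length mismatch: {len(a)} vs {len(b)}")
    cut = int(rng.integers(1, len(a)))
    child = a[:cut] + b[cut:]
    if "ATG" in child:
        child = strip_augs(child, rng)
    return child


def diverse_top_k(
    candidates: list[tuple[str, float]], k: int = 5, min_dist: int = 5
) -> list[tuple[str, float]]:
    """Greedy fitness-ranked selection with a pairwise Hamming floor.

    Candidates are sorted by fitness descending (ties by sequence
    lexicographic); one is accepted iff its Hamming distance to every
    already-accepted sequence is >= min_dist.  Stops at k or exhaustion.
    """
    seen: set[str] = set()
    unique: list[tuple[str, float]] = []
    for seq, fit in candidates:
        if seq not in seen:
            seen.add(seq)
            unique.append((seq, fit))
    ordered = sorted(unique, key=lambda c: (-c[1], c[0]))
    accepted: list[tuple[str, float]] = []
    for seq, fit in ordered:
        if len(accepted) >= k:
            break
        if all(hamming(seq, s) >= min_dist for s, _ in accepted):
            accepted.append((seq, fit))
    return accepted


def gc_dinucleotide_fitness(seq: str) -> float:
    """Toy objective: number of dinucleotide windows made only of G/C.

    The analytic maximum on an L-mer is L-1 (any all-G/C sequence), useful
    for exercising the search without a trained surrogate.
    """
    strong = [b in "GC" for b in seq]
    return float(
        sum(1 for i in range(len(seq) - 1) if strong[i] and strong[i + 1])
    )


def _tournament(
    pop: list[str],
    fits: list[float],
    rng: np.random.Generator,
    size: int,
) -> str:
    idx = rng.integers(len(pop), size=size)
    best = idx[0]
    for i in idx[1:]:
        if fits[i] > fits[best]:
            best = i
    return pop[best]


def evolve(seed_pool, fitness_fn, config: GAConfig | None = None) -> GAResult:
    """Run one genetic-algorithm search from a pool of natural seeds.

    ``seed_pool`` is a list of UtrRecord or sequences (standardized,
    AUG-free, equal length, at least ``pop_size`` of them); ``fitness_fn``
    maps a sequence to a float (memoized per sequence).  Returns a
    :class:`GAResult` whose ``kept`` designs satisfy all invariants: fixed
    length, no ATG, pairwise Hamming >= min_hamming, and fitness at least
    ``min_improvement`` above the best initial seed.
    """
    if config is None:
        config = GAConfig()
    seqs = [
        r.sequence if isinstance(r, UtrRecord) else str(r).upper()
        for r in seed_pool
    ]
    ids = [
        r.id if isinstance(r, UtrRecord) else f"seed{i}"
        for i, r in enumerate(seed_pool)
    ]
    if len(seqs) < config.pop_size:
        raise UtrkitError(
            f"seed pool ({len(seqs)}) smaller than pop_size "
            f"({config.pop_size})"
        )
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise UtrkitError("seed sequences must share one length")
    rng = np.random.default_rng(config.seed)

    memo: dict[str, float] = {}
    evaluated: dict[str, tuple[float, int]] = {}  # seq -> (fitness, gen found)

    def score(seq: str, gen: int) -> float:
        if seq not in memo:
            try:
                memo[seq] = float(fitness_fn(seq))
            except Exception as exc:
                raise UtrkitError(
                    f"fitness function failed at generation {gen}: {exc}"
                ) from exc
            evaluated[seq] = (memo[seq], gen)
        return memo[seq]

    pick = rng.choice(len(seqs), size=config.pop_size, replace=False)
    pop = [seqs[i] for i in pick]
    fits = [score(s, 0) for s in pop]
    initial_best = max(fits)
    trajectory = [max(fits)]

    for gen in range(1, config.max_generations + 1):
        order = sorted(range(len(pop)), key=lambda i: (-fits[i], pop[i]))
        elites = [pop[i] for i in order[: config.elitism_count]]
        children = list(elites)
        while len(children) < config.pop_size:
            p1 = _tournament(pop, fits, rng, config.tournament_size)
            p2 = _tournament(pop, fits, rng, config.tournament_size)
            child = (
                recombine(p1, p2, rng)
                if rng.random() < config.crossover_rate
                else p1
            )
            children.append(mutate(child, config.mutation_rate, rng))
        pop = children
        fits = [score(s, gen) for s in pop]
        trajectory.append(max(fits))

    candidates = [(seq, fit) for seq, (fit, _) in evaluated.items()]
    kept_pairs = diverse_top_k(candidates, config.n_keep, config.min_hamming)
    threshold = initial_best + config.min_improvement
    kept = [
        (seq, fit, evaluated[seq][1])
        for seq, fit in kept_pairs
        if fit >= threshold
    ]
    return GAResult(
        kept=kept,
        best_fitness_trajectory=trajectory,
        initial_best=initial_best,
        seed_pool_ids=ids,
        n_evaluated=len(evaluated),
        config=asdict(config),
    )


class GeneticDesigner(BaseEstimator):
    """Estimator-style wrapper around :func:`evolve`.

    Parameters mirror :class:`GAConfig`; ``fitness`` is the sequence ->
    float objective.  ``fit(seed_pool)`` runs the search and exposes
    ``kept_``, ``best_fitness_trajectory_``, ``initial_best_``.
    """

    def __init__(
        self,
        fitness=None,
        pop_size: int = 100,
        max_generations: int = 50,
        n_keep: int = 5,
        min_hamming: int = 5,
        min_improvement: float = 0.05,
        mutation_rate: float = 0.02,
        crossover_rate: float = 0.5,
        elitism_count: int = 2,
        tournament_size: int = 3,
        random_state: int = 0,
    ):
        self.fitness = fitness
        self.pop_size = pop_size
        self.max_generations = max_generations
        self.n_keep = n_keep
        self.min_hamming = min_hamming
        self.min_improvement = min_improvement
        self.mutation_rate = mutation_rate
        self.crossover_rate = crossover_rate
        self.elitism_count = elitism_count
        self.tournament_size = tournament_size
        self.random_state = random_state

    def _config(self) -> GAConfig:
        return GAConfig(
            pop_size=self.pop_size,
            max_generations=self.max_generations,
            n_keep=self.n_keep,
            min_hamming=self.min_hamming,
            min_improvement=self.min_improvement,
            mutation_rate=self.mutation_rate,
            crossover_rate=self.crossover_rate,
            elitism_count=self.elitism_count,
            tournament_size=self.tournament_size,
            seed=self.random_state,
        )

    def fit(self, X, y=None):
        if self.fitness is None:
            raise UtrkitError("GeneticDesigner needs a fitness callable")
        result = evolve(X, self.fitness, self._config())
        self.result_ = result
        self.kept_ = result.kept
        self.best_fitness_trajectory_ = result.best_fitness_trajectory
        self.initial_best_ = result.initial_best
        return self

    def transform(self, X=None) -> list[str]:
        if not hasattr(self, "kept_"):
            raise UtrkitError("GeneticDesigner is not fitted")
        return [seq for seq, _, _ in self.kept_]
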