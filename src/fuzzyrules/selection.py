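"""Genetic selection of small, short, accurate rule subsets.

A classifier is a subset S of the Q pre-screened candidate rules, encoded
as a binary string r_1...r_Q. Three objectives — training accuracy, rule
count and total rule length — are scalarized into a single fitness

    f(S) = w1·NCCP(S) − w2·NOR(S) − w3·NOA(S)

with nonnegative weights summing to one: NCCP is the number of correctly
classified training patterns, NOR the number of selected rules and NOA the
total number of antecedent conditions. A generational GA evolves the
strings with two-point crossover and *biased* mutation — the 1→0 rate is
boosted by the interpretability weights w2 + w3 so selection pressure and
mutation both push toward leaner rule bases. After every evaluation,
rules that never attain the winning score on any training pattern are
removed from the string (they cannot affect any prediction), and survivors
into the next generation are the top-fitness individuals among parents and
children.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ExpressionDataset
from .rules import CandidatePool, compatibility

__all__ = [
    "ObjectiveWeights",
    "GAConfig",
    "GenerationTrace",
    "PoolEvaluator",
    "fitness",
    "mutation_rates",
    "crossover",
    "mutate",
    "remove_unnecessary_rules",
    "evolve",
]


@dataclass(frozen=True)
class ObjectiveWeights:
    """Weights (w1, w2, w3) for accuracy, rule count and total rule length."""

    w1: float
    w2: float
    w3: float

    _TOL = 1e-9

    def __post_init__(self) -> None:
        if min(self.w1, self.w2, self.w3) < 0:
            raise ValueError("objective weights must be nonnegative")
        total = self.w1 + self.w2 + self.w3
        if abs(total - 1.0) > self._TOL:
            raise ValueError(f"objective weights must sum to 1, got {total}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


@dataclass(frozen=True)
class GAConfig:
    """Settings for the generational GA; ``seed`` makes runs reproducible."""

    n_pop: int = 50
    p_c: float = 0.9
    pa_10: float = 0.1
    pa_01: float = 0.01
    max_generations: int = 200
    stagnation_window: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pop < 2:
            raise ValueError("n_pop must be >= 2")
        for name in ("p_c", "pa_10", "pa_01"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.max_generations < 1:
            raise ValueError("max_generations must be >= 1")


@dataclass
class GenerationTrace:
    """Best-so-far statistics per generation (fitness, accuracy, NOR, NOA)."""

    generation: list[int] = field(default_factory=list)
    fitness: list[float] = field(default_factory=list)
    test_accuracy: list[float] = field(default_factory=list)
    nor: list[int] = field(default_factory=list)
    noa: list[int] = field(default_factory=list)

    def append(self, gen: int, fit: float, acc: float, nor: int, noa: int) -> None:
        self.generation.append(gen)
        self.fitness.append(fit)
        self.test_accuracy.append(acc)
        self.nor.append(nor)
        self.noa.append(noa)

    def __len__(self) -> int:
        return len(self.generation)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "generation": self.generation,
                "fitness": self.fitness,
                "test_accuracy": self.test_accuracy,
                "nor": self.nor,
                "noa": self.noa,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


class PoolEvaluator:
    """Vectorized scoring of rule subsets against one dataset.

    Precomputes the m × Q matrix of compatibility × CF scores once, so a
    subset evaluation reduces to a masked row-max. A rule is *necessary*
    for a subset if it attains the winning (maximal, positive) score on at
    least one training pattern; every rule kept by pruning attains a row
    maximum, so pruning never changes any prediction.
    """

    def __init__(self, pool: CandidatePool, data: ExpressionDataset):
        if len(pool) == 0:
            raise ValueError("empty candidate pool")
        from .partitions import build_vocabulary

        v = build_vocabulary()
        self.q = len(pool)
        self.labels = data.labels
        self.m = data.m
        self.classes = np.array([r.consequent_class for r in pool.rules])
        self.lengths = np.array([r.length for r in pool.rules])
        self.scores = np.empty((data.m, self.q))
        for j, r in enumerate(pool.rules):
            self.scores[:, j] = (
                compatibility(r.antecedent, data.values, v) * r.weight
            )

    def nccp(self, bits: np.ndarray) -> int:
        nccp, _ = self._nccp_and_used(bits)
        return nccp

    def _nccp_and_used(self, bits: np.ndarray) -> tuple[int, np.ndarray]:
        sel = np.flatnonzero(bits)
        used = np.zeros(self.q, dtype=bool)
        if sel.size == 0:
            return 0, used
        sub = self.scores[:, sel]
        row_max = sub.max(axis=1)
        covered = row_max > 0.0
        at_max = covered[:, None] & (sub == row_max[:, None])
        cls = self.classes[sel]
        pos_hit = (at_max & (cls == 1)).any(axis=1)
        neg_hit = (at_max & (cls == -1)).any(axis=1)
        # exact cross-class tie -> reject (never correct)
        decided_pos = pos_hit & ~neg_hit
        decided_neg = neg_hit & ~pos_hit
        nccp = int(
            np.sum(decided_pos & (self.labels == 1))
            + np.sum(decided_neg & (self.labels == -1))
        )
        used[sel[at_max.any(axis=0)]] = True
        return nccp, used

    def prune(self, bits: np.ndarray) -> np.ndarray:
        """Clear every selected rule that never attains a winning score."""
        _, used = self._nccp_and_used(bits)
        return used.astype(bits.dtype)

    def fitness(self, bits: np.ndarray, w: ObjectiveWeights) -> float:
        nccp, _ = self._nccp_and_used(bits)
        nor = int(bits.sum())
        noa = int(self.lengths[bits.astype(bool)].sum())
        return w.w1 * nccp - w.w2 * nor - w.w3 * noa

    def accuracy(self, bits: np.ndarray) -> float:
        return self.nccp(bits) / self.m


def fitness(
    S: np.ndarray,
    pool: CandidatePool,
    data: ExpressionDataset,
    w: ObjectiveWeights,
) -> float:
    """Scalarized three-objective fitness of the subset encoded by ``S``."""
    return PoolEvaluator(pool, data).fitness(np.asarray(S), w)


def mutation_rates(
    w: ObjectiveWeights, pa_10: float, pa_01: float
) -> tuple[float, float]:
    """Per-bit mutation probabilities biased by the objective weights.

    The 1→0 rate grows with the interpretability weights (w2 + w3) and the
    0→1 rate with the accuracy weight w1, so emphasising interpretability
    drains rules from strings faster than it adds them.
    """
    p_10 = min(1.0, pa_10 * (1.0 + w.w2 + w.w3))
    p_01 = min(1.0, pa_01 * (1.0 + w.w1))
    return p_10, p_01


def crossover(
    parent_a: np.ndarray,
    parent_b: np.ndarray,
    p_c: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Two-point crossover with probability ``p_c``; otherwise copy parent a."""
    a = np.asarray(parent_a)
    b = np.asarray(parent_b)
    if a.shape != b.shape:
        raise ValueError("parent strings must have equal length")
    child = a.copy()
    if rng.random() < p_c:
        i, j = np.sort(rng.integers(0, a.size + 1, size=2))
        child[i:j] = b[i:j]
    return child


def mutate(
    S: np.ndarray, p_10: float, p_01: float, rng: np.random.Generator
) -> np.ndarray:
    """Biased bit-flip mutation: 1→0 with p_10, 0→1 with p_01, independently."""
    bits = np.asarray(S).copy()
    u = rng.random(bits.size)
    ones = bits == 1
    bits[ones & (u < p_10)] = 0
    bits[~ones & (u < p_01)] = 1
    return bits


def remove_unnecessary_rules(
    S: np.ndarray, pool: CandidatePool, data: ExpressionDataset
) -> np.ndarray:
    """Drop selected rules that never win on any training pattern.

    The result classifies every training pattern identically (same NCCP)
    with no more rules and no more conditions; applying it twice changes
    nothing.
    """
    return PoolEvaluator(pool, data).prune(np.asarray(S))


def evolve(
    pool: CandidatePool,
    data: ExpressionDataset,
    w: ObjectiveWeights,
    cfg: GAConfig,
    test_data: ExpressionDataset | None = None,
) -> tuple[np.ndarray, GenerationTrace]:
    """Run the generational GA and return the best subset ever seen.

    Each generation produces ``n_pop`` children by two-point crossover of
    randomly paired parents and biased mutation; every evaluated string is
    pruned of unnecessary rules in place (the cleaned string is what
    survives), and the next population is the top ``n_pop`` of parents and
    children, ranked by fitness with ties broken toward fewer rules and
    fewer conditions (parsimony, in keeping with the interpretability
    objectives). Stops at ``max_generations`` or, if a stagnation
    window is configured, when the best fitness has not improved for that
    many generations. Fully reproducible from ``cfg.seed``.
    """
    ev = PoolEvaluator(pool, data)
    test_ev = PoolEvaluator(pool, test_data) if test_data is not None else None
    rng = np.random.default_rng(cfg.seed)
    p_10, p_01 = mutation_rates(w, cfg.pa_10, cfg.pa_01)

    def assess(bits: np.ndarray) -> tuple[np.ndarray, float]:
        pruned = ev.prune(bits)
        f = ev.fitness(pruned, w)
        if not np.isfinite(f):
            raise RuntimeError(f"non-finite fitness {f}")
        return pruned, f

    def complexity(bits: np.ndarray) -> tuple[int, int]:
        on = bits.astype(bool)
        return int(on.sum()), int(ev.lengths[on].sum())

    def leaner(a: np.ndarray, b: np.ndarray) -> bool:
        return complexity(a) < complexity(b)

    pop = rng.integers(0, 2, size=(cfg.n_pop, ev.q), dtype=np.int8)
    fits = np.empty(cfg.n_pop)
    for i in range(cfg.n_pop):
        pop[i], fits[i] = assess(pop[i])

    def rank(population: np.ndarray, fit_vals: np.ndarray) -> np.ndarray:
        # lexicographic: fitness desc, then NOR asc, then NOA asc
        nor = population.sum(axis=1)
        noa = np.array([ev.lengths[ind.astype(bool)].sum() for ind in population])
        return np.lexsort((noa, nor, -fit_vals))

    order = rank(pop, fits)
    pop, fits = pop[order], fits[order]
    best_bits = pop[0].copy()
    best_fit = float(fits[0])
    since_improved = 0
    trace = GenerationTrace()

    for gen in range(1, cfg.max_generations + 1):
        children = np.empty_like(pop)
        child_fits = np.empty(cfg.n_pop)
        for i in range(cfg.n_pop):
            # binary-tournament parent selection
            cand = rng.integers(0, cfg.n_pop, size=4)
            pa = cand[0] if fits[cand[0]] >= fits[cand[1]] else cand[1]
            pb = cand[2] if fits[cand[2]] >= fits[cand[3]] else cand[3]
            child = crossover(pop[pa], pop[pb], cfg.p_c, rng)
            child = mutate(child, p_10, p_01, rng)
            children[i], child_fits[i] = assess(child)

        all_pop = np.vstack([pop, children])
        all_fits = np.concatenate([fits, child_fits])
        order = rank(all_pop, all_fits)[: cfg.n_pop]
        pop, fits = all_pop[order], all_fits[order]

        if fits[0] > best_fit or (fits[0] == best_fit and leaner(pop[0], best_bits)):
            if fits[0] > best_fit:
                since_improved = 0
            best_fit = float(fits[0])
            best_bits = pop[0].copy()
        else:
            since_improved += 1

        acc = test_ev.accuracy(best_bits) if test_ev is not None else float("nan")
        trace.append(
            gen,
            best_fit,
            acc,
            int(best_bits.sum()),
            int(ev.lengths[best_bits.astype(bool)].sum()),
        )
        if (
            cfg.stagnation_window is not None
            and since_improved >= cfg.stagnation_window
        ):
            break

    return best_bits, trace
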