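"""Genetic algorithm over fixed-size variant subsets.

Candidate solutions ("chromosomes") are k-variant subsets whose fitness
is the squared Pearson correlation between burden score and trait.
Each generation keeps the ``elitism`` best members and fills the rest by
fitness-proportional (roulette) selection of two parents, a
size-preserving set crossover (shared variants are inherited, the
remainder drawn uniformly from the symmetric difference), and per-slot
mutation to a uniformly chosen non-member.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .association import Fitness
from .base import BaseSubsetSearch, SearchContext, weighted_subset_sample
from .score_stats import SnpSubset, WeightScheme

__all__ = [
    "GaPopulation",
    "GaResult",
    "GaSubsetSearch",
    "select_parents",
    "crossover",
    "mutate",
    "run_ga",
]


@dataclass
class GaPopulation:
    """One generation: member subsets and their fitness values."""

    members: list
    fitnesses: np.ndarray
    generation: int = 0


def select_parents(pop: GaPopulation, rng: np.random.Generator):
    """Two members drawn with replacement, probability proportional to r^2.

    Falls back to uniform selection when every fitness is zero.
    """
    f = np.asarray(pop.fitnesses, dtype=float)
    if f.size == 0:
        raise ValueError("population is empty")
    total = f.sum()
    p = f / total if total > 0 else None
    i, j = rng.choice(f.size, size=2, replace=True, p=p)
    return pop.members[i], pop.members[j]


def crossover(parent_a, parent_b, rng: np.random.Generator) -> np.ndarray:
    """Size-preserving recombination of two k-subsets.

    The child inherits every variant the parents share and fills the
    remaining slots with a uniform draw (without replacement) from the
    symmetric difference.
    """
    a = parent_a.as_array() if isinstance(parent_a, SnpSubset) else np.asarray(parent_a, dtype=np.intp)
    b = parent_b.as_array() if isinstance(parent_b, SnpSubset) else np.asarray(parent_b, dtype=np.intp)
    if a.size != b.size:
        raise ValueError("parents must have equal subset size")
    shared = np.intersect1d(a, b)
    diff = np.setxor1d(a, b)
    need = a.size - shared.size
    if need == 0:
        return shared
    picked = rng.choice(diff, size=need, replace=False)
    return np.sort(np.concatenate([shared, picked]))


def mutate(
    subset, mutation_rate: float, n_variants: int, rng: np.random.Generator
) -> np.ndarray:
    """Independently replace each member w.p. ``mutation_rate`` by a uniform
    non-member; subset size and distinctness are preserved."""
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError("mutation_rate must lie in [0, 1]")
    members = (
        subset.as_array() if isinstance(subset, SnpSubset) else np.asarray(subset, dtype=np.intp)
    ).copy()
    k = members.size
    if k >= n_variants:
        return members  # nothing outside the subset to mutate into
    mask = np.zeros(n_variants, dtype=bool)
    mask[members] = True
    for slot in range(k):
        if rng.random() < mutation_rate:
            non_members = np.flatnonzero(~mask)
            new = int(non_members[rng.integers(non_members.size)])
            mask[members[slot]] = False
            mask[new] = True
            members[slot] = new
    return members


@dataclass
class GaResult:
    """Outcome of one GA run."""

    best_subset: SnpSubset
    best_fitness: Fitness
    inclusion_freq: np.ndarray
    fitness_trace: np.ndarray


def _run_core(
    ctx: SearchContext,
    rng: np.random.Generator,
    pop_size: int,
    generations: int,
    mutation_rate: float,
    elitism: int,
) -> dict:
    if pop_size < 2:
        raise ValueError("pop_size must be >= 2")
    if not 0 <= elitism <= pop_size:
        raise ValueError("elitism must lie in [0, pop_size]")
    members = [weighted_subset_sample(rng, ctx.kernel, ctx.k) for _ in range(pop_size)]
    fitnesses = np.array([ctx.r2(ctx.score(m)) for m in members])
    best_i = int(np.argmax(fitnesses))
    best_r2 = float(fitnesses[best_i])
    best_members = members[best_i].copy()
    trace = np.empty(generations + 1)
    trace[0] = best_r2
    for gen in range(1, generations + 1):
        pop = GaPopulation(members=members, fitnesses=fitnesses, generation=gen - 1)
        order = np.argsort(fitnesses)[::-1]
        next_members = [members[i].copy() for i in order[:elitism]]
        while len(next_members) < pop_size:
            pa, pb = select_parents(pop, rng)
            child = crossover(pa, pb, rng)
            child = mutate(child, mutation_rate, ctx.m, rng)
            next_members.append(child)
        members = next_members
        fitnesses = np.array([ctx.r2(ctx.score(m)) for m in members])
        gen_best = int(np.argmax(fitnesses))
        if fitnesses[gen_best] > best_r2:
            best_r2 = float(fitnesses[gen_best])
            best_members = members[gen_best].copy()
        trace[gen] = best_r2 if elitism >= 1 else float(fitnesses[gen_best])
    incl = np.zeros(ctx.m)
    for m in members:
        incl[m] += 1.0
    return {
        "best_members": best_members,
        "best_r2": best_r2,
        "inclusion_freq": incl / pop_size,
        "fitness_trace": trace,
    }


def run_ga(
    genotypes,
    weights: WeightScheme | np.ndarray,
    phenotype: np.ndarray,
    k: int = 20,
    pop_size: int = 100,
    generations: int = 200,
    mutation_rate: float = 0.05,
    elitism: int = 1,
    rng_seed: int | np.random.Generator | None = None,
    kernel: np.ndarray | None = None,
) -> GaResult:
    """Run the GA search; returns the best subset, fitness, final-generation
    inclusion frequencies, and the best-fitness-per-generation trace."""
    from .genotypes import GenotypeMatrix

    X = genotypes.dosage() if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    w = weights.weights if isinstance(weights, WeightScheme) else np.asarray(weights, dtype=float)
    ctx = SearchContext(X, w, phenotype, k, kernel=kernel)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    out = _run_core(ctx, rng, pop_size, generations, mutation_rate, elitism)
    return GaResult(
        best_subset=SnpSubset.from_indices(out["best_members"]),
        best_fitness=Fitness(r=math.sqrt(out["best_r2"]), n=ctx.n),
        inclusion_freq=out["inclusion_freq"],
        fitness_trace=out["fitness_trace"],
    )


class GaSubsetSearch(BaseSubsetSearch):
    """Genetic-algorithm subset searcher (scikit-learn estimator).

    Parameters mirror :func:`run_ga`; fitted attributes match
    :class:`~burdenscan.mcmc.McmcSubsetSearch` with ``fitness_trace_``
    (best r^2 per generation) in place of a sampling trace, and
    ``inclusion_freq_`` computed over the final generation.
    """

    def __init__(
        self,
        statistic: str = "MB",
        k: int = 20,
        pop_size: int = 100,
        generations: int = 200,
        mutation_rate: float = 0.05,
        elitism: int = 1,
        random_state: int | None = None,
        signed_me: bool = False,
        classical_mb: bool = False,
    ):
        super().__init__(
            statistic=statistic,
            k=k,
            random_state=random_state,
            signed_me=signed_me,
            classical_mb=classical_mb,
        )
        self.pop_size = pop_size
        self.generations = generations
        self.mutation_rate = mutation_rate
        self.elitism = elitism

    def _search(self, ctx: SearchContext, rng: np.random.Generator) -> dict:
        return _run_core(
            ctx, rng, self.pop_size, self.generations, self.mutation_rate, self.elitism
        )
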