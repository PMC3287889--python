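"""Metropolis-coupled MCMC over fixed-size variant subsets.

Five chains (by default) run in parallel at temperatures T_j = 1/(1 + 0.2 j).
Each sweep proposes, per chain, a single swap move — remove one subset
member uniformly at random, add one non-member drawn with probability
proportional to its (floored) marginal association with the trait — and
accepts it with probability

    min(1, exp(T * (l' - l) + log q(reverse)/q(forward))),

where l = -(n/2) ln(1 - r^2) approximates the log-likelihood of the
normal linear model linking burden score to trait.  After the per-chain
sweeps, one exchange between a random adjacent temperature pair is
attempted.  The cold (T = 1) chain's visited subsets form the posterior
sample from which per-variant inclusion frequencies are reported; the
best subset ever seen in any chain is tracked separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .association import Fitness
from .base import BaseSubsetSearch, SearchContext, weighted_subset_sample
from .score_stats import SnpSubset, WeightScheme

__all__ = [
    "ChainState",
    "McmcResult",
    "McmcSubsetSearch",
    "temperature_ladder",
    "init_chains",
    "propose_swap",
    "mcmc_step",
    "swap_move",
    "run_mc3",
]


def temperature_ladder(n_chains: int, delta: float = 0.2) -> np.ndarray:
    """Chain temperatures T_j = 1 / (1 + delta * j), j = 0..n_chains-1."""
    return 1.0 / (1.0 + delta * np.arange(n_chains))


class ChainState:
    """Mutable state of one tempered chain.

    Caches the subset's per-individual score so a swap move updates it in
    O(n) instead of recomputing the full column sum.
    """

    __slots__ = ("members", "mask", "score", "r2", "log_lik", "temperature", "n_accept", "n_prop")

    def __init__(self, members: np.ndarray, ctx: SearchContext, temperature: float):
        self.members = np.asarray(members, dtype=np.intp).copy()
        self.mask = np.zeros(ctx.m, dtype=bool)
        self.mask[self.members] = True
        self.score = ctx.score(self.members)
        self.r2 = ctx.r2(self.score)
        self.log_lik = ctx.log_lik(self.r2)
        self.temperature = float(temperature)
        self.n_accept = 0
        self.n_prop = 0

    @property
    def subset(self) -> SnpSubset:
        return SnpSubset.from_indices(self.members)

    @property
    def fitness(self) -> Fitness:
        return Fitness(r=math.sqrt(self.r2), n=self.score.shape[0])


def init_chains(
    ctx: SearchContext,
    n_chains: int = 5,
    rng: np.random.Generator | None = None,
    delta: float = 0.2,
) -> list[ChainState]:
    """Kernel-weighted random initial subsets, one per temperature rung."""
    rng = rng if rng is not None else np.random.default_rng()
    temps = temperature_ladder(n_chains, delta)
    return [
        ChainState(weighted_subset_sample(rng, ctx.kernel, ctx.k), ctx, t) for t in temps
    ]


def _propose(chain: ChainState, ctx: SearchContext, rng: np.random.Generator):
    """Draw a single remove+add swap; returns (slot, removed, added, logH)."""
    pos = int(rng.integers(ctx.k))
    rem = int(chain.members[pos])
    w = np.where(chain.mask, 0.0, ctx.kernel)
    cs = np.cumsum(w)
    total = cs[-1]
    u = rng.random() * total
    add = int(np.searchsorted(cs, u, side="right"))
    add = min(add, ctx.m - 1)
    while chain.mask[add]:  # numeric edge of searchsorted on a zero-weight slot
        add = (add + 1) % ctx.m
    # reverse move re-adds `rem` under the candidate's non-member weights
    total_rev = total - ctx.kernel[add] + ctx.kernel[rem]
    log_hastings = (
        math.log(ctx.kernel[rem]) - math.log(total_rev)
        - math.log(ctx.kernel[add]) + math.log(total)
    )
    return pos, rem, add, log_hastings


def propose_swap(chain: ChainState, ctx: SearchContext, rng: np.random.Generator):
    """Candidate subset and log Hastings correction for one swap proposal."""
    pos, rem, add, log_h = _propose(chain, ctx, rng)
    candidate = chain.members.copy()
    candidate[pos] = add
    return SnpSubset.from_indices(candidate), log_h


def mcmc_step(chain: ChainState, ctx: SearchContext, rng: np.random.Generator) -> bool:
    """One tempered Metropolis-Hastings swap update in place; True if accepted."""
    if ctx.k == ctx.m:
        return False  # the full set is the only state
    pos, rem, add, log_h = _propose(chain, ctx, rng)
    new_score = chain.score - ctx.Xw[:, rem] + ctx.Xw[:, add]
    new_r2 = ctx.r2(new_score)
    new_ll = ctx.log_lik(new_r2)
    chain.n_prop += 1
    log_alpha = chain.temperature * (new_ll - chain.log_lik) + log_h
    if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
        chain.members[pos] = add
        chain.mask[rem] = False
        chain.mask[add] = True
        chain.score = new_score
        chain.r2 = new_r2
        chain.log_lik = new_ll
        chain.n_accept += 1
        return True
    return False


def swap_move(chains: list[ChainState], rng: np.random.Generator) -> bool:
    """Attempt one state exchange between a random adjacent temperature pair.

    Temperatures stay attached to chain positions; only the subset state
    moves.  Accepted with probability min(1, exp((T_j - T_{j+1}) *
    (l_{j+1} - l_j))).  Returns True if the exchange happened.
    """
    if len(chains) < 2:
        return False
    j = int(rng.integers(len(chains) - 1))
    a, b = chains[j], chains[j + 1]
    log_alpha = (a.temperature - b.temperature) * (b.log_lik - a.log_lik)
    if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
        for attr in ("members", "mask", "score", "r2", "log_lik"):
            tmp = getattr(a, attr)
            setattr(a, attr, getattr(b, attr))
            setattr(b, attr, tmp)
        return True
    return False


@dataclass
class McmcResult:
    """Posterior summary of one MC3 run."""

    inclusion_freq: np.ndarray
    best_subset: SnpSubset
    best_fitness: Fitness
    trace: np.ndarray
    acceptance_rates: dict


def _run_core(
    ctx: SearchContext,
    rng: np.random.Generator,
    n_chains: int,
    iterations: int,
    burn_in: int,
    delta: float,
) -> dict:
    if not 0 <= burn_in < iterations:
        raise ValueError("need iterations > burn_in >= 0")
    chains = init_chains(ctx, n_chains=n_chains, rng=rng, delta=delta)
    best_r2 = max(c.r2 for c in chains)
    best_members = max(chains, key=lambda c: c.r2).members.copy()
    incl = np.zeros(ctx.m)
    trace = np.empty(iterations)
    swap_accepts = 0
    swap_attempts = 0
    cold = chains[0]
    for it in range(iterations):
        for chain in chains:
            if mcmc_step(chain, ctx, rng) and chain.r2 > best_r2:
                best_r2 = chain.r2
                best_members = chain.members.copy()
        if n_chains > 1:
            swap_attempts += 1
            swap_accepts += swap_move(chains, rng)
        trace[it] = cold.log_lik
        if it >= burn_in:
            incl[cold.members] += 1.0
    n_samples = iterations - burn_in
    return {
        "best_members": best_members,
        "best_r2": best_r2,
        "inclusion_freq": incl / n_samples,
        "trace": trace,
        "acceptance_rates": {
            "chains": [c.n_accept / max(c.n_prop, 1) for c in chains],
            "swap": swap_accepts / max(swap_attempts, 1),
        },
    }


def run_mc3(
    genotypes,
    weights: WeightScheme | np.ndarray,
    phenotype: np.ndarray,
    k: int = 20,
    n_chains: int = 5,
    iterations: int = 20_000,
    burn_in: int = 4_000,
    rng_seed: int | np.random.Generator | None = None,
    delta: float = 0.2,
    kernel: np.ndarray | None = None,
) -> McmcResult:
    """Run the full MC3 search and summarize the cold-chain posterior.

    ``genotypes`` may be a GenotypeMatrix or a dosage array; ``weights``
    a WeightScheme or raw per-variant weights.  Returns per-variant
    inclusion frequencies (cold chain, post burn-in), the best subset
    seen in any chain, the cold-chain log-likelihood trace, and
    acceptance rates.
    """
    from .genotypes import GenotypeMatrix

    X = genotypes.dosage() if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    w = weights.weights if isinstance(weights, WeightScheme) else np.asarray(weights, dtype=float)
    ctx = SearchContext(X, w, phenotype, k, kernel=kernel)
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    out = _run_core(ctx, rng, n_chains, iterations, burn_in, delta)
    return McmcResult(
        inclusion_freq=out["inclusion_freq"],
        best_subset=SnpSubset.from_indices(out["best_members"]),
        best_fitness=Fitness(r=math.sqrt(out["best_r2"]), n=ctx.n),
        trace=out["trace"],
        acceptance_rates=out["acceptance_rates"],
    )


class McmcSubsetSearch(BaseSubsetSearch):
    """Metropolis-coupled MCMC subset searcher (scikit-learn estimator).

    Parameters
    ----------
    statistic : {"MB", "LL", "ME"}, default "MB"
        Burden weighting scheme.
    k : int, default 20
        Fixed subset size.
    n_chains : int, default 5
        Number of tempered chains.
    iterations, burn_in : int
        Sweeps in total / discarded before inclusion frequencies are
        accumulated.
    temp_delta : float, default 0.2
        Temperature-ladder spacing, T_j = 1/(1 + temp_delta * j).

    Attributes
    ----------
    best_subset_ : SnpSubset
    best_fitness_ : Fitness
    inclusion_freq_ : ndarray
        Cold-chain posterior inclusion frequency per variant.
    trace_ : ndarray
        Cold-chain log-likelihood per sweep.
    acceptance_rates_ : dict
    """

    def __init__(
        self,
        statistic: str = "MB",
        k: int = 20,
        n_chains: int = 5,
        iterations: int = 20_000,
        burn_in: int = 4_000,
        temp_delta: float = 0.2,
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
        self.n_chains = n_chains
        self.iterations = iterations
        self.burn_in = burn_in
        self.temp_delta = temp_delta

    def _search(self, ctx: SearchContext, rng: np.random.Generator) -> dict:
        return _run_core(
            ctx, rng, self.n_chains, self.iterations, self.burn_in, self.temp_delta
        )
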