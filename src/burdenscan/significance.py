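"""Permutation significance, causal-enrichment testing, and Q-Q data.

The optimized best r^2 is compared against its null distribution obtained
by rerunning the identical search on phenotype vectors permuted across
individuals; the empirical p-value is (1 + b) / (1 + B) where b counts
null values at or above the observed one.  Causal recovery is summarized
by a pooled 2x2 chi-square test of selection status against causality
across replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import clone

from .genotypes import GenotypeMatrix
from .score_stats import SnpSubset

__all__ = [
    "PermutationNull",
    "EnrichmentTable",
    "permutation_test",
    "causal_enrichment",
    "qq_data",
]

logger = logging.getLogger(__name__)


@dataclass
class PermutationNull:
    """Observed best fitness against B permutation-null best fitnesses."""

    observed_best: float
    null_best: np.ndarray
    p_value: float
    observed_subset: SnpSubset | None = None

    @property
    def B(self) -> int:
        return int(self.null_best.size)


def empirical_p(observed: float, null_values: np.ndarray) -> float:
    """(1 + #{null >= observed}) / (1 + B); always in (0, 1]."""
    null_values = np.asarray(null_values, dtype=float)
    b = int(np.sum(null_values >= observed))
    return (1 + b) / (1 + null_values.size)


def permutation_test(
    search,
    genotypes,
    phenotype: np.ndarray,
    B: int = 1000,
    rng_seed: int | None = None,
) -> PermutationNull:
    """Empirical p-value for the optimized region fit.

    Runs the configured search estimator once on the supplied (typically
    PC-adjusted) phenotype and once on each of B uniform permutations of
    it.  The search is cloned per run and reseeded from ``rng_seed``, so
    observed and permuted runs are exchangeable under the null.  Any
    phenotype-dependent ingredient of the statistic (ME weights, the
    proposal kernel) is recomputed inside ``fit`` per permutation.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    y = np.asarray(phenotype, dtype=float)
    rng = np.random.default_rng(rng_seed)
    seeds = rng.integers(0, 2**31, size=B + 1)

    est = clone(search).set_params(random_state=int(seeds[0]))
    est.fit(genotypes, y)
    observed = est.best_fitness_.r2
    observed_subset = est.best_subset_

    null_best = np.empty(B)
    for b in range(B):
        y_perm = rng.permutation(y)
        est = clone(search).set_params(random_state=int(seeds[b + 1]))
        est.fit(genotypes, y_perm)
        null_best[b] = est.best_fitness_.r2
    return PermutationNull(
        observed_best=float(observed),
        null_best=null_best,
        p_value=empirical_p(observed, null_best),
        observed_subset=observed_subset,
    )


@dataclass
class EnrichmentTable:
    """Pooled 2x2 table of (selected?, causal?) variant-replicate counts."""

    table: np.ndarray  # rows: selected / not selected; cols: causal / non-causal
    chi2: float
    p: float


def causal_enrichment(
    selected_per_replicate,
    causal_ids,
    n_variants: int,
    variant_ids=None,
    unique_snps: bool = False,
) -> EnrichmentTable:
    """Chi-square test for preferential selection of causal variants.

    Accumulates, across replicates, (variant, replicate) events
    cross-classified by membership in the replicate's best subset and by
    causality, and applies a 1-df Pearson chi-square (no continuity
    correction) to the pooled table.  With ``unique_snps=True`` each
    variant counts once, as selected if it appears in any replicate.

    ``causal_ids`` may be variant indices, or identifiers resolved
    through ``variant_ids``.
    """
    if variant_ids is not None:
        lookup = {v: i for i, v in enumerate(variant_ids)}
        causal_idx = {lookup[c] for c in causal_ids}
    else:
        causal_idx = {int(c) for c in causal_ids}
    if not causal_idx:
        raise ValueError("causal_ids must be non-empty")
    if len(causal_idx) >= n_variants:
        raise ValueError("causal_ids must be a strict subset of all variants")
    subsets = [
        s.as_array() if isinstance(s, SnpSubset) else np.asarray(s, dtype=np.intp)
        for s in selected_per_replicate
    ]
    if not subsets:
        raise ValueError("need at least one replicate")

    causal_mask = np.zeros(n_variants, dtype=bool)
    causal_mask[list(causal_idx)] = True
    n_causal = int(causal_mask.sum())

    if unique_snps:
        selected_mask = np.zeros(n_variants, dtype=bool)
        for s in subsets:
            selected_mask[s] = True
        sel_causal = int(np.sum(selected_mask & causal_mask))
        sel_total = int(selected_mask.sum())
        tot_causal, tot_all = n_causal, n_variants
    else:
        sel_causal = sum(int(causal_mask[s].sum()) for s in subsets)
        sel_total = sum(s.size for s in subsets)
        tot_causal = n_causal * len(subsets)
        tot_all = n_variants * len(subsets)

    table = np.array(
        [
            [sel_causal, sel_total - sel_causal],
            [tot_causal - sel_causal, (tot_all - sel_total) - (tot_causal - sel_causal)],
        ],
        dtype=float,
    )
    # Pearson chi-square on the pooled table, 1 df, no Yates correction
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if np.any(expected == 0):
        chi2 = 0.0
    else:
        chi2 = float(np.sum((table - expected) ** 2 / expected))
    p = float(stats.chi2.sf(chi2, df=1))
    return EnrichmentTable(table=table, chi2=chi2, p=p)


def qq_data(p_values, b_permutations: int = 1000) -> np.ndarray:
    """(expected, observed) -log10 p pairs for a Q-Q plot.

    p-values are ranked ascending; the i-th expected quantile is
    i/(m+1).  Zero p-values are clamped to 1/(1 + b_permutations) with a
    warning (an empirical permutation p cannot truly be zero).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        logger.warning("zero p-value(s) clamped to 1/(1+B)")
        p = np.where(p == 0, 1.0 / (1 + b_permutations), p)
    m = p.size
    observed = -np.log10(np.sort(p))
    expected = -np.log10(np.arange(1, m + 1) / (m + 1))
    return np.column_stack([expected, observed])
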