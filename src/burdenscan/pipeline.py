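"""Per-region analysis pipeline over phenotype replicates.

Mirrors the intended workflow: for each region, PC-adjust every replicate
trait, run the configured subset search per replicate, assess the
optimized fit by phenotype permutation, accumulate how often each variant
appears in the per-replicate best subsets, and (when the causal truth is
known) test for causal enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import derive_seed
from .association import PcAdjuster, Phenotype
from .ga import GaSubsetSearch
from .genotypes import GenotypeMatrix
from .io import write_json
from .mcmc import McmcSubsetSearch
from .significance import causal_enrichment, permutation_test, qq_data

__all__ = ["RunConfig", "RegionResult", "make_searcher", "analyze_replicates", "run_pipeline"]

logger = logging.getLogger(__name__)


def make_searcher(optimizer: str = "mcmc", statistic: str = "MB", k: int = 20, **params):
    """Build a configured subset-search estimator by name."""
    if optimizer == "mcmc":
        return McmcSubsetSearch(statistic=statistic, k=k, **params)
    if optimizer == "ga":
        return GaSubsetSearch(statistic=statistic, k=k, **params)
    raise ValueError(f"optimizer must be 'mcmc' or 'ga', got {optimizer!r}")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (defaults: k=20, 10 PCs, B=1000)."""

    genotype_path: str = ""
    genotype_format: str = "vcf"
    metadata_path: str | None = None
    phenotype_path: str = ""
    causal_path: str | None = None
    region: str = "all"
    statistic: str = "MB"
    optimizer: str = "mcmc"
    k: int = 20
    n_pcs: int = 10
    B: int = 1000
    seed: int = 0
    output_dir: str = "burdenscan_out"
    optimizer_params: dict = field(default_factory=dict)
    perm_effort: float = 1.0


@dataclass
class RegionResult:
    """Per-replicate permutation results and pooled diagnostics for one region."""

    region: str
    table: pd.DataFrame           # replicate, observed_best_r2, B, p_value
    selection_freq: np.ndarray    # fraction of replicates selecting each variant
    best_subsets: list
    enrichment: object | None = None


def _reduced(searcher, effort: float):
    """Scale down per-permutation search effort (logged approximation)."""
    if effort >= 1.0:
        return searcher
    logger.warning(
        "perm_effort=%.2f: permutation searches use reduced effort; "
        "null distribution is approximate and p-values may be anti-conservative",
        effort,
    )
    s = type(searcher)(**searcher.get_params())
    if hasattr(s, "iterations"):
        s.set_params(
            iterations=max(10, int(s.iterations * effort)),
            burn_in=int(s.burn_in * effort),
        )
    if hasattr(s, "generations"):
        s.set_params(generations=max(1, int(s.generations * effort)))
    return s


def analyze_replicates(
    genotypes: GenotypeMatrix,
    phenotypes,
    searcher,
    n_pcs: int = 10,
    B: int = 1000,
    seed: int = 0,
    causal_ids=None,
    region: str = "all",
    perm_effort: float = 1.0,
) -> RegionResult:
    """Run the full per-region analysis across phenotype replicates.

    PCs are computed once from the genotypes and reused for every
    replicate; each replicate's trait is residualized, searched, and
    permutation-tested with its own derived random substream.
    """
    adjuster = PcAdjuster(n_pcs=n_pcs).fit(genotypes) if n_pcs > 0 else None
    perm_searcher = _reduced(searcher, perm_effort)

    rows, best_subsets = [], []
    selection = np.zeros(genotypes.n_variants)
    for rep, pheno in enumerate(phenotypes):
        y = pheno.values if isinstance(pheno, Phenotype) else np.asarray(pheno, dtype=float)
        y_adj = adjuster.adjust(y) if adjuster is not None else y
        if perm_effort >= 1.0:
            null = permutation_test(
                searcher, genotypes, y_adj, B=B, rng_seed=derive_seed(seed, "perm", region, rep)
            )
            observed, p_value = null.observed_best, null.p_value
            best = null.observed_subset
        else:
            # observed run at full effort, permutations at reduced effort
            full = type(searcher)(**searcher.get_params())
            full.set_params(random_state=derive_seed(seed, "obs", region, rep))
            full.fit(genotypes, y_adj)
            observed = full.best_fitness_.r2
            null = permutation_test(
                perm_searcher, genotypes, y_adj, B=B,
                rng_seed=derive_seed(seed, "perm", region, rep),
            )
            p_value = (1 + int(np.sum(null.null_best >= observed))) / (1 + null.B)
            best = full.best_subset_
        best_subsets.append(best)
        selection[best.as_array()] += 1.0
        rows.append(
            {
                "region": region,
                "replicate": rep,
                "observed_best_r2": observed,
                "B": B,
                "p_value": p_value,
            }
        )
        logger.info("region=%s replicate=%d best_r2=%.4f p=%.4g", region, rep, observed, p_value)

    enrichment = None
    if causal_ids is not None and len(causal_ids) > 0:
        enrichment = causal_enrichment(
            best_subsets, causal_ids, genotypes.n_variants,
            variant_ids=list(genotypes.variant_ids),
        )
    return RegionResult(
        region=region,
        table=pd.DataFrame(rows),
        selection_freq=selection / len(best_subsets),
        best_subsets=best_subsets,
        enrichment=enrichment,
    )


def run_pipeline(config: RunConfig) -> Path:
    """File-to-file pipeline: read inputs, analyze each region, write outputs.

    Writes, per region: a p-value table (region, statistic, replicate,
    observed_best_r2, B, p_value), a selection-frequency table with
    variant coordinates, Q-Q pairs over the replicate p-values, and an
    enrichment JSON when a causal-truth table was supplied.
    """
    from .io import read_genotypes, read_phenotypes

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    genotypes = read_genotypes(
        config.genotype_path, format=config.genotype_format, metadata_path=config.metadata_path
    )
    phenotypes = read_phenotypes(config.phenotype_path, individual_ids=genotypes.individual_ids)
    causal_ids = None
    if config.causal_path:
        causal_ids = pd.read_csv(config.causal_path, sep="\t")["variant_id"].astype(str).tolist()

    regions = (
        list(dict.fromkeys(genotypes.chromosome)) if config.region == "all" else [config.region]
    )
    all_tables = []
    for region_name in regions:
        G = genotypes.subset_region(region_name) if config.region != "all" or len(regions) > 1 else genotypes
        region_causal = None
        if causal_ids is not None:
            region_causal = [c for c in causal_ids if c in set(G.variant_ids)]
            region_causal = region_causal or None
        searcher = make_searcher(
            config.optimizer, config.statistic, config.k, **config.optimizer_params
        )
        result = analyze_replicates(
            G,
            phenotypes,
            searcher,
            n_pcs=config.n_pcs,
            B=config.B,
            seed=config.seed,
            causal_ids=region_causal,
            region=region_name,
            perm_effort=config.perm_effort,
        )
        table = result.table.copy()
        table.insert(1, "statistic", config.statistic)
        all_tables.append(table)
        freq = G.variant_table()
        freq["selection_freq"] = result.selection_freq
        freq.to_csv(out / f"selection_freq_{region_name}.tsv", sep="\t", index=False)
        qq = qq_data(table["p_value"].to_numpy(), b_permutations=config.B)
        pd.DataFrame(qq, columns=["expected_neglog10_p", "observed_neglog10_p"]).to_csv(
            out / f"qq_{region_name}.tsv", sep="\t", index=False
        )
        if result.enrichment is not None:
            write_json(
                {
                    "region": region_name,
                    "table": result.enrichment.table,
                    "chi2": result.enrichment.chi2,
                    "p": result.enrichment.p,
                },
                out / f"enrichment_{region_name}.json",
            )
    pd.concat(all_tables, ignore_index=True).to_csv(out / "p_values.tsv", sep="\t", index=False)
    return out
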