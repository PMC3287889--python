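"""Synthetic mini-exome-style data with structure and replicate traits.

Emulates the study design the searchers are meant for: a fixed panel of
mostly rare variants genotyped once, two or more ancestral subpopulations
(Balding-Nichols model), and many quantitative-trait replicates that
share the genotypes and redraw only the noise realization.  Three preset
scenarios cover the canonical cases: a trait driven by many rare causal
variants (``q1_like``), a weaker polygenic trait (``q2_like``), and a
null trait confounded with population structure (``q4_like``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from ._rng import derive_rng
from .association import Phenotype
from .genotypes import GenotypeMatrix

__all__ = ["SimConfig", "SimOutput", "simulate_genotypes", "simulate_traits", "simulate", "scenario_presets"]

logger = logging.getLogger(__name__)

_MONO_RETRY_CAP = 20


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    maf_spectrum = (min_maf, max_maf, shape): ancestral MAFs are drawn as
    min + (max - min) * Beta(shape, 1); shape < 1 skews the density toward
    rare variants (shape 0.1 puts ~80% of variants below MAF 0.05).
    structure_effect shifts the trait mean per subpopulation label,
    creating confounding when fst > 0.
    """

    n_individuals: int = 200
    n_variants: int = 150
    n_subpops: int = 2
    fst: float = 0.0
    maf_spectrum: tuple = (0.001, 0.5, 0.1)
    causal_ids: tuple = ()
    effect_sizes: tuple = ()
    causal_maf_max: float = 0.05
    structure_effect: float = 0.0
    noise_sd: float = 1.0
    n_replicates: int = 200
    seed: int = 0
    trait_name: str = "trait"

    def __post_init__(self):
        if self.n_individuals < 2 or self.n_variants < 1:
            raise ValueError("need at least 2 individuals and 1 variant")
        if not 1 <= self.n_subpops <= self.n_individuals:
            raise ValueError("invalid n_subpops")
        if not 0.0 <= self.fst < 0.5:
            raise ValueError("fst must lie in [0, 0.5)")
        lo, hi, shape = self.maf_spectrum
        if not (0 < lo < hi <= 0.5 and shape > 0):
            raise ValueError("maf_spectrum must satisfy 0 < min < max <= 0.5, shape > 0")
        if len(self.causal_ids) != len(self.effect_sizes):
            raise ValueError("causal_ids and effect_sizes must align")
        if any(not 0 <= c < self.n_variants for c in self.causal_ids):
            raise ValueError("causal_ids out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimOutput:
    """Fixed genotypes plus replicate traits and the planted truth."""

    genotypes: GenotypeMatrix
    subpop_labels: np.ndarray
    phenotypes: list
    truth: dict = field(default_factory=dict)


def _ancestral_mafs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi, shape = config.maf_spectrum
    maf = lo + (hi - lo) * rng.beta(shape, 1.0, size=config.n_variants)
    if config.causal_ids:
        # causal variants are rare by design (preset constraint)
        cap = min(config.causal_maf_max, hi)
        idx = np.asarray(config.causal_ids, dtype=int)
        maf[idx] = lo + (cap - lo) * rng.beta(shape, 1.0, size=idx.size)
    return maf


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, np.ndarray]:
    """Draw the fixed genotype panel and subpopulation labels.

    Ancestral MAFs come from the rare-skewed spectrum; each
    subpopulation's allele frequency is a Balding-Nichols draw
    Beta(p (1-F)/F, (1-p)(1-F)/F) around the ancestral p; genotypes are
    Binomial(2, subpop frequency).  Variants that come out monomorphic in
    sample are redrawn a bounded number of times, then kept with a
    warning.
    """
    rng = derive_rng(config.seed, "sim", "genotypes")
    n, m = config.n_individuals, config.n_variants
    labels = np.arange(n) % config.n_subpops
    maf = _ancestral_mafs(config, rng)

    def draw_column(p: float) -> np.ndarray:
        if config.fst > 0:
            a = p * (1 - config.fst) / config.fst
            b = (1 - p) * (1 - config.fst) / config.fst
            sub_freq = rng.beta(a, b, size=config.n_subpops)
        else:
            sub_freq = np.full(config.n_subpops, p)
        return rng.binomial(2, sub_freq[labels]).astype(float)

    counts = np.empty((n, m))
    n_stuck = 0
    for j in range(m):
        col = draw_column(maf[j])
        tries = 0
        while np.ptp(col) == 0 and tries < _MONO_RETRY_CAP:
            col = draw_column(maf[j])
            tries += 1
        if np.ptp(col) == 0:
            n_stuck += 1
        counts[:, j] = col
    if n_stuck:
        logger.warning("%d variant(s) remain monomorphic in sample after retries", n_stuck)

    ids = [f"snp{j:05d}" for j in range(m)]
    genotypes = GenotypeMatrix(
        counts=counts,
        variant_ids=ids,
        chromosome=np.repeat("chr1", m),
        position=np.arange(1, m + 1) * 100,
    )
    return genotypes, labels


def simulate_traits(
    genotypes: GenotypeMatrix, subpop_labels: np.ndarray, config: SimConfig
) -> list:
    """Replicate traits over the fixed genotypes.

    y_r = sum_causal effect_i * count_i + structure_effect * subpop_label
          + Normal(0, noise_sd), with fresh noise per replicate.
    """
    X = genotypes.dosage()
    base = config.structure_effect * np.asarray(subpop_labels, dtype=float)
    if config.causal_ids:
        idx = np.asarray(config.causal_ids, dtype=int)
        base = base + X[:, idx] @ np.asarray(config.effect_sizes, dtype=float)
    phenotypes = []
    for r in range(config.n_replicates):
        rng = derive_rng(config.seed, "sim", "trait", r)
        y = base + rng.normal(0.0, config.noise_sd, size=X.shape[0])
        phenotypes.append(Phenotype(values=y, replicate_id=r, trait_name=config.trait_name))
    return phenotypes


def simulate(config: SimConfig) -> SimOutput:
    """Full synthetic study: genotypes, labels, replicate traits, truth."""
    genotypes, labels = simulate_genotypes(config)
    phenotypes = simulate_traits(genotypes, labels, config)
    truth = {
        "causal_ids": tuple(config.causal_ids),
        "causal_variant_ids": tuple(genotypes.variant_ids[list(config.causal_ids)]),
        "effect_sizes": tuple(config.effect_sizes),
    }
    return SimOutput(genotypes=genotypes, subpop_labels=labels, phenotypes=phenotypes, truth=truth)


_PRESETS = {
    # many rare causal variants in a few clusters, moderate effects
    "q1_like": dict(
        n_individuals=600,
        n_variants=300,
        n_subpops=2,
        fst=0.02,
        causal_ids=tuple(list(range(40, 45)) + list(range(140, 145)) + list(range(240, 245))),
        effect_sizes=(1.2,) * 15,
        structure_effect=0.0,
        noise_sd=1.0,
        trait_name="q1_like",
    ),
    # fewer, weaker causal variants
    "q2_like": dict(
        n_individuals=600,
        n_variants=300,
        n_subpops=2,
        fst=0.02,
        causal_ids=tuple(range(100, 108)),
        effect_sizes=(0.5,) * 8,
        structure_effect=0.0,
        noise_sd=1.0,
        trait_name="q2_like",
    ),
    # structured null: no causal variant, trait shifted by subpopulation
    "q4_like": dict(
        n_individuals=200,
        n_variants=150,
        n_subpops=2,
        fst=0.05,
        causal_ids=(),
        effect_sizes=(),
        structure_effect=1.5,
        noise_sd=1.0,
        trait_name="q4_like",
    ),
}


def scenario_presets(name: str, **overrides) -> SimConfig:
    """Named study scenarios (``q1_like``, ``q2_like``, ``q4_like``).

    Keyword overrides replace any SimConfig field, e.g.
    ``scenario_presets("q4_like", structure_effect=0.0)`` for an
    unstructured null.
    """
    if name not in _PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(_PRESETS)}")
    cfg = SimConfig(**_PRESETS[name])
    return replace(cfg, **overrides) if overrides else cfg
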