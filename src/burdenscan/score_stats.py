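"""Weighted-sum burden score statistics.

Three per-individual aggregation schemes over a subset S of variants:

* ``LL`` — unweighted count of minor alleles across S (Li-Leal-style
  collapsing): score_I = sum_{i in S} c_{I,i}.
* ``MB`` — inverse minor-allele-frequency weighting (Madsen-Browning
  style): weight_i = 1 / MAF_i with the in-sample MAF.  The classical
  1/sqrt(n q (1-q)) form is available via ``classical=True``.
* ``ME`` — marginal-effect weighting: weight_i = |b_i| where b_i is the
  univariate OLS slope of the trait on the allele count (log odds ratio
  for a binary trait).  Signed weights available via ``signed=True``.

Weights are a property of the whole variant panel and a phenotype (for
ME); a search then moves subsets around while the weights stay fixed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genotypes import GenotypeMatrix

__all__ = [
    "WeightScheme",
    "SnpSubset",
    "compute_weights",
    "marginal_effects",
    "aggregate_score",
    "WEIGHT_KINDS",
]

logger = logging.getLogger(__name__)

WEIGHT_KINDS = ("LL", "MB", "ME")


@dataclass(frozen=True)
class WeightScheme:
    """Per-variant non-negative weights under a named scheme."""

    kind: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in WEIGHT_KINDS:
            raise ValueError(f"kind must be one of {WEIGHT_KINDS}, got {self.kind!r}")
        w = np.asarray(self.weights, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite")
        object.__setattr__(self, "weights", w)


@dataclass(frozen=True)
class SnpSubset:
    """A fixed-size set of k distinct variant indices — the search state."""

    indices: frozenset = field()
    k: int = 20

    def __post_init__(self) -> None:
        idx = frozenset(int(i) for i in self.indices)
        object.__setattr__(self, "indices", idx)
        if len(idx) != self.k:
            raise ValueError(f"subset must contain exactly k={self.k} distinct indices")
        if self.k < 1:
            raise ValueError("subset size k must be >= 1")
        if any(i < 0 for i in idx):
            raise ValueError("indices must be non-negative")

    @classmethod
    def from_indices(cls, indices) -> "SnpSubset":
        idx = frozenset(int(i) for i in indices)
        return cls(indices=idx, k=len(idx))

    def as_array(self) -> np.ndarray:
        return np.fromiter(sorted(self.indices), dtype=np.intp)


def marginal_effects(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: np.ndarray,
    trait_type: str = "quantitative",
) -> np.ndarray:
    """Per-variant univariate effect of allele count on the trait.

    Quantitative traits: OLS slope of the one-predictor regression of the
    trait on the allele count.  Binary traits: log odds ratio from the
    2x2 carrier (count > 0) vs non-carrier table with a 0.5 continuity
    correction applied to zero cells.  Monomorphic variants get effect 0.
    """
    X = genotypes.dosage() if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("phenotype length must match number of individuals")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 individuals")
    if np.ptp(y) == 0:
        raise ValueError("phenotype is constant; marginal effects undefined")

    if trait_type == "quantitative":
        Xc = X - X.mean(axis=0)
        var = np.einsum("ij,ij->j", Xc, Xc)
        cov = Xc.T @ (y - y.mean())
        with np.errstate(invalid="ignore", divide="ignore"):
            beta = np.where(var > 0, cov / np.where(var > 0, var, 1.0), 0.0)
        return beta
    if trait_type == "binary":
        cases = y != 0
        carrier = X > 0
        a = np.sum(carrier[cases], axis=0).astype(float)   # carrier, case
        b = np.sum(carrier[~cases], axis=0).astype(float)  # carrier, control
        c = cases.sum() - a                                # non-carrier, case
        d = (~cases).sum() - b
        table = np.stack([a, b, c, d])
        zero = (table == 0).any(axis=0)
        table[:, zero] += 0.5
        a, b, c, d = table
        lor = np.log(a * d) - np.log(b * c)
        mono = np.all(X == X[0, :], axis=0)
        return np.where(mono, 0.0, lor)
    raise ValueError(f"trait_type must be 'quantitative' or 'binary', got {trait_type!r}")


def compute_weights(
    genotypes: GenotypeMatrix,
    kind: str = "MB",
    phenotype: np.ndarray | None = None,
    *,
    trait_type: str = "quantitative",
    signed: bool = False,
    classical: bool = False,
) -> WeightScheme:
    """Per-variant weights for one of the three score statistics.

    Parameters
    ----------
    kind : {"LL", "MB", "ME"}
        Weighting scheme (see module docstring).
    phenotype : array, required for kind="ME"
        Trait values used to estimate marginal effects.
    signed : bool
        For ME, keep the sign of the effect instead of its absolute value.
    classical : bool
        For MB, use the original 1/sqrt(n q (1-q)) weight instead of the
        plain inverse-MAF form.
    """
    if kind not in WEIGHT_KINDS:
        raise ValueError(f"kind must be one of {WEIGHT_KINDS}, got {kind!r}")
    m = genotypes.n_variants
    if kind == "LL":
        return WeightScheme("LL", np.ones(m))
    if kind == "MB":
        maf = genotypes.maf
        mono = maf == 0
        if mono.any():
            warnings.warn(
                f"{int(mono.sum())} monomorphic variant(s) under MB weighting; weight set to 0",
                stacklevel=2,
            )
        if classical:
            n = genotypes.n_individuals
            q = maf
            with np.errstate(divide="ignore", invalid="ignore"):
                w = np.where(mono, 0.0, 1.0 / np.sqrt(n * q * (1.0 - q)))
        else:
            with np.errstate(divide="ignore"):
                w = np.where(mono, 0.0, 1.0 / np.where(mono, 1.0, maf))
        return WeightScheme("MB", w)
    # kind == "ME"
    if phenotype is None:
        raise ValueError("phenotype is required for ME weights")
    beta = marginal_effects(genotypes, phenotype, trait_type=trait_type)
    w = beta if signed else np.abs(beta)
    return WeightScheme("ME", w)


def aggregate_score(
    genotypes: GenotypeMatrix | np.ndarray,
    subset: SnpSubset | np.ndarray,
    weights: WeightScheme | np.ndarray,
) -> np.ndarray:
    """Per-individual burden score for one subset: sum_i w_i * c_{I,i}.

    Missing genotype entries contribute 0 (treated as reference
    homozygote).  Returns one value per individual.
    """
    X = genotypes.dosage() if isinstance(genotypes, GenotypeMatrix) else np.nan_to_num(np.asarray(genotypes, dtype=float), nan=0.0)
    idx = subset.as_array() if isinstance(subset, SnpSubset) else np.asarray(subset, dtype=np.intp)
    w = weights.weights if isinstance(weights, WeightScheme) else np.asarray(weights, dtype=float)
    if idx.size == 0:
        raise ValueError("subset must be non-empty")
    if idx.max() >= X.shape[1] or w.shape[0] != X.shape[1]:
        raise ValueError("subset indices / weights do not match the genotype matrix")
    return X[:, idx] @ w[idx]
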