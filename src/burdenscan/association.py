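"""Association measures, the MCMC likelihood approximation, and PC adjustment.

Fitness of a subset is the squared Pearson correlation r^2 between its
burden score and the quantitative trait.  Under a normal linear model for
trait given score, the profile log-likelihood (up to an additive constant
that cancels in the Hastings ratio) is

    l = -(n / 2) * ln(1 - r^2),

which lets the sampler evaluate proposals from r alone.

Population-structure confounding is handled by regressing the phenotype
on the leading principal components of the column-standardized genotype
matrix and carrying the residual forward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix

__all__ = [
    "Phenotype",
    "Fitness",
    "fitness",
    "log_likelihood",
    "marginal_association",
    "PcAdjuster",
    "pc_adjust",
]

_R2_CLAMP = 1.0 - 1e-12


@dataclass(frozen=True)
class Phenotype:
    """One quantitative-trait replicate aligned to a genotype matrix."""

    values: np.ndarray
    replicate_id: int = 0
    trait_name: str = "trait"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(v)):
            raise ValueError("phenotype values must be finite")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class Fitness:
    """Pearson correlation between a score vector and the trait."""

    r: float
    n: int

    @property
    def r2(self) -> float:
        return self.r * self.r


def fitness(score: np.ndarray, phenotype: np.ndarray) -> Fitness:
    """Sample Pearson correlation of burden score against trait.

    A constant (zero-variance) score vector gets r = 0 by convention:
    subsets of rare variants can produce all-zero scores and the samplers
    must be able to traverse them.  A constant phenotype is an error.
    """
    s = np.asarray(score, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("score and phenotype must be 1-d arrays of equal length")
    n = s.shape[0]
    if n < 3:
        raise ValueError("need at least 3 individuals")
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y == 0:
        raise ValueError("phenotype is constant; association undefined")
    sc = s - s.mean()
    ss_s = sc @ sc
    if ss_s == 0:
        return Fitness(r=0.0, n=n)
    r = float((sc @ yc) / np.sqrt(ss_s * ss_y))
    r = float(np.clip(r, -1.0, 1.0))
    return Fitness(r=r, n=n)


def log_likelihood(fit: Fitness) -> float:
    """Profile log-likelihood -(n/2) ln(1 - r^2), clamped away from r^2 = 1."""
    r2 = min(fit.r2, _R2_CLAMP)
    return -0.5 * fit.n * np.log1p(-r2)


def marginal_association(
    genotypes: GenotypeMatrix | np.ndarray, phenotype: np.ndarray
) -> np.ndarray:
    """Per-variant squared Pearson correlation of allele count with trait.

    Monomorphic variants get 0.  This is the association measure that
    drives the samplers' proposal kernels and weighted initialization.
    """
    X = genotypes.dosage() if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    yc = y - y.mean()
    ss_y = yc @ yc
    if ss_y == 0:
        raise ValueError("phenotype is constant")
    Xc = X - X.mean(axis=0)
    var = np.einsum("ij,ij->j", Xc, Xc)
    cov = Xc.T @ yc
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(var > 0, cov**2 / (np.where(var > 0, var, 1.0) * ss_y), 0.0)
    return np.clip(r2, 0.0, 1.0)


class PcAdjuster(BaseEstimator):
    """Remove population-structure signal from a phenotype via genotype PCs.

    Fitting computes the top ``n_pcs`` principal-component scores of the
    column-standardized genotype matrix (monomorphic variants are dropped
    from the PCA but remain in the search space).  ``adjust`` then returns
    the least-squares residual of a phenotype on [intercept, PC1..PCn].
    PCs are computed once per genotype matrix; each phenotype replicate
    re-fits only the projection.

    Parameters
    ----------
    n_pcs : int, default 10
        Number of leading PCs to regress out.  ``n_pcs <= 0`` degrades to
        centering only.

    Attributes
    ----------
    pc_scores_ : ndarray of shape (n_individuals, n_pcs)
        Principal-component scores (unit-norm directions scaled by the
        singular values).
    explained_variance_ratio_ : ndarray
        Fraction of standardized-genotype variance per retained PC.
    """

    def __init__(self, n_pcs: int = 10):
        self.n_pcs = n_pcs

    def fit(self, X, y=None) -> "PcAdjuster":
        G = X.dosage() if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
        n = G.shape[0]
        n_pcs = int(self.n_pcs)
        if n_pcs >= n:
            raise ValueError("n_pcs must be smaller than the number of individuals")
        if n_pcs <= 0:
            self.pc_scores_ = np.empty((n, 0))
            self.explained_variance_ratio_ = np.empty(0)
            return self
        sd = G.std(axis=0, ddof=1)
        poly = sd > 0
        if poly.sum() < n_pcs:
            raise ValueError(
                f"need at least n_pcs={n_pcs} non-monomorphic variants, have {int(poly.sum())}"
            )
        Z = (G[:, poly] - G[:, poly].mean(axis=0)) / sd[poly]
        # thin SVD of the standardized matrix; scores = U * S
        U, S, _ = np.linalg.svd(Z, full_matrices=False)
        self.pc_scores_ = U[:, :n_pcs] * S[:n_pcs]
        self.explained_variance_ratio_ = (S[:n_pcs] ** 2) / np.sum(S**2)
        return self

    def adjust(self, phenotype: np.ndarray) -> np.ndarray:
        """Residual of the phenotype on [intercept, retained PCs]."""
        if not hasattr(self, "pc_scores_"):
            raise RuntimeError("PcAdjuster must be fitted before adjusting")
        y = np.asarray(phenotype, dtype=float)
        yc = y - y.mean()
        if self.pc_scores_.shape[1] == 0:
            return yc
        # PC scores are mutually orthogonal and mean-zero (columns of U*S
        # from a column-centered matrix), so projection is a direct inner
        # product per component.
        P = self.pc_scores_
        coef = (P.T @ yc) / np.einsum("ij,ij->j", P, P)
        return yc - P @ coef

    def transform(self, y):
        """Alias for :meth:`adjust` so the class composes as a transformer."""
        return self.adjust(np.asarray(y, dtype=float).ravel())


def pc_adjust(
    genotypes: GenotypeMatrix | np.ndarray,
    phenotype: np.ndarray,
    n_pcs: int = 10,
) -> np.ndarray:
    """One-shot PC adjustment: fit a :class:`PcAdjuster` and residualize."""
    return PcAdjuster(n_pcs=n_pcs).fit(genotypes).adjust(phenotype)
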