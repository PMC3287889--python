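"""Shared machinery for the subset-search estimators.

Both optimizers move through the space of fixed-size variant subsets,
scoring each subset by the squared Pearson correlation between its burden
score and the trait.  This module holds the precomputed search context
(weighted dosage columns, centered trait, proposal-kernel weights) and the
scikit-learn estimator base class they both extend.
"""

from __future__ import annotations

import numbers

import numpy as np
from sklearn.base import BaseEstimator

from .association import Fitness, log_likelihood, marginal_association
from .genotypes import GenotypeMatrix
from .score_stats import SnpSubset, WeightScheme, compute_weights

__all__ = ["BaseSubsetSearch", "SearchContext", "kernel_weights", "weighted_subset_sample"]

# fraction of the max marginal r^2 added to every kernel weight so that
# zero-association variants stay reachable (ergodicity floor)
KERNEL_FLOOR_FRAC = 0.01


def kernel_weights(r2_marginal: np.ndarray, floor_frac: float = KERNEL_FLOOR_FRAC) -> np.ndarray:
    """Association-proportional proposal weights with an ergodicity floor.

    weights = marginal r^2 + eps, eps = floor_frac * max(r^2).  A fully
    null panel (all r^2 = 0) degrades to uniform weights.
    """
    r2 = np.asarray(r2_marginal, dtype=float)
    top = r2.max() if r2.size else 0.0
    if top <= 0:
        return np.ones_like(r2)
    return r2 + floor_frac * top


def weighted_subset_sample(rng: np.random.Generator, weights: np.ndarray, k: int) -> np.ndarray:
    """k distinct indices drawn sequentially with probability ~ weights."""
    w = np.asarray(weights, dtype=float).copy()
    if k > w.size:
        raise ValueError("k exceeds the number of variants")
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative and not all zero")
    out = np.empty(k, dtype=np.intp)
    for j in range(k):
        cs = np.cumsum(w)
        u = rng.random() * cs[-1]
        i = int(np.searchsorted(cs, u, side="right"))
        i = min(i, w.size - 1)
        out[j] = i
        w[i] = 0.0
    return out


class SearchContext:
    """Precomputed quantities shared by every move of a search.

    Holds the weighted dosage matrix Xw (so a subset's score is a column
    sum), the centered trait, and the floored proposal-kernel weights.
    Built once per (genotypes, weights, phenotype) triple.
    """

    __slots__ = ("Xw", "yc", "ss_y", "kernel", "n", "m", "k")

    def __init__(
        self,
        dosage: np.ndarray,
        weights: np.ndarray,
        phenotype: np.ndarray,
        k: int,
        kernel: np.ndarray | None = None,
    ):
        X = np.asarray(dosage, dtype=float)
        y = np.asarray(phenotype, dtype=float)
        self.n, self.m = X.shape
        if y.shape != (self.n,):
            raise ValueError("phenotype length must match number of individuals")
        if not 1 <= k <= self.m:
            raise ValueError(f"subset size k={k} must be in [1, {self.m}]")
        self.k = int(k)
        self.Xw = X * np.asarray(weights, dtype=float)
        self.yc = y - y.mean()
        self.ss_y = float(self.yc @ self.yc)
        if self.ss_y == 0:
            raise ValueError("phenotype is constant")
        if kernel is None:
            kernel = kernel_weights(marginal_association(X, y))
        self.kernel = np.asarray(kernel, dtype=float)

    def score(self, members: np.ndarray) -> np.ndarray:
        return self.Xw[:, members].sum(axis=1)

    def r2(self, score: np.ndarray) -> float:
        sc = score - score.mean()
        ss_s = sc @ sc
        if ss_s == 0:
            return 0.0
        r2 = float((sc @ self.yc) ** 2 / (ss_s * self.ss_y))
        return min(r2, 1.0)

    def log_lik(self, r2: float) -> float:
        return log_likelihood(Fitness(r=np.sqrt(r2), n=self.n))


class BaseSubsetSearch(BaseEstimator):
    """Common fit plumbing for the MCMC and GA subset searchers.

    Subclasses implement ``_search(ctx, rng)`` returning a dict with keys
    ``best_members``, ``best_r2``, ``inclusion_freq`` and any
    search-specific extras.
    """

    def __init__(
        self,
        statistic: str = "MB",
        k: int = 20,
        random_state: int | None = None,
        signed_me: bool = False,
        classical_mb: bool = False,
    ):
        self.statistic = statistic
        self.k = k
        self.random_state = random_state
        self.signed_me = signed_me
        self.classical_mb = classical_mb

    # -- subclass hook -------------------------------------------------
    def _search(self, ctx: SearchContext, rng: np.random.Generator) -> dict:
        raise NotImplementedError

    def _as_genotypes(self, X) -> GenotypeMatrix:
        if isinstance(X, GenotypeMatrix):
            return X
        X = np.asarray(X, dtype=float)
        ids = [f"v{i}" for i in range(X.shape[1])]
        return GenotypeMatrix(
            counts=X,
            variant_ids=ids,
            chromosome=np.repeat("1", X.shape[1]),
            position=np.arange(1, X.shape[1] + 1),
        )

    def _rng(self) -> np.random.Generator:
        if self.random_state is None or isinstance(self.random_state, numbers.Integral):
            return np.random.default_rng(self.random_state)
        raise TypeError("random_state must be an int or None")

    def fit(self, X, y):
        """Search for the k-variant subset whose burden score best tracks y.

        Parameters
        ----------
        X : GenotypeMatrix or array of shape (n_individuals, n_variants)
            Allele counts in {0, 1, 2} (nan = missing).
        y : array of shape (n_individuals,)
            Quantitative trait, typically already PC-adjusted.
        """
        G = self._as_genotypes(X)
        y = np.asarray(y, dtype=float).ravel()
        self.weights_ = compute_weights(
            G,
            kind=self.statistic,
            phenotype=y if self.statistic == "ME" else None,
            signed=self.signed_me,
            classical=self.classical_mb,
        )
        dosage = G.dosage()
        self.kernel_weights_ = kernel_weights(marginal_association(dosage, y))
        ctx = SearchContext(dosage, self.weights_.weights, y, self.k, kernel=self.kernel_weights_)
        out = self._search(ctx, self._rng())
        members = np.sort(np.asarray(out["best_members"], dtype=np.intp))
        self.best_subset_ = SnpSubset.from_indices(members)
        self.best_fitness_ = Fitness(r=float(np.sqrt(out["best_r2"])), n=ctx.n)
        self.inclusion_freq_ = np.asarray(out["inclusion_freq"], dtype=float)
        self.n_features_in_ = ctx.m
        self._extras_ = {
            key: val
            for key, val in out.items()
            if key not in ("best_members", "best_r2", "inclusion_freq")
        }
        for key, val in self._extras_.items():
            setattr(self, key + "_", val)
        return self

    def get_support(self, indices: bool = False):
        """Mask (or indices) of the variants in the best subset found."""
        if not hasattr(self, "best_subset_"):
            raise RuntimeError("estimator is not fitted")
        idx = self.best_subset_.as_array()
        if indices:
            return idx
        mask = np.zeros(self.n_features_in_, dtype=bool)
        mask[idx] = True
        return mask

    def transform(self, X):
        """Burden score of the best subset, shape (n_individuals, 1)."""
        if not hasattr(self, "best_subset_"):
            raise RuntimeError("estimator is not fitted")
        G = self._as_genotypes(X)
        score = G.dosage()[:, self.best_subset_.as_array()] @ self.weights_.weights[
            self.best_subset_.as_array()
        ]
        return score[:, None]

    def fit_transform(self, X, y):
        return self.fit(X, y).transform(X)
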