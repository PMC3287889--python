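"""Genotype matrix container for rare-variant subset searches.

Genotypes are stored as minor-allele counts (0/1/2) in an individuals x
variants array, with ``nan`` marking missing calls.  Variant metadata
(identifier, chromosome, 1-based position, in-sample minor-allele
frequency) rides along so that region filtering and reporting keep
coordinates intact.  Internal variant indexing is 0-based throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix", "sample_maf"]


def sample_maf(counts: np.ndarray) -> np.ndarray:
    """In-sample minor-allele frequency per variant, folded into [0, 0.5].

    Missing entries (nan) are excluded from the denominator.  Columns with
    no observed genotypes get MAF 0.
    """
    counts = np.asarray(counts, dtype=float)
    n_obs = np.sum(~np.isnan(counts), axis=0)
    with np.errstate(invalid="ignore"):
        freq = np.nansum(counts, axis=0) / np.maximum(2 * n_obs, 1)
    freq = np.where(n_obs == 0, 0.0, freq)
    return np.minimum(freq, 1.0 - freq)


@dataclass
class GenotypeMatrix:
    """Individuals x variants allele-count matrix with variant metadata.

    Parameters
    ----------
    counts : ndarray of shape (n_individuals, n_variants)
        Minor-allele counts; entries in {0, 1, 2} or nan for missing.
    variant_ids : sequence of str
        Unique variant identifiers.
    chromosome : sequence of str
        Chromosome label per variant.
    position : sequence of int
        1-based physical position per variant.
    maf : ndarray, optional
        In-sample minor-allele frequency; recomputed from ``counts`` when
        omitted.
    individual_ids : sequence of str, optional
        Sample identifiers; defaults to ``ind0..ind{n-1}``.
    """

    counts: np.ndarray
    variant_ids: np.ndarray
    chromosome: np.ndarray
    position: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]
    individual_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-dimensional (individuals x variants)")
        self.variant_ids = np.asarray(self.variant_ids, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position = np.asarray(self.position, dtype=int)
        n_ind, n_var = self.counts.shape
        for name, arr in (
            ("variant_ids", self.variant_ids),
            ("chromosome", self.chromosome),
            ("position", self.position),
        ):
            if arr.shape != (n_var,):
                raise ValueError(f"{name} must have one entry per variant")
        if len(set(self.variant_ids)) != n_var:
            raise ValueError("variant_ids must be unique")
        valid = np.isnan(self.counts) | np.isin(self.counts, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("genotype entries must be 0, 1, 2 or missing")
        if self.maf is None:
            self.maf = sample_maf(self.counts)
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if self.maf.shape != (n_var,):
                raise ValueError("maf must have one entry per variant")
            if np.any((self.maf < 0) | (self.maf > 0.5)):
                raise ValueError("maf must lie in [0, 0.5]")
        if self.individual_ids is None:
            self.individual_ids = np.asarray(
                [f"ind{i}" for i in range(n_ind)], dtype=object
            )
        else:
            self.individual_ids = np.asarray(self.individual_ids, dtype=object)
            if self.individual_ids.shape != (n_ind,):
                raise ValueError("individual_ids must have one entry per individual")

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_variants(self) -> int:
        return self.counts.shape[1]

    def dosage(self) -> np.ndarray:
        """Counts with missing entries imputed as 0 (reference homozygote)."""
        return np.nan_to_num(self.counts, nan=0.0)

    def is_monomorphic(self) -> np.ndarray:
        """Boolean mask of variants with zero in-sample variance."""
        X = self.dosage()
        return np.all(X == X[0, :], axis=0)

    def subset_region(self, chromosome: str) -> "GenotypeMatrix":
        """Restrict to the variants on one chromosome, preserving order."""
        mask = self.chromosome == chromosome
        if not mask.any():
            raise KeyError(f"no variants on chromosome {chromosome!r}")
        return GenotypeMatrix(
            counts=self.counts[:, mask],
            variant_ids=self.variant_ids[mask],
            chromosome=self.chromosome[mask],
            position=self.position[mask],
            maf=self.maf[mask],
            individual_ids=self.individual_ids,
        )

    def variant_table(self) -> pd.DataFrame:
        """Variant metadata as a DataFrame (id, chromosome, position, maf)."""
        return pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chromosome": self.chromosome,
                "position": self.position,
                "maf": self.maf,
            }
        )
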