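"""Readers and writers: VCF and TSV genotypes, phenotype tables, results.

VCF positions are 1-based and preserved in every output; internal arrays
index variants 0-based.  The TSV genotype format is an individuals x
variants matrix of 0/1/2 counts (header row of variant IDs, first column
individual IDs) with a sidecar metadata table (variant_id, chromosome,
position).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .association import Phenotype
from .genotypes import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "read_vcf",
    "read_genotypes_tsv",
    "write_vcf",
    "write_genotypes_tsv",
    "read_phenotypes",
    "write_phenotypes_tsv",
    "write_json",
]

_MISSING = float("nan")


def read_genotypes(path, format: str = "vcf", metadata_path=None) -> GenotypeMatrix:
    """Dispatch to the VCF or TSV reader by ``format``."""
    if format == "vcf":
        return read_vcf(path)
    if format == "tsv":
        if metadata_path is None:
            metadata_path = Path(str(path)).with_suffix(".variants.tsv")
        return read_genotypes_tsv(path, metadata_path)
    raise ValueError(f"format must be 'vcf' or 'tsv', got {format!r}")


def read_vcf(path) -> GenotypeMatrix:
    """Load a biallelic VCF into allele counts (number of ALT alleles).

    Multi-allelic records are rejected with an error naming the record;
    missing genotypes become nan.
    """
    from cyvcf2 import VCF  # deferred: optional extra

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows, ids, chroms, positions = [], [], [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ValueError(
                f"non-biallelic record at {variant.CHROM}:{variant.POS} "
                f"(ALT={variant.ALT}); split multi-allelic sites first"
            )
        counts = np.empty(len(samples))
        for i, gt in enumerate(variant.genotypes):
            a = gt[:-1]  # trailing element is the phased flag
            if any(al < 0 for al in a):
                counts[i] = _MISSING
            else:
                counts[i] = sum(1 for al in a if al > 0)
        rows.append(counts)
        vid = variant.ID if variant.ID not in (None, ".") else f"{variant.CHROM}:{variant.POS}"
        ids.append(vid)
        chroms.append(variant.CHROM)
        positions.append(variant.POS)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    return GenotypeMatrix(
        counts=np.asarray(rows).T,
        variant_ids=ids,
        chromosome=chroms,
        position=positions,
        individual_ids=samples,
    )


def read_genotypes_tsv(path, metadata_path) -> GenotypeMatrix:
    """Load the TSV matrix + metadata sidecar."""
    mat = pd.read_csv(path, sep="\t", index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"chromosome": str})
    required = {"variant_id", "chromosome", "position"}
    if not required <= set(meta.columns):
        raise ValueError(f"metadata must have columns {sorted(required)}")
    meta = meta.set_index("variant_id").loc[list(mat.columns)]
    return GenotypeMatrix(
        counts=mat.to_numpy(dtype=float),
        variant_ids=list(mat.columns),
        chromosome=meta["chromosome"].to_numpy(),
        position=meta["position"].to_numpy(),
        individual_ids=list(mat.index.astype(str)),
    )


def write_vcf(genotypes: GenotypeMatrix, path) -> None:
    """Emit a minimal unphased GT-only VCF 4.2 (REF=A, ALT=T placeholders)."""
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(genotypes.chromosome):
            fh.write(f"##contig=<ID={chrom}>\n")
        header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "FORMAT"]
        fh.write("\t".join(header[:7] + ["INFO", "FORMAT"] + list(map(str, genotypes.individual_ids))) + "\n")
        for j in range(genotypes.n_variants):
            gts = [
                gt_map.get(genotypes.counts[i, j], "./.")
                for i in range(genotypes.n_individuals)
            ]
            row = [
                str(genotypes.chromosome[j]),
                str(int(genotypes.position[j])),
                str(genotypes.variant_ids[j]),
                "A",
                "T",
                ".",
                "PASS",
                ".",
                "GT",
            ] + gts
            fh.write("\t".join(row) + "\n")


def write_genotypes_tsv(genotypes: GenotypeMatrix, path, metadata_path) -> None:
    """Write the matrix and its metadata sidecar."""
    pd.DataFrame(
        genotypes.counts,
        index=pd.Index(genotypes.individual_ids, name="individual_id"),
        columns=list(genotypes.variant_ids),
    ).to_csv(path, sep="\t")
    genotypes.variant_table().to_csv(metadata_path, sep="\t", index=False)


def read_phenotypes(path, individual_ids=None) -> list:
    """Load a phenotype TSV (ID column + one column per trait replicate).

    When ``individual_ids`` is given, rows are realigned to that order;
    unknown or missing IDs are an error listing the offenders.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if individual_ids is not None:
        wanted = [str(i) for i in individual_ids]
        missing = sorted(set(wanted) - set(df.index))
        extra = sorted(set(df.index) - set(wanted))
        if missing or extra:
            raise ValueError(
                f"phenotype IDs do not match genotypes; missing={missing[:5]}, unknown={extra[:5]}"
            )
        df = df.loc[wanted]
    phenotypes = []
    for r, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.index[vals.isna()][:5].tolist()
            raise ValueError(f"non-numeric phenotype values in column {col!r} at {bad}")
        phenotypes.append(Phenotype(values=vals.to_numpy(), replicate_id=r, trait_name=col))
    if not phenotypes:
        raise ValueError(f"no trait columns in {path}")
    return phenotypes


def write_phenotypes_tsv(phenotypes, individual_ids, path) -> None:
    df = pd.DataFrame(
        {p.trait_name if len(phenotypes) == 1 else f"{p.trait_name}_{p.replicate_id}": p.values for p in phenotypes},
        index=pd.Index(individual_ids, name="individual_id"),
    )
    df.to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        if isinstance(o, frozenset):
            return sorted(o)
        return str(o)

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=default)
        fh.write("\n")
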