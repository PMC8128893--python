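"""Plain-text readers and writers for the pipeline's tables.

Everything is TSV; genotypes are a delimited dosage matrix with a
sidecar SNP table, and the LD reference is a directory with one SNP
table and one correlation matrix per gene.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from crosstwas.simulate import Genotypes, LdReference

GWAS_COLUMNS = ["snp", "chr", "pos", "a1", "a2", "z", "n", "p"]
WEIGHT_COLUMNS = ["gene_id", "tissue_id", "snp_id", "effect_allele", "other_allele", "weight"]
ANNOTATION_COLUMNS = ["gene_id", "chr", "start", "end"]


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def _read_checked(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    return df


def read_gwas(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, GWAS_COLUMNS[:7])


def read_weights(path: str | Path) -> pd.DataFrame:
    df = _read_checked(path, WEIGHT_COLUMNS)
    if df.duplicated(["gene_id", "tissue_id", "snp_id"]).any():
        raise ValueError(f"{path}: duplicate (gene, tissue, snp) rows")
    return df


def read_annotation(path: str | Path) -> pd.DataFrame:
    return _read_checked(path, ANNOTATION_COLUMNS)


def write_genotypes(genotypes: Genotypes, prefix: str | Path) -> None:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.savetxt(f"{prefix}.dosage.tsv", genotypes.X, fmt="%d", delimiter="\t")
    write_tsv(genotypes.snps, f"{prefix}.snps.tsv")


def read_genotypes(prefix: str | Path) -> Genotypes:
    X = np.loadtxt(f"{prefix}.dosage.tsv", dtype=np.int8, delimiter="\t", ndmin=2)
    snps = pd.read_csv(f"{prefix}.snps.tsv", sep="\t", float_precision="round_trip")
    return Genotypes(X=X, snps=snps)


def write_ld(ld: LdReference, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for gene, (snps, D) in ld.genes.items():
        write_tsv(snps, directory / f"{gene}.snps.tsv")
        np.savetxt(directory / f"{gene}.D.tsv", D, delimiter="\t", fmt="%.17g")


def read_ld(directory: str | Path) -> LdReference:
    directory = Path(directory)
    ld = LdReference()
    for snp_path in sorted(directory.glob("*.snps.tsv")):
        gene = snp_path.name[: -len(".snps.tsv")]
        snps = pd.read_csv(snp_path, sep="\t", float_precision="round_trip")
        D = np.loadtxt(directory / f"{gene}.D.tsv", delimiter="\t", ndmin=2)
        ld.genes[gene] = (snps, D)
    return ld
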