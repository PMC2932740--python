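"""File formats: VCF v4.2 genotypes, genotype/phenotype/kinship/truth TSVs.

The VCF dialect is deliberately narrow: unphased diploid autosomal GT on
contig "1" with a single ALT allele per record.  Multi-allelic or phased
records are rejected loudly rather than silently recoded.  Reading goes
through cyvcf2; writing emits the dialect directly.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .models import InvalidParameterError, KinshipMatrix
from .sim import GenotypeMatrix, StudyDesign

__all__ = [
    "UnsupportedDialectError",
    "write_vcf",
    "read_vcf",
    "write_tsv",
    "read_tsv",
    "write_pheno",
    "read_pheno",
    "write_kinship",
    "read_kinship",
    "write_truth",
]

_GT_STRINGS = {0: "0/0", 1: "0/1", 2: "1/1"}


class UnsupportedDialectError(ValueError):
    """A record falls outside the supported VCF dialect (names the record)."""


def write_vcf(panel: GenotypeMatrix, design: StudyDesign | None, path: str | os.PathLike) -> None:
    """Write a panel as uncompressed VCF v4.2 (contig 1, sequential positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=1>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(panel.sample_ids)
            + "\n"
        )
        counts = panel.counts
        missing = panel.missing
        for j in range(panel.n_snps):
            gts = [
                "./." if missing[i, j] else _GT_STRINGS[int(counts[i, j])]
                for i in range(panel.n_samples)
            ]
            fh.write(
                f"1\t{j + 1}\t{panel.snp_ids[j]}\t{panel.ref[j]}\t{panel.alt[j]}"
                f"\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def read_vcf(path: str | os.PathLike) -> tuple[GenotypeMatrix, list[str]]:
    """Read a VCF into a GenotypeMatrix; returns (panel, sample_ids).

    Raises :class:`UnsupportedDialectError` on multi-allelic or phased
    records, naming the offending record.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    counts_cols: list[np.ndarray] = []
    missing_cols: list[np.ndarray] = []
    snp_ids: list[str] = []
    ref: list[str] = []
    alt: list[str] = []
    for var in vcf:
        label = var.ID or f"{var.CHROM}:{var.POS}"
        if len(var.ALT) != 1:
            raise UnsupportedDialectError(
                f"record {label}: expected exactly one ALT allele, got {var.ALT}"
            )
        geno = np.asarray(var.genotypes, dtype=object)  # rows [a1, a2, phased]
        if any(bool(g[-1]) for g in geno):
            raise UnsupportedDialectError(f"record {label}: phased genotypes are unsupported")
        gt = np.asarray(var.gt_types, dtype=np.int64)  # 0,1,2 counts; 3 = missing
        miss = gt == 3
        gt = np.where(miss, 0, gt)
        counts_cols.append(gt.astype(np.int8))
        missing_cols.append(miss)
        snp_ids.append(label)
        ref.append(var.REF)
        alt.append(var.ALT[0])
    vcf.close()
    if not snp_ids:
        raise UnsupportedDialectError(f"{path}: VCF contains no records")
    counts = np.column_stack(counts_cols)
    missing = np.column_stack(missing_cols)
    return GenotypeMatrix(counts, missing, snp_ids, samples, ref, alt), samples


def write_tsv(panel: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Genotype TSV: header of sample IDs, one row per SNP, NA for missing."""
    g = panel.counts.astype(object)
    g[panel.missing] = "NA"
    df = pd.DataFrame(g.T, columns=panel.sample_ids)
    df.insert(0, "snp_id", panel.snp_ids)
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path: str | os.PathLike) -> GenotypeMatrix:
    """Read the genotype TSV dialect; parse errors carry the line number."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.columns[0] != "snp_id":
        raise InvalidParameterError(f"{path}: first column must be 'snp_id'")
    sample_ids = list(df.columns[1:])
    snp_ids = df["snp_id"].tolist()
    body = df.iloc[:, 1:].to_numpy(dtype=object)
    counts = np.zeros(body.shape, dtype=np.int8)
    missing = np.zeros(body.shape, dtype=bool)
    for r in range(body.shape[0]):
        for c in range(body.shape[1]):
            tok = body[r, c]
            if tok == "NA":
                missing[r, c] = True
            elif tok in ("0", "1", "2"):
                counts[r, c] = int(tok)
            else:
                raise InvalidParameterError(
                    f"{path}: line {r + 2}: token {tok!r} is not one of 0, 1, 2, NA"
                )
    return GenotypeMatrix(counts.T, missing.T, snp_ids, sample_ids)


def write_pheno(design: StudyDesign, sample_ids: list[str], path: str | os.PathLike) -> None:
    """Phenotype TSV with columns sample_id, status, site."""
    site = design.site_label if design.site_label is not None else [""] * design.n
    pd.DataFrame({"sample_id": sample_ids, "status": design.status, "site": site}).to_csv(
        path, sep="\t", index=False
    )


def read_pheno(path: str | os.PathLike) -> tuple[StudyDesign, list[str]]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "site": str}, keep_default_na=False)
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise InvalidParameterError(f"{path}: missing required column {col!r}")
    status = df["status"].astype(int).to_numpy()
    site = df["site"].tolist() if "site" in df.columns else None
    return StudyDesign(status, site), df["sample_id"].tolist()


def write_kinship(k: KinshipMatrix, path: str | os.PathLike) -> None:
    """Kinship TSV: header of sample IDs, full matrix at 10 significant digits."""
    with open(path, "w") as fh:
        fh.write("sample_id\t" + "\t".join(k.sample_ids) + "\n")
        for i, sid in enumerate(k.sample_ids):
            fh.write(sid + "\t" + "\t".join(f"{v:.10g}" for v in k.values[i]) + "\n")


def read_kinship(path: str | os.PathLike) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    ids = list(df.columns)
    if list(df.index.astype(str)) != ids:
        raise InvalidParameterError(f"{path}: kinship row and column sample IDs disagree")
    return KinshipMatrix(df.to_numpy(dtype=float), ids)


def write_truth(truth: dict[str, pd.DataFrame], prefix: str | os.PathLike) -> None:
    """Write truth tables next to a panel as <prefix>.truth_snps/samples.tsv."""
    truth["snps"].to_csv(f"{prefix}.truth_snps.tsv", sep="\t", index=False)
    truth["samples"].to_csv(f"{prefix}.truth_samples.tsv", sep="\t", index=False)
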