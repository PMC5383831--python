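"""Readers and writers for the pipeline's plain-text artefacts.

VCF v4.2 (GT field only) for genotypes, tab-separated matrices for read
counts, a tab-separated metadata table, and a key/value run summary.
All round trips are lossless for in-domain values.
"""

from __future__ import annotations

import os
from typing import Mapping

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .data_model import (
    FEMALE,
    MALE,
    MISSING,
    UNKNOWN,
    GenotypeMatrix,
    PresenceMatrix,
    SampleTable,
    SnpRecord,
    ValidationError,
)

_GT_STRING = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}

_SEX_TOKENS = {
    "m": MALE,
    "male": MALE,
    "f": FEMALE,
    "female": FEMALE,
    "na": UNKNOWN,
    "unknown": UNKNOWN,
}


def read_vcf(path: str, strict: bool = False) -> GenotypeMatrix:
    """Load a biallelic-SNP VCF as alternate-allele counts.

    ``./.`` (and half calls) become the missing sentinel.  Records that
    are not biallelic SNPs are skipped, or rejected when ``strict``.
    """
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare OSError on malformed headers
        raise ValidationError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if len(set(samples)) != len(samples):
        raise ValidationError("duplicated sample name in VCF header")
    snps: list[SnpRecord] = []
    columns: list[np.ndarray] = []
    for v in vcf:
        biallelic_snp = (
            len(v.ALT) == 1 and len(v.REF) == 1 and len(v.ALT[0]) == 1
            and v.REF != v.ALT[0]
        )
        if not biallelic_snp:
            if strict:
                raise ValidationError(
                    f"record {v.CHROM}:{v.POS} is not a biallelic SNP"
                )
            continue
        geno = np.asarray([g[:2] for g in v.genotypes], dtype=np.int64)
        col = geno.sum(axis=1)
        col[(geno < 0).any(axis=1)] = MISSING
        columns.append(col.astype(np.int16))
        locus_id = v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}"
        snps.append(SnpRecord(locus_id, v.REF, v.ALT[0], position=v.POS))
    values = (
        np.stack(columns, axis=1)
        if columns
        else np.zeros((len(samples), 0), dtype=np.int16)
    )
    return GenotypeMatrix(samples=samples, snps=snps, values=values)


def write_vcf(genotypes: GenotypeMatrix, path: str, contig: str = "catalog") -> None:
    """Write a minimal VCF v4.2 with GT only, one record per SNP.

    POS is the SNP's position when set, else its 1-based column index.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=radgsd\n")
        fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(genotypes.samples)
            + "\n"
        )
        for j, snp in enumerate(genotypes.snps):
            pos = snp.position if snp.position is not None else j + 1
            gts = "\t".join(_GT_STRING[int(g)] for g in genotypes.values[:, j])
            fh.write(
                f"{contig}\t{pos}\t{snp.locus_id}\t{snp.allele_ref}\t"
                f"{snp.allele_alt}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_counts_tsv(path: str) -> PresenceMatrix:
    """Load a locus x sample read-count TSV (loci as rows)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"ragged or malformed counts table {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValidationError(f"ragged counts table {path}: empty cells found")
    try:
        counts = df.to_numpy(dtype=np.int64)
        if not (df.to_numpy(dtype=float) == counts).all():
            raise ValueError
    except ValueError as exc:
        raise ValidationError(f"non-integer read count in {path}") from exc
    if (counts < 0).any():
        raise ValidationError(f"negative read count in {path}")
    return PresenceMatrix(
        samples=[str(c) for c in df.columns],
        loci=[str(i) for i in df.index],
        counts=counts.T.copy(),
    )


def write_counts_tsv(presence: PresenceMatrix, path: str) -> None:
    df = pd.DataFrame(
        presence.counts.T, index=presence.loci, columns=presence.samples
    )
    df.to_csv(path, sep="\t", index_label="locus_id")


def read_metadata_tsv(path: str) -> SampleTable:
    """Load sample metadata (sample_id, population, phenotype_sex).

    Sex tokens are case-insensitive: m/f/male/female/unknown/NA.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "population", "phenotype_sex"}
    if not required.issubset(df.columns):
        raise ValidationError(
            f"metadata {path} must have columns {sorted(required)}"
        )
    sexes: list[str] = []
    for raw in df["phenotype_sex"]:
        token = "na" if pd.isna(raw) else str(raw).strip().lower()
        if token not in _SEX_TOKENS:
            raise ValidationError(f"unrecognized sex token {raw!r} in {path}")
        sexes.append(_SEX_TOKENS[token])
    return SampleTable(
        sample_ids=list(df["sample_id"]),
        populations=list(df["population"]),
        phenotype_sex=sexes,
    )


def write_metadata_tsv(table: SampleTable, path: str) -> None:
    pd.DataFrame(
        {
            "sample_id": table.sample_ids,
            "population": table.populations,
            "phenotype_sex": table.phenotype_sex,
        }
    ).to_csv(path, sep="\t", index=False)


def write_summary(summary: Mapping[str, object], path: str) -> None:
    """Write a run summary as deterministic key<TAB>value lines."""
    with open(path, "w") as fh:
        for key, value in summary.items():
            fh.write(f"{key}\t{_format_value(value)}\n")


def read_summary(path: str) -> dict[str, str]:
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            key, _, value = line.rstrip("\n").partition("\t")
            out[key] = value
    return out


def _format_value(value: object) -> str:
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return f"{value:.10g}"
    return str(value)


def ensure_dir(path: str) -> str:
    os.makedirs(path, exist_ok=True)
    return path
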