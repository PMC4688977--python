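"""Readers and writers for the plain-text interchange formats.

Genotypes travel either as VCF v4.2 (GT, plus DS for imputed dosages;
one contig per chromosome) or as a 0/1/2 matrix TSV with individuals in
rows; the SNP map, pedigree, phenotypes and EBVs are headered TSVs.
VCF reading uses cyvcf2 when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix, SNPMap
from .popsim import EBVRecord

__all__ = [
    "write_genotype_tsv",
    "read_genotype_tsv",
    "write_snp_map",
    "read_snp_map",
    "write_vcf",
    "read_vcf",
    "write_ebv_tsv",
    "read_ebv_tsv",
    "write_qc_report",
]

_GT_CODE = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_genotype_tsv(genotypes: GenotypeMatrix, path):
    df = pd.DataFrame(genotypes.values, index=genotypes.ids, columns=genotypes.snp_ids)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_genotype_tsv(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return GenotypeMatrix(
        list(df.index), df.columns.to_numpy(), df.to_numpy(dtype=np.int8)
    )


def write_snp_map(snp_map: SNPMap, path):
    snp_map.table.to_csv(path, sep="\t", index=False)


def read_snp_map(path) -> SNPMap:
    return SNPMap(pd.read_csv(path, sep="\t"))


def write_vcf(
    genotypes: GenotypeMatrix, snp_map: SNPMap, path, dosages: np.ndarray | None = None
):
    """VCF v4.2 with GT (and DS when dosages are given); REF=A, ALT=B as
    placeholder alleles for array data."""
    if not np.array_equal(snp_map.snp_ids, genotypes.snp_ids):
        raise ValueError("snp map does not match genotype columns")
    tab = snp_map.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=ovimp\n")
        for chrom in snp_map.chromosomes:
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosages is not None:
            fh.write(
                '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Imputed dosage">\n'
            )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in genotypes.ids)
            + "\n"
        )
        fmt = "GT:DS" if dosages is not None else "GT"
        for j in range(genotypes.n_markers):
            fields = [
                str(tab["chrom"].iloc[j]),
                str(tab["pos_bp"].iloc[j]),
                str(tab["snp_id"].iloc[j]),
                "A",
                "B",
                ".",
                "PASS",
                ".",
                fmt,
            ]
            col = genotypes.values[:, j]
            if dosages is not None:
                cells = [
                    f"{_GT_CODE[int(g)]}:{dosages[i, j]:.3f}" for i, g in enumerate(col)
                ]
            else:
                cells = [_GT_CODE[int(g)] for g in col]
            fh.write("\t".join(fields + cells) + "\n")


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read GT genotypes from a VCF; returns the matrix and a marker table
    (snp_id, chrom, pos_bp). Requires cyvcf2."""
    try:
        from cyvcf2 import VCF
    except ImportError as e:  # pragma: no cover
        raise ImportError("reading VCF requires cyvcf2") from e
    vcf = VCF(str(path))
    ids = list(vcf.samples)
    rows, meta = [], []
    for var in vcf:
        gt = var.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        codes = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        rows.append(codes.astype(np.int8))
        meta.append({"snp_id": var.ID, "chrom": var.CHROM, "pos_bp": var.POS})
    values = np.array(rows, dtype=np.int8).T if rows else np.empty((len(ids), 0), np.int8)
    meta_df = pd.DataFrame(meta)
    return GenotypeMatrix(ids, meta_df["snp_id"].to_numpy(), values), meta_df


def write_ebv_tsv(records: list, path):
    pd.DataFrame(
        [
            {
                "id": r.id,
                "true_bv": r.true_bv,
                "reported_ebv": r.reported_ebv,
                "target_accuracy": r.target_accuracy,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)


def read_ebv_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t")
    return [
        EBVRecord(row.id, row.true_bv, row.reported_ebv, row.target_accuracy)
        for row in df.itertuples()
    ]


def write_qc_report(report, path):
    Path(path).write_text(json.dumps(report.to_dict(), indent=2))
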