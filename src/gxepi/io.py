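"""Readers and writers for cohort tables and genotype matrices.

Genotype matrices travel as TSV (rows = participants, columns = rsids, values
minor-allele counts 0/1/2, '.' for missing) or as minimal VCFv4.2 with a GT
FORMAT field only.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd


def write_cohort_tsv(cohort: pd.DataFrame, path: str | os.PathLike) -> None:
    cohort.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_cohort_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"],
                       dtype={"participant_id": str})


def write_genotypes_tsv(geno: pd.DataFrame, path: str | os.PathLike) -> None:
    out = geno.copy()
    out.index.name = "participant_id"
    formatted = out.map(lambda v: "." if pd.isna(v) else str(int(v)))
    formatted.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="participant_id",
                     na_values=["."], dtype=str)
    return df.astype(float)


def write_vcf(geno: pd.DataFrame, path: str | os.PathLike,
              genes: dict[str, str] | None = None) -> None:
    """Minimal VCFv4.2: one pseudo-contig per gene, GT field only.

    Alleles are written as A (major, REF) / G (minor, ALT) placeholders; only
    the minor-allele dosage is meaningful.
    """
    samples = list(geno.index)
    gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        contigs = sorted(set((genes or {}).values())) or ["chr1"]
        for c in contigs:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for pos, rsid in enumerate(geno.columns, start=1):
            chrom = (genes or {}).get(rsid, "chr1")
            calls = [
                "./." if pd.isna(v) else gt_map[int(v)]
                for v in geno[rsid].to_numpy()
            ]
            fh.write(f"{chrom}\t{pos}\t{rsid}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_vcf(path: str | os.PathLike) -> pd.DataFrame:
    """Read a VCF into a participants x rsids minor-allele-count matrix.

    Uses cyvcf2 when importable, otherwise a plain-text GT parser (sufficient
    for the minimal GT-only files this package writes).
    """
    try:
        from cyvcf2 import VCF
    except ImportError:
        VCF = None
    if VCF is not None:
        vcf = VCF(os.fspath(path))
        samples = list(vcf.samples)
        cols, names = [], []
        for var in vcf:
            # gt_types: 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
            g = np.asarray(var.gt_types, dtype=float)
            g[g == 2] = np.nan
            g[g == 3] = 2.0
            cols.append(g)
            names.append(var.ID or f"{var.CHROM}:{var.POS}")
        vcf.close()
        return pd.DataFrame(np.column_stack(cols) if cols else [],
                            index=samples, columns=names)
    return _read_vcf_text(path)


def _read_vcf_text(path: str | os.PathLike) -> pd.DataFrame:
    samples: list[str] = []
    names: list[str] = []
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("##") or not line:
                continue
            fields = line.split("\t")
            if line.startswith("#CHROM"):
                samples = fields[9:]
                continue
            names.append(fields[2])
            fmt = fields[8].split(":")
            gt_i = fmt.index("GT")
            calls = np.empty(len(samples))
            for j, cell in enumerate(fields[9:]):
                gt = cell.split(":")[gt_i].replace("|", "/")
                alleles = gt.split("/")
                if "." in alleles:
                    calls[j] = np.nan
                else:
                    calls[j] = sum(a != "0" for a in alleles)
            rows.append(calls)
    return pd.DataFrame(np.column_stack(rows) if rows else [],
                        index=samples, columns=names)
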