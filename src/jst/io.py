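"""Readers and writers for genotype, region and phenotype files.

Genotypes come either from VCF (diploid GT field, one file per cohort side)
or from a tab-delimited n x m table whose first column is the pair identifier
and whose remaining columns are SNP identifiers.  SNP metadata (id, chrom,
pos, ref, alt) rides along in a sites table; for the TSV path it is supplied
as a separate file.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

SITES_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


def read_genotype_tsv(path: str | Path) -> pd.DataFrame:
    """Genotype matrix TSV: first column sample/pair id, one column per SNP.

    Entries are allele counts 0/1/2; empty cells or 'NA' are missing.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    df = df.set_index(df.columns[0])
    df.index.name = "sample_id"
    return df.astype(float)


def read_sites_tsv(path: str | Path) -> pd.DataFrame:
    """SNP metadata TSV with columns snp_id, chrom, pos, ref, alt (1-based pos)."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in SITES_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sites file {path} lacks column(s): {missing}")
    df["pos"] = df["pos"].astype(int)
    return df[SITES_COLUMNS]


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a diploid VCF into (genotypes, sites).

    Genotypes are ALT-allele counts per sample (rows) and SNP (columns);
    missing calls become NaN.  Multi-allelic records are skipped with a count
    in the log, since the matching scores assume diallelic SNPs.
    """
    import logging

    from cyvcf2 import VCF

    logger = logging.getLogger(__name__)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows, sites, n_multi = [], [], 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        gt = var.gt_types.astype(float)  # 0/1/2 ALT count, 3 = unknown
        gt[gt == 3] = np.nan
        rows.append(gt)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        sites.append((snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
    vcf.close()
    if n_multi:
        logger.info("skipped %d multi-allelic VCF record(s)", n_multi)
    sites_df = pd.DataFrame(sites, columns=SITES_COLUMNS)
    geno = pd.DataFrame(
        np.array(rows).T if rows else np.empty((len(samples), 0)),
        index=pd.Index(samples, name="sample_id"),
        columns=sites_df["snp_id"],
    )
    return geno, sites_df


def read_genotypes(path: str | Path, sites: str | Path | None = None):
    """Dispatch on extension: .vcf/.vcf.gz -> VCF, otherwise TSV (+ sites file)."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    geno = read_genotype_tsv(path)
    sites_df = read_sites_tsv(sites) if sites is not None else None
    return geno, sites_df


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED regions (0-based half-open on disk) as 1-based inclusive intervals.

    Returns columns gene_id, chrom, start, end with start <= end, 1-based.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: malformed BED line (need >=3 fields)")
            chrom, start0, end0 = parts[0], int(parts[1]), int(parts[2])
            if end0 <= start0:
                raise ValueError(f"{path}:{ln}: empty/negative BED interval")
            gene_id = parts[3] if len(parts) > 3 else f"{chrom}:{start0}-{end0}"
            rows.append({"gene_id": gene_id, "chrom": str(chrom), "start": start0 + 1, "end": end0})
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def read_phenotype_table(path: str | Path, id_col: str = "pair_id") -> pd.DataFrame:
    """Delimited covariate/phenotype table indexed by pair id."""
    df = pd.read_csv(path, sep="\t", dtype={id_col: str})
    if id_col not in df.columns:
        raise ValueError(f"{path} lacks id column {id_col!r}")
    return df.set_index(id_col)


def write_match_scores(path: str | Path, scores: pd.DataFrame) -> None:
    """Write per-gene matching scores: pair_id, gene_id, score_type, z."""
    scores.to_csv(path, sep="\t", index=False)
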