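"""Gene-by-gene joint score test scan over a paired donor/recipient dataset.

Workflow: load and harmonise the four inputs (recipient genotypes, donor
genotypes, covariates, phenotype), filter SNPs by pooled minor-allele
frequency, group SNPs into gene regions, compute each gene's matching score,
run the joint score test per gene and score type, and adjust p-values across
genes by Benjamini-Hochberg within each score type.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, io
from .jst_core import PairedCohort, bh_adjust, jst_test
from .matching_scores import gene_score, pooled_maf

logger = logging.getLogger(__name__)


@dataclass
class GeneRegion:
    """A gene interval (1-based inclusive) and the SNP columns falling in it."""

    gene_id: str
    chrom: str
    start: int
    end: int
    snp_indices: np.ndarray

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")


@dataclass
class PairedData:
    """Harmonised genotype matrices plus covariates and outcome for n pairs."""

    pair_ids: list
    X_recipient: np.ndarray  # (n, m) minor-allele counts
    X_donor: np.ndarray
    sites: pd.DataFrame      # snp_id, chrom, pos, ref, alt, maf
    covariates: pd.DataFrame
    phenotype: np.ndarray
    outcome_type: str

    @property
    def n(self) -> int:
        return len(self.pair_ids)


@dataclass
class AnalysisReport:
    """Per gene x score type test results with BH-adjusted q-values."""

    table: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def write(self, out_tsv: str | Path, meta_json: str | Path | None = None) -> None:
        self.table.to_csv(out_tsv, sep="\t", index=False, float_format="%.6g")
        if meta_json is not None:
            Path(meta_json).write_text(json.dumps(self.metadata, indent=2, default=str))


def _infer_outcome_type(y: np.ndarray) -> str:
    vals = np.unique(y[~np.isnan(y)])
    return "binary" if np.isin(vals, (0.0, 1.0)).all() else "continuous"


def load_paired_data(
    geno_r: str | Path,
    geno_d: str | Path,
    covar: str | Path | None,
    pheno: str | Path,
    sites_r: str | Path | None = None,
    sites_d: str | Path | None = None,
    pheno_col: str | None = None,
    covar_cols: list | None = None,
    maf_threshold: float = 0.05,
    maf_basis: str = "pooled",
) -> PairedData:
    """Load and harmonise the four inputs into a PairedData bundle.

    Pair identifiers must agree across all files (donor and recipient
    genotype files index the *pair*, not the individual).  Variants are
    matched by snp_id; a variant whose REF/ALT are swapped between the donor
    and recipient files is flipped onto the recipient coding with a log
    record.  After harmonisation every SNP is re-coded to minor-allele counts
    and SNPs with MAF below ``maf_threshold`` are removed.

    ``maf_basis`` selects the samples the MAF is computed on: "pooled"
    (default; keeps D/R coding consistent), "recipient" or "donor".
    """
    gr, sr = io.read_genotypes(geno_r, sites_r)
    gd, sd = io.read_genotypes(geno_d, sites_d)
    ph = io.read_phenotype_table(pheno)
    cv = io.read_phenotype_table(covar) if covar is not None else None

    # align variants between the two genotype files
    common = [s for s in gr.columns if s in set(gd.columns)]
    if not common:
        raise ValueError("no shared SNP identifiers between donor and recipient files")
    gr, gd = gr[common], gd[common]
    if sr is not None and sd is not None:
        sr = sr.set_index("snp_id").loc[common]
        sd = sd.set_index("snp_id").loc[common]
        swapped = (sr["ref"].values == sd["alt"].values) & (sr["alt"].values == sd["ref"].values)
        conflict = ~swapped & (
            (sr["ref"].values != sd["ref"].values) | (sr["alt"].values != sd["alt"].values)
        )
        if conflict.any():
            bad = list(np.asarray(common)[conflict][:5])
            raise ValueError(f"allele-coding conflict between donor/recipient files at {bad}")
        if swapped.any():
            cols = np.asarray(common)[swapped]
            logger.info("flipping %d SNP(s) with swapped REF/ALT in donor file", len(cols))
            gd[cols] = 2.0 - gd[cols]
        sites = sr.reset_index()
    else:
        sites = pd.DataFrame(
            {"snp_id": common, "chrom": "NA", "pos": 0, "ref": "N", "alt": "N"}
        )

    # align pairs across all four inputs
    ids = [i for i in gr.index if i in set(gd.index) and i in set(ph.index)]
    for name, have in (("donor genotypes", gd.index), ("phenotype", ph.index)):
        miss = [i for i in gr.index if i not in set(have)]
        if miss:
            raise ValueError(f"pair id(s) missing from {name}: {miss}")
    if cv is not None:
        miss = [i for i in ids if i not in set(cv.index)]
        if miss:
            raise ValueError(f"pair id(s) missing from covariates: {miss}")
        cv = cv.loc[ids]
        if covar_cols is not None:
            cv = cv[covar_cols]
    else:
        cv = pd.DataFrame(index=pd.Index(ids, name="pair_id"))
    gr, gd, ph = gr.loc[ids], gd.loc[ids], ph.loc[ids]

    pheno_col = pheno_col or ph.columns[0]
    y = ph[pheno_col].to_numpy(dtype=float)

    X_R, X_D = gr.to_numpy(), gd.to_numpy()
    # re-code to minor-allele counts
    if maf_basis == "pooled":
        freq_src = np.vstack([X_R, X_D])
    elif maf_basis == "recipient":
        freq_src = X_R
    elif maf_basis == "donor":
        freq_src = X_D
    else:
        raise ValueError("maf_basis must be 'pooled', 'recipient' or 'donor'")
    alt_freq = np.nanmean(freq_src, axis=0) / 2.0
    flip = alt_freq > 0.5
    if flip.any():
        X_R[:, flip] = 2.0 - X_R[:, flip]
        X_D[:, flip] = 2.0 - X_D[:, flip]
        logger.info("re-coded %d SNP(s) to minor-allele counts", int(flip.sum()))
    maf = np.where(flip, 1.0 - alt_freq, alt_freq)

    keep = maf >= maf_threshold
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("removed %d SNP(s) with MAF < %g", n_drop, maf_threshold)
    sites = sites.loc[keep].reset_index(drop=True)
    sites["maf"] = maf[keep]

    return PairedData(
        pair_ids=ids,
        X_recipient=X_R[:, keep],
        X_donor=X_D[:, keep],
        sites=sites,
        covariates=cv,
        phenotype=y,
        outcome_type=_infer_outcome_type(y),
    )


def assign_genes(
    sites: pd.DataFrame, regions: pd.DataFrame, flank: int = 0
) -> list[GeneRegion]:
    """Assign SNPs to every overlapping region (1-based inclusive boundaries).

    A SNP may belong to several overlapping genes.  Regions containing no SNP
    are dropped with a log count.
    """
    out, n_empty = [], 0
    chrom = sites["chrom"].astype(str).to_numpy()
    pos = sites["pos"].to_numpy()
    for row in regions.itertuples(index=False):
        lo, hi = row.start - flank, row.end + flank
        idx = np.flatnonzero((chrom == str(row.chrom)) & (pos >= lo) & (pos <= hi))
        if idx.size == 0:
            n_empty += 1
            continue
        out.append(
            GeneRegion(
                gene_id=row.gene_id, chrom=str(row.chrom), start=lo, end=hi, snp_indices=idx
            )
        )
    if n_empty:
        logger.info("skipped %d region(s) containing no SNPs", n_empty)
    return out


def run_genome_scan(
    data: PairedData,
    regions: list[GeneRegion],
    score_types: tuple = ("ibs", "incomp", "ams", "mm"),
    var_explained: float = 0.85,
    bh_within_score_type: bool = True,
    weighted_score: bool = False,
) -> AnalysisReport:
    """Joint score test per gene and score type, with BH FDR across genes.

    BH adjustment is applied within each score type across genes by default
    (set ``bh_within_score_type=False`` to pool all tests).  Per-gene failures
    are recorded in the report and the scan continues.
    """
    W = data.covariates.to_numpy(dtype=float)
    rows = []
    for region in regions:
        idx = region.snp_indices
        X_R = data.X_recipient[:, idx]
        X_D = data.X_donor[:, idx]
        snp_ids = data.sites["snp_id"].to_numpy()[idx]
        for st in score_types:
            weights = 1.0 / data.sites["maf"].to_numpy()[idx] if weighted_score else None
            try:
                score = gene_score(X_D, X_R, st, weights=weights, snp_ids=list(snp_ids))
                cohort = PairedCohort(
                    Y=data.phenotype, W=W, X=X_R, Z=score.z, outcome_type=data.outcome_type
                )
                res = jst_test(cohort, var_explained=var_explained)
            except Exception as exc:  # per-gene failure: record and continue
                logger.warning("gene %s (%s) failed: %s", region.gene_id, st, exc)
                rows.append(
                    {
                        "gene_id": region.gene_id, "score_type": st,
                        "n_snps_used": len(idx), "s": np.nan, "df": np.nan,
                        "statistic": np.nan, "p_value": np.nan, "error": str(exc),
                    }
                )
                continue
            rows.append(
                {
                    "gene_id": region.gene_id, "score_type": st,
                    "n_snps_used": res.n_snps_used, "s": res.s, "df": res.df,
                    "statistic": res.statistic, "p_value": res.p_value, "error": "",
                }
            )
    table = pd.DataFrame(rows)

    table["fdr_q"] = np.nan
    ok = table["p_value"].notna()
    if bh_within_score_type:
        for st in score_types:
            mask = ok & (table["score_type"] == st)
            if mask.any():
                table.loc[mask, "fdr_q"] = bh_adjust(table.loc[mask, "p_value"].to_numpy())
    elif ok.any():
        table.loc[ok, "fdr_q"] = bh_adjust(table.loc[ok, "p_value"].to_numpy())

    metadata = {
        "version": __version__,
        "n_pairs": data.n,
        "n_genes": len(regions),
        "score_types": list(score_types),
        "var_explained": var_explained,
        "bh_within_score_type": bh_within_score_type,
        "outcome_type": data.outcome_type,
    }
    return AnalysisReport(table=table, metadata=metadata)
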