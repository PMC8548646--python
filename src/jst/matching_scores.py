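"""Gene-based donor/recipient matching scores.

A matching score summarises, for one donor/recipient (D/R) pair and one gene
region, how genetically different the donor is from the recipient.  Each SNP
contributes a small integer distance between the two diploid genotypes (coded
as minor-allele counts 0/1/2), and the gene score is the sum of those per-SNP
distances — optionally a weighted average with weights such as 1/MAF that
up-weight rarer variants.

Four single-SNP distance functions are provided:

``ibs``
    Identity-by-state mismatch ``|x_D - x_R|``: the number of allele copies
    by which the two genotypes differ.
``incomp``
    Incompatibility indicator: 1 if the genotypes differ at all.
``ams``
    Allogenomics mismatch: the number of donor allele *copies* whose allele
    type is absent from the recipient genotype.  Models exposure of the
    recipient immune system to non-self antigen; not symmetric in D/R.
``mm``
    Binary mismatch: 1 if the donor carries any allele type the recipient
    lacks, i.e. ``ams > 0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

SCORE_TYPES = ("ibs", "incomp", "ams", "mm")

# Per-SNP distance lookup tables, indexed [donor genotype, recipient genotype]
# with genotypes coded as minor-allele counts.  A genotype g corresponds to
# the allele multiset {g copies of alt, 2-g copies of ref} at a diallelic SNP.
_IBS_TABLE = np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0]], dtype=np.int64)
_INCOMP_TABLE = np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], dtype=np.int64)
_AMS_TABLE = np.array([[0, 0, 2], [1, 0, 1], [2, 0, 0]], dtype=np.int64)
_MM_TABLE = np.array([[0, 0, 1], [1, 0, 1], [1, 0, 0]], dtype=np.int64)

_TABLES = {
    "ibs": _IBS_TABLE,
    "incomp": _INCOMP_TABLE,
    "ams": _AMS_TABLE,
    "mm": _MM_TABLE,
}


def _check_genotype(x: int, who: str) -> int:
    xi = int(x)
    if xi not in (0, 1, 2):
        raise ValueError(f"{who} genotype must be in {{0,1,2}}, got {x!r}")
    return xi


def d_ibs(x_donor: int, x_recipient: int) -> int:
    """Identity-by-state distance ``|x_D - x_R|`` in {0, 1, 2}."""
    return int(
        _IBS_TABLE[_check_genotype(x_donor, "donor"), _check_genotype(x_recipient, "recipient")]
    )


def d_incomp(x_donor: int, x_recipient: int) -> int:
    """Incompatibility indicator: 1 if the genotypes differ, else 0."""
    return int(
        _INCOMP_TABLE[_check_genotype(x_donor, "donor"), _check_genotype(x_recipient, "recipient")]
    )


def d_ams(x_donor: int, x_recipient: int) -> int:
    """Allogenomics mismatch: donor allele copies of a type absent in the recipient.

    Each donor allele copy contributes 1 if its allele *type* does not occur
    in the recipient's genotype.  E.g. donor 2 (alt/alt) against recipient 0
    (ref/ref) gives 2; any pairing with a heterozygous recipient gives 0
    because the recipient carries both allele types.
    """
    return int(
        _AMS_TABLE[_check_genotype(x_donor, "donor"), _check_genotype(x_recipient, "recipient")]
    )


def d_mm(x_donor: int, x_recipient: int) -> int:
    """Binary mismatch: 1 if the donor carries any allele type the recipient lacks."""
    return int(
        _MM_TABLE[_check_genotype(x_donor, "donor"), _check_genotype(x_recipient, "recipient")]
    )


@dataclass
class MatchScore:
    """Per-pair gene-based matching score vector.

    Attributes
    ----------
    z : np.ndarray
        Length-n score, one value per D/R pair.  Non-negative; integer valued
        when unweighted.
    score_type : str
        One of ``{"ibs", "incomp", "ams", "mm"}``.
    snp_ids : list[str]
        Identifiers of the SNPs that were summed.
    weighted : bool
        Whether per-SNP weights were applied (weighted average form).
    weights : np.ndarray | None
        The positive per-SNP weights, when ``weighted``.
    """

    z: np.ndarray
    score_type: str
    snp_ids: list = field(default_factory=list)
    weighted: bool = False
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.score_type not in SCORE_TYPES:
            raise ValueError(f"score_type must be one of {SCORE_TYPES}")
        self.z = np.asarray(self.z, dtype=float)
        if np.any(self.z < 0):
            raise ValueError("matching scores must be non-negative")


def snp_distances(
    x_donor: np.ndarray,
    x_recipient: np.ndarray,
    score_type: str,
    missing_policy: str = "mean",
) -> np.ndarray:
    """Per-SNP distance matrix for paired genotype matrices.

    Parameters
    ----------
    x_donor, x_recipient : (n, m) arrays
        Minor-allele counts in {0, 1, 2}; NaN marks a missing genotype.
    score_type : str
        Distance function label.
    missing_policy : {"mean", "strict"}
        With ``"mean"``, a pair missing either genotype at SNP j contributes
        the mean distance of the complete pairs at j (keeps n constant per
        gene); ``"strict"`` raises on any missing value.

    Returns
    -------
    (n, m) float array of distances.
    """
    if score_type not in _TABLES:
        raise ValueError(f"unknown score_type {score_type!r}; choose from {SCORE_TYPES}")
    xd = np.asarray(x_donor, dtype=float)
    xr = np.asarray(x_recipient, dtype=float)
    if xd.ndim == 1:
        xd = xd[None, :]
    if xr.ndim == 1:
        xr = xr[None, :]
    if xd.shape != xr.shape:
        raise ValueError(f"donor shape {xd.shape} != recipient shape {xr.shape}")

    miss = np.isnan(xd) | np.isnan(xr)
    observed = np.where(miss, 0, np.stack([xd, xr]))
    for arr, who in ((observed[0], "donor"), (observed[1], "recipient")):
        if not np.isin(arr, (0, 1, 2)).all():
            raise ValueError(f"{who} genotypes must be 0/1/2 minor-allele counts (or NaN)")

    table = _TABLES[score_type]
    dist = table[observed[0].astype(np.int64), observed[1].astype(np.int64)].astype(float)

    if miss.any():
        if missing_policy == "strict":
            raise ValueError(f"{int(miss.sum())} missing genotype(s) with missing_policy='strict'")
        if missing_policy != "mean":
            raise ValueError("missing_policy must be 'mean' or 'strict'")
        dist[miss] = np.nan
        col_mean = np.nanmean(np.where(miss, np.nan, dist), axis=0)
        # a SNP missing in every pair has no information; count it as 0 distance
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        dist = np.where(np.isnan(dist), col_mean[None, :], dist)
    return dist


def gene_score(
    x_donor: np.ndarray,
    x_recipient: np.ndarray,
    score_type: str,
    weights: Sequence[float] | np.ndarray | None = None,
    snp_ids: Sequence[str] | None = None,
    missing_policy: str = "mean",
) -> MatchScore:
    """Aggregate per-SNP D/R distances into a gene-based matching score.

    Unweighted: ``Z_i = sum_j D(x_ij^D, x_ij^R)``.  Weighted:
    ``Z_i = sum_j w_j D_j / sum_j w_j`` with all ``w_j > 0`` (e.g. ``1/MAF_j``
    to up-weight rare variants).
    """
    dist = snp_distances(x_donor, x_recipient, score_type, missing_policy=missing_policy)
    n, m = dist.shape
    ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(m)]
    if len(ids) != m:
        raise ValueError("snp_ids length does not match number of SNPs")

    if weights is None:
        z = dist.sum(axis=1)
        return MatchScore(z=z, score_type=score_type, snp_ids=ids)

    w = np.asarray(weights, dtype=float)
    if w.shape != (m,):
        raise ValueError(f"weights must have shape ({m},), got {w.shape}")
    if np.any(w <= 0) or not np.all(np.isfinite(w)):
        raise ValueError("weights must be finite and strictly positive")
    z = dist @ w / w.sum()
    return MatchScore(z=z, score_type=score_type, snp_ids=ids, weighted=True, weights=w)


def maf_weights(maf: np.ndarray) -> np.ndarray:
    """Inverse-MAF weights ``w_j = 1 / MAF_j`` for the weighted gene score."""
    maf = np.asarray(maf, dtype=float)
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("MAF values must lie in (0, 0.5]")
    return 1.0 / maf


def pooled_maf(x_donor: np.ndarray, x_recipient: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per SNP from pooled donor + recipient genotypes.

    Pooling keeps the allele coding consistent between the two members of each
    pair.  The returned frequency is folded to [0, 0.5].
    """
    pooled = np.vstack([np.asarray(x_donor, float), np.asarray(x_recipient, float)])
    freq = np.nanmean(pooled, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)
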