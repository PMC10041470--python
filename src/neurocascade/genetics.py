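"""Polygenic risk scores from additive genotypes and GWAS weights.

A PRS is the weighted sum of risk-allele counts over the SNPs surviving
standard filters: sample MAF, allele ambiguity (A/T and G/C pairs),
greedy LD clumping within a physical window and a GWAS significance
threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

AMBIGUOUS = {frozenset(("A", "T")), frozenset(("G", "C"))}

META_COLS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


@dataclass
class PrsResult:
    scores: pd.Series            # indexed by IID
    n_snps_used: int
    filter_log: Dict[str, int] = field(default_factory=dict)
    imputed: Dict[str, float] = field(default_factory=dict)


def read_plink_raw(path) -> pd.DataFrame:
    """Read a PLINK .raw additive-coded genotype table (whitespace-separated)."""
    return pd.read_csv(path, sep=r"\s+")


def _genotype_columns(genotypes: pd.DataFrame) -> Dict[str, Tuple[str, str]]:
    """Map SNP id -> (column name, counted allele) from `SNP_ALLELE` headers."""
    out = {}
    for col in genotypes.columns:
        if col in META_COLS:
            continue
        snp, _, allele = col.rpartition("_")
        if snp:
            out[snp] = (col, allele)
    return out


def sample_maf(geno: np.ndarray) -> float:
    """Minor allele frequency from additive counts (missing ignored)."""
    g = geno[~np.isnan(geno)]
    if g.size == 0:
        return np.nan
    af = g.mean() / 2.0
    return min(af, 1.0 - af)


def filter_snps(
    weights: pd.DataFrame,
    genotypes: pd.DataFrame,
    maf_threshold: float = 0.05,
    r2_threshold: float = 0.10,
    window_bp: int = 500_000,
    p_threshold: float = 5e-8,
) -> Tuple[pd.DataFrame, Dict[str, int]]:
    """Apply the SNP filters and return the surviving weight table.

    Removal order: SNPs absent from the genotype table (warned, skipped),
    ambiguous allele pairs, sample MAF below threshold, greedy clumping
    (within ``window_bp`` on the same chromosome, pairwise genotype
    r^2 > ``r2_threshold``; the SNP with the smaller GWAS p is retained),
    and finally the GWAS significance threshold.
    """
    cols = _genotype_columns(genotypes)
    log = {"missing_in_genotypes": 0, "ambiguous": 0, "low_maf": 0, "clumped": 0, "gwas_p": 0}

    rows = []
    geno_vectors = {}
    for _, row in weights.iterrows():
        snp = row["snp"]
        if snp not in cols:
            logger.warning("SNP %s in weight table absent from genotypes; skipped", snp)
            log["missing_in_genotypes"] += 1
            continue
        pair = frozenset((row["effect_allele"], row["other_allele"]))
        if pair in AMBIGUOUS:
            log["ambiguous"] += 1
            continue
        g = genotypes[cols[snp][0]].to_numpy(dtype=float)
        if sample_maf(g) < maf_threshold:
            log["low_maf"] += 1
            continue
        rows.append(row)
        geno_vectors[snp] = g

    kept = pd.DataFrame(rows).reset_index(drop=True)
    if len(kept) == 0:
        return kept, log

    # greedy clumping: best (smallest) GWAS p retained first
    order = kept.sort_values("gwas_p", kind="mergesort").index
    retained = []
    dropped = set()
    for i in order:
        if i in dropped:
            continue
        retained.append(i)
        gi = geno_vectors[kept.loc[i, "snp"]]
        for j in kept.index:
            if j == i or j in dropped or j in retained:
                continue
            if kept.loc[j, "chrom"] != kept.loc[i, "chrom"]:
                continue
            if abs(int(kept.loc[j, "pos"]) - int(kept.loc[i, "pos"])) > window_bp:
                continue
            gj = geno_vectors[kept.loc[j, "snp"]]
            ok = ~(np.isnan(gi) | np.isnan(gj))
            if ok.sum() < 3 or gi[ok].std() == 0 or gj[ok].std() == 0:
                continue
            r2 = np.corrcoef(gi[ok], gj[ok])[0, 1] ** 2
            if r2 > r2_threshold:
                dropped.add(j)
    log["clumped"] = len(dropped)
    kept = kept.loc[sorted(retained)].reset_index(drop=True)

    sig = kept["gwas_p"] <= p_threshold
    log["gwas_p"] = int((~sig).sum())
    return kept.loc[sig].reset_index(drop=True), log


def compute_prs(genotypes: pd.DataFrame, weights: pd.DataFrame) -> PrsResult:
    """Weighted sum of risk-allele counts, score_s = sum_k beta_k * count_sk.

    The counted allele of each .raw column is resolved against the
    weight-table effect allele; when the counted allele is the *other*
    allele the count is flipped (c -> 2 - c). Missing genotypes are
    imputed with twice the sample frequency of the effect allele
    (logged per SNP); all-missing SNPs are dropped with a warning.
    """
    cols = _genotype_columns(genotypes)
    n = len(genotypes)
    scores = np.zeros(n)
    used = 0
    imputed = {}
    log = {"missing_in_genotypes": 0, "allele_mismatch": 0, "all_missing": 0}

    for _, row in weights.iterrows():
        snp = row["snp"]
        if snp not in cols:
            logger.warning("SNP %s absent from genotypes; skipped", snp)
            log["missing_in_genotypes"] += 1
            continue
        col, counted = cols[snp]
        g = genotypes[col].to_numpy(dtype=float)
        if counted == row["effect_allele"]:
            count = g
        elif counted == row["other_allele"]:
            count = 2.0 - g
        else:
            logger.warning("SNP %s counted allele %s matches neither weight allele", snp, counted)
            log["allele_mismatch"] += 1
            continue
        miss = np.isnan(count)
        if miss.all():
            logger.warning("SNP %s has no called genotypes; dropped", snp)
            log["all_missing"] += 1
            continue
        if miss.any():
            af = count[~miss].mean() / 2.0
            count = np.where(miss, 2.0 * af, count)
            imputed[snp] = float(2.0 * af)
            logger.info("SNP %s: %d missing genotypes imputed at 2*AF=%.4f", snp, miss.sum(), 2 * af)
        scores = scores + row["beta"] * count
        used += 1

    iid = genotypes["IID"] if "IID" in genotypes else pd.RangeIndex(n)
    return PrsResult(
        scores=pd.Series(scores, index=pd.Index(iid, name="IID"), name="prs"),
        n_snps_used=used,
        filter_log=log,
        imputed=imputed,
    )


def split_apoe_region(
    weights: pd.DataFrame,
    chrom: int = 19,
    start_bp: int = 44_400_000,
    end_bp: int = 46_500_000,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Split a weight table into (inside, outside) a genomic region.

    The interval is closed on both ends; defaults cover the APOE region
    on chromosome 19 (44.4-46.5 Mb).
    """
    if len(weights) == 0:
        return weights.copy(), weights.copy()
    inside = (
        (weights["chrom"].astype(int) == int(chrom))
        & (weights["pos"].astype(int) >= int(start_bp))
        & (weights["pos"].astype(int) <= int(end_bp))
    )
    return weights.loc[inside].reset_index(drop=True), weights.loc[~inside].reset_index(drop=True)
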