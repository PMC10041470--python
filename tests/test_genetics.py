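"""Polygenic scoring: hand-checked sums, filters, invariances."""

import numpy as np
import pandas as pd
import pytest

from neurocascade.genetics import (
    filter_snps,
    compute_prs,
    split_apoe_region,
    sample_maf,
)


def make_weights(rows):
    return pd.DataFrame(
        rows,
        columns=["snp", "chrom", "pos", "effect_allele", "other_allele", "beta", "gwas_p"],
    )


@pytest.fixture
def five_snp_fixture():
    """Five SNPs with fixed betas/counts; expected scores summed by hand.

    rs4 is counted on the *other* allele in the .raw header, so its
    stored code must be flipped (c -> 2 - c) before weighting.
    """
    weights = make_weights(
        [
            ("rs1", 1, 1000, "A", "G", 0.3, 1e-10),
            ("rs2", 2, 2000, "C", "T", -0.2, 1e-10),
            ("rs3", 3, 3000, "G", "T", 0.1, 1e-10),
            ("rs4", 4, 4000, "A", "C", 0.05, 1e-10),
            ("rs5", 5, 5000, "T", "G", -0.4, 1e-10),
        ]
    )
    genotypes = pd.DataFrame(
        {
            "FID": ["F1", "F2"],
            "IID": ["S1", "S2"],
            "PAT": 0,
            "MAT": 0,
            "SEX": 1,
            "PHENOTYPE": -9,
            "rs1_A": [2, 1],
            "rs2_C": [0, 2],
            "rs3_G": [1, 1],
            "rs4_C": [2, 0],  # counted allele is the non-effect allele
            "rs5_T": [1, 2],
        }
    )
    # S1: .3*2 + -.2*0 + .1*1 + .05*(2-2) + -.4*1 = 0.3
    # S2: .3*1 + -.2*2 + .1*1 + .05*(2-0) + -.4*2 = -0.7
    return weights, genotypes, {"S1": 0.3, "S2": -0.7}


def test_prs_matches_hand_sum(five_snp_fixture):
    weights, genotypes, expected = five_snp_fixture
    res = compute_prs(genotypes, weights)
    assert res.n_snps_used == 5
    for iid, val in expected.items():
        assert res.scores[iid] == pytest.approx(val, abs=1e-12)


def test_single_snp_and_zero_beta_cases():
    weights = make_weights([("rs1", 1, 1, "A", "G", 0.3, 1e-9)])
    geno = pd.DataFrame({"IID": ["a"], "rs1_A": [2]})
    assert compute_prs(geno, weights).scores["a"] == pytest.approx(0.6)
    weights["beta"] = 0.0
    assert compute_prs(geno, weights).scores["a"] == 0.0


def test_prs_linear_in_betas_and_column_order(five_snp_fixture):
    weights, genotypes, _ = five_snp_fixture
    base = compute_prs(genotypes, weights).scores
    doubled = weights.assign(beta=2 * weights["beta"])
    assert np.allclose(compute_prs(genotypes, doubled).scores, 2 * base)
    shuffled = genotypes[
        list(genotypes.columns[:6]) + ["rs3_G", "rs5_T", "rs1_A", "rs4_C", "rs2_C"]
    ]
    assert np.allclose(compute_prs(shuffled, weights).scores, base)


def test_orientation_flip_invariance(five_snp_fixture):
    """Swapping the counted allele and flipping codes c -> 2 - c leaves
    every score unchanged."""
    weights, genotypes, _ = five_snp_fixture
    base = compute_prs(genotypes, weights).scores
    flipped = genotypes.rename(columns={"rs1_A": "rs1_G"}).copy()
    flipped["rs1_G"] = 2 - flipped["rs1_G"]
    assert np.allclose(compute_prs(flipped, weights).scores, base)


def test_missing_genotypes_mean_imputed():
    weights = make_weights([("rs1", 1, 1, "A", "G", 1.0, 1e-9)])
    geno = pd.DataFrame({"IID": ["a", "b", "c"], "rs1_A": [2.0, np.nan, 0.0]})
    res = compute_prs(geno, weights)
    assert res.scores["b"] == pytest.approx(1.0)  # 2 * AF = 2 * 0.5
    assert res.imputed == {"rs1": 1.0}


def test_all_missing_snp_dropped():
    weights = make_weights([("rs1", 1, 1, "A", "G", 1.0, 1e-9)])
    geno = pd.DataFrame({"IID": ["a"], "rs1_A": [np.nan]})
    res = compute_prs(geno, weights)
    assert res.n_snps_used == 0
    assert res.filter_log["all_missing"] == 1


def test_ambiguous_and_low_maf_snps_filtered():
    weights = make_weights(
        [
            ("rs_at", 1, 1000, "A", "T", 0.1, 1e-9),
            ("rs_gc", 1, 500_000_000, "G", "C", 0.1, 1e-9),
            ("rs_rare", 2, 1000, "A", "G", 0.1, 1e-9),
            ("rs_ok", 3, 1000, "A", "G", 0.1, 1e-9),
            ("rs_weak", 4, 1000, "C", "T", 0.1, 1e-5),
        ]
    )
    n = 200
    rng = np.random.default_rng(0)
    geno = pd.DataFrame({"IID": [f"s{i}" for i in range(n)]})
    for snp, maf in [("rs_at_A", 0.3), ("rs_gc_G", 0.3), ("rs_rare_A", 0.01),
                     ("rs_ok_A", 0.3), ("rs_weak_C", 0.3)]:
        geno[snp] = rng.binomial(2, maf, size=n)
    kept, log = filter_snps(weights, geno)
    assert list(kept["snp"]) == ["rs_ok"]
    assert log["ambiguous"] == 2
    assert log["low_maf"] == 1
    assert log["gwas_p"] == 1


def test_clumping_keeps_smaller_gwas_p():
    """Two SNPs 100 kb apart with genotype r^2 = 0.25: the one with the
    larger GWAS p is eliminated; an uncorrelated neighbour survives."""
    n = 400
    rng = np.random.default_rng(1)
    g1 = rng.binomial(2, 0.4, size=n).astype(float)
    noise = rng.binomial(2, 0.4, size=n).astype(float)
    # r^2 = 0.25 target: mix with weight chosen for corr 0.5
    g2 = np.where(rng.random(n) < 0.55, g1, noise)
    r2 = np.corrcoef(g1, g2)[0, 1] ** 2
    assert 0.15 < r2 < 0.45  # comfortably above the 0.10 threshold
    g3 = rng.binomial(2, 0.4, size=n).astype(float)
    weights = make_weights(
        [
            ("rs_best", 1, 1_000_000, "A", "G", 0.2, 1e-9),
            ("rs_worse", 1, 1_100_000, "C", "T", 0.2, 1e-8),
            ("rs_far", 1, 900_000_000, "A", "G", 0.2, 1e-8),
        ]
    )
    geno = pd.DataFrame({"IID": [f"s{i}" for i in range(n)],
                         "rs_best_A": g1, "rs_worse_C": g2, "rs_far_A": g3})
    kept, log = filter_snps(weights, geno)
    assert set(kept["snp"]) == {"rs_best", "rs_far"}
    assert log["clumped"] == 1


def test_snp_absent_from_genotypes_skipped_not_fatal():
    weights = make_weights(
        [("rs1", 1, 1, "A", "G", 0.1, 1e-9), ("rs_gone", 1, 2, "C", "T", 0.1, 1e-9)]
    )
    geno = pd.DataFrame({"IID": ["a"], "rs1_A": [1.0]})
    kept, log = filter_snps(weights, geno)
    assert list(kept["snp"]) == ["rs1"]
    assert log["missing_in_genotypes"] == 1


def test_apoe_region_split():
    weights = make_weights(
        [
            ("rs_in", 19, 45_000_000, "A", "G", 0.1, 1e-9),
            ("rs_edge_lo", 19, 44_400_000, "A", "G", 0.1, 1e-9),
            ("rs_edge_hi", 19, 46_500_000, "A", "G", 0.1, 1e-9),
            ("rs_out_pos", 19, 47_000_000, "A", "G", 0.1, 1e-9),
            ("rs_chr2", 2, 45_000_000, "A", "G", 0.1, 1e-9),
        ]
    )
    inside, outside = split_apoe_region(weights)
    assert set(inside["snp"]) == {"rs_in", "rs_edge_lo", "rs_edge_hi"}
    assert set(outside["snp"]) == {"rs_out_pos", "rs_chr2"}


def test_apoe_split_of_empty_table():
    empty = make_weights([]).iloc[0:0]
    inside, outside = split_apoe_region(empty)
    assert len(inside) == 0 and len(outside) == 0


def test_sample_maf_is_minor_frequency():
    g = np.array([2, 2, 2, 1, np.nan])
    # AF of counted allele = 7/8; minor = 1/8
    assert sample_maf(g) == pytest.approx(1 / 8)
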