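"""Generator checks: reproducibility, planted structure, marginals."""

import numpy as np
import pandas as pd
import pytest

from neurocascade.synthetic import (
    SimulationConfig,
    simulate_bundle,
    simulate_phenotypes,
    simulate_genotypes,
    simulate_gene_matrix,
    simulate_time_series,
    make_parcel_meta,
    _community_plan,
)
from neurocascade.phenotypes import adversity_scores, syndrome_scores
from neurocascade.cca import fit_cca


def test_identical_seed_gives_identical_bundle(small_config, small_bundle):
    again = simulate_bundle(small_config)
    assert small_bundle.phenotypes.equals(again.phenotypes)
    assert small_bundle.genotypes.equals(again.genotypes)
    assert np.array_equal(small_bundle.gene_matrix, again.gene_matrix)
    assert np.array_equal(
        small_bundle.get_time_series(0, "SST", 1), again.get_time_series(0, "SST", 1)
    )


def test_bundle_is_finite(small_bundle):
    for df in (
        small_bundle.gene_matrix,
        small_bundle.receptor_maps,
        small_bundle.phenotypes.select_dtypes("number"),
    ):
        assert np.isfinite(df.to_numpy(dtype=float)).all()
    assert np.isfinite(small_bundle.get_time_series(1, "MID", 2)).all()


@pytest.mark.parametrize("frac,expected", [(0.0, 0), (1.0, 100), (0.3, 30)])
def test_community_shift_fraction_is_exact(frac, expected):
    cfg = SimulationConfig(n_parcels=100, community_shift_fraction=frac)
    plan = _community_plan(cfg, make_parcel_meta(cfg))
    n_diff = int((np.array(plan["MID"]) != np.array(plan["SST"])).sum())
    assert n_diff == expected


def test_within_community_correlation_exceeds_between():
    """At SNR 1 the within-community mean Pearson r should beat the
    between-community mean by a clear margin."""
    cfg = SimulationConfig(
        n_subjects=1,
        n_parcels=300,
        n_networks=6,
        n_timepoints=400,
        community_shift_fraction=0.0,
        snr=1.0,
        seed=11,
    )
    series = simulate_time_series(cfg)[(0, "MID", 1)]
    labels = np.asarray(_community_plan(cfg, make_parcel_meta(cfg))["MID"])
    r = np.corrcoef(series)
    same = labels[:, None] == labels[None, :]
    np.fill_diagonal(same, False)
    off = ~np.eye(len(labels), dtype=bool)
    within = r[same].mean()
    between = r[off & ~same].mean()
    assert within - between > 0.2


def test_timepoint_floor_rejected():
    with pytest.raises(ValueError, match="n_timepoints"):
        SimulationConfig(n_timepoints=9).validate()


def test_canonical_r_bounds_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(canonical_r=1.0).validate()
    with pytest.raises(ValueError):
        SimulationConfig(canonical_r=-0.1).validate()


def test_planted_canonical_correlation_recovered():
    """With canonical_r = 0.5 at n = 1000 the first sample canonical
    correlation between the adversity/PRS block and the syndrome block
    lands within +-0.1 of the plant."""
    cfg = SimulationConfig(n_subjects=1000, canonical_r=0.5, seed=21)
    table, _ = simulate_phenotypes(cfg)
    X = pd.concat(
        [adversity_scores(table, 1), table[["prs_mdd", "prs_ad_noapoe"]]], axis=1
    ).to_numpy(float)
    Y = syndrome_scores(table, "cbcl_w1_", cfg.n_syndromes).to_numpy(float)
    _, _, r = fit_cca(X, Y)
    assert abs(r[0] - 0.5) < 0.1


def test_checklist_maximum_sum():
    cfg = SimulationConfig(n_subjects=5, n_items=112)
    table, _ = simulate_phenotypes(cfg)
    cols = [c for c in table.columns if c.startswith("cbcl_w1_")]
    assert len(cols) == 112
    table.loc[:, cols] = 2
    assert (table[cols].sum(axis=1) == 224).all()


def test_genotype_allele_frequencies_match_plant():
    cfg = SimulationConfig(n_subjects=10000, n_snps=12, seed=5)
    genotypes, weights, truth = simulate_genotypes(cfg)
    mafs = np.array(truth["mafs"])
    geno_cols = [c for c in genotypes.columns if c.startswith("rs")]
    for k, col in enumerate(geno_cols):
        g = genotypes[col].to_numpy(float)
        emp = min(g.mean() / 2, 1 - g.mean() / 2)
        assert abs(emp - min(mafs[k], 1 - mafs[k])) < 0.01


def test_weight_table_contains_filter_fodder():
    cfg = SimulationConfig(n_subjects=50, n_snps=20)
    _, weights, truth = simulate_genotypes(cfg)
    pairs = set(
        frozenset(p) for p in zip(weights["effect_allele"], weights["other_allele"])
    )
    assert frozenset("AT") in pairs and frozenset("GC") in pairs
    assert (weights["gwas_p"] > 5e-8).any()
    assert truth["clump_pair"] is not None


def test_stress_sets_have_default_sizes(small_bundle):
    assert len(small_bundle.stress_low) == 27
    assert len(small_bundle.stress_high) == 45
    assert not set(small_bundle.stress_low) & set(small_bundle.stress_high)


def test_planted_gene_loading_recovered():
    cfg = SimulationConfig(
        n_parcels=297, n_genes=800, gene_loading=0.6, spatial_rho=0.5, seed=9
    )
    meta = make_parcel_meta(cfg)
    genes, low, high, truth = simulate_gene_matrix(cfg, meta)
    pattern = np.asarray(truth["spatial_pattern"])
    hi_corr = [np.corrcoef(genes[g], pattern)[0, 1] for g in high]
    lo_corr = [np.corrcoef(genes[g], pattern)[0, 1] for g in low]
    assert abs(np.mean(hi_corr) - 0.6) < 0.1
    assert abs(np.mean(lo_corr) + 0.6) < 0.1


def test_zero_spatial_rho_gives_unstructured_maps():
    cfg = SimulationConfig(n_parcels=120, n_genes=400, spatial_rho=0.0, gene_loading=0.0, seed=3)
    meta = make_parcel_meta(cfg)
    genes, *_ = simulate_gene_matrix(cfg, meta)
    coords = meta[["x", "y", "z"]].to_numpy()
    d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.argmin(axis=1)
    vals = genes.to_numpy()
    neigh_corr = [np.corrcoef(vals[:, g], vals[nn, g])[0, 1] for g in range(80)]
    assert abs(np.median(np.abs(neigh_corr))) < 0.15


def test_gene_count_floor_rejected():
    with pytest.raises(ValueError, match="stress"):
        SimulationConfig(n_genes=50).validate()


def test_parcel_ids_shared_across_tables(small_bundle):
    ids = small_bundle.parcel_meta["parcel_id"]
    assert list(small_bundle.gene_matrix.index) == list(ids)
    assert list(small_bundle.receptor_maps.index) == list(ids)
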