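"""Normalisation formulas, donor aggregation and the overlap test."""

import numpy as np
import pandas as pd
import pytest

from neurocascade.transcriptomics import (
    StressGeneSets,
    robust_sigmoid,
    unit_rescale,
    robust_sigmoid_normalize,
    aggregate_samples_to_parcels,
    overlap_test,
    null_overlap_counts,
)


def test_robust_sigmoid_at_median_and_median_plus_iqr():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])  # median 3, IQR 2
    out = robust_sigmoid(x)
    assert out[2] == pytest.approx(0.5)
    # value at median + IQR: 1/(1+e^-1)
    assert robust_sigmoid(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))[4] == pytest.approx(
        1 / (1 + np.exp(-1)), abs=1e-12
    )
    assert round(float(robust_sigmoid(np.array([1, 2, 3, 4, 5.0]))[4]), 4) == 0.7311


def test_unit_rescale_endpoints():
    x = np.array([0.3, 0.9, 0.5])
    out = unit_rescale(x)
    assert out.min() == 0.0 and out.max() == 1.0
    assert out[0] == 0.0 and out[1] == 1.0


def test_full_normalisation_bounded_and_rank_preserving(rng):
    df = pd.DataFrame(rng.standard_normal((6, 40)) * 3 + 10,
                      index=[f"s{i}" for i in range(6)])
    out = robust_sigmoid_normalize(df)
    assert ((out >= 0) & (out <= 1)).all().all()
    # the first (per-sample) pass is monotone: check rank preservation of
    # the row-wise transform in isolation
    from neurocascade.transcriptomics import _sigmoid_pass
    rows = _sigmoid_pass(df, axis=1, kind="sample")
    for i in range(6):
        assert np.array_equal(
            np.argsort(df.iloc[i].to_numpy()), np.argsort(rows.iloc[i].to_numpy())
        )


def test_zero_iqr_sample_is_named():
    df = pd.DataFrame(
        [[1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0]], index=["flat", "ok"]
    )
    with pytest.raises(ValueError, match="flat"):
        robust_sigmoid_normalize(df)


def test_two_stage_donor_aggregation():
    # one donor, one sample per parcel: identity
    df = pd.DataFrame(
        {"donor_id": ["d1", "d1"], "parcel_id": ["p1", "p2"], "g": [0.3, 0.7]}
    )
    out, _ = aggregate_samples_to_parcels(df)
    assert out.loc["p1", "g"] == 0.3 and out.loc["p2", "g"] == 0.7

    # two donors with parcel means 0.2 and 0.8 -> 0.5
    df2 = pd.DataFrame(
        {"donor_id": ["a", "b"], "parcel_id": ["p", "p"], "g": [0.2, 0.8]}
    )
    out2, _ = aggregate_samples_to_parcels(df2)
    assert out2.loc["p", "g"] == pytest.approx(0.5)


def test_unbalanced_donors_use_mean_of_means_not_pooled_mean():
    """Six samples, three donors with 3/2/1 samples in one parcel: the
    two-stage mean differs from the pooled mean and equals the
    hand-computed donor-mean-of-means."""
    df = pd.DataFrame(
        {
            "donor_id": ["a", "a", "a", "b", "b", "c"],
            "parcel_id": ["p"] * 6,
            "g": [0.0, 0.3, 0.6, 1.0, 0.8, 0.1],
        }
    )
    out, _ = aggregate_samples_to_parcels(df)
    hand = np.mean([np.mean([0.0, 0.3, 0.6]), np.mean([1.0, 0.8]), 0.1])
    assert out.loc["p", "g"] == pytest.approx(hand)
    assert out.loc["p", "g"] != pytest.approx(df["g"].mean())


def toy_overlap_instance():
    """10 genes, 2 nulls, every count checkable by hand."""
    symbols = [f"g{i}" for i in range(10)]
    sets = StressGeneSets(stress_low=["g0", "g1"], stress_high=["g2", "g3", "g4"])
    gene_corr = np.array([-0.9, -0.8, 0.9, 0.8, 0.7, 0.1, -0.1, 0.2, -0.2, 0.05])
    robust = np.abs(gene_corr) >= 0.7  # g0,g1 negative; g2,g3,g4 positive
    P = 6
    rng = np.random.default_rng(0)
    gene_matrix = rng.standard_normal((P, 10))
    # craft null LVs whose correlation rankings we control exactly by
    # building the nulls as noisy copies of chosen gene columns
    null1 = gene_matrix[:, 5] + 0.01 * rng.standard_normal(P)   # top gene g5
    null2 = gene_matrix[:, 2] + 0.01 * rng.standard_normal(P)   # top gene g2
    nulls = np.column_stack([null1, null2])
    return symbols, sets, gene_corr, robust, gene_matrix, nulls


def test_overlap_toy_instance_matches_exhaustive_count():
    symbols, sets, gene_corr, robust, gene_matrix, nulls = toy_overlap_instance()
    res = overlap_test(
        gene_corr, robust, symbols, sets, nulls, gene_matrix, brain_gene_r=0.5
    )
    assert res.orig_pos == 3 and res.orig_neg == 2
    assert res.stress_high_pos == 3 and res.stress_low_neg == 2
    obs = res.stress_high_pos + res.stress_low_neg  # 5

    # independent exhaustive count over the two nulls
    Xz = (gene_matrix - gene_matrix.mean(0)) / gene_matrix.std(0)
    exceed = 0
    for k in range(2):
        lv = nulls[:, k]
        lvz = (lv - lv.mean()) / lv.std()
        corr = lvz @ Xz / len(lv)
        top_pos = np.argsort(-corr)[:3]
        top_neg = np.argsort(-corr)[-2:]
        count = sum(symbols[i] in sets.stress_high for i in top_pos) + sum(
            symbols[i] in sets.stress_low for i in top_neg
        )
        exceed += count >= obs
    assert res.p_susceptibility == pytest.approx((1 + exceed) / 3)


def test_overlap_direction_swaps_with_negative_brain_gene_r():
    symbols, sets, gene_corr, robust, gene_matrix, nulls = toy_overlap_instance()
    pos = overlap_test(gene_corr, robust, symbols, sets, nulls, gene_matrix, 0.5)
    neg = overlap_test(gene_corr, robust, symbols, sets, nulls, gene_matrix, -0.5)
    assert pos.p_susceptibility != neg.p_susceptibility or pos.p_inverse != neg.p_inverse


def test_overlap_empty_robust_set_warns_and_is_undefined():
    symbols, sets, gene_corr, _, gene_matrix, nulls = toy_overlap_instance()
    with pytest.warns(UserWarning, match="no robust genes"):
        res = overlap_test(
            gene_corr, np.zeros(10, bool), symbols, sets, nulls, gene_matrix, 0.5
        )
    assert res.p_susceptibility is None and res.p_inverse is None


def test_null_counts_match_hypergeometric_expectation(rng):
    """Pure-noise null LV correlations: the expected number of stress
    genes among the top Orig_pos equals Orig_pos * |set| / n_genes."""
    G, n_null = 200, 2000
    high = np.zeros(G, bool)
    high[rng.choice(G, 40, replace=False)] = True
    low = np.zeros(G, bool)
    low[rng.choice(np.where(~high)[0], 20, replace=False)] = True
    null_corr = rng.standard_normal((G, n_null))
    counts = null_overlap_counts(null_corr, orig_pos=30, orig_neg=25, high=high, low=low)
    expected_high_pos = 30 * 40 / G            # 6.0
    se = np.sqrt(counts["high_pos"].var() / n_null)
    assert abs(counts["high_pos"].mean() - expected_high_pos) < 4 * se + 0.05
    expected_low_neg = 25 * 20 / G             # 2.5
    assert abs(counts["low_neg"].mean() - expected_low_neg) < 0.3


def test_overlapping_stress_sets_rejected():
    with pytest.raises(ValueError, match="disjoint"):
        StressGeneSets(stress_low=["a", "b"], stress_high=["b", "c"])
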