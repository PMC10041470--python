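"""Multilayer modularity, generalised Louvain, flexibility/recruitment."""

import numpy as np
import networkx as nx
import pytest
from sklearn.metrics import adjusted_rand_score

from neurocascade.connectome import ConnectivityMatrix, correlation_matrix, zero_negative
from neurocascade.communities import (
    MultilayerNetwork,
    PartitionEnsemble,
    modularity,
    louvain_multilayer,
    run_ensemble,
    flexibility,
    recruitment,
    brute_force_optimum,
    supra_modularity_matrix,
    two_mu,
)
from neurocascade.synthetic import (
    SimulationConfig,
    simulate_time_series,
    make_parcel_meta,
    _community_plan,
)


def cm(values, task="MID", wave=1):
    return ConnectivityMatrix(values=np.asarray(values, dtype=float), task=task, wave=wave)


def two_cliques_layer():
    """Two disconnected 3-cliques with unit weights."""
    W = np.zeros((6, 6))
    for block in ([0, 1, 2], [3, 4, 5]):
        for i in block:
            for j in block:
                if i != j:
                    W[i, j] = 1.0
    return W


def single_layer(W, omega=0.0, gamma=1.0):
    return MultilayerNetwork(layers=[cm(W)], coupling_pairs=(), omega=omega, gamma=gamma)


def dense_q_oracle(network, labels):
    """Independent evaluation: explicit double loop over the printed
    formula, nothing shared with the package implementation."""
    labels = np.asarray(labels)
    total = 0.0
    for l, lay in enumerate(network.layers):
        W = lay.values
        s = W.sum(1)
        v = s.sum()
        for i in range(W.shape[0]):
            for j in range(W.shape[0]):
                if labels[l, i] == labels[l, j]:
                    e = s[i] * s[j] / v if v > 0 else 0.0
                    total += W[i, j] - network.gamma_for(l) * e
    for l, r in network.coupling_pairs:
        for j in range(network.n_parcels):
            if labels[l, j] == labels[r, j]:
                total += 2 * network.omega
    return total / two_mu(network)


def test_all_in_one_community_single_layer_q_is_zero(rng):
    W = rng.random((5, 5))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    net = single_layer(W)
    q = modularity(net, np.zeros((1, 5), dtype=int))
    assert q == pytest.approx(0.0, abs=1e-12)


def test_two_clique_partition_q_is_half():
    net = single_layer(two_cliques_layer())
    labels = np.array([[0, 0, 0, 1, 1, 1]])
    assert modularity(net, labels) == pytest.approx(0.5, abs=1e-12)


def test_two_layer_q_matches_independent_dense_evaluation(rng):
    W = rng.random((5, 5))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 0)
    net = MultilayerNetwork(
        layers=[cm(W), cm(W, task="SST")], coupling_pairs=((0, 1),), omega=0.5
    )
    for _ in range(5):
        labels = rng.integers(0, 3, size=(2, 5))
        assert modularity(net, labels) == pytest.approx(
            dense_q_oracle(net, labels), abs=1e-12
        )


def test_supra_matrix_agrees_with_modularity(rng):
    W1 = rng.random((4, 4)); W1 = (W1 + W1.T) / 2; np.fill_diagonal(W1, 0)
    W2 = rng.random((4, 4)); W2 = (W2 + W2.T) / 2; np.fill_diagonal(W2, 0)
    net = MultilayerNetwork(layers=[cm(W1), cm(W2, task="SST")],
                            coupling_pairs=((0, 1),), omega=0.3)
    B, norm = supra_modularity_matrix(net)
    labels = rng.integers(0, 3, size=(2, 4))
    flat = labels.reshape(-1)
    same = flat[:, None] == flat[None, :]
    assert B[same].sum() / norm == pytest.approx(modularity(net, labels), abs=1e-12)


def test_single_layer_reduces_to_newman_girvan(rng):
    """With one layer and omega = 0, Q must equal the standard weighted
    modularity computed by networkx on 20 random graphs."""
    for k in range(20):
        n = int(rng.integers(5, 12))
        W = rng.random((n, n)) * (rng.random((n, n)) < 0.5)
        W = (W + W.T) / 2
        np.fill_diagonal(W, 0)
        if W.sum() == 0:
            continue
        labels = rng.integers(0, 3, size=n)
        net = single_layer(W)
        G = nx.from_numpy_array(W)
        comms = [set(np.where(labels == c)[0]) for c in np.unique(labels)]
        q_nx = nx.community.modularity(G, comms, weight="weight")
        assert abs(modularity(net, labels[None, :]) - q_nx) < 1e-10


def test_louvain_recovers_cliques_across_layers():
    W = two_cliques_layer()
    net = MultilayerNetwork(
        layers=[cm(W), cm(W, task="SST")], coupling_pairs=((0, 1),), omega=0.5
    )
    labels, q = louvain_multilayer(net, seed=0)
    # two communities, each persistent across both layers
    assert adjusted_rand_score(labels[0], [0, 0, 0, 1, 1, 1]) == 1.0
    assert np.array_equal(labels[0], labels[1])
    assert q == pytest.approx(modularity(net, labels), abs=1e-9)


def test_louvain_beats_or_matches_brute_force_on_toys(rng):
    for k in range(5):
        n = 4
        W1 = rng.random((n, n)); W1 = (W1 + W1.T) / 2; np.fill_diagonal(W1, 0)
        W2 = rng.random((n, n)); W2 = (W2 + W2.T) / 2; np.fill_diagonal(W2, 0)
        net = MultilayerNetwork(layers=[cm(W1), cm(W2, task="SST")],
                                coupling_pairs=((0, 1),), omega=0.4)
        _, q_opt = brute_force_optimum(net)
        _, q_louvain = louvain_multilayer(net, seed=k)
        assert q_louvain >= 0.999 * q_opt


def test_louvain_seeded_determinism():
    W = two_cliques_layer() + 0.01
    np.fill_diagonal(W, 0)
    net = MultilayerNetwork(layers=[cm(W), cm(W, task="SST")],
                            coupling_pairs=((0, 1),), omega=0.5)
    l1, q1 = louvain_multilayer(net, seed=42)
    l2, q2 = louvain_multilayer(net, seed=42)
    assert np.array_equal(l1, l2) and q1 == q2


def test_louvain_dominates_trivial_partitions(rng):
    W = rng.random((8, 8)); W = (W + W.T) / 2; np.fill_diagonal(W, 0)
    net = MultilayerNetwork(layers=[cm(W), cm(W, task="SST")],
                            coupling_pairs=((0, 1),), omega=0.2)
    _, q = louvain_multilayer(net, seed=1)
    singletons = np.arange(16).reshape(2, 8)
    allone = np.zeros((2, 8), dtype=int)
    assert q >= modularity(net, singletons) - 1e-12
    assert q >= modularity(net, allone) - 1e-12


def test_label_permutation_invariance(rng):
    W = two_cliques_layer()
    net = MultilayerNetwork(layers=[cm(W), cm(W, task="SST")],
                            coupling_pairs=((0, 1),), omega=0.5)
    labels = rng.integers(0, 3, size=(2, 6))
    relabel = np.array([2, 0, 1])
    assert modularity(net, relabel[labels]) == pytest.approx(
        modularity(net, labels), abs=1e-12
    )


def test_ensemble_of_one_and_unambiguous_repeats():
    W = two_cliques_layer()
    net = MultilayerNetwork(layers=[cm(W), cm(W, task="SST")],
                            coupling_pairs=((0, 1),), omega=0.5)
    ens1 = run_ensemble(net, n_iterations=1, base_seed=0)
    assert ens1.labels.shape[0] == 1
    ens = run_ensemble(net, n_iterations=20, base_seed=0)
    # unambiguous optimum: every restart finds the identical partition
    for k in range(1, 20):
        assert adjusted_rand_score(
            ens.labels[0].reshape(-1), ens.labels[k].reshape(-1)
        ) == 1.0
    assert ens.q_values.std() == pytest.approx(0.0, abs=1e-12)


def make_ensemble(labels):
    arr = np.asarray(labels)
    return PartitionEnsemble(labels=arr, q_values=np.zeros(arr.shape[0]))


def test_flexibility_counts_cross_task_changes():
    # 10 iterations, 2 layers, 3 parcels: parcel 0 never changes, parcel 1
    # always, parcel 2 in 4 of 10 iterations
    K = 10
    labels = np.zeros((K, 2, 3), dtype=int)
    labels[:, 1, 1] = 1
    labels[:4, 1, 2] = 1
    flex = flexibility(make_ensemble(labels), {1: (0, 1)})[1]
    assert flex[0] == 0.0
    assert flex[1] == 1.0
    assert flex[2] == pytest.approx(0.4)


def test_flexibility_invalid_wave_mapping():
    with pytest.raises(ValueError):
        flexibility(make_ensemble(np.zeros((2, 2, 3), dtype=int)), {1: (0, 5)})


def test_recruitment_identities():
    native = np.array([0, 0, 0, 1, 1])
    # partition equals native systems in every iteration -> recruitment 1
    labels = np.tile(native, (3, 1, 1))
    rec = recruitment(make_ensemble(labels), native)[0]
    assert np.allclose(rec, 1.0)
    # parcel 0 never co-assigned with its mates -> 0
    labels2 = np.tile(np.array([9, 0, 0, 1, 1]), (3, 1, 1))
    rec2 = recruitment(make_ensemble(labels2), native)[0]
    assert rec2[0] == 0.0
    assert rec2[1] == pytest.approx(0.5)  # with one of its two mates


def test_recruitment_partial_co_assignment():
    """A parcel co-assigned with 3 of its 9 system-mates in every
    iteration recruits at exactly 1/3."""
    native = np.zeros(10, dtype=int)
    layer = np.array([0, 0, 0, 0, 1, 1, 1, 1, 1, 1])  # parcel 0 with 3 mates
    labels = np.tile(layer, (5, 1, 1))
    rec = recruitment(make_ensemble(labels), native)[0]
    assert rec[0] == pytest.approx(3 / 9)


def test_recruitment_singleton_system_is_nan():
    native = np.array([0, 0, 1])
    with pytest.warns(UserWarning, match="singleton|single parcel"):
        rec = recruitment(make_ensemble(np.zeros((2, 1, 3), dtype=int)), native)[0]
    assert np.isnan(rec[2])
    assert np.isfinite(rec[:2]).all()


def test_metrics_invariant_to_community_relabeling(rng):
    labels = rng.integers(0, 4, size=(6, 2, 8))
    relabel = rng.permutation(4)
    native = rng.integers(0, 2, size=8)
    base_f = flexibility(make_ensemble(labels), {1: (0, 1)})[1]
    base_r = recruitment(make_ensemble(labels), native)[0]
    new_f = flexibility(make_ensemble(relabel[labels]), {1: (0, 1)})[1]
    new_r = recruitment(make_ensemble(relabel[labels]), native)[0]
    assert np.allclose(base_f, new_f)
    assert np.allclose(base_r, new_r)


def test_planted_partition_recovery_from_time_series():
    """End-to-end: synthetic series at SNR 1 -> connectivity -> Louvain
    recovers the planted per-task partition (adjusted agreement > 0.9)."""
    cfg = SimulationConfig(
        n_subjects=1, n_parcels=60, n_timepoints=300, n_networks=5,
        community_shift_fraction=0.3, snr=1.0, seed=2,
    )
    plan = _community_plan(cfg, make_parcel_meta(cfg))
    series = simulate_time_series(cfg)
    layers = [
        zero_negative(correlation_matrix(series[(0, task, wave)], task=task, wave=wave))
        for task, wave in [("MID", 1), ("SST", 1), ("MID", 2), ("SST", 2)]
    ]
    net = MultilayerNetwork(layers=layers)
    labels, _ = louvain_multilayer(net, seed=0)
    assert adjusted_rand_score(plan["MID"], labels[0]) > 0.9
    assert adjusted_rand_score(plan["SST"], labels[1]) > 0.9


def test_empty_network_rejected():
    with pytest.raises(ValueError):
        MultilayerNetwork(layers=[])
    zero = single_layer(np.zeros((3, 3)))
    with pytest.raises(ValueError, match="empty"):
        modularity(zero, np.zeros((1, 3), dtype=int))
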