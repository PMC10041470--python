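"""Multilayer community detection and partition diagnostics.

The four task x wave connectivity matrices form one multilayer network
whose partition is found by maximising the multilayer modularity

    Q = (1/2mu) * sum_ijlr [ (w_ijl - gamma_l * e_ijl) d_lr
                             + d_ij * omega_jlr ] * d(g_il, g_jr)

with e_ijl = s_il * s_jl / v_l the within-layer chance expectation
(s_il node strength, v_l total layer weight) and omega the interlayer
coupling carried by node-identity edges on the configured layer pairs.
2mu counts every ordered intralayer pair plus every ordered coupled
(node, layer-pair). Interlayer edges are *excluded* from s_il and v_l
(the null model is intra-layer) but included in 2mu.

Optimisation is a generalised Louvain: greedy single-node moves over all
(parcel, layer) supra-nodes followed by community aggregation, repeated
to convergence. Restart ensembles yield node flexibility (community
change between tasks) and recruitment (co-assignment with native-system
peers).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .connectome import ConnectivityMatrix

logger = logging.getLogger(__name__)

# canonical layer order for the task x wave design
LAYER_NAMES = ("MID_w1", "SST_w1", "MID_w2", "SST_w2")

# 4-cycle coupling: cross-task within wave, cross-wave within task
DEFAULT_COUPLING = ((0, 1), (2, 3), (0, 2), (1, 3))


@dataclass
class MultilayerNetwork:
    layers: List[ConnectivityMatrix]
    coupling_pairs: Sequence[Tuple[int, int]] = DEFAULT_COUPLING
    omega: float = 0.5
    gamma: float = 1.0

    def __post_init__(self):
        if len(self.layers) == 0:
            raise ValueError("network has no layers")
        n = self.layers[0].values.shape[0]
        for lay in self.layers:
            if lay.values.shape[0] != n:
                raise ValueError("all layers must share the parcel set")
        if self.omega < 0:
            raise ValueError("omega must be >= 0")
        if np.any(np.asarray(self.gamma) <= 0):
            raise ValueError("gamma must be > 0")
        for l, r in self.coupling_pairs:
            if not (0 <= l < len(self.layers) and 0 <= r < len(self.layers)):
                raise ValueError(f"coupling pair ({l},{r}) references invalid layer")

    @property
    def n_parcels(self) -> int:
        return self.layers[0].values.shape[0]

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    def gamma_for(self, l: int) -> float:
        g = np.asarray(self.gamma, dtype=float)
        return float(g) if g.ndim == 0 else float(g[l])


@dataclass
class PartitionEnsemble:
    """Community labels per (iteration, layer, parcel) from restart runs."""

    labels: np.ndarray          # (n_iterations, n_layers, n_parcels) int
    q_values: np.ndarray        # (n_iterations,)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be (iteration, layer, parcel)")
        if self.labels.shape[0] < 1:
            raise ValueError("need at least one iteration")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def n_iterations(self) -> int:
        return self.labels.shape[0]


def two_mu(network: MultilayerNetwork) -> float:
    """Total ordered connection weight including interlayer coupling."""
    intra = sum(float(lay.values.sum()) for lay in network.layers)
    inter = 2.0 * network.omega * network.n_parcels * len(network.coupling_pairs)
    return intra + inter


def modularity(network: MultilayerNetwork, labels: np.ndarray) -> float:
    """Evaluate multilayer modularity for a full (layer, parcel) labeling.

    The sum runs over all ordered node pairs within each layer (the
    diagonal included, with w_iil = 0 but e_iil > 0) plus 2*omega per
    coupled layer pair and node with matching labels.
    """
    labels = np.asarray(labels)
    if labels.shape != (network.n_layers, network.n_parcels):
        raise ValueError("labels must cover every (layer, parcel)")
    norm = two_mu(network)
    if norm <= 0:
        raise ValueError("empty network: total weight is zero")

    total = 0.0
    for l, lay in enumerate(network.layers):
        W = lay.values
        s = W.sum(axis=1)
        v = s.sum()
        g = labels[l]
        same = g[:, None] == g[None, :]
        w_term = float(W[same].sum())
        if v > 0:
            # sum over same-community ordered pairs of s_i s_j / v
            comm_strength = np.bincount(g, weights=s)
            null_term = float((comm_strength ** 2).sum() / v)
        else:
            null_term = 0.0
        total += w_term - network.gamma_for(l) * null_term
    for l, r in network.coupling_pairs:
        match = int((labels[l] == labels[r]).sum())
        total += 2.0 * network.omega * match
    return total / norm


def supra_modularity_matrix(network: MultilayerNetwork) -> Tuple[np.ndarray, float]:
    """Dense (N*L) x (N*L) modularity matrix B and the 2mu normaliser.

    Supra-node index = layer * n_parcels + parcel. Q(labels) =
    sum of B over same-community ordered pairs / 2mu.
    """
    N, L = network.n_parcels, network.n_layers
    B = np.zeros((N * L, N * L))
    for l, lay in enumerate(network.layers):
        W = lay.values
        s = W.sum(axis=1)
        v = s.sum()
        block = W.copy()
        if v > 0:
            block = block - network.gamma_for(l) * np.outer(s, s) / v
        B[l * N:(l + 1) * N, l * N:(l + 1) * N] = block
    idx = np.arange(N)
    for l, r in network.coupling_pairs:
        B[l * N + idx, r * N + idx] += network.omega
        B[r * N + idx, l * N + idx] += network.omega
    return B, two_mu(network)


def _move_phase(B: np.ndarray, labels: np.ndarray, rng, tol: float) -> bool:
    """Greedy node sweeps; mutates ``labels``; True if anything moved."""
    n = B.shape[0]
    n_comm = labels.max() + 1
    improved = False
    while True:
        moved = 0
        for k in rng.permutation(n):
            row = B[k]
            w_to = np.bincount(labels, weights=row, minlength=n_comm)
            current = labels[k]
            # gain of community c relative to staying: w_to[c] - (w_to[cur] - B_kk)
            stay = w_to[current] - B[k, k]
            w_to[current] = -np.inf
            best = int(np.argmax(w_to))
            if w_to[best] - stay > tol:
                labels[k] = best
                moved += 1
        if moved == 0:
            break
        improved = True
    return improved


def _aggregate(B: np.ndarray, labels: np.ndarray) -> np.ndarray:
    n_comm = labels.max() + 1
    S = np.zeros((B.shape[0], n_comm))
    S[np.arange(B.shape[0]), labels] = 1.0
    return S.T @ B @ S


def louvain_multilayer(
    network: MultilayerNetwork,
    seed: int = 0,
    tol: float = 1e-10,
    max_outer: int = 100,
) -> Tuple[np.ndarray, float]:
    """Generalised Louvain maximisation of multilayer modularity.

    Node-level moves over all (parcel, layer) supra-nodes accept the
    best strictly positive gain (ties keep the current community; sweep
    order is a seeded shuffle), then communities are collapsed into
    super-nodes and the procedure repeats until no move improves Q by
    more than ``tol``. Returns ``(labels, Q)`` with labels shaped
    (n_layers, n_parcels) and comparable across layers.
    """
    B, norm = supra_modularity_matrix(network)
    if norm <= 0:
        raise ValueError("empty network: total weight is zero")
    rng = np.random.default_rng(seed)
    # move-phase tolerance in B units: delta_Q = 2 * delta_B / 2mu
    tol_b = tol * norm / 2.0

    n = B.shape[0]
    assignment = np.arange(n)  # supra-node -> current flat community
    Bcur = B
    for _ in range(max_outer):
        labels = np.arange(Bcur.shape[0])
        improved = _move_phase(Bcur, labels, rng, tol_b)
        _, labels = np.unique(labels, return_inverse=True)
        assignment = labels[assignment]
        if not improved or labels.max() + 1 == Bcur.shape[0]:
            break
        Bcur = _aggregate(Bcur, labels)

    final = assignment.reshape(network.n_layers, network.n_parcels)
    return final, modularity(network, final)


def run_ensemble(
    network: MultilayerNetwork, n_iterations: int = 100, base_seed: int = 0
) -> PartitionEnsemble:
    """Restart the optimiser ``n_iterations`` times (seed base_seed + k)."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    all_labels = np.empty(
        (n_iterations, network.n_layers, network.n_parcels), dtype=int
    )
    qs = np.empty(n_iterations)
    for k in range(n_iterations):
        labels, q = louvain_multilayer(network, seed=base_seed + k)
        all_labels[k] = labels
        qs[k] = q
    if n_iterations > 1 and qs.std() > 0:
        logger.info("ensemble Q spread: sd=%.3g over %d restarts", qs.std(), n_iterations)
    return PartitionEnsemble(labels=all_labels, q_values=qs)


def flexibility(
    ensemble: PartitionEnsemble,
    wave_layer_pairs: Dict[int, Tuple[int, int]],
) -> Dict[int, np.ndarray]:
    """Cross-task reorganisation: per parcel and wave, the fraction of
    restarts in which the community label differs between the two task
    layers of that wave."""
    L = ensemble.labels.shape[1]
    out = {}
    for wave, (la, lb) in wave_layer_pairs.items():
        if not (0 <= la < L and 0 <= lb < L):
            raise ValueError(f"wave {wave} maps to invalid layers ({la},{lb})")
        diff = ensemble.labels[:, la, :] != ensemble.labels[:, lb, :]
        out[wave] = diff.mean(axis=0)
    return out


def recruitment(
    ensemble: PartitionEnsemble,
    native_system: np.ndarray,
    layers: Optional[Sequence[int]] = None,
) -> Dict[int, np.ndarray]:
    """Segregation: per parcel and layer, the mean fraction of the
    parcel's native-system peers sharing its community, averaged over
    restarts. Singleton systems are undefined (NaN, with a warning)."""
    native = np.asarray(native_system)
    K, L, P = ensemble.labels.shape
    if native.shape != (P,):
        raise ValueError("native_system must give one label per parcel")
    if layers is None:
        layers = range(L)
    out = {}
    singleton_warned = False
    for l in layers:
        vals = np.full(P, np.nan)
        for sys in np.unique(native):
            members = np.where(native == sys)[0]
            if members.size < 2:
                if not singleton_warned:
                    warnings.warn(
                        f"native system {sys} has a single parcel; recruitment undefined"
                    )
                    singleton_warned = True
                continue
            sub = ensemble.labels[:, l, :][:, members]  # (K, |S|)
            same = sub[:, :, None] == sub[:, None, :]   # (K, |S|, |S|)
            co = (same.sum(axis=2) - 1) / (members.size - 1)
            vals[members] = co.mean(axis=0)
        out[l] = vals
    return out


def brute_force_optimum(network: MultilayerNetwork) -> Tuple[np.ndarray, float]:
    """Exhaustive maximisation over all set partitions of the supra-nodes.

    Only feasible for tiny fixtures (<= ~8 supra-nodes); serves as the
    independent oracle for the Louvain engine.
    """
    n = network.n_layers * network.n_parcels
    if n > 10:
        raise ValueError("brute force is restricted to <= 10 supra-nodes")
    best_q = -np.inf
    best = None
    for labels in _set_partitions(n):
        arr = np.asarray(labels).reshape(network.n_layers, network.n_parcels)
        q = modularity(network, arr)
        if q > best_q:
            best_q = q
            best = arr
    return best, best_q


def _set_partitions(n: int):
    """All labelings in restricted-growth form (one per set partition)."""

    def rec(prefix, max_label):
        if len(prefix) == n:
            yield prefix
            return
        for lab in range(max_label + 2):
            yield from rec(prefix + [lab], max(max_label, lab))

    yield from rec([0], 0)
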