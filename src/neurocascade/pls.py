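"""Behavioural and gene partial least squares (PLS correlation).

Behavioural PLS decomposes the condition-wise correlation matrix between
a behavioural variate and parcel-level brain measures (six conditions:
task reorganisation at each wave, and per-task segregation at each wave)
by SVD, yielding latent variables (LVs) with condition and parcel
saliences. Gene PLS relates a parcel-level brain LV map to the parcel x
gene expression matrix. Both are evaluated out-of-sample (folds over
subjects for the brain variant, over parcels for the gene variant),
with permutation nulls (free within-condition permutations, or spin
nulls for maps) Procrustes-aligned to the reference solution, and
percentile-bootstrap reliability for element-level contributions.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import orthogonal_procrustes

from .cca import make_folds, _percentile_ci
from .spatial import SpinNullSet

logger = logging.getLogger(__name__)

CONDITION_NAMES = (
    "reorg_w1",
    "reorg_w2",
    "segregation_MID_w1",
    "segregation_MID_w2",
    "segregation_SST_w1",
    "segregation_SST_w2",
)


@dataclass
class PlsResult:
    condition_saliences: Optional[np.ndarray]   # (C, k) or None for gene PLS
    element_saliences: np.ndarray               # (P or G, k)
    singular_values: np.ndarray
    variance_explained: float                   # first LV, s1^2 / sum s^2
    predicted_lv_scores: np.ndarray             # per observation (subject/parcel)
    cross_fold_r: Optional[float] = None
    perm_p: Optional[float] = None
    behav_correlations: Optional[dict] = None
    element_corr: Optional[dict] = None         # estimate / lo / hi / robust

    @property
    def robust_elements(self) -> Optional[np.ndarray]:
        if self.element_corr is None:
            return None
        return np.where(self.element_corr["robust"])[0]


def procrustes_align(
    reference: np.ndarray, resampled: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Orthogonal transform of a resampled solution onto the reference.

    Returns ``(aligned, rotation)`` where ``aligned = resampled @
    rotation`` minimises the Frobenius distance to the reference;
    ``rotation`` should be inverse-applied to the partner singular
    vectors. Fixes the arbitrary sign flips and axis rotations of
    resampled SVDs.
    """
    reference = np.atleast_2d(np.asarray(reference, dtype=float))
    resampled = np.atleast_2d(np.asarray(resampled, dtype=float))
    if reference.shape != resampled.shape:
        raise ValueError("reference and resampled saliences must share shape")
    R, _ = orthogonal_procrustes(resampled, reference)
    return resampled @ R, R


def _zscore_cols(A: np.ndarray, mean=None, sd=None):
    mean = A.mean(axis=0) if mean is None else mean
    sd = A.std(axis=0) if sd is None else sd
    safe = np.where(sd == 0, np.inf, sd)
    return (A - mean) / safe, mean, sd


def _corr_matrix(behaviour_z: np.ndarray, Xz: np.ndarray) -> np.ndarray:
    """Correlation of one z-scored variate with every z-scored column."""
    return behaviour_z @ Xz / len(behaviour_z)


def stack_correlations(
    conditions: Dict[str, np.ndarray], behaviour: np.ndarray
) -> np.ndarray:
    """Condition x parcel matrix of behaviour-brain correlations.

    Zero-variance parcel measures contribute a 0 correlation (warned).
    """
    bz = (behaviour - behaviour.mean()) / behaviour.std()
    rows = []
    for name, X in conditions.items():
        Xz, _, sd = _zscore_cols(np.asarray(X, dtype=float))
        if np.any(sd == 0):
            warnings.warn(f"zero-variance parcel measure(s) in condition {name}; correlation set to 0")
        rows.append(_corr_matrix(bz, Xz))
    return np.vstack(rows)


def behavioural_pls(
    conditions: Dict[str, np.ndarray],
    behaviour: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    n_perm: int = 1000,
    n_boot: int = 1000,
    ci_level: float = 0.999,
) -> PlsResult:
    """Behavioural PLS with test-fold prediction and permutation nulls.

    Per fold, the condition-wise correlation matrix is computed on the
    training subjects and SVD'd; test subjects receive predicted brain
    scores ``sum_c u_c * (X_c @ v)`` from the training saliences.
    Significance: fraction of within-condition permutations of the
    behavioural variate whose Procrustes-aligned first singular value
    meets or exceeds the observed one. Element reliability: percentile
    bootstrap (over subjects) of the correlation between each
    (condition, parcel) measure and the pooled predicted brain score;
    elements whose CI excludes 0 are robust.
    """
    behaviour = np.asarray(behaviour, dtype=float)
    names = list(conditions)
    mats = {k: np.asarray(v, dtype=float) for k, v in conditions.items()}
    n = behaviour.size
    C = len(names)
    P = next(iter(mats.values())).shape[1]
    for k, X in mats.items():
        if X.shape[0] != n:
            raise ValueError(f"condition {k} does not share the subject set")

    # full-sample reference solution
    R_full = stack_correlations(mats, behaviour)
    U, s, Vt = np.linalg.svd(R_full, full_matrices=False)
    # the joint sign of (u, v) is arbitrary; orient the first LV so the
    # first condition's salience is nonnegative (deterministic downstream maps)
    if U[0, 0] < 0:
        U = U.copy()
        Vt = Vt.copy()
        U[:, 0] *= -1
        Vt[0] *= -1
    varexp = float(s[0] ** 2 / (s ** 2).sum())

    # cross-validated predicted brain scores
    folds = make_folds(n, k_folds, seed)
    scores = np.empty(n)
    for f in range(k_folds):
        test = folds == f
        train = ~test
        R_tr = stack_correlations(
            {k: X[train] for k, X in mats.items()}, behaviour[train]
        )
        Ut, st, Vtt = np.linalg.svd(R_tr, full_matrices=False)
        u1, v1 = Ut[:, 0], Vtt[0]
        if u1 @ U[:, 0] + v1 @ Vt[0] < 0:
            u1, v1 = -u1, -v1
        sc = np.zeros(test.sum())
        for ci, k in enumerate(names):
            Xz, _, _ = _zscore_cols(mats[k][train])
            Xtz = (mats[k][test] - mats[k][train].mean(0)) / np.where(
                mats[k][train].std(0) == 0, np.inf, mats[k][train].std(0)
            )
            sc += u1[ci] * (Xtz @ v1)
        scores[test] = sc
    r = float(np.corrcoef(scores, behaviour)[0, 1])

    # permutation null on the first singular value: behaviour permuted
    # independently within each condition, SVD re-extracted per null
    rng = np.random.default_rng(seed)
    bz = (behaviour - behaviour.mean()) / behaviour.std()
    Xzs = [_zscore_cols(mats[k])[0] for k in names]
    count = 0
    for _ in range(n_perm):
        rows = [
            _corr_matrix(bz[rng.permutation(n)], Xz) for Xz in Xzs
        ]
        s1_null = np.linalg.svd(np.vstack(rows), compute_uv=False)[0]
        if s1_null >= s[0]:
            count += 1
    perm_p = (1 + count) / (1 + n_perm)

    # behaviour <-> per-condition predicted score correlations with 95% CI
    rng_b = np.random.default_rng(seed + 1)
    Wb = _bootstrap_weights(rng_b, n, n_boot)
    behav_corr = {}
    flat = np.hstack([mats[k] for k in names])         # n x (C*P)
    for ci, k in enumerate(names):
        Xz, _, _ = _zscore_cols(mats[k])
        cond_score = Xz @ (Vt[0] * U[ci, 0])
        est = float(np.corrcoef(behaviour, cond_score)[0, 1])
        draws = _weighted_corr(Wb, cond_score[:, None], behaviour)[:, 0]
        lo, hi = np.quantile(draws, 0.025), np.quantile(draws, 0.975)
        behav_corr[k] = {"estimate": est, "lo": float(lo), "hi": float(hi)}

    # element-level (condition x parcel) reliability against pooled scores
    est = _weighted_corr(np.ones((1, n)), flat, scores)[0]
    draws = _weighted_corr(Wb, flat, scores)
    lo, hi = _percentile_ci(draws, ci_level)
    element_corr = {
        "estimate": est.reshape(C, P),
        "lo": lo.reshape(C, P),
        "hi": hi.reshape(C, P),
        "robust": ((lo > 0) | (hi < 0)).reshape(C, P),
    }

    return PlsResult(
        condition_saliences=U,
        element_saliences=Vt.T,
        singular_values=s,
        variance_explained=varexp,
        predicted_lv_scores=scores,
        cross_fold_r=r,
        perm_p=perm_p,
        behav_correlations=behav_corr,
        element_corr=element_corr,
    )


def _bootstrap_weights(rng, n: int, n_boot: int) -> np.ndarray:
    """Multinomial resampling weights, one row per bootstrap draw."""
    W = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)
    return W.astype(float)


def _weighted_corr(W: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Correlation of y with each column of X under resampling weights.

    Equivalent to recomputing Pearson r on each bootstrap resample, but
    expressed as weighted moments so all draws run as matrix products.
    """
    n = X.shape[0]
    tot = W.sum(axis=1, keepdims=True)
    sy = (W @ y)[:, None] / tot
    syy = (W @ (y * y))[:, None] / tot
    sx = W @ X / tot
    sxx = W @ (X * X) / tot
    sxy = W @ (X * y[:, None]) / tot
    cov = sxy - sx * sy
    var_x = np.clip(sxx - sx ** 2, 0, None)
    var_y = np.clip(syy - sy ** 2, 0, None)
    denom = np.sqrt(var_x * var_y)
    denom[denom == 0] = np.inf
    return cov / denom


def gene_pls(
    gene_matrix: np.ndarray,
    brain_lv: np.ndarray,
    spins: Optional[SpinNullSet] = None,
    k_folds: int = 10,
    seed: int = 0,
    n_boot: int = 1000,
    ci_level: float = 0.999,
) -> PlsResult:
    """Gene-expression PLS against a parcel-level brain LV map.

    Folds partition parcels. Per fold, gene weights are the brain-gene
    correlations on the training parcels (the first singular vector of a
    1 x G correlation matrix); the predicted gene LV score of a test
    parcel is its expression profile projected on those weights. The
    reported statistic is the pooled test-fold correlation between the
    brain LV and the predicted gene LV; significance uses spin nulls of
    the brain map: p = (1 + #{|r_null| >= |r|}) / (1 + n_null).
    Parcels with missing expression must be excluded beforehand.
    """
    X = np.asarray(gene_matrix, dtype=float)
    lv = np.asarray(brain_lv, dtype=float)
    P, G = X.shape
    if lv.size != P:
        raise ValueError("brain_lv must align with the gene-matrix parcels")
    if np.isnan(X).any():
        raise ValueError("gene matrix contains NaN; exclude parcels without expression first")

    folds = make_folds(P, k_folds, seed)
    r, scores, ref_w = _cv_gene_fit(X, lv, folds)

    perm_p = None
    if spins is not None:
        # each spin re-runs the fold-wise weighting on the spun brain map
        count = 0
        for perm in spins.permutations:
            r_null, _, _ = _cv_gene_fit(X, lv[perm], folds)
            if abs(r_null) >= abs(r):
                count += 1
        perm_p = (1 + count) / (1 + spins.n_null)

    # gene-level reliability: bootstrap (over parcels) of gene <-> gene LV corr
    rng = np.random.default_rng(seed + 1)
    Wb = _bootstrap_weights(rng, P, n_boot)
    est = _weighted_corr(np.ones((1, P)), X, scores)[0]
    draws = _weighted_corr(Wb, X, scores)
    lo, hi = _percentile_ci(draws, ci_level)
    element_corr = {
        "estimate": est,
        "lo": lo,
        "hi": hi,
        "robust": (lo > 0) | (hi < 0),
    }

    s1 = float(np.linalg.norm(_gene_corr_vector(X, lv)))
    return PlsResult(
        condition_saliences=None,
        element_saliences=ref_w[:, None],
        singular_values=np.array([s1]),
        variance_explained=1.0,
        predicted_lv_scores=scores,
        cross_fold_r=r,
        perm_p=perm_p,
        element_corr=element_corr,
    )


def _cv_gene_fit(X: np.ndarray, lv: np.ndarray, folds: np.ndarray):
    """Fold-wise gene weighting and out-of-fold projection.

    Returns (pooled r, per-parcel predicted gene LV scores, full-sample
    reference weights). Fold weights are sign-aligned to the full-sample
    solution of the same brain map.
    """
    P = X.shape[0]
    ref_w = _gene_weights(X, lv)
    scores = np.empty(P)
    for f in np.unique(folds):
        test = folds == f
        train = ~test
        w = _gene_weights(X[train], lv[train])
        if w @ ref_w < 0:
            w = -w
        sd = X[train].std(0)
        Xz = (X[test] - X[train].mean(0)) / np.where(sd == 0, np.inf, sd)
        scores[test] = Xz @ w
    return float(np.corrcoef(lv, scores)[0, 1]), scores, ref_w


def _gene_corr_vector(X: np.ndarray, lv: np.ndarray) -> np.ndarray:
    Xz, _, _ = _zscore_cols(X)
    lz = (lv - lv.mean()) / lv.std()
    return lz @ Xz / len(lv)


def _gene_weights(X: np.ndarray, lv: np.ndarray) -> np.ndarray:
    r = _gene_corr_vector(X, lv)
    norm = np.linalg.norm(r)
    return r / norm if norm > 0 else r


def null_gene_lvs(
    gene_matrix: np.ndarray,
    brain_lv: np.ndarray,
    spins: SpinNullSet,
    reference_scores: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Null gene LV scores (parcels x n_null) from spun brain maps.

    Each null recomputes the gene weights against a spun brain LV and
    projects the expression matrix on them; the resulting null gene LV
    is sign-aligned (1-D Procrustes) to the original gene LV so overlap
    counts are comparable across nulls.
    """
    X = np.asarray(gene_matrix, dtype=float)
    lv = np.asarray(brain_lv, dtype=float)
    Xz, _, _ = _zscore_cols(X)
    out = np.empty((X.shape[0], spins.n_null))
    ref = reference_scores
    if ref is None:
        ref = Xz @ _gene_weights(X, lv)
    for k in range(spins.n_null):
        w = _gene_weights(X, lv[spins.permutations[k]])
        sc = Xz @ w
        if sc @ ref < 0:
            sc = -sc
        out[:, k] = sc
    return out
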