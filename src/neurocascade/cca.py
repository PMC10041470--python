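"""Cross-validated canonical correlation analysis.

CCA finds paired linear combinations (canonical variates) of two
variable sets with maximal correlation. Here the model is evaluated
out-of-sample: weights are estimated on k-1 training folds, variate
scores are predicted in the held-out fold, the pooled test-fold variates
are correlated (``cross_fold_r``), and significance comes from a
permutation test on the pooled variates. Variable-level reliability
(loadings and standardised-coefficient analogues) uses a percentile
bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg

logger = logging.getLogger(__name__)


@dataclass
class CvMultivariateResult:
    fold_assignment: np.ndarray
    weights_x: list                  # per-fold weight vectors
    weights_y: list
    x_variate: np.ndarray            # pooled out-of-sample variate scores
    y_variate: np.ndarray
    cross_fold_r: float
    perm_p: Optional[float] = None
    loadings: Optional[Dict[str, np.ndarray]] = None
    std_coefs: Optional[Dict[str, np.ndarray]] = None


def _center(A: np.ndarray, mean: Optional[np.ndarray] = None):
    mean = A.mean(axis=0) if mean is None else mean
    return A - mean, mean


def fit_cca(
    X: np.ndarray,
    Y: np.ndarray,
    n_components: int = 1,
    ridge: float = 1e-8,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """First canonical weight pairs via whitened SVD.

    Returns ``(Wx, Wy, r)`` with columns the canonical weight vectors and
    ``r`` the in-sample canonical correlations. A singular within-set
    covariance triggers a logged ridge fallback.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    Xc, _ = _center(X)
    Yc, _ = _center(Y)
    Sxx = Xc.T @ Xc / (n - 1)
    Syy = Yc.T @ Yc / (n - 1)
    Sxy = Xc.T @ Yc / (n - 1)

    def chol_inv_sqrt(S):
        try:
            C = linalg.cholesky(S, lower=True)
        except linalg.LinAlgError:
            logger.info("singular covariance; ridge jitter %g applied", ridge)
            C = linalg.cholesky(S + ridge * np.eye(S.shape[0]), lower=True)
        return linalg.solve_triangular(C, np.eye(S.shape[0]), lower=True)

    Kx = chol_inv_sqrt(Sxx)
    Ky = chol_inv_sqrt(Syy)
    M = Kx @ Sxy @ Ky.T
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    k = min(n_components, s.size)
    Wx = Kx.T @ U[:, :k]
    Wy = Ky.T @ Vt[:k].T
    return Wx, Wy, np.clip(s[:k], 0, 1)


def fit_cca_fold(
    train_X: np.ndarray,
    train_Y: np.ndarray,
    ref_wx: Optional[np.ndarray] = None,
    ref_wy: Optional[np.ndarray] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """First canonical weight pair on a training fold.

    Sign-oriented to the full-sample reference solution when given (the
    joint (wx, wy) sign is arbitrary; without alignment pooled variates
    are meaningless). Warns when n_train < 10 * (p + q).
    """
    p, q = train_X.shape[1], train_Y.shape[1]
    if train_X.shape[0] <= 10 * (p + q):
        warnings.warn(
            f"training n={train_X.shape[0]} below 10x the {p + q} contributing variables"
        )
    Wx, Wy, _ = fit_cca(train_X, train_Y, n_components=1)
    wx, wy = Wx[:, 0], Wy[:, 0]
    if ref_wx is not None:
        s = np.sign(wx @ ref_wx + wy @ ref_wy)
        if s == 0:
            s = 1.0
        wx, wy = s * wx, s * wy
    return wx, wy


def make_folds(
    n: int, k_folds: int, seed: int, stratify: Optional[np.ndarray] = None
) -> np.ndarray:
    """Seeded fold assignment, optionally stratified by a grouping column
    (e.g. scanner site) so no fold is confounded with a single group."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(n, dtype=int)
    if stratify is None:
        perm = rng.permutation(n)
        for f, chunk in enumerate(np.array_split(perm, k_folds)):
            assignment[chunk] = f
    else:
        stratify = np.asarray(stratify)
        for g in np.unique(stratify):
            idx = np.where(stratify == g)[0]
            perm = rng.permutation(idx)
            offset = rng.integers(k_folds)
            for j, i in enumerate(perm):
                assignment[i] = (j + offset) % k_folds
    return assignment


def residualize_covariates(
    data: np.ndarray,
    covariates: np.ndarray,
    fold_assignment: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Remove covariate effects without leaking test-fold information.

    For each test fold, regression coefficients (with intercept) are
    estimated on the training folds only and applied to the test fold.
    With ``fold_assignment=None`` a single full-sample fit is used.
    Collinear covariate columns are dropped with a warning.
    """
    data = np.asarray(data, dtype=float)
    one_d = data.ndim == 1
    if one_d:
        data = data[:, None]
    C = np.column_stack([np.ones(len(data)), np.asarray(covariates, dtype=float)])

    # drop collinear/zero-variance columns (keep the intercept)
    keep = [0]
    for j in range(1, C.shape[1]):
        trial = C[:, keep + [j]]
        if np.linalg.matrix_rank(trial) > len(keep):
            keep.append(j)
    if len(keep) < C.shape[1]:
        warnings.warn(
            f"dropped {C.shape[1] - len(keep)} collinear/constant covariate column(s)"
        )
    C = C[:, keep]

    out = np.empty_like(data)
    if fold_assignment is None:
        beta, *_ = np.linalg.lstsq(C, data, rcond=None)
        out = data - C @ beta
    else:
        fold_assignment = np.asarray(fold_assignment)
        for f in np.unique(fold_assignment):
            test = fold_assignment == f
            train = ~test
            beta, *_ = np.linalg.lstsq(C[train], data[train], rcond=None)
            out[test] = data[test] - C[test] @ beta
    return out[:, 0] if one_d else out


def cross_validate_cca(
    X: np.ndarray,
    Y: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    covariates: Optional[np.ndarray] = None,
    stratify: Optional[np.ndarray] = None,
    fold_assignment: Optional[np.ndarray] = None,
) -> CvMultivariateResult:
    """Pooled out-of-sample canonical variates and their correlation.

    Each fold's weights come from the other k-1 folds (after within-fold
    covariate residualisation when covariates are given) and score the
    held-out observations; every observation is scored exactly once.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if Y.ndim == 1:
        Y = Y[:, None]
    n = X.shape[0]
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    if fold_assignment is None:
        fold_assignment = make_folds(n, k_folds, seed, stratify)
    counts = np.bincount(fold_assignment, minlength=k_folds)
    if (n - counts).min() < 3:
        raise ValueError("every training split needs at least 3 observations")

    if covariates is not None:
        X = residualize_covariates(X, covariates, fold_assignment)
        Y = residualize_covariates(Y, covariates, fold_assignment)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ref_wx, ref_wy = fit_cca_fold(X, Y)

    u = np.empty(n)
    v = np.empty(n)
    wxs, wys = [], []
    for f in range(k_folds):
        test = fold_assignment == f
        train = ~test
        Xt, mx = _center(X[train])
        Yt, my = _center(Y[train])
        wx, wy = fit_cca_fold(Xt, Yt, ref_wx, ref_wy)
        wxs.append(wx)
        wys.append(wy)
        u[test] = (X[test] - mx) @ wx
        v[test] = (Y[test] - my) @ wy

    r = float(np.corrcoef(u, v)[0, 1])
    return CvMultivariateResult(
        fold_assignment=fold_assignment,
        weights_x=wxs,
        weights_y=wys,
        x_variate=u,
        y_variate=v,
        cross_fold_r=r,
    )


def permutation_test(
    x_variate: np.ndarray,
    y_variate: np.ndarray,
    n_perm: int = 100_000,
    seed: int = 0,
) -> float:
    """One-sided permutation p for the pooled-variate correlation.

    p = (1 + #{perm r >= observed r}) / (1 + n_perm); the theoretical
    floor is 1/(n_perm + 1). Permutes the observation order of one
    pooled variate.
    """
    x = np.asarray(x_variate, dtype=float)
    y = np.asarray(y_variate, dtype=float)
    if x.shape != y.shape:
        raise ValueError("variates must have equal length")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p-value")
    rng = np.random.default_rng(seed)
    xz = (x - x.mean()) / x.std()
    yz = (y - y.mean()) / y.std()
    n = x.size
    observed = float(xz @ yz / n)
    count = 0
    chunk = max(1, min(n_perm, 50_000_000 // max(n, 1)))
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        idx = np.argsort(rng.random((b, n)), axis=1)
        perm_r = (yz[idx] @ xz) / n
        count += int((perm_r >= observed).sum())
        done += b
    return (1 + count) / (1 + n_perm)


class _FoldCache:
    """Per-fold precomputations for the X side, reused across permutations."""

    def __init__(self, X: np.ndarray, fold_assignment: np.ndarray):
        self.folds = np.asarray(fold_assignment)
        self.X = X
        self.parts = []
        for f in np.unique(self.folds):
            test = self.folds == f
            train = ~test
            Xt = X[train]
            mx = Xt.mean(0)
            Xc = Xt - mx
            Sxx = Xc.T @ Xc / (len(Xt) - 1)
            self.parts.append(
                {
                    "test": test,
                    "train": train,
                    "mx": mx,
                    "Xc": Xc,
                    "Kx": _chol_inv_sqrt(Sxx),
                    "X_test": X[test] - mx,
                }
            )


def _chol_inv_sqrt(S: np.ndarray, ridge: float = 1e-8):
    try:
        C = linalg.cholesky(S, lower=True)
    except linalg.LinAlgError:
        C = linalg.cholesky(S + ridge * np.eye(S.shape[0]), lower=True)
    return linalg.solve_triangular(C, np.eye(S.shape[0]), lower=True)


def _pooled_r_for_y(cache: _FoldCache, Y: np.ndarray) -> float:
    """Cross-fold pooled-variate correlation for one Y realisation.

    Lean re-implementation of the cross_validate_cca scoring path used
    inside the re-fit permutation loop; fold weights are sign-aligned to
    the full-sample solution of the same (X, Y) realisation.
    """
    n = Y.shape[0]
    Yc_all = Y - Y.mean(0)
    Syy = Yc_all.T @ Yc_all / (n - 1)
    Ky = _chol_inv_sqrt(Syy)
    # full-sample reference for sign alignment
    Xc_all = cache.X - cache.X.mean(0)
    Sxy = Xc_all.T @ Yc_all / (n - 1)
    Kx_all = _chol_inv_sqrt(Xc_all.T @ Xc_all / (n - 1))
    U, s, Vt = np.linalg.svd(Kx_all @ Sxy @ Ky.T, full_matrices=False)
    ref_wx = Kx_all.T @ U[:, 0]
    ref_wy = Ky.T @ Vt[0]

    u = np.empty(n)
    v = np.empty(n)
    for part in cache.parts:
        Yt = Y[part["train"]]
        my = Yt.mean(0)
        Yc = Yt - my
        m = len(Yt)
        Kyf = _chol_inv_sqrt(Yc.T @ Yc / (m - 1))
        M = part["Kx"] @ (part["Xc"].T @ Yc / (m - 1)) @ Kyf.T
        Uf, sf, Vtf = np.linalg.svd(M, full_matrices=False)
        wx = part["Kx"].T @ Uf[:, 0]
        wy = Kyf.T @ Vtf[0]
        if wx @ ref_wx + wy @ ref_wy < 0:
            wx, wy = -wx, -wy
        u[part["test"]] = part["X_test"] @ wx
        v[part["test"]] = (Y[part["test"]] - my) @ wy
    return float(np.corrcoef(u, v)[0, 1])


def permutation_test_refit(
    X: np.ndarray,
    Y: np.ndarray,
    result: CvMultivariateResult,
    n_perm: int = 999,
    seed: int = 0,
    covariates: Optional[np.ndarray] = None,
    permutations: Optional[np.ndarray] = None,
) -> float:
    """Full re-fit permutation p for the cross-validated correlation.

    Each permutation reorders the rows of Y (or applies a supplied
    permutation, e.g. spin nulls for parcel maps) and re-runs the entire
    fold-wise fit-and-score procedure, so the null honours the
    dependence between out-of-fold predictions that the pooled-variate
    shortcut ignores. p = (1 + #{null r >= observed r}) / (1 + n_perm).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    if covariates is not None:
        X = residualize_covariates(X, covariates, result.fold_assignment)
        Y = residualize_covariates(Y, covariates, result.fold_assignment)
    cache = _FoldCache(X, result.fold_assignment)
    observed = result.cross_fold_r
    rng = np.random.default_rng(seed)
    n = Y.shape[0]
    count = 0
    for k in range(n_perm):
        perm = permutations[k] if permutations is not None else rng.permutation(n)
        if _pooled_r_for_y(cache, Y[perm]) >= observed:
            count += 1
    return (1 + count) / (1 + n_perm)


def _percentile_ci(draws: np.ndarray, level: float) -> Tuple[np.ndarray, np.ndarray]:
    alpha = (1 - level) / 2
    return (
        np.quantile(draws, alpha, axis=0),
        np.quantile(draws, 1 - alpha, axis=0),
    )


def bootstrap_reliability(
    X: np.ndarray,
    Y: np.ndarray,
    result: CvMultivariateResult,
    n_boot: int = 1000,
    ci_level: float = 0.999,
    seed: int = 0,
) -> CvMultivariateResult:
    """Percentile-bootstrap CIs for variable-level association measures.

    For each set: (a) loadings — correlation of every observed variable
    with the predicted variate of its own set; (b) standardised
    coefficients — multiple-regression coefficients of the set's
    (z-scored) variables predicting the opposite set's predicted
    variate. A variable is "robust" iff its CI excludes 0. Resampling is
    over observations, holding the pooled variates fixed.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    if Y.shape[0] == 1:
        Y = Y.T
    n = X.shape[0]
    u, v = result.x_variate, result.y_variate
    rng = np.random.default_rng(seed)

    def stats(idx):
        xs, ys, us, vs = X[idx], Y[idx], u[idx], v[idx]
        out = {}
        out["x_loadings"] = _cols_corr(xs, us)
        out["y_loadings"] = _cols_corr(ys, vs)
        out["x_coefs"] = _std_coefs(xs, vs)
        out["y_coefs"] = _std_coefs(ys, us)
        return out

    point = stats(np.arange(n))
    draws = {k: np.empty((n_boot, val.size)) for k, val in point.items()}
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        st = stats(idx)
        for k in draws:
            draws[k][b] = st[k]

    loadings = {}
    coefs = {}
    for k in ("x_loadings", "y_loadings"):
        lo, hi = _percentile_ci(draws[k], ci_level)
        loadings[k] = {"estimate": point[k], "lo": lo, "hi": hi,
                       "robust": (lo > 0) | (hi < 0)}
    for k in ("x_coefs", "y_coefs"):
        lo, hi = _percentile_ci(draws[k], ci_level)
        coefs[k] = {"estimate": point[k], "lo": lo, "hi": hi,
                    "robust": (lo > 0) | (hi < 0)}
    result.loadings = loadings
    result.std_coefs = coefs
    return result


def _cols_corr(A: np.ndarray, v: np.ndarray) -> np.ndarray:
    Ac = A - A.mean(axis=0)
    vc = v - v.mean()
    denom = np.sqrt((Ac ** 2).sum(0) * (vc ** 2).sum())
    denom[denom == 0] = np.inf
    return Ac.T @ vc / denom


def _std_coefs(A: np.ndarray, v: np.ndarray) -> np.ndarray:
    sd = A.std(axis=0)
    sd[sd == 0] = np.inf
    Az = (A - A.mean(axis=0)) / sd
    vz = (v - v.mean()) / (v.std() or 1.0)
    D = np.column_stack([np.ones(len(Az)), Az])
    beta, *_ = np.linalg.lstsq(D, vz, rcond=None)
    return beta[1:]
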