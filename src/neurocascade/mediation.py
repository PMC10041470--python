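"""Moderated mediation with percentile-bootstrap inference.

The model has PROCESS model-14 topology: the predictor X affects the
mediator M (path a); M affects the outcome Y with a slope that depends
on a binary moderator W (paths b and b3 for the M x W interaction);
X retains a direct path. The conditional indirect effect at moderator
level w is a * (b + b3 * w) and the index of moderated mediation is
a * b3. Coefficient tests use heteroscedasticity-consistent standard
errors (HC3 by default); indirect-effect CIs are percentile bootstrap.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)


@dataclass
class MediationResult:
    a_path: float
    b_path: float
    b_interaction: float
    interaction_t: float
    interaction_df: int
    interaction_p: float
    conditional_indirect: Dict[int, dict]   # w -> {estimate, lo, hi}
    index_modmed: dict                      # {estimate, se, lo, hi}
    covariate_coefs: Dict[str, float]
    n_redrawn: int = 0


def median_split(variate: np.ndarray) -> np.ndarray:
    """Binary split at the median; ties (values == median) go to group 0."""
    v = np.asarray(variate, dtype=float)
    if np.unique(v).size < 2:
        raise ValueError("cannot median-split a constant variate")
    return (v > np.median(v)).astype(int)


def prepare_outcome(
    psychopathology_t3: np.ndarray, psychopathology_t2: np.ndarray
) -> np.ndarray:
    """Square-root both totals and residualise follow-up on baseline.

    Returns the residuals of sqrt(t3) regressed on sqrt(t2) with an
    intercept — the "change in psychopathology" outcome.
    """
    t3 = np.asarray(psychopathology_t3, dtype=float)
    t2 = np.asarray(psychopathology_t2, dtype=float)
    if np.any(t3 < 0) or np.any(t2 < 0):
        raise ValueError("psychopathology totals must be nonnegative")
    y = np.sqrt(t3)
    x = np.sqrt(t2)
    D = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(D, y, rcond=None)
    return y - D @ beta


def _drop_collinear(D: np.ndarray, names: list) -> Tuple[np.ndarray, list]:
    keep = [0]
    for j in range(1, D.shape[1]):
        if np.linalg.matrix_rank(D[:, keep + [j]]) > len(keep):
            keep.append(j)
    if len(keep) < D.shape[1]:
        dropped = [names[j] for j in range(D.shape[1]) if j not in keep]
        warnings.warn(f"dropped collinear columns: {dropped}")
    return D[:, keep], [names[j] for j in keep]


def fit_moderated_mediation(
    data: pd.DataFrame,
    predictor: str = "x",
    mediator: str = "m",
    moderator: str = "w",
    outcome: str = "y",
    covariates: Sequence[str] = (),
    n_boot: int = 5000,
    seed: int = 0,
    hc_type: str = "HC3",
    ci_level: float = 0.95,
) -> MediationResult:
    """Fit the moderated mediation model and bootstrap its indirect effects.

    Mediator model: M ~ X + covariates (OLS). Outcome model: Y ~ X + M +
    W + M*W + covariates (OLS). ``hc_type`` selects the
    heteroscedasticity-consistent covariance for coefficient tests
    ("none" falls back to classical OLS standard errors). The bootstrap
    resamples observations, refits both models and collects
    a*(b + b3*w) for each moderator level and a*b3; CIs are percentile.
    """
    df = data[[predictor, mediator, moderator, outcome, *covariates]].dropna()
    n = len(df)
    x = df[predictor].to_numpy(dtype=float)
    m = df[mediator].to_numpy(dtype=float)
    w = df[moderator].to_numpy(dtype=float)
    y = df[outcome].to_numpy(dtype=float)
    if not set(np.unique(w)) <= {0.0, 1.0}:
        raise ValueError("moderator must be dummy-coded 0/1")
    C = df[list(covariates)].to_numpy(dtype=float) if covariates else np.empty((n, 0))

    m_names = ["const", predictor] + [f"cov_{c}" for c in covariates]
    Dm = np.column_stack([np.ones(n), x, C])
    Dm, m_names = _drop_collinear(Dm, m_names)

    y_names = ["const", predictor, mediator, moderator, "m_x_w"] + [
        f"cov_{c}" for c in covariates
    ]
    Dy = np.column_stack([np.ones(n), x, m, w, m * w, C])
    Dy, y_names = _drop_collinear(Dy, y_names)

    cov_kw = {} if hc_type.lower() == "none" else {"cov_type": hc_type}
    m_fit = sm.OLS(m, Dm).fit(**cov_kw)
    y_fit = sm.OLS(y, Dy).fit(**cov_kw)

    a = float(m_fit.params[m_names.index(predictor)])
    b = float(y_fit.params[y_names.index(mediator)])
    j_int = y_names.index("m_x_w")
    b3 = float(y_fit.params[j_int])
    t_int = float(y_fit.tvalues[j_int])
    df_resid = int(y_fit.df_resid)
    p_int = float(y_fit.pvalues[j_int])

    # percentile bootstrap of the indirect effects (batched normal equations)
    rng = np.random.default_rng(seed)
    draws_a = np.empty(n_boot)
    draws_b = np.empty(n_boot)
    draws_b3 = np.empty(n_boot)
    jx_m = m_names.index(predictor)
    jm_y = y_names.index(mediator)
    redrawn = 0
    b_done = 0
    while b_done < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            bm = np.linalg.solve(Dm[idx].T @ Dm[idx], Dm[idx].T @ m[idx])
            by = np.linalg.solve(Dy[idx].T @ Dy[idx], Dy[idx].T @ y[idx])
        except np.linalg.LinAlgError:
            redrawn += 1
            if redrawn > 100 * n_boot:
                raise RuntimeError("too many singular bootstrap fits")
            continue
        draws_a[b_done] = bm[jx_m]
        draws_b[b_done] = by[jm_y]
        draws_b3[b_done] = by[j_int]
        b_done += 1
    if redrawn:
        logger.info("%d singular bootstrap samples redrawn", redrawn)

    alpha = (1 - ci_level) / 2

    def q(d, level):
        # percentile CI endpoints as actual order statistics of the draws
        return float(np.quantile(d, level, method="closest_observation"))

    conditional = {}
    for lvl in (0, 1):
        eff = draws_a * (draws_b + draws_b3 * lvl)
        conditional[lvl] = {
            "estimate": a * (b + b3 * lvl),
            "lo": q(eff, alpha),
            "hi": q(eff, 1 - alpha),
        }
    idx_draws = draws_a * draws_b3
    index = {
        "estimate": a * b3,
        "se": float(idx_draws.std(ddof=1)),
        "lo": q(idx_draws, alpha),
        "hi": q(idx_draws, 1 - alpha),
    }

    cov_coefs = {
        name: float(y_fit.params[j])
        for j, name in enumerate(y_names)
        if name.startswith("cov_")
    }

    return MediationResult(
        a_path=a,
        b_path=b,
        b_interaction=b3,
        interaction_t=t_int,
        interaction_df=df_resid,
        interaction_p=p_int,
        conditional_indirect=conditional,
        index_modmed=index,
        covariate_coefs=cov_coefs,
        n_redrawn=redrawn,
    )
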