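"""Phenotype scoring: checklist totals and adversity scale scores."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd


def checklist_total(table: pd.DataFrame, prefix: str) -> pd.Series:
    """Total problems score: the sum of all 0/1/2 item responses whose
    column name starts with ``prefix`` (e.g. ``cbcl_w2_``)."""
    cols = [c for c in table.columns if c.startswith(prefix)]
    if not cols:
        raise ValueError(f"no item columns with prefix {prefix!r}")
    return table[cols].sum(axis=1)


def syndrome_scores(
    table: pd.DataFrame, prefix: str, n_syndromes: int
) -> pd.DataFrame:
    """Item sums over ``n_syndromes`` contiguous item groups.

    Splits the ordered item columns into nearly equal blocks; a coarse
    syndrome-scale stand-in for a real instrument's subscales.
    """
    cols = sorted(c for c in table.columns if c.startswith(prefix))
    if not cols:
        raise ValueError(f"no item columns with prefix {prefix!r}")
    out = {}
    for k, block in enumerate(np.array_split(np.array(cols), n_syndromes)):
        out[f"{prefix}syn{k + 1}"] = table[list(block)].sum(axis=1)
    return pd.DataFrame(out, index=table.index)


def mean_score(table: pd.DataFrame, cols: Sequence[str]) -> pd.Series:
    """Scale score as the mean of its items."""
    return table[list(cols)].mean(axis=1)


def reverse_code(values: pd.Series, scale_min: int, scale_max: int) -> pd.Series:
    """Reverse a Likert item: x -> (min + max) - x.

    Used to turn "higher = safer" neighbourhood ratings into a crime /
    threat index where higher = more adverse.
    """
    return (scale_min + scale_max) - values


def adversity_scores(table: pd.DataFrame, wave: int) -> pd.DataFrame:
    """Deprivation, family conflict and neighbourhood crime at one wave.

    Deprivation and conflict are item means; neighbourhood safety
    (5-point, higher = safer) is reverse-coded into a crime index.
    """
    dep_cols = [c for c in table.columns if c.startswith(f"dep_w{wave}_")]
    con_cols = [c for c in table.columns if c.startswith(f"conflict_w{wave}_")]
    out = pd.DataFrame(index=table.index)
    out[f"deprivation_w{wave}"] = mean_score(table, dep_cols)
    out[f"conflict_w{wave}"] = mean_score(table, con_cols)
    out[f"crime_w{wave}"] = reverse_code(table[f"neigh_safety_w{wave}"], 1, 5)
    return out


def covariate_matrix(
    table: pd.DataFrame,
    site_col: str = "site",
    extra: Sequence[str] = (
        "age_months",
        "sex",
        "handedness",
        "medical_problems",
        "motion_mid",
        "motion_sst",
    ),
) -> np.ndarray:
    """Nuisance design: age, sex, handedness, medical problems, motion
    and scanner-site dummies (reference site omitted)."""
    parts = [table[list(extra)].to_numpy(dtype=float)]
    sites = pd.get_dummies(table[site_col], drop_first=True)
    if sites.shape[1]:
        parts.append(sites.to_numpy(dtype=float))
    return np.column_stack(parts)
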