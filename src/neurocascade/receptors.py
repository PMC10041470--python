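"""Neurotransmitter receptor density maps and their link to brain maps.

Tracer-level parcel maps are combined into one map per receptor by a
weighted average over the participant counts of the contributing
studies, standardised across parcels; four correlated serotonin indices
(HT1a, HT2, HT4, HT6) are averaged into a composite while HT1b enters
separately. The receptor block is related to a parcel-level brain LV by
the shared cross-validated CCA machinery, with spin nulls (the
observations are parcels, so free permutations would ignore spatial
autocorrelation).
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence

import numpy as np
import pandas as pd

from .cca import CvMultivariateResult, cross_validate_cca, permutation_test_refit
from .spatial import SpinNullSet

HT_COMPOSITE_MEMBERS = ("HT1a", "HT2", "HT4", "HT6")


def standardize(maps: pd.DataFrame) -> pd.DataFrame:
    """Z-score each receptor map across parcels (idempotent)."""
    return (maps - maps.mean(axis=0)) / maps.std(axis=0, ddof=0)


def weighted_average_tracers(
    tracer_maps: Sequence[np.ndarray], participant_counts: Sequence[float]
) -> np.ndarray:
    """Parcel-wise average of tracer maps weighted by study sample size."""
    if len(tracer_maps) == 0:
        raise ValueError("need at least one tracer map")
    counts = np.asarray(participant_counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("participant counts must be > 0")
    arrs = [np.asarray(m, dtype=float) for m in tracer_maps]
    shape = arrs[0].shape
    for a in arrs:
        if a.shape != shape:
            raise ValueError("tracer maps cover mismatched parcel sets")
    stacked = np.stack(arrs)
    return (counts[:, None] * stacked).sum(0) / counts.sum()


def composite_ht(standardized_maps: Dict[str, np.ndarray]) -> np.ndarray:
    """Parcel-wise mean of the four correlated serotonin density indices.

    Inputs must already be standardised; HT1b is not part of the
    composite and should be carried through untouched.
    """
    missing = [m for m in HT_COMPOSITE_MEMBERS if m not in standardized_maps]
    if missing:
        raise ValueError(f"missing serotonin maps: {missing}")
    return np.mean([np.asarray(standardized_maps[m], dtype=float) for m in HT_COMPOSITE_MEMBERS], axis=0)


def build_receptor_block(maps: pd.DataFrame) -> pd.DataFrame:
    """Analysis-ready receptor block: composite HT plus the other maps."""
    z = standardize(maps)
    out = pd.DataFrame(index=maps.index)
    for col in z.columns:
        if col in HT_COMPOSITE_MEMBERS:
            continue
        out[col] = z[col]
    out["HT_composite"] = composite_ht({m: z[m].to_numpy() for m in HT_COMPOSITE_MEMBERS})
    return out


def receptor_cca(
    brain_lv: np.ndarray,
    receptor_block: pd.DataFrame,
    spins: SpinNullSet,
    k_folds: int = 10,
    seed: int = 0,
) -> CvMultivariateResult:
    """Cross-validated CCA of a brain map against the receptor block.

    Observations are parcels. Significance replaces free permutation
    with spin nulls of the brain map (the side with known spherical
    geometry): each spin re-runs the full fold-wise fit, and
    p = (1 + #{r_spun >= r}) / (1 + n_null).
    """
    lv = np.asarray(brain_lv, dtype=float)
    Y = receptor_block.to_numpy(dtype=float)
    if lv.size != Y.shape[0]:
        raise ValueError("brain map and receptor block cover different parcel sets")
    result = cross_validate_cca(lv[:, None], Y, k_folds=k_folds, seed=seed)
    result.perm_p = permutation_test_refit(
        Y,
        lv,
        result,
        n_perm=spins.n_null,
        seed=seed,
        permutations=spins.permutations,
    )
    return result
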