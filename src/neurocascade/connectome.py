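"""Task connectomes: Fisher-z correlation matrices with negative zeroing."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

# keeps atanh finite when two series correlate at exactly +/-1
CLIP = 1e-7


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal matrix of Fisher-z connectivity scores."""

    values: np.ndarray
    task: str = ""
    wave: int = 0
    parcel_ids: Optional[List[str]] = None
    n_zeroed: int = 0

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("connectivity matrix must be symmetric")
        if not np.all(np.isfinite(v)):
            raise ValueError("connectivity matrix contains non-finite values")
        self.values = v


def correlation_matrix(
    series: np.ndarray,
    task: str = "",
    wave: int = 0,
    parcel_ids: Optional[Sequence[str]] = None,
) -> ConnectivityMatrix:
    """Pairwise Pearson correlations of parcel time series as Fisher z.

    ``series`` is parcels x timepoints; runs belonging to the same task
    should be concatenated along time before calling (run order = run
    index). z = atanh(clip(r, +/-(1 - 1e-7))), diagonal set to 0.
    """
    series = np.asarray(series, dtype=float)
    if series.ndim != 2:
        raise ValueError("series must be a 2-D parcels x timepoints matrix")
    if series.shape[1] < 10:
        raise ValueError("need at least 10 timepoints for stable correlations")
    if np.isnan(series).any():
        raise ValueError("series contains NaN")
    sd = series.std(axis=1)
    constant = sd <= 1e-10 * (1.0 + np.abs(series.mean(axis=1)))
    if np.any(constant):
        bad = np.where(constant)[0]
        names = (
            [parcel_ids[i] for i in bad] if parcel_ids is not None else bad.tolist()
        )
        raise ValueError(f"constant time series for parcel(s): {names}")

    r = np.corrcoef(series)
    r = np.clip(r, -(1 - CLIP), 1 - CLIP)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2  # remove floating-point asymmetry
    return ConnectivityMatrix(
        values=z,
        task=task,
        wave=wave,
        parcel_ids=list(parcel_ids) if parcel_ids is not None else None,
    )


def zero_negative(matrix: ConnectivityMatrix) -> ConnectivityMatrix:
    """Set negative Fisher-z entries to zero.

    Only positive weights enter the multilayer community analyses; the
    count of zeroed entries is logged and stored on the result.
    """
    v = matrix.values.copy()
    neg = v < 0
    n_zeroed = int(neg.sum())
    v[neg] = 0.0
    if n_zeroed:
        logger.info("zeroed %d negative edges (%s wave %s)", n_zeroed, matrix.task, matrix.wave)
    return ConnectivityMatrix(
        values=v,
        task=matrix.task,
        wave=matrix.wave,
        parcel_ids=matrix.parcel_ids,
        n_zeroed=n_zeroed,
    )
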