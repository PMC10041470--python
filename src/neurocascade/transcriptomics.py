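"""Gene-expression normalisation and the stress-gene overlap test.

Expression values are normalised with a robust sigmoid,

    x_norm = 1 / (1 + exp(-(x - <x>) / IQR_x)),

where <x> is the median and IQR_x the interquartile range of one tissue
sample across genes, then rescaled to the unit interval; the identical
procedure is applied across tissue samples (per gene). Samples assigned
to the same parcel are averaged within donor and then across donors.

The overlap test asks whether genes robustly associated with a gene LV
are enriched for externally defined stress genes: stress_high genes
whose risk alleles increase expression, stress_low genes whose risk
alleles decrease it. Null counts come from Procrustes-aligned null gene
LVs (spin-based), taking from each null the same number of top genes as
observed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd


@dataclass
class StressGeneSets:
    stress_low: list        # risk alleles reduce expression
    stress_high: list       # risk alleles increase expression

    def __post_init__(self):
        if set(self.stress_low) & set(self.stress_high):
            raise ValueError("stress_low and stress_high must be disjoint")


@dataclass
class OverlapResult:
    orig_pos: int
    orig_neg: int
    stress_high_pos: int
    stress_low_pos: int
    stress_high_neg: int
    stress_low_neg: int
    p_susceptibility: Optional[float]
    p_inverse: Optional[float]
    brain_gene_r: float


def robust_sigmoid(values: np.ndarray) -> np.ndarray:
    """The robust sigmoid itself: 1/(1+exp(-(x - median)/IQR)).

    Median and IQR are taken over ``values``; the value at the median
    maps to 0.5 and at median + IQR to 1/(1+e^-1) ~ 0.7311.
    """
    x = np.asarray(values, dtype=float)
    med = np.median(x)
    q75, q25 = np.percentile(x, [75, 25])
    iqr = q75 - q25
    if iqr == 0:
        raise ValueError("zero IQR")
    z = np.clip((x - med) / iqr, -500, 500)  # avoid exp overflow, same result
    return 1.0 / (1.0 + np.exp(-z))


def unit_rescale(values: np.ndarray) -> np.ndarray:
    """(x - min) / (max - min); endpoints map to exactly 0 and 1."""
    x = np.asarray(values, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def robust_sigmoid_normalize(values: pd.DataFrame) -> pd.DataFrame:
    """Two-pass robust sigmoid normalisation to [0, 1].

    First across genes within each sample (row), then the identical
    procedure across samples within each gene (column). A zero-IQR
    sample or gene is an error naming the offender.
    """
    out = _sigmoid_pass(values, axis=1, kind="sample")
    out = _sigmoid_pass(out, axis=0, kind="gene")
    return out


def _sigmoid_pass(df: pd.DataFrame, axis: int, kind: str) -> pd.DataFrame:
    X = df.to_numpy(dtype=float)
    # operate with rows as the normalisation unit
    work = X if axis == 1 else X.T
    labels = df.index if axis == 1 else df.columns
    med = np.median(work, axis=1, keepdims=True)
    q75 = np.percentile(work, 75, axis=1, keepdims=True)
    q25 = np.percentile(work, 25, axis=1, keepdims=True)
    iqr = q75 - q25
    if np.any(iqr == 0):
        bad = labels[np.where(iqr[:, 0] == 0)[0]].tolist()
        raise ValueError(f"zero IQR for {kind}(s): {bad}")
    norm = 1.0 / (1.0 + np.exp(-(work - med) / iqr))
    lo = norm.min(axis=1, keepdims=True)
    hi = norm.max(axis=1, keepdims=True)
    span = np.where(hi - lo == 0, 1.0, hi - lo)
    scaled = (norm - lo) / span
    result = scaled if axis == 1 else scaled.T
    return pd.DataFrame(result, index=df.index, columns=df.columns)


def aggregate_samples_to_parcels(
    samples: pd.DataFrame,
    parcel_col: str = "parcel_id",
    donor_col: str = "donor_id",
) -> Tuple[pd.DataFrame, list]:
    """Two-stage mean: within donor per parcel, then across donors.

    ``samples`` holds one row per tissue sample with its parcel
    assignment (samples without one should already be discarded) and
    donor id; remaining columns are gene values. Parcels with no samples
    anywhere are simply absent; the list of parcels contributed by fewer
    donors than the maximum is returned for logging.
    """
    gene_cols = [c for c in samples.columns if c not in (parcel_col, donor_col)]
    per_donor = samples.groupby([donor_col, parcel_col])[gene_cols].mean()
    across = per_donor.groupby(level=parcel_col).mean()
    donor_counts = per_donor.groupby(level=parcel_col).size()
    sparse = donor_counts[donor_counts < donor_counts.max()].index.tolist()
    return across, sparse


def overlap_test(
    gene_corr: np.ndarray,
    robust_mask: np.ndarray,
    gene_symbols: Sequence[str],
    sets: StressGeneSets,
    null_gene_lvs: np.ndarray,
    gene_matrix: np.ndarray,
    brain_gene_r: float,
) -> OverlapResult:
    """Stress-susceptibility enrichment against spin-based null gene LVs.

    Observed counts: among genes with a robust positive (negative)
    association with the gene LV, how many belong to stress_high and
    stress_low. For each null LV the same *number* of genes as observed
    (Orig_pos top-ranked positive, Orig_neg top-ranked negative, by the
    null gene-LV correlations) is selected and the same counts taken.

    With a positive brain-gene correlation, susceptibility is the
    conjunction count (stress_high among the positives + stress_low
    among the negatives); with a negative correlation the directions
    swap. The inverse test uses the opposite pairing. p = (1 + #{null
    count >= observed}) / (1 + n_null); an empty robust set makes the
    corresponding p undefined (None, with a warning).
    """
    gene_corr = np.asarray(gene_corr, dtype=float)
    robust_mask = np.asarray(robust_mask, dtype=bool)
    symbols = np.asarray(gene_symbols)
    G = gene_corr.size

    low = np.isin(symbols, list(sets.stress_low))
    high = np.isin(symbols, list(sets.stress_high))

    pos = robust_mask & (gene_corr > 0)
    neg = robust_mask & (gene_corr < 0)
    orig_pos, orig_neg = int(pos.sum()), int(neg.sum())

    counts = {
        "stress_high_pos": int((pos & high).sum()),
        "stress_low_pos": int((pos & low).sum()),
        "stress_high_neg": int((neg & high).sum()),
        "stress_low_neg": int((neg & low).sum()),
    }

    if brain_gene_r >= 0:
        obs_susc = counts["stress_high_pos"] + counts["stress_low_neg"]
        obs_inv = counts["stress_low_pos"] + counts["stress_high_neg"]
    else:
        obs_susc = counts["stress_low_pos"] + counts["stress_high_neg"]
        obs_inv = counts["stress_high_pos"] + counts["stress_low_neg"]

    if orig_pos == 0 and orig_neg == 0:
        warnings.warn("no robust genes; overlap p-values undefined")
        return OverlapResult(
            orig_pos, orig_neg, *counts.values(), None, None, brain_gene_r
        )

    # null correlations of every gene with each null gene LV
    X = np.asarray(gene_matrix, dtype=float)
    Xz = (X - X.mean(0)) / np.where(X.std(0) == 0, np.inf, X.std(0))
    L = np.asarray(null_gene_lvs, dtype=float)
    Lz = (L - L.mean(0)) / np.where(L.std(0) == 0, np.inf, L.std(0))
    null_corr = Xz.T @ Lz / X.shape[0]           # (G, n_null)
    n_null = null_corr.shape[1]

    nc = null_overlap_counts(null_corr, orig_pos, orig_neg, high, low)
    if brain_gene_r >= 0:
        null_susc = nc["high_pos"] + nc["low_neg"]
        null_inv = nc["low_pos"] + nc["high_neg"]
    else:
        null_susc = nc["low_pos"] + nc["high_neg"]
        null_inv = nc["high_pos"] + nc["low_neg"]
    susc_count = int((null_susc >= obs_susc).sum())
    inv_count = int((null_inv >= obs_inv).sum())

    return OverlapResult(
        orig_pos=orig_pos,
        orig_neg=orig_neg,
        **counts,
        p_susceptibility=(1 + susc_count) / (1 + n_null),
        p_inverse=(1 + inv_count) / (1 + n_null),
        brain_gene_r=brain_gene_r,
    )


def null_overlap_counts(
    null_corr: np.ndarray,
    orig_pos: int,
    orig_neg: int,
    high: np.ndarray,
    low: np.ndarray,
) -> Dict[str, np.ndarray]:
    """Per-null stress-set membership counts.

    For each null LV, take the ``orig_pos`` most positively and
    ``orig_neg`` most negatively correlated genes and count how many
    fall in each stress set. Under pure-noise nulls the expected
    high_pos count is the hypergeometric value
    orig_pos * |stress_high| / n_genes.
    """
    G, n_null = null_corr.shape
    order = np.argsort(-null_corr, axis=0)
    out = {
        "high_pos": np.zeros(n_null, dtype=int),
        "low_pos": np.zeros(n_null, dtype=int),
        "high_neg": np.zeros(n_null, dtype=int),
        "low_neg": np.zeros(n_null, dtype=int),
    }
    for k in range(n_null):
        top_pos = order[:orig_pos, k]
        top_neg = order[G - orig_neg:, k] if orig_neg else np.empty(0, dtype=int)
        out["high_pos"][k] = int(high[top_pos].sum())
        out["low_pos"][k] = int(low[top_pos].sum())
        out["high_neg"][k] = int(high[top_neg].sum())
        out["low_neg"][k] = int(low[top_neg].sum())
    return out


def read_stress_lists(low_path, high_path) -> StressGeneSets:
    """Plain-text gene lists, one symbol per line."""
    def read(p):
        with open(p) as fh:
            return [line.strip() for line in fh if line.strip()]

    return StressGeneSets(stress_low=read(low_path), stress_high=read(high_path))
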