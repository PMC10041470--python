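"""Synthetic study-data generator with planted, recoverable structure.

Every input the analysis cascade consumes can be generated here: parcel
metadata on two mirrored hemispheres, per-subject task time series with
block community structure that differs between tasks, a phenotype table
with a planted canonical correlation between an adversity/PRS set and
psychopathology, additive genotypes plus a GWAS weight table, a spatially
autocorrelated parcel x gene expression matrix with planted stress-gene
subsets, and receptor density maps loaded on the same spatial pattern.

All planted parameters are recorded in ``SyntheticBundle.truth`` so each
downstream stage can be checked against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple, Optional

import numpy as np
import pandas as pd

# rng stream constants: one independent child stream per generated artefact
_S_PARCELS = 1
_S_GENOTYPES = 2
_S_PHENOTYPES = 3
_S_TIMESERIES = 4
_S_GENES = 5
_S_RECEPTORS = 6
_S_PATTERN = 7

TASKS = ("MID", "SST")
WAVES = (1, 2)

# marginal probabilities of item responses 0/1/2 at zero latent severity
_ITEM_MARGINALS = (0.70, 0.20, 0.10)
_ITEM_LOADING = 0.4

RECEPTOR_NAMES = ("D2", "GABA", "GLU5R", "ACh", "HT1a", "HT2", "HT4", "HT6", "HT1b")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Counts are all >= 1; ``canonical_r`` lives in [0, 1);
    ``community_shift_fraction`` in [0, 1]. An identical config (seed
    included) regenerates a bit-identical bundle.
    """

    n_subjects: int = 300
    n_parcels: int = 297
    n_timepoints: int = 200
    n_genes: int = 15632
    n_networks: int = 7
    n_items: int = 112
    n_syndromes: int = 8
    n_snps: int = 60
    n_sites: int = 3
    canonical_r: float = 0.5
    community_shift_fraction: float = 0.3
    spatial_rho: float = 0.5
    snr: float = 1.0
    gene_loading: float = 0.6
    receptor_loading: float = 0.6
    n_stress_low: int = 27
    n_stress_high: int = 45
    effect_a: float = 0.5
    effect_b_low: float = 0.0
    effect_b_high: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_parcels": self.n_parcels,
            "n_timepoints": self.n_timepoints,
            "n_genes": self.n_genes,
            "n_networks": self.n_networks,
            "n_items": self.n_items,
            "n_syndromes": self.n_syndromes,
            "n_snps": self.n_snps,
            "n_sites": self.n_sites,
        }
        for name, value in counts.items():
            if int(value) < 1:
                raise ValueError(f"{name} must be >= 1, got {value}")
        if not (0.0 <= self.canonical_r < 1.0):
            raise ValueError("canonical_r must lie in [0, 1)")
        if not (0.0 <= self.community_shift_fraction <= 1.0):
            raise ValueError("community_shift_fraction must lie in [0, 1]")
        if self.spatial_rho < 0:
            raise ValueError("spatial_rho must be >= 0")
        if self.n_timepoints < 10:
            raise ValueError("n_timepoints < 10 gives unstable correlations")
        if self.n_genes < self.n_stress_low + self.n_stress_high:
            raise ValueError(
                "n_genes must be at least |stress_low| + |stress_high|"
            )


@dataclass
class SyntheticBundle:
    """Everything the pipeline consumes, plus the ground-truth record."""

    config: SimulationConfig
    parcel_meta: pd.DataFrame
    phenotypes: pd.DataFrame
    genotypes: pd.DataFrame
    weights: pd.DataFrame
    gene_matrix: pd.DataFrame
    stress_low: list
    stress_high: list
    receptor_maps: pd.DataFrame
    truth: dict
    time_series: Optional[Dict[Tuple[int, str, int], np.ndarray]] = None

    def get_time_series(self, subject: int, task: str, wave: int) -> np.ndarray:
        """Parcels x timepoints matrix for one subject/task/wave.

        Generated lazily and deterministically; the bundle does not need
        to hold all series in memory at once.
        """
        if self.time_series is not None and (subject, task, wave) in self.time_series:
            return self.time_series[(subject, task, wave)]
        return _subject_time_series(
            self.config,
            subject,
            task,
            wave,
            self.truth["community_plan"],
            np.asarray(self.truth["brain_factor"]),
            np.asarray(self.truth["spatial_pattern"]),
        )


def _rng(config: SimulationConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, *extra])


# ---------------------------------------------------------------------------
# parcel geometry


def make_parcel_meta(config: SimulationConfig) -> pd.DataFrame:
    """Parcel table: id, hemisphere, unit-sphere centroid, network label.

    Centroids are placed on two mirrored unit hemispheres via a Fibonacci
    lattice so spherical rotation nulls have true geometry. Networks are
    mirror-symmetric, spatially coherent groups obtained by slicing the
    polar angle, and double as the planted base community partition.
    """
    config.validate()
    n = config.n_parcels
    n_left = (n + 1) // 2
    n_right = n - n_left

    golden = (1 + 5 ** 0.5) / 2
    i = np.arange(n_left)
    z = 1 - 2 * (i + 0.5) / n_left
    theta = 2 * np.pi * i / golden
    r = np.sqrt(np.clip(1 - z ** 2, 0, None))
    x = r * np.cos(theta)
    y = r * np.sin(theta)
    # push onto the left hemisphere (x < 0) by folding
    x = -np.abs(x) - 1e-3

    norms = np.sqrt(x ** 2 + y ** 2 + z ** 2)
    left = np.column_stack([x, y, z]) / norms[:, None]
    right = left[:n_right].copy()
    right[:, 0] *= -1

    coords = np.vstack([left, right])
    hemis = np.array(["L"] * n_left + ["R"] * n_right)

    # mirror-symmetric networks from the polar angle (same rule per hemisphere)
    polar = np.arccos(np.clip(coords[:, 2], -1, 1))
    edges = np.quantile(polar, np.linspace(0, 1, config.n_networks + 1))
    networks = np.clip(
        np.searchsorted(edges, polar, side="right") - 1, 0, config.n_networks - 1
    )

    return pd.DataFrame(
        {
            "parcel_id": [f"parcel_{k:04d}" for k in range(n)],
            "hemisphere": hemis,
            "x": coords[:, 0],
            "y": coords[:, 1],
            "z": coords[:, 2],
            "network": networks.astype(int),
        }
    )


def _community_plan(config: SimulationConfig, parcel_meta: pd.DataFrame) -> dict:
    """Per-task planted community labels; SST differs from MID for exactly
    round(community_shift_fraction * n_parcels) parcels."""
    base = parcel_meta["network"].to_numpy().copy()
    n_shift = int(round(config.community_shift_fraction * config.n_parcels))
    rng = _rng(config, _S_PARCELS)
    shifted_idx = rng.choice(config.n_parcels, size=n_shift, replace=False)
    shifted = base.copy()
    shifted[shifted_idx] = (shifted[shifted_idx] + 1) % config.n_networks
    return {
        "MID": base.tolist(),
        "SST": shifted.tolist(),
        "shifted_parcels": np.sort(shifted_idx).tolist(),
    }


def _spatial_pattern(config: SimulationConfig, parcel_meta: pd.DataFrame) -> np.ndarray:
    """Smooth, standardized spatial pattern shared by genes/receptors and
    the risk-modulated task architecture."""
    L = _spatial_chol(config, parcel_meta)
    z = _rng(config, _S_PATTERN).standard_normal(config.n_parcels)
    pattern = L @ z
    pattern = (pattern - pattern.mean()) / pattern.std()
    return pattern


def _spatial_chol(config: SimulationConfig, parcel_meta: pd.DataFrame) -> np.ndarray:
    coords = parcel_meta[["x", "y", "z"]].to_numpy()
    if config.spatial_rho == 0:
        return np.eye(config.n_parcels)
    d = np.sqrt(
        np.maximum(
            ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1), 0.0
        )
    )
    K = np.exp(-d / config.spatial_rho)
    return np.linalg.cholesky(K + 1e-8 * np.eye(config.n_parcels))


# ---------------------------------------------------------------------------
# genotypes and weights


def simulate_genotypes(config: SimulationConfig):
    """Additive genotype table (PLINK .raw dialect) plus a GWAS weight table.

    The weight table deliberately contains ambiguous (A/T, G/C) SNPs,
    low-MAF SNPs, GWAS-nonsignificant SNPs and one clumping duplicate so
    that every downstream filter is exercised. Truth-level per-trait PRS
    (over the SNPs planted as clean) are returned via the truth dict of
    :func:`simulate_bundle`.
    """
    config.validate()
    rng = _rng(config, _S_GENOTYPES)
    m = config.n_snps
    n = config.n_subjects

    mafs = rng.uniform(0.1, 0.5, size=m)
    chroms = rng.integers(1, 23, size=m)
    positions = rng.integers(1_000_000, 200_000_000, size=m)
    traits = np.where(np.arange(m) % 2 == 0, "MDD", "AD")
    betas = rng.normal(0.0, 0.15, size=m)
    gwas_p = 10 ** rng.uniform(-30, -9, size=m)

    pairs = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T")]
    alleles = [pairs[k] for k in rng.integers(0, len(pairs), size=m)]

    # planted special cases (indices fixed relative to m)
    special = {}
    if m >= 8:
        alleles[0] = ("A", "T")           # ambiguous
        alleles[1] = ("G", "C")           # ambiguous
        mafs[2] = 0.01                    # below the MAF filter
        gwas_p[3] = 1e-5                  # GWAS-nonsignificant
        special = {"ambiguous": [0, 1], "low_maf": [2], "nonsig": [3]}
    # APOE-region AD SNPs on chr19 44.4-46.5 Mb (drawn from SNPs that are
    # not already planted to fail a filter, so the APOE score is non-trivial)
    apoe_pool = [
        k for k in range(m) if traits[k] == "AD" and 4 <= k < m - 2
    ] or [k for k in range(m) if traits[k] == "AD"]
    apoe_idx = apoe_pool[: max(1, m // 10)]
    for k in apoe_idx:
        chroms[k] = 19
        positions[k] = int(rng.integers(44_400_000, 46_500_000))
    special["apoe"] = apoe_idx

    counts = rng.binomial(2, mafs[None, :], size=(n, m)).astype(float)

    # clumping duplicate: SNP m-1 becomes a noisy copy of SNP m-2, nearby,
    # with the worse (larger) GWAS p so greedy clumping drops it
    clump_pair = None
    if m >= 8:
        a, b = m - 2, m - 1
        flip = rng.random(n) < 0.15
        counts[:, b] = counts[:, a]
        counts[flip, b] = rng.binomial(2, mafs[a], size=flip.sum())
        chroms[b] = chroms[a]
        positions[b] = positions[a] + 100_000
        traits = traits.copy()
        traits[b] = traits[a]
        gwas_p[b] = min(gwas_p[a] * 10, 1e-8)
        clump_pair = (a, b)
        special["clump_duplicate"] = [b]

    snp_ids = [f"rs{100000 + k}" for k in range(m)]
    weights = pd.DataFrame(
        {
            "snp": snp_ids,
            "chrom": chroms,
            "pos": positions,
            "effect_allele": [a for a, _ in alleles],
            "other_allele": [b for _, b in alleles],
            "beta": betas,
            "gwas_p": gwas_p,
            "trait": traits,
        }
    )

    # counted allele in the .raw column header: mostly the effect allele,
    # a few flipped to exercise orientation resolution
    flip_orient = rng.random(m) < 0.2
    col_names = []
    geno_cols = {}
    for k in range(m):
        if flip_orient[k]:
            counted = alleles[k][1]
            geno = 2 - counts[:, k]
        else:
            counted = alleles[k][0]
            geno = counts[:, k]
        col = f"{snp_ids[k]}_{counted}"
        col_names.append(col)
        geno_cols[col] = geno

    genotypes = pd.DataFrame(
        {
            "FID": [f"F{s:05d}" for s in range(n)],
            "IID": [f"S{s:05d}" for s in range(n)],
            "PAT": 0,
            "MAT": 0,
            "SEX": rng.integers(1, 3, size=n),
            "PHENOTYPE": -9,
        }
    )
    for col in col_names:
        genotypes[col] = geno_cols[col]

    excluded = set(sum((v for v in special.values() if v is not apoe_idx), []))
    kept = [k for k in range(m) if k not in excluded]
    truth_geno = {
        "mafs": mafs.tolist(),
        "special": special,
        "clump_pair": clump_pair,
        "kept_snps": [snp_ids[k] for k in kept],
        "effect_counts": None,  # filled below
    }
    # truth PRS on effect-allele counts over clean SNPs
    prs = {}
    for trait in ("MDD", "AD"):
        idx = [k for k in kept if traits[k] == trait]
        prs[trait] = counts[:, idx] @ betas[idx]
    apoe_clean = [k for k in special["apoe"] if k in kept]
    noapoe_clean = [k for k in kept if traits[k] == "AD" and k not in special["apoe"]]
    prs["AD_apoe"] = counts[:, apoe_clean] @ betas[apoe_clean]
    prs["AD_noapoe"] = counts[:, noapoe_clean] @ betas[noapoe_clean]
    truth_geno["prs"] = {k: v.tolist() for k, v in prs.items()}

    return genotypes, weights, truth_geno


# ---------------------------------------------------------------------------
# phenotypes


def _items_from_latent(latent: np.ndarray, n_items: int, rng) -> np.ndarray:
    """Ordinal 0/1/2 items by thresholding a latent Gaussian.

    Thresholds are set so an average subject reproduces the configured
    marginal severity; totals then behave like checklist raw sums.
    """
    lam = _ITEM_LOADING
    from scipy.stats import norm

    t1 = norm.ppf(_ITEM_MARGINALS[0])
    t2 = norm.ppf(_ITEM_MARGINALS[0] + _ITEM_MARGINALS[1])
    z = lam * latent[:, None] + np.sqrt(1 - lam ** 2) * rng.standard_normal(
        (latent.size, n_items)
    )
    return (z > t1).astype(int) + (z > t2).astype(int)


def _zscore(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        return v - v.mean()
    return (v - v.mean()) / sd


def simulate_phenotypes(config: SimulationConfig, prs: Optional[dict] = None):
    """Subject table with planted multivariate structure.

    Contains item-level psychopathology scores (0/1/2) at waves 1-3,
    adversity items at two waves (neighbourhood safety coded so that
    higher = safer, exercising reverse coding downstream), three PRS
    columns and covariates. A linear combination of the adversity/PRS
    block correlates ``canonical_r`` with a combination of the
    psychopathology block by construction.

    Returns ``(table, truth)``; truth holds the planted latents, the
    subject-level brain factor and the vulnerability group.
    """
    config.validate()
    rng = _rng(config, _S_PHENOTYPES)
    n = config.n_subjects
    r = config.canonical_r

    if prs is None:
        prs = {
            "MDD": rng.standard_normal(n).tolist(),
            "AD_apoe": rng.standard_normal(n).tolist(),
            "AD_noapoe": rng.standard_normal(n).tolist(),
        }

    cols: dict = {"subject_id": [f"S{s:05d}" for s in range(n)]}

    # covariates
    cols["age_months"] = rng.normal(120, 7.4, size=n).round(1)
    cols["sex"] = rng.integers(0, 2, size=n)
    cols["handedness"] = (rng.random(n) < 0.17).astype(int)
    cols["medical_problems"] = rng.poisson(0.3, size=n) / 4.0
    cols["site"] = rng.integers(0, config.n_sites, size=n)
    cols["motion_mid"] = np.exp(rng.normal(-1.5, 0.4, size=n)).round(4)
    cols["motion_sst"] = np.exp(rng.normal(-1.5, 0.4, size=n)).round(4)

    # adversity latents, correlated across waves
    shared = rng.standard_normal((n, 3))
    scale_scores = {}
    for w in WAVES:
        lat = 0.85 * shared + np.sqrt(1 - 0.85 ** 2) * rng.standard_normal((n, 3))
        dep_items = (
            0.5 * lat[:, [0]] + np.sqrt(0.75) * rng.standard_normal((n, 7)) > 1.0
        ).astype(int)
        con_items = (
            0.5 * lat[:, [1]] + np.sqrt(0.75) * rng.standard_normal((n, 9)) > 0.8
        ).astype(int)
        safety = np.clip(
            np.round(4.2 - 0.8 * lat[:, 2] + 0.5 * rng.standard_normal(n)), 1, 5
        ).astype(int)
        for i in range(7):
            cols[f"dep_w{w}_i{i + 1}"] = dep_items[:, i]
        for i in range(9):
            cols[f"conflict_w{w}_i{i + 1}"] = con_items[:, i]
        cols[f"neigh_safety_w{w}"] = safety
        scale_scores[w] = np.column_stack(
            [dep_items.mean(1), con_items.mean(1), 6 - safety]  # crime = reversed
        )

    cols["prs_mdd"] = np.asarray(prs["MDD"])
    cols["prs_ad_apoe"] = np.asarray(prs["AD_apoe"])
    cols["prs_ad_noapoe"] = np.asarray(prs["AD_noapoe"])

    # planted risk latent per wave: an exact linear combination of observed
    # X-block quantities, so the canonical structure is recoverable
    u = {}
    for w in WAVES:
        comps = np.column_stack(
            [
                _zscore(scale_scores[w][:, 0]),
                _zscore(scale_scores[w][:, 1]),
                _zscore(scale_scores[w][:, 2]),
                _zscore(np.asarray(cols["prs_mdd"])),
                _zscore(np.asarray(cols["prs_ad_noapoe"])),
            ]
        )
        u[w] = _zscore(comps.mean(axis=1))

    # psychopathology latents and items at waves 1 and 2
    v = {}
    for w in WAVES:
        v[w] = r * u[w] + np.sqrt(1 - r ** 2) * rng.standard_normal(n)
        items = _items_from_latent(v[w], config.n_items, rng)
        for i in range(config.n_items):
            cols[f"cbcl_w{w}_i{i + 1:03d}"] = items[:, i]

    # wave-3 items: outcome latent carries the planted moderated mediation
    u_avg = _zscore(0.5 * (u[1] + u[2]))
    group = (u_avg > np.median(u_avg)).astype(int)
    a = config.effect_a
    brain_factor = a * u_avg + np.sqrt(max(0.0, 1 - a ** 2)) * rng.standard_normal(n)
    b_w = config.effect_b_low + (config.effect_b_high - config.effect_b_low) * group
    v3 = 0.5 * v[2] + b_w * brain_factor + 0.6 * rng.standard_normal(n)
    items3 = _items_from_latent(v3, config.n_items, rng)
    for i in range(config.n_items):
        cols[f"cbcl_w3_i{i + 1:03d}"] = items3[:, i]

    table = pd.DataFrame(cols)
    truth = {
        "risk_latent_w1": u[1].tolist(),
        "risk_latent_w2": u[2].tolist(),
        "risk_latent_avg": u_avg.tolist(),
        "psychopathology_latent_w1": v[1].tolist(),
        "psychopathology_latent_w2": v[2].tolist(),
        "brain_factor": brain_factor.tolist(),
        "vulnerability_group": group.tolist(),
    }
    return table, truth


# ---------------------------------------------------------------------------
# time series


# risk modulation of task reorganisation: mixing weight of the shifted
# community latent is sigmoid(_MIX_BASE + _MIX_GAIN * brain_factor * pattern)
_MIX_BASE = 1.0
_MIX_GAIN = 2.0


def _subject_time_series(
    config: SimulationConfig,
    subject: int,
    task: str,
    wave: int,
    plan: dict,
    brain_factor: Optional[np.ndarray] = None,
    pattern: Optional[np.ndarray] = None,
) -> np.ndarray:
    """One parcels x timepoints matrix.

    Parcel signal = sqrt(SNR) * community latent + unit Gaussian noise.
    Without risk modulation (``brain_factor``/``pattern`` None) each
    parcel follows its planted per-task community exactly. With it, a
    shifted parcel's SST signal blends the shifted and base community
    latents, with the shifted weight sigmoid(1 + 2 * B_s * pattern_p):
    high-risk subjects express the cross-task reorganisation more, and
    they do so along the planted spatial pattern.
    """
    rng = np.random.default_rng(
        [config.seed, _S_TIMESERIES, subject, TASKS.index(task), wave]
    )
    labels = np.asarray(plan[task])
    T = config.n_timepoints
    latents = rng.standard_normal((config.n_networks, T))
    signal = latents[labels]
    if task == "SST" and brain_factor is not None and pattern is not None:
        shifted = np.asarray(plan["shifted_parcels"], dtype=int)
        if shifted.size:
            base_labels = np.asarray(plan["MID"])[shifted]
            drive = _MIX_BASE + _MIX_GAIN * float(brain_factor[subject]) * pattern[shifted]
            alpha = 1.0 / (1.0 + np.exp(-drive))
            signal = signal.copy()
            signal[shifted] = (
                np.sqrt(alpha)[:, None] * latents[labels[shifted]]
                + np.sqrt(1 - alpha)[:, None] * latents[base_labels]
            )
    series = np.sqrt(config.snr) * signal + rng.standard_normal(
        (config.n_parcels, T)
    )
    return series


def simulate_time_series(
    config: SimulationConfig,
    parcel_meta: Optional[pd.DataFrame] = None,
    subjects=None,
    brain_factor: Optional[np.ndarray] = None,
    pattern: Optional[np.ndarray] = None,
) -> Dict[Tuple[int, str, int], np.ndarray]:
    """Per-(subject, task, wave) parcel-by-time matrices.

    The community plan is shared across waves; the SST plan differs from
    MID for exactly round(community_shift_fraction * n_parcels) parcels.
    """
    config.validate()
    if parcel_meta is None:
        parcel_meta = make_parcel_meta(config)
    plan = _community_plan(config, parcel_meta)
    if subjects is None:
        subjects = range(config.n_subjects)
    out = {}
    for s in subjects:
        for task in TASKS:
            for wave in WAVES:
                out[(s, task, wave)] = _subject_time_series(
                    config, s, task, wave, plan, brain_factor, pattern
                )
    return out


# ---------------------------------------------------------------------------
# gene expression and receptors


def simulate_gene_matrix(config: SimulationConfig, parcel_meta: pd.DataFrame):
    """Spatially autocorrelated parcel x gene matrix plus stress-gene sets.

    Columns share an exponential spatial covariance over centroid
    distances. Designated "high" genes load positively, and "low" genes
    negatively, on the planted spatial pattern (default set sizes 45 and
    27). Returns ``(gene_df, stress_low, stress_high, truth)``.
    """
    config.validate()
    rng = _rng(config, _S_GENES)
    P, G = config.n_parcels, config.n_genes
    L = _spatial_chol(config, parcel_meta)
    pattern = _spatial_pattern(config, parcel_meta)

    base = L @ rng.standard_normal((P, G))
    base = (base - base.mean(0)) / base.std(0)

    symbols = np.array([f"GENE{k:05d}" for k in range(G)])
    idx = rng.choice(G, size=config.n_stress_low + config.n_stress_high, replace=False)
    low_idx = np.sort(idx[: config.n_stress_low])
    high_idx = np.sort(idx[config.n_stress_low:])

    lam = config.gene_loading
    mix = np.sqrt(max(0.0, 1 - lam ** 2))
    base[:, high_idx] = mix * base[:, high_idx] + lam * pattern[:, None]
    base[:, low_idx] = mix * base[:, low_idx] - lam * pattern[:, None]

    gene_df = pd.DataFrame(base, index=parcel_meta["parcel_id"], columns=symbols)
    truth = {
        "spatial_pattern": pattern.tolist(),
        "stress_low_idx": low_idx.tolist(),
        "stress_high_idx": high_idx.tolist(),
    }
    return gene_df, symbols[low_idx].tolist(), symbols[high_idx].tolist(), truth


def simulate_receptor_maps(
    config: SimulationConfig, parcel_meta: pd.DataFrame, pattern: np.ndarray
) -> pd.DataFrame:
    """Parcel x receptor density table, each map partially loaded on the
    planted spatial pattern with spatially smooth residual noise."""
    rng = _rng(config, _S_RECEPTORS)
    L = _spatial_chol(config, parcel_meta)
    lam = config.receptor_loading
    cols = {}
    for name in RECEPTOR_NAMES:
        noise = L @ rng.standard_normal(config.n_parcels)
        noise = (noise - noise.mean()) / noise.std()
        m = lam * pattern + np.sqrt(max(0.0, 1 - lam ** 2)) * noise
        cols[name] = m
    return pd.DataFrame(cols, index=parcel_meta["parcel_id"])


# ---------------------------------------------------------------------------
# mediation fixture and bundle assembly


def simulate_mediation_data(
    n: int,
    a: float,
    b_low: float,
    b_high: float,
    seed: int,
    direct: float = 0.2,
    n_covariates: int = 0,
) -> pd.DataFrame:
    """Standalone moderated-mediation dataset with known paths.

    ``x`` is the risk predictor, ``w`` its median split, ``m`` the
    mediator (x -> m path ``a``) and ``y`` the outcome whose m -> y slope
    is ``b_low`` for w = 0 and ``b_high`` for w = 1, so the index of
    moderated mediation is a * (b_high - b_low).
    """
    rng = np.random.default_rng(seed)
    x = rng.standard_normal(n)
    w = (x > np.median(x)).astype(int)
    m = a * x + np.sqrt(max(0.0, 1 - a ** 2)) * rng.standard_normal(n)
    y = (b_low + (b_high - b_low) * w) * m + direct * x + rng.standard_normal(n)
    data = pd.DataFrame({"x": x, "w": w, "m": m, "y": y})
    for k in range(n_covariates):
        data[f"c{k + 1}"] = rng.standard_normal(n)
    return data


def simulate_bundle(config: SimulationConfig, materialize_time_series: bool = False) -> SyntheticBundle:
    """Generate the full synthetic study.

    Order matters: genotypes feed the PRS columns of the phenotype table,
    whose planted risk latent drives the subject-level brain factor that
    modulates the SST time series along the spatial pattern shared with
    gene expression and receptor maps.
    """
    config.validate()
    parcel_meta = make_parcel_meta(config)
    genotypes, weights, truth_geno = simulate_genotypes(config)
    phenotypes, truth_pheno = simulate_phenotypes(config, prs=truth_geno["prs"])
    gene_df, stress_low, stress_high, truth_genes = simulate_gene_matrix(
        config, parcel_meta
    )
    pattern = np.asarray(truth_genes["spatial_pattern"])
    receptor_maps = simulate_receptor_maps(config, parcel_meta, pattern)
    plan = _community_plan(config, parcel_meta)

    truth = {
        "config": asdict(config),
        "community_plan": plan,
        **truth_genes,
        **truth_pheno,
        "genotypes": truth_geno,
    }

    bundle = SyntheticBundle(
        config=config,
        parcel_meta=parcel_meta,
        phenotypes=phenotypes,
        genotypes=genotypes,
        weights=weights,
        gene_matrix=gene_df,
        stress_low=stress_low,
        stress_high=stress_high,
        receptor_maps=receptor_maps,
        truth=truth,
    )
    if materialize_time_series:
        bundle.time_series = simulate_time_series(
            config,
            parcel_meta,
            brain_factor=np.asarray(truth["brain_factor"]),
            pattern=pattern,
        )
    return bundle
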