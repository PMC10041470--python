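"""End-to-end orchestration of the risk-to-psychopathology cascade.

Stage order (each consuming the previous stage's outputs): polygenic
scoring -> phenotype CCAs (per wave) -> connectomes -> multilayer
communities -> behavioural PLS -> gene PLS + stress overlap -> receptor
CCA -> moderated mediation. A manifest records seeds, configuration,
and per-stage summary statistics; rerunning with the same configuration
reproduces the manifest exactly. A stage failure halts its dependents
while independent branches continue.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .synthetic import SimulationConfig, SyntheticBundle, simulate_bundle
from .genetics import filter_snps, compute_prs, split_apoe_region
from .phenotypes import (
    adversity_scores,
    checklist_total,
    syndrome_scores,
    covariate_matrix,
)
from .connectome import correlation_matrix, zero_negative
from .communities import (
    MultilayerNetwork,
    run_ensemble,
    flexibility,
    recruitment,
    LAYER_NAMES,
)
from .cca import (
    cross_validate_cca,
    permutation_test_refit,
    residualize_covariates,
)
from .pls import behavioural_pls, gene_pls, null_gene_lvs, _zscore_cols
from .spatial import generate_spins
from .transcriptomics import StressGeneSets, overlap_test
from .receptors import build_receptor_block, receptor_cca
from .mediation import median_split, prepare_outcome, fit_moderated_mediation

logger = logging.getLogger(__name__)


def _package_version() -> str:
    from . import __version__

    return __version__


SST_SEG_CONDITIONS = ("segregation_SST_w1", "segregation_SST_w2")


@dataclass
class PipelineConfig:
    """Desk-scale defaults; ``full=True`` restores the publication-scale
    resampling counts (1e5 permutations/bootstraps, 5e4 mediation
    bootstraps, 100 community restarts)."""

    simulation: SimulationConfig = field(
        default_factory=lambda: SimulationConfig(
            n_subjects=300, n_parcels=100, n_genes=2000
        )
    )
    k_folds: int = 10
    n_perm: int = 999
    n_boot: int = 500
    n_spins: int = 199
    community_iterations: int = 5
    gamma: float = 1.0
    omega: float = 0.5
    mediation_boots: int = 1000
    seed: int = 0
    out_dir: Optional[str] = None
    full: bool = False

    def __post_init__(self):
        if self.full:
            self.n_perm = 100_000
            self.n_boot = 100_000
            self.n_spins = 100_000
            self.mediation_boots = 50_000
            self.community_iterations = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        return cls(simulation=sim, **raw)


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(
        {**asdict(config), "simulation": asdict(config.simulation)},
        sort_keys=True,
        default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _prs_stage(bundle: SyntheticBundle, summary: dict) -> pd.DataFrame:
    weights, log = filter_snps(bundle.weights, bundle.genotypes)
    mdd = weights[weights["trait"] == "MDD"]
    ad = weights[weights["trait"] == "AD"]
    apoe, noapoe = split_apoe_region(ad)
    out = pd.DataFrame(index=bundle.genotypes["IID"])
    counts = {}
    for name, tab in (("mdd", mdd), ("ad_apoe", apoe), ("ad_noapoe", noapoe)):
        res = compute_prs(bundle.genotypes, tab)
        out[f"prs_{name}"] = res.scores
        counts[name] = res.n_snps_used
    summary["prs"] = {"filter_log": log, "n_snps": counts}
    return out.reset_index().rename(columns={"IID": "subject_id"})


def _phenotype_cca_stage(
    bundle: SyntheticBundle,
    prs: pd.DataFrame,
    config: PipelineConfig,
    summary: dict,
):
    # the CCA consumes the stage-computed scores, not the table's planted ones
    ph = bundle.phenotypes.drop(
        columns=["prs_mdd", "prs_ad_apoe", "prs_ad_noapoe"], errors="ignore"
    ).merge(prs, on="subject_id", how="left")
    cov = covariate_matrix(ph)
    variates = {}
    for wave in (1, 2):
        X = pd.concat(
            [
                adversity_scores(ph, wave),
                ph[["prs_mdd", "prs_ad_apoe", "prs_ad_noapoe"]],
            ],
            axis=1,
        ).to_numpy(dtype=float)
        Y = syndrome_scores(
            ph, f"cbcl_w{wave}_", bundle.config.n_syndromes
        ).to_numpy(dtype=float)
        res = cross_validate_cca(
            X,
            Y,
            k_folds=config.k_folds,
            seed=config.seed + wave,
            covariates=cov,
            stratify=ph["site"].to_numpy(),
        )
        res.perm_p = permutation_test_refit(
            X,
            Y,
            res,
            n_perm=config.n_perm,
            seed=config.seed + wave,
            covariates=cov,
        )
        variates[wave] = res
        summary[f"phenotype_cca_w{wave}"] = {
            "cross_fold_r": round(res.cross_fold_r, 6),
            "perm_p": res.perm_p,
        }
    return variates


def _network_stage(bundle: SyntheticBundle, config: PipelineConfig, summary: dict):
    """Per-subject multilayer communities -> six condition matrices."""
    n = bundle.config.n_subjects
    P = bundle.config.n_parcels
    native = bundle.parcel_meta["network"].to_numpy()
    parcel_ids = bundle.parcel_meta["parcel_id"].tolist()
    conditions = {
        "reorg_w1": np.empty((n, P)),
        "reorg_w2": np.empty((n, P)),
        "segregation_MID_w1": np.empty((n, P)),
        "segregation_MID_w2": np.empty((n, P)),
        "segregation_SST_w1": np.empty((n, P)),
        "segregation_SST_w2": np.empty((n, P)),
    }
    q_means = np.empty(n)
    layer_order = [("MID", 1), ("SST", 1), ("MID", 2), ("SST", 2)]
    for s in range(n):
        layers = []
        for task, wave in layer_order:
            series = bundle.get_time_series(s, task, wave)
            cm = zero_negative(
                correlation_matrix(series, task=task, wave=wave, parcel_ids=parcel_ids)
            )
            layers.append(cm)
        net = MultilayerNetwork(layers=layers, omega=config.omega, gamma=config.gamma)
        ens = run_ensemble(
            net,
            n_iterations=config.community_iterations,
            base_seed=config.seed * 100_003 + s * 1009,
        )
        q_means[s] = ens.q_values.mean()
        flex = flexibility(ens, {1: (0, 1), 2: (2, 3)})
        conditions["reorg_w1"][s] = flex[1]
        conditions["reorg_w2"][s] = flex[2]
        recr = recruitment(ens, native)
        conditions["segregation_MID_w1"][s] = recr[0]
        conditions["segregation_SST_w1"][s] = recr[1]
        conditions["segregation_MID_w2"][s] = recr[2]
        conditions["segregation_SST_w2"][s] = recr[3]
    summary["communities"] = {
        "mean_q": round(float(q_means.mean()), 6),
        "sd_q": round(float(q_means.std()), 6),
    }
    return conditions


def _brain_pls_stage(
    bundle: SyntheticBundle,
    conditions: Dict[str, np.ndarray],
    behaviour: np.ndarray,
    config: PipelineConfig,
    summary: dict,
):
    cov = covariate_matrix(bundle.phenotypes)
    res_conditions = {
        k: residualize_covariates(v, cov) for k, v in conditions.items()
    }
    res_behaviour = residualize_covariates(behaviour, cov)
    pls = behavioural_pls(
        res_conditions,
        res_behaviour,
        k_folds=config.k_folds,
        seed=config.seed + 11,
        n_perm=config.n_perm,
        n_boot=config.n_boot,
    )
    # subject-level mediator: predicted brain score restricted to the
    # inhibition-task segregation conditions
    names = list(res_conditions)
    v1 = pls.element_saliences[:, 0]
    mediator = np.zeros(len(behaviour))
    for ci, name in enumerate(names):
        if name in SST_SEG_CONDITIONS:
            Xz, _, _ = _zscore_cols(res_conditions[name])
            mediator += pls.condition_saliences[ci, 0] * (Xz @ v1)
    summary["brain_pls"] = {
        "variance_explained_pct": round(100 * pls.variance_explained, 3),
        "cross_fold_r": round(float(pls.cross_fold_r), 6),
        "perm_p": pls.perm_p,
        "n_robust_elements": int(pls.element_corr["robust"].sum()),
    }
    return pls, v1, mediator


def run_pipeline(
    config: PipelineConfig, bundle: Optional[SyntheticBundle] = None
) -> dict:
    """Execute the cascade and return the manifest.

    The manifest contains the package version, the configuration hash,
    every seed, and one summary block per stage. When ``config.out_dir``
    is set the manifest is also written there as JSON.
    """
    if bundle is None:
        bundle = simulate_bundle(config.simulation)
    manifest: dict = {
        "package_version": _package_version(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
        "errors": {},
    }
    summary = manifest["stages"]
    state: dict = {}

    def stage(name, fn, *deps):
        missing = [d for d in deps if d not in state]
        if missing:
            manifest["errors"][name] = f"skipped: missing upstream {missing}"
            return
        try:
            state[name] = fn()
        except Exception as exc:  # stage failure halts dependents only
            logger.exception("stage %s failed", name)
            manifest["errors"][name] = f"{type(exc).__name__}: {exc}"

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")

        stage("prs", lambda: _prs_stage(bundle, summary))
        stage(
            "phenotype_cca",
            lambda: _phenotype_cca_stage(bundle, state["prs"], config, summary),
            "prs",
        )
        stage("communities", lambda: _network_stage(bundle, config, summary))

        def brain_pls():
            behaviour = state["phenotype_cca"][2].x_variate
            return _brain_pls_stage(
                bundle, state["communities"], behaviour, config, summary
            )

        stage("brain_pls", brain_pls, "phenotype_cca", "communities")

        def spins():
            return generate_spins(
                bundle.parcel_meta, config.n_spins, seed=config.seed + 23
            )

        stage("spins", spins)

        def gene():
            _, brain_lv, _ = state["brain_pls"]
            X = bundle.gene_matrix.to_numpy(dtype=float)
            res = gene_pls(
                X,
                brain_lv,
                spins=state["spins"],
                k_folds=config.k_folds,
                seed=config.seed + 31,
                n_boot=config.n_boot,
            )
            summary["gene_pls"] = {
                "brain_gene_r": round(float(res.cross_fold_r), 6),
                "perm_p": res.perm_p,
                "n_robust_genes": int(res.element_corr["robust"].sum()),
            }
            return res

        stage("gene_pls", gene, "brain_pls", "spins")

        def overlap():
            _, brain_lv, _ = state["brain_pls"]
            res = state["gene_pls"]
            X = bundle.gene_matrix.to_numpy(dtype=float)
            nulls = null_gene_lvs(
                X, brain_lv, state["spins"], reference_scores=res.predicted_lv_scores
            )
            out = overlap_test(
                gene_corr=res.element_corr["estimate"],
                robust_mask=res.element_corr["robust"],
                gene_symbols=bundle.gene_matrix.columns,
                sets=StressGeneSets(bundle.stress_low, bundle.stress_high),
                null_gene_lvs=nulls,
                gene_matrix=X,
                brain_gene_r=res.cross_fold_r,
            )
            summary["overlap"] = {
                "orig_pos": out.orig_pos,
                "orig_neg": out.orig_neg,
                "stress_high_pos": out.stress_high_pos,
                "stress_low_neg": out.stress_low_neg,
                "p_susceptibility": out.p_susceptibility,
                "p_inverse": out.p_inverse,
            }
            return out

        stage("overlap", overlap, "gene_pls", "brain_pls", "spins")

        def receptor():
            _, brain_lv, _ = state["brain_pls"]
            block = build_receptor_block(bundle.receptor_maps)
            res = receptor_cca(
                brain_lv,
                block,
                spins=state["spins"],
                k_folds=config.k_folds,
                seed=config.seed + 41,
            )
            summary["receptor_cca"] = {
                "cross_fold_r": round(float(res.cross_fold_r), 6),
                "perm_p": res.perm_p,
            }
            return res

        stage("receptor", receptor, "brain_pls", "spins")

        def mediation():
            variates = state["phenotype_cca"]
            _, _, mediator = state["brain_pls"]
            u1 = variates[1].x_variate
            u2 = variates[2].x_variate
            z = lambda v: (v - v.mean()) / v.std()
            predictor = z((z(u1) + z(u2)) / 2)
            w = median_split(predictor)
            ph = bundle.phenotypes
            y = prepare_outcome(
                checklist_total(ph, "cbcl_w3_"), checklist_total(ph, "cbcl_w2_")
            )
            cov_names = [
                "age_months",
                "sex",
                "handedness",
                "medical_problems",
                "motion_mid",
                "motion_sst",
            ]
            data = pd.DataFrame(
                {"x": predictor, "m": z(mediator), "w": w, "y": y}
            )
            for c in cov_names:
                data[c] = ph[c].to_numpy(dtype=float)
            res = fit_moderated_mediation(
                data,
                covariates=cov_names,
                n_boot=config.mediation_boots,
                seed=config.seed + 53,
            )
            summary["mediation"] = {
                "index_modmed": round(res.index_modmed["estimate"], 6),
                "index_ci": [
                    round(res.index_modmed["lo"], 6),
                    round(res.index_modmed["hi"], 6),
                ],
                "interaction_b": round(res.b_interaction, 6),
                "interaction_t": round(res.interaction_t, 4),
                "interaction_df": res.interaction_df,
                "interaction_p": round(res.interaction_p, 6),
                "a_path": round(res.a_path, 6),
            }
            return res

        stage("mediation", mediation, "phenotype_cca", "brain_pls")

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return manifest


def collect_p_values(manifest: dict) -> Dict[str, float]:
    """Every stage-level p-value in one flat mapping."""
    s = manifest["stages"]
    out = {}
    for key, fields in (
        ("phenotype_cca_w1", ["perm_p"]),
        ("phenotype_cca_w2", ["perm_p"]),
        ("brain_pls", ["perm_p"]),
        ("gene_pls", ["perm_p"]),
        ("overlap", ["p_susceptibility", "p_inverse"]),
        ("receptor_cca", ["perm_p"]),
        ("mediation", ["interaction_p"]),
    ):
        if key in s:
            for f in fields:
                if s[key].get(f) is not None:
                    out[f"{key}.{f}"] = s[key][f]
    return out
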