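"""Plain-text readers and writers for every pipeline artefact.

Formats: time series as ``sub-<id>_task-<MID|SST>_wave-<1|2>.tsv``
(parcels x timepoints; header row of timepoint indices, first column the
parcel id), phenotypes CSV, genotypes in the PLINK .raw dialect, weight
table TSV, parcel metadata TSV, gene matrix TSV, receptor TSV, stress
lists TXT, truth record and result JSONs.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Tuple

import numpy as np
import pandas as pd

from .connectome import ConnectivityMatrix
from .synthetic import SimulationConfig, SyntheticBundle


def write_time_series(path: Path, series: np.ndarray, parcel_ids) -> None:
    df = pd.DataFrame(series, index=pd.Index(parcel_ids, name="parcel_id"))
    df.columns = [str(t) for t in range(series.shape[1])]
    df.to_csv(path, sep="\t")


def read_time_series(path: Path) -> Tuple[np.ndarray, list]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(dtype=float), df.index.tolist()


def time_series_filename(subject: str, task: str, wave: int) -> str:
    return f"sub-{subject}_task-{task}_wave-{wave}.tsv"


def write_connectivity(path: Path, matrix: ConnectivityMatrix) -> None:
    ids = matrix.parcel_ids or [str(i) for i in range(matrix.values.shape[0])]
    df = pd.DataFrame(matrix.values, index=ids, columns=ids)
    df.to_csv(path, sep="\t")


def read_connectivity(path: Path, task: str = "", wave: int = 0) -> ConnectivityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ConnectivityMatrix(
        values=df.to_numpy(dtype=float), task=task, wave=wave,
        parcel_ids=df.index.tolist(),
    )


def write_bundle(bundle: SyntheticBundle, out_dir, time_series: bool = False) -> Path:
    """Write every bundle artefact under ``out_dir`` as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.parcel_meta.to_csv(out / "parcel_meta.tsv", sep="\t", index=False)
    bundle.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    bundle.genotypes.to_csv(out / "genotypes.raw", sep=" ", index=False)
    bundle.weights.to_csv(out / "gwas_weights.tsv", sep="\t", index=False)
    bundle.gene_matrix.to_csv(out / "gene_matrix.tsv", sep="\t")
    bundle.receptor_maps.to_csv(out / "receptor_maps.tsv", sep="\t")
    (out / "stress_low.txt").write_text("\n".join(bundle.stress_low) + "\n")
    (out / "stress_high.txt").write_text("\n".join(bundle.stress_high) + "\n")
    with open(out / "truth.json", "w") as fh:
        json.dump(bundle.truth, fh, indent=1)
    if time_series:
        ts_dir = out / "timeseries"
        ts_dir.mkdir(exist_ok=True)
        ids = bundle.parcel_meta["parcel_id"]
        for s in range(bundle.config.n_subjects):
            for task in ("MID", "SST"):
                for wave in (1, 2):
                    series = bundle.get_time_series(s, task, wave)
                    write_time_series(
                        ts_dir / time_series_filename(f"{s:05d}", task, wave),
                        series,
                        ids,
                    )
    return out


def read_bundle(in_dir) -> SyntheticBundle:
    """Reload a written bundle (time series stay on disk, loaded lazily
    through the truth record's generative plan)."""
    p = Path(in_dir)
    with open(p / "truth.json") as fh:
        truth = json.load(fh)
    config = SimulationConfig(**truth["config"])
    return SyntheticBundle(
        config=config,
        parcel_meta=pd.read_csv(p / "parcel_meta.tsv", sep="\t"),
        phenotypes=pd.read_csv(p / "phenotypes.csv"),
        genotypes=pd.read_csv(p / "genotypes.raw", sep=r"\s+"),
        weights=pd.read_csv(p / "gwas_weights.tsv", sep="\t"),
        gene_matrix=pd.read_csv(p / "gene_matrix.tsv", sep="\t", index_col=0),
        stress_low=(p / "stress_low.txt").read_text().split(),
        stress_high=(p / "stress_high.txt").read_text().split(),
        receptor_maps=pd.read_csv(p / "receptor_maps.tsv", sep="\t", index_col=0),
        truth=truth,
    )
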