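"""Generate a synthetic longitudinal imaging-genetics study.

The bundle contains everything the analysis cascade consumes — parcel
geometry, task fMRI time series, a phenotype table, genotypes with a
GWAS weight table, gene expression, receptor maps — with every planted
effect recorded in the truth dictionary.
"""

import numpy as np

from neurocascade import SimulationConfig, simulate_bundle

config = SimulationConfig(
    n_subjects=80, n_parcels=60, n_timepoints=150, n_genes=500,
    n_items=48, n_snps=30, canonical_r=0.5, seed=1,
)
bundle = simulate_bundle(config)

print(f"phenotype table: {bundle.phenotypes.shape[0]} subjects x "
      f"{bundle.phenotypes.shape[1]} columns")
print(f"gene matrix:     {bundle.gene_matrix.shape[0]} parcels x "
      f"{bundle.gene_matrix.shape[1]} genes")
print(f"stress sets:     {len(bundle.stress_low)} low / {len(bundle.stress_high)} high")
series = bundle.get_time_series(0, "SST", 1)
print(f"one time series: {series.shape[0]} parcels x {series.shape[1]} timepoints")

plan = bundle.truth["community_plan"]
n_shift = len(plan["shifted_parcels"])
print(f"planted plan:    {n_shift} of {config.n_parcels} parcels change "
      "community between MID and SST")
# The planted canonical correlation links the adversity/PRS block to the
# psychopathology items; the risk latent is stored for ground-truth checks.
u = np.asarray(bundle.truth["risk_latent_w1"])
print(f"risk latent:     mean {u.mean():+.3f}, sd {u.std():.3f} "
      f"(planted canonical r = {config.canonical_r})")
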