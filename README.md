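# neurocascade

Analysis pipeline for a longitudinal network-neuroscience question: do
early-life adversity and polygenic risk for depression and Alzheimer's
disease relate to how adolescent task-fMRI networks mature, and does
that brain profile — together with its transcriptomic and receptor
correlates — carry risk forward into later psychopathology?

The package implements the full analytic cascade as a reusable,
separately testable library, and ships a synthetic-data generator that
emulates every input (parcellated task time series, phenotypes,
genotypes and GWAS weights, regional gene expression, receptor density
maps) with *planted*, recoverable effects. Real cohort, donor-brain
microarray and PET-atlas data are access-restricted; the generator makes
the entire method exercisable, end to end, with known ground truth.

Intended users: imaging-genetics and network-neuroscience researchers
who need the individual stages (multilayer community metrics,
cross-validated multivariate models, spatially constrained nulls,
enrichment and mediation inference) or the whole cascade.

## The models

**Multilayer communities.** Per subject, the four task x wave Fisher-z
connectivity matrices (negative weights zeroed) form one multilayer
network whose partition maximises

```
Q = (1/2mu) * sum_{ijlr} [ (w_ijl - gamma_l * e_ijl) d_lr + d_ij * omega_jlr ] d(g_il, g_jr)
```

with `e_ijl = s_il s_jl / v_l` the within-layer chance expectation and
`omega` the interlayer coupling (default 0.5 on the task-within-wave and
wave-within-task pairs; `gamma = 1`). A generalised Louvain optimiser is
restarted many times; **flexibility** (fraction of restarts in which a
parcel changes community between tasks) and **recruitment** (fraction of
a parcel's native-system peers sharing its community) summarise
reorganisation and segregation.

**Cross-validated CCA / PLS.** Canonical weights (or PLS saliences from
the SVD of the condition-wise behaviour-brain correlation matrix) are
estimated on training folds and used to predict variate scores in the
held-out fold; the pooled out-of-sample correlation is the effect
estimate. Significance comes from permutation tests that re-run the full
fold-wise fit per permutation — for parcel-level maps the permutations
are *spin* nulls: random sphere rotations (mirrored across hemispheres)
followed by greedy one-to-one reassignment, which preserve spatial
autocorrelation. Variable-level reliability uses percentile bootstrap
CIs (99.9% for element-level robustness, 95% at the variate level).

**Transcriptomics.** Expression is normalised with a robust sigmoid,
`x_norm = 1/(1+exp(-(x - <x>)/IQR_x))`, rescaled to [0, 1], per sample
then per gene, and aggregated within donor then across donors. The
stress-gene overlap test asks whether genes robustly associated with the
brain-derived gene LV are enriched for externally defined stress_high /
stress_low genes, against Procrustes-aligned spin-null gene LVs.

**Moderated mediation.** With risk X, brain score M, median-split
vulnerability W and symptom change Y (sqrt-transformed follow-up
residualised on baseline): `M ~ X`, `Y ~ X + M + W + M*W` (OLS, HC3
standard errors). The conditional indirect effect at level w is
`a(b + b3 w)` and the index of moderated mediation is `a*b3`, with
percentile-bootstrap CIs.

## Worked example

`examples/05_moderated_mediation.py` simulates a risk predictor, a
mediating brain score and a moderated outcome, then fits the model:

```
a path (risk -> brain):          +0.458  (planted 0.5)
m x w interaction b3:            +0.383  (planted 0.4), t(1495) = 6.81, p = 0.0000
indirect effect | low risk :      +0.012 [-0.026, +0.052]
indirect effect | high risk:      +0.187 [+0.150, +0.226]
index of moderated mediation:    +0.175 [+0.121, +0.229]  (planted 0.2)
```

Only the high-vulnerability group shows an indirect path from risk
through the brain score to symptom change, and the index CI excluding
zero says the two groups genuinely differ — exactly the planted
structure. The other examples cover the generator
(`01_simulate_study.py`), multilayer communities
(`02_multilayer_communities.py`, which prints flexibility ~0.76 for
parcels planted to switch communities versus ~0.04 for stable ones),
the risk-psychopathology CCA (`03_...`), gene/receptor correlates
(`04_...`) and the one-call pipeline (`06_full_pipeline.py`). A thin
CLI covers the two shell-level entry points:

```bash
neurocascade simulate --out study/ --seed 1     # write a synthetic study
neurocascade run --out results/ --seed 1        # run the cascade
```

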