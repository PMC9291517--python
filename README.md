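# rvshape

Particle-based statistical shape analysis of the right ventricle (RV) in
tricuspid regurgitation (TR), for researchers studying how RV geometry
remodels under valve disease. The package implements the full analysis
chain — binary segmentation masks → signed distance transforms →
corresponding surface landmarks → PCA shape space → TR classification →
per-point significance maps and shape scores — together with a synthetic
RV-like cohort generator with known ground truth, so every stage runs
and is tested without patient data.

## The analysis

Each subject's RV blood pool enters as a binary mask, is isotropically
resampled, rigidly aligned (common grid, coincident centroids) and
converted to a signed Euclidean distance transform. M = 512 ordered
particles are optimized across the cohort by gradient descent on

    α · log det( Cov(z₁,…,z_K) + εI )  +  (1−α) · Σₖ Σᵢ≠ⱼ exp(−‖xᵢ−xⱼ‖²/2σ²)

where z_k is subject k's flattened 3M-vector of particle coordinates:
the first term makes index j land on the anatomically analogous spot on
every subject, the second spreads particles uniformly over each surface.
PCA of the K×3M matrix yields loading vectors sᵢ; a lasso-stability
feature selection (dominance probability = fraction of resampled lasso
fits giving a mode non-zero weight) picks the top four modes for a
cross-validated logistic regression of TR vs control, with
Borderline-SMOTE balancing of the minority groups on the training side.
Group shape differences are localized per correspondence point with the
two-sample Hotelling T² statistic (F-transform p-values,
Benjamini–Hochberg FDR at 0.05), and summarized by the linear
discrimination of variation: projecting each shape onto the group-mean
difference vector d = μ_B − μ_A gives a scalar shape score, affinely
normalized so the group means map to −1 (TR-bearing group) and +1.

See `docs/methods.md` for the model details, parameter defaults, and
what the synthetic generator does and does not emulate.

## Worked example

```python
from rvshape import (CohortSpec, PipelineConfig, run_pipeline)

config = PipelineConfig()          # 54 subjects: 6 healthy / 27 control / 21 TR
config.cohort = CohortSpec(seed=3)
config.lasso_repeats = 30          # default 1000; reduced for a quick demo
config.seed = 3
manifest = run_pipeline(config, "results/demo")
```

which logs, stage by stage:

```
INFO rvshape: generate: 54 subjects (seed 3)
INFO rvshape: correspond: ground-truth bypass, M=512
INFO rvshape: shape_space: 21 modes for 99% variance
INFO rvshape: classify: acc=1.000 prec=1.000 rec=1.000 f1=1.000
INFO rvshape: group_statistics: control vs tr, 512/512 significant points
INFO rvshape: group_statistics: healthy vs control, 0/512 significant points
INFO rvshape: group_statistics: healthy vs tr, 507/512 significant points
INFO rvshape: group_statistics: LDV chf, overlap=0.00
INFO rvshape: group_statistics: LDV phtn, overlap=0.00
```

Reading the output: the synthetic cohort's default TR deformation (a
5 mm free-wall bulge plus apex blunting and base widening over 1 mm
shape noise) is strong relative to the noise, so 21 PCA modes cover 99%
of the variance and the held-out 11-subject test set is classified
perfectly. Essentially every correspondence point separates TR from
control after FDR correction — the deformation bumps have smooth global
tails — whereas the healthy-vs-control contrast, with only six healthy
subjects, leaves 27 points with raw p < 0.05 and none surviving the
correction: per-point power, not effect direction, is the limit at that
group size. The subgroup LDV overlaps of 0.00 reflect the generator's
strong-effect regime (fully separated score ranges).
`results/demo/` then contains the cohort manifest, per-subject
`.particles` files, `loadings.csv`, `report.json` (confusion matrix,
accuracy/precision/recall/F1, ROC, selected modes, dominance table),
per-contrast significance maps (`sigmap_*.csv`) and per-subgroup LDV
score tables (`ldv_chf.csv`, `ldv_phtn.csv`).

The same pipeline is scriptable from the shell:

```
rvshape run --config config.yaml --out results/
rvshape preprocess --spacing 1.5 manifest.csv outdir/
rvshape correspond --particles 512 --seed 17 dts/ particles/
rvshape classify --repeats 1000 --top-modes 4 loadings.csv report.json
```

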