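# elastoage

Brain-age estimation from magnetic resonance elastography (MRE) maps, with a
self-supervised contrastive-regression model, occlusion saliency, and
Theil-Sen-corrected brain-age gaps for disease cohorts.

## The problem

MRE reconstructs the complex shear modulus G\* = G′ + iG″ of brain tissue
from induced shear waves. Two scalar maps summarise it per voxel:

- stiffness μ = 2|G\*|² / (G′ + |G\*|)  (kPa), with |G\*| = √(G′² + G″²)
- damping ratio ξ = G″ / (2G′)  (dimensionless)

Whole-brain stiffness declines with age (≈ −0.33 %/yr) while damping ratio
rises (≈ +0.34 %/yr), which makes these maps candidates for brain-age
prediction: train a model to predict chronological age from the maps of
healthy subjects, then read the bias-corrected *brain-age gap*
(BAG = corrected predicted age − chronological age) of a patient as a
marker of accelerated aging. This package implements that pipeline for
scientists who want to study it end to end — including on machines without
access to clinical MRE data, via a synthetic phantom generator that
reproduces the statistical structure the analysis relies on.

## What is inside

- `elastoage.synthetic` — phantom atlas (10 subcortical structures + grey
  and white matter) and cohort generator: configurable aging rates, regional
  baselines, young-skewed age mixture, and localized disease effects
  (damping elevation in hippocampus/brain stem for MCI, stiffness loss in
  thalamus/pallidum for AD). Maps are emitted as (G′, G″) pairs so the
  property computation is always exercised.
- `elastoage.mech` — μ/ξ computation, its algebraic inverse, coverage
  masking, dataset- and image-level z-scoring.
- `elastoage.contrastive` — contrastive regression: a Gaussian age kernel
  w_ik = exp(−(y_i−y_k)²/2σ²) grades pairwise attraction; three losses
  (kernel-weighted InfoNCE, exponential repulsion scaling, and the
  adaptive-neighbourhood loss whose per-anchor comparison pool shrinks over
  training), all differentiable through the package's own minimal
  reverse-mode autodiff core (`elastoage._tensor`, `elastoage.nn`).
- `elastoage.models` — three families behind one train/predict contract:
  PCA + Gaussian-process regression (linear kernel, marginal-likelihood
  optimisation), a supervised 3D residual CNN (L1 loss), and the
  self-supervised contrastive encoder with a ridge readout on frozen
  embeddings.
- `elastoage.evaluation` — 80:20 healthy-only splits, mean/median absolute
  error, multi-seed protocol tables.
- `elastoage.saliency` — occlusion sensitivity: 7³ blocks zeroed on a 13³
  origin grid (2 197 origins at the 91×109×91 geometry), ΔMAE per block,
  percentile clipping, cubic upsampling and min-max scaling per age bin.
- `elastoage.cohort` — Theil-Sen bias correction, leave-cohort-out
  retraining, per-region BAG profiles, at-risk flagging by profile
  correlation, and a Shapiro-Wilk-gated statistics dispatch.
- `elastoage.pipeline` / `elastoage` CLI — config-driven end-to-end runs
  with a provenance manifest.

## Worked example

```python
import numpy as np
from elastoage.synthetic import CohortSpec, build_atlas
from elastoage.evaluation import build_phantom_dataset, run_protocol, summarize_protocol

atlas = build_atlas((24, 24, 24), voxel_size_mm=2.0, seed=0)
spec = CohortSpec(n_healthy=60, noise_sd=0.02, seed=0)
ds = build_phantom_dataset(spec, atlas)          # G',G'' -> mu, xi per subject

table = run_protocol(ds, ["ssl_contrastive", "pca_gp", "null"], ["mre"], n_seeds=3)
print(summarize_protocol(table))
```

On this desk-scale cohort the held-out mean absolute errors (averaged over
three splits) come out at roughly **0.09 yr for PCA+GP**, **3.5 yr for the
self-supervised contrastive model**, against **16.3 yr for the null
predictor** that always answers the training-mean age — i.e. every model
family recovers the phantom aging signal, and the ordering of families on
clean low-dimensional phantoms (where an affine PCA direction captures the
signal almost perfectly) differs from real data, where deep models win.
Disease phantoms behave like the clinical readout is supposed to: an AD
cohort shows a positive median whole-brain BAG (Mann-Whitney vs controls
p ≈ 5e-5), and the regional BAG profile peaks at the thalamus for AD and at
the hippocampus for MCI.

A full pipeline run from a YAML config:

```bash
elastoage run --config run.yaml --seed 0     # writes manifest.json + tables
```

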