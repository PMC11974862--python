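# Methods

## Mechanical properties

Voxelwise stiffness and damping ratio are derived from the complex shear
modulus G\* = G′ + iG″ as

    mu = 2|G*|^2 / (G' + |G*|),      xi = G'' / (2 G'),   |G*| = sqrt(G'^2 + G''^2)

with μ in kPa and ξ dimensionless. The inverse used by the phantom
generator follows from substituting G″ = 2ξG′: with q = √(1+4ξ²),
G′ = μ(1+q)/(2q²) and G″ = 2ξG′. The round trip is exact to ~1e-15 and is
asserted in the tests, so phantoms always pass through the same property
computation as real data would.

Volumes are z-scored per channel either over the pooled in-mask voxels of a
dataset ("dataset" mode, the default for mechanical channels) or per volume
("image" mode, always used for the anatomical channel and available as a
variant for the mechanical ones to remove global trends). Out-of-mask
voxels are set to exactly 0 after normalisation; this makes the zero-fill
used by occlusion saliency coincide with background. Normalisation
statistics are fitted on the training split only and re-applied to held-out
and disease subjects; fitting on everything is available through the same
API (pass a pre-fitted state or none) for literal replication of pooled
normalisation, but the default avoids leakage.

## Contrastive regression

Embeddings f(x) are L2-normalised; s_ik is their cosine similarity. Age
similarity is graded by a Gaussian kernel w_ik = exp(−(y_i−y_k)²/(2σ²)).
Three losses are implemented:

- y-aware: L = −Σ_i Σ_{k≠i} w_ik · log[ exp(s_ik) / Σ_t exp(s_it) ]
- exponential scaling: denominator terms exp(s_it·(1−w_it)), so
  age-dissimilar samples keep full repulsion;
- adaptive neighbourhood: exponential form with per-anchor weight
  normalisation w_ik/Σ_t w_it and the denominator restricted to the
  anchor's current nearest-neighbour set, whose size shrinks linearly per
  epoch: size(e) = clamp(start − step·e, end, start), start defaulting to
  n−1. Neighbour sets are recomputed per batch from the current embeddings
  under a configurable metric (Manhattan, Euclidean, or descending cosine
  similarity).

Two typographic ambiguities in the printed sums were resolved as design
choices: (i) denominator index sets exclude both the anchor i and the
positive k (self-similarity terms are constant e^1 and only flatten the
softmax; an anchor is never in its own neighbour set); (ii) the scaled
denominator exponent is read as exp(s·(1−w)) = exp(s)^{1−w}, not
exp(s^{1−w}). The kernel bandwidth σ is not constrained by the source
material; the default is 2 years, configurable. All three losses are
verified against scalar-loop enumerations to 1e-10 and their autodiff
gradients against central finite differences to 1e-4.

The phrase "stepwise learning rate decay (reduced by 0.9 every 10 epochs)"
appears in the source hyperparameter list attached to an unrelated clause;
it is implemented as plain learning-rate decay (×0.9 every 10 epochs) and
nothing else.

## Model families

All gradient-based training runs on a minimal numpy reverse-mode autodiff
core written for this package (broadcasted arithmetic, matmul, im2col 3D
convolution, reductions, L2 normalisation) with an Adam optimiser. Every
fit is a pure function of its seed on CPU, which gives bit-identical
reruns.

- **PCA + GP**: in-mask voxels are flattened (channels concatenated), k
  principal components extracted, and an exact GP with linear kernel
  K = v·ZZᵀ + s·I fitted on the scores. "Training for 50 epochs with Adam"
  is interpreted as 50 Adam steps on the log marginal likelihood over
  (log v, log s) — a GP has no other notion of epochs — with fresh Gaussian
  noise added to the scores each step as augmentation. Ages are centred;
  predictions add the training mean back.
- **Supervised CNN**: a small-ResNet-style 3D encoder — stride-2 stages,
  each a downsampling convolution plus a two-convolution residual block,
  ReLU throughout, global average pooling, linear latent head — and a
  two-layer MLP regression head (embedding → 64 → 1 at full scale),
  trained with the L1 loss. The head predicts the deviation from the
  training-mean age, which centres the optimisation without changing the
  model class. Augmentation noise is added inside the coverage mask only,
  after normalisation. Reference channel widths are [16, 32, 64, 128] with
  a 256-dimensional embedding.
- **SSL + ridge**: the same encoder trained with the adaptive-neighbourhood
  loss on L2-normalised embeddings; after training the encoder is frozen
  and a ridge regressor (α = 1 by default; the source states no value) maps
  embeddings to age. Embeddings are L2-normalised before the readout — the
  same space the loss shaped. Training batches smaller than
  max(3, end_count+1) are dropped: the loss needs three samples and a
  neighbour pool larger than the end count.

A desk-scale profile (24³–32³ grids, channels [4, 8, 16, 32], embedding 32,
~20 epochs, learning rate 1e-3) runs the full pipeline in minutes on one
CPU; the full-scale settings above are shipped as presets
(`models.PAPER_PRESETS`) including the per-modality best hyperparameters
(e.g. SSL on two-channel MRE: Manhattan distance, weight decay 5e-5, noise
sd 0.1, neighbour step 5, end count 9). Hyperparameter search itself is out
of scope; configurations are taken as given.

## Evaluation protocol

Healthy subjects only, 80:20 train/test split per seed, normalisation
fitted on the training split, fresh model fit per (family, modality, seed).
Both expansions of "MAE" — mean absolute error and median absolute error —
are always computed, because published values mix the two; neither is
asserted against clinical numbers (see Limitations). A null predictor
(training-mean age) anchors all signal-recovery claims.

## Occlusion saliency

Test subjects are split into five quantile age bins. Per bin, 7³ blocks are
zeroed at origins forming a 13-per-axis grid and ΔMAE (occluded − original)
recorded per origin. The printed grid parameters (block 7, 13 positions,
9 superior slices excluded, 91×109×91 volumes) are arithmetically
inconsistent on the 109-voxel axis and the excluded axis; origins are
therefore spaced by rounded linear interpolation over each admissible
extent, which reproduces the exact stride-7 tiling on clean 91-voxel axes
and preserves the 13³ = 2 197 origin count. The grid is clipped to its
5th–95th percentiles, cubically upsampled (spline interpolation on exact
target coordinates), zero-padded over the excluded superior slab, and
min-max scaled to [0, 1]. A constant grid yields an all-zero map with a
warning. Blocks are independent; no sliding-window averaging.

## Brain-age gaps and regional profiles

Models are refitted on healthy subjects excluding the disease cohort's
matched-control subset; a Theil-Sen line (slope = median of pairwise
slopes over distinct-age pairs, intercept = median(y − slope·x), via
`scipy.stats.theilslopes(method="joint")`) is fitted to predicted-vs-true
age on the controls and applied to the disease cohort. BAG = raw
prediction − (intercept + slope·age); the corrected prediction is
age + BAG. For any affine prediction rule all BAGs are exactly zero.

Regional profiles repeat this per atlas region with volumes masked to the
region (all other voxels zero) and the whole-brain configuration reused;
profiles share one fixed region order (10 subcortical structures, then
grey and white matter) and regions that vanish under the coverage mask are
recorded as NaN, never dropped. Cohort profiles are entrywise means.
At-risk flagging ranks healthy subjects by the Pearson correlation of
their profile with a disease cohort profile (threshold 0.7 by default);
the similarity metric is a declared design decision — the source shows
examples but names no metric.

Group comparisons are gated by Shapiro-Wilk normality (α = 0.05): both
groups normal → paired/independent t-test, otherwise Wilcoxon signed-rank
or Mann-Whitney U. Significance is reported at p < 0.05 with no
multiple-testing correction (none is described in the source); this is a
known limitation.

## Synthetic phantoms

The generator emulates the *statistical* structure the analysis assumes,
not the physics of wave propagation (no displacement fields, no inversion,
no scanner modelling, no registration):

- **Atlas**: 12 ellipsoidal regions in a common space; paired subcortical
  structures are exactly mirror-symmetric, the cerebellum is the largest
  region and the nucleus accumbens the smallest; a per-seed ±3 % radius
  jitter varies geometry across atlases. Desk default 32×40×32 (tests and
  the acceptance script use 24³ for speed); the full 91×109×91 at 2 mm is
  available.
- **Ages**: two-component uniform mixture, default 0.5·U[18,35] +
  0.5·U[35,90], emulating a young-skewed cohort (mean ≈ 44 yr) and the
  non-uniform low-data regime the contrastive method targets.
- **Trends**: per region r, μ_r(age) = baseline_r·(1 + m_r·β_μ·(age−41))
  with β_μ = −0.0033/yr, and analogously ξ with β_ξ = +0.0034/yr —
  the global aging rates reported for real cohorts. Per-region baselines
  are literature-plausible placeholders (μ ≈ 1.9–2.6 kPa, ξ ≈ 0.23–0.30)
  and fully configurable, since no per-region reference values are
  published with the rates.
- **Disease effects** (fractional offsets inside their regions only):
  MCI → ξ +10 % hippocampus, +5 % brain stem; AD → μ −15 % thalamus,
  −8 % pallidum. Magnitudes are free parameters chosen so the planted
  signatures are unambiguous: the dominant region of each profile
  (hippocampus for MCI, thalamus for AD) matches the clinical pattern, and
  the within-disease ordering is robust to atlas jitter and model seed —
  a 2:1 offset ratio keeps it so even though small regions estimate their
  BAG less precisely than large ones.
- **Noise**: multiplicative Gaussian voxel noise (sd 0.02 by default),
  spatially smoothed (Gaussian, width 1 voxel) to mimic the
  autocorrelation of reconstructed maps; values clipped to μ > 0,
  ξ ∈ (0, 1) with a warning when clipping occurs. At noise 0 the maps are
  exact, which the trend- and round-trip tests exploit.
- **Anatomical channel**: a monotone transform of the label map plus
  noise, carrying a weak (configurable, default −0.001/yr, zero for
  ordering experiments) age slope, so mechanical-vs-anatomical comparisons
  are meaningful.
- **Matched controls**: the oldest healthy subjects are flagged as the
  control subsets for MCI/AD, mirroring the old disease cohorts.

What passing tests on phantoms do **not** show: clinical error magnitudes,
the real ranking of model families (phantom signals are low-rank and
near-affine, so PCA+GP is unrealistically strong), scanner/site effects,
or registration artefacts. All claims on phantoms are qualitative
(signal recovered, orderings, planted effects localised).

## Numerical choices

- Losses exclude degenerate pairs: an adaptive-loss pair whose effective
  denominator set is empty is skipped with a warning.
- Neighbour selection breaks ties by stable argsort; the self-distance is
  +inf.
- GP kernel adds 1e-8 jitter before Cholesky; PCA k is clamped to
  min(n−1, feature dimension) by callers when regions are tiny.
- Quantile age bins that come out empty under ties are merged into their
  lower neighbour with a warning.
- Desk problem sizes (24³ grids, n = 40–60, 20 epochs, 3–10 seeds) were
  chosen so the complete suite and the acceptance script run in minutes on
  a single CPU; they are the package's default study conditions, not
  tuned quantities.
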