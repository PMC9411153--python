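# Methods

## Problem setting

Tissue-microarray cores from a tumour are scanned at 0.25 µm/pixel and a
patient's outcome is summarized as a right-censored disease-specific
survival label (t, δ). No patch-level annotation exists: a single label
covers hundreds of image patches, which is the multiple-instance-learning
(MIL) premise this package is built around. The pipeline has five stages —
preprocessing, feature encoding, bag construction, attention-MIL risk
modelling, and survival statistics — each exposed as an independent module.

## Preprocessing

Masking is a fixed pipeline: greyscale conversion, Otsu thresholding
(tissue = the darker side; H&E tissue is darker than glass), morphological
closing with a disc of 5 px at 0.25 µm/px (scaled inversely with
resolution — it fills stain gaps without bridging separate fragments at
this scale), retention of the largest connected tissue component, and
hole handling on a *physical* area threshold of 1470 µm² (23,520 px² at
0.25 µm/px): enclosed background regions smaller than the threshold are
stain artefacts and are filled; larger ones are genuine damage and stay
background. Background touching the image border is never treated as a
hole. A constant-intensity image makes Otsu degenerate; it yields an
empty mask with a warning rather than an error.

Patch grids start at (0, 0), are aligned to multiples of the patch size
(0-based, half-open), discard partial boundary patches, and retain a patch
when its mask-positive share is ≥ `min_tissue_fraction` (default 0.5; the
per-patch tissue requirement is a package choice).

Augmentation is deterministic: `geo4` = {identity, horizontal flip,
vertical flip, 90° rotation} (4× the cohort); `geocolour13` adds the six
distinct flip/rotation compositions each with and without a fixed-strength
brightness/saturation jitter (13×). Geometric transforms are pixel
bijections, so tissue pixel counts are preserved exactly. All augmented
copies share the source patient's survival label, with provenance
recorded. Every patient receives the full transform set; "up to" smaller
expansions are not implemented.

## Feature encoding

The pretrained compression encoder that maps a 128×128 tile at 0.5 µm/px
to a 128-vector is an *external artifact*; the package defines only the
contract (`EncoderContract`) and ships a deterministic synthetic stand-in:
block-averaging to 16×16×3 followed by a seeded Gaussian random projection
and tanh. It preserves pixel-content differences (a one-pixel change
perturbs the output) but carries no histology semantics — results obtained
with it validate the *pipeline*, not histological feature quality.
256-px patches are downsampled by 2 with 2×2 block means before encoding.
Four adjacent patch vectors aligned to even multiples of the patch size
form one 2×2×128 super-patch instance; blocks with any missing child
(lost to tissue filtering) are dropped rather than zero-padded, so
instance counts are conservative near tissue boundaries.

## The MIL network

Units (phenotype stacks or single instances) are embedded by a shared
1×1 convolution over positions (a linear map d→M) → ReLU → global average
pooling; for 2×2 super-patch instances in the instance model the kernel
spans the grid (acts on the flattened 4d vector). Attention pooling
follows the tanh form a_i ∝ exp(wᵀ tanh(V h_i)); tanh is kept (no gating)
so both similarity and dissimilarity contribute. The risk head is
M → 32 → 1 with ReLU. Defaults: M = 64, L = 128, dropout off
(configurable 0.5–0.7, which helped in some experiments). None of M, L,
or the head depth are externally prescribed; all are config-exposed.

**Attention sign identifiability.** The training objectives depend on
attention only through z, and the head can absorb either orientation of
the attention logits: a solution attending *toward* risk-carrying
instances and one attending *away* from them (toward the background
majority) fit equally well. With sign-symmetric initialization the
trained orientation flips with the seed. `init_params` therefore draws
the attention parameters V and w half-normal (positive): unit
representations are non-negative (ReLU), so initial attention logits grow
with a unit's activation energy, which is systematically larger for
motif-shifted instances, and training stays in the aligned basin. This is
a deliberate symmetry-breaking choice — heatmaps are only interpretable
under the aligned orientation.

All forward/backward passes are exact NumPy; gradients are verified
against central finite differences (relative error ≤ 1e-4) in the tests,
and forward passes are bitwise reproducible with dropout off.

## Losses and training

The negative partial log-likelihood (NPLL) uses the Breslow convention
for ties: the risk set of an event at t is {j : t_j ≥ t} and tied events
each contribute a full term. Each event term −o_i + log Σ_{R(t_i)} e^{o_j}
is non-negative (i is in its own risk set), the loss is shift-invariant
in o, and depends only on the ordering of event times. Log-sum-exp is
computed stably.

The ranking refinement −log σ(o_i − o_j) runs over comparable pairs —
(i, j) with δ_i = 1 and t_i < t_j, exactly the pairs whose true ordering
is known under right-censoring — added to the objective from
`rank_loss_start_epoch` (default 10) with weight `rank_loss_weight`
(default 1.0; the relative weighting of the two losses is not externally
fixed). If comparable pairs exceed 10,000, a seeded uniform subsample is
used.

Optimization is Adam with weight decay 5e-3 and learning rates 1e-5
(clustered) / 2e-5 (instance) by default. `batch_scheme='full'` uses the
entire training split per step so risk sets — and hence the NPLL — are
exact; minibatch mode forms risk sets within each batch. Model selection
keeps the checkpoint with the highest validation c-index, ties resolved
toward the earlier epoch. Training is fully reproducible given the seed.
No learning-rate schedules or early stopping beyond checkpoint selection.

For *synthetic-cohort recovery runs* the standard recipe
(`RECOVERY_TRAIN_CONFIG`) is lr 3e-4, 300 epochs, dropout 0.5, M = 6,
L = 8: synthetic features are raw Gaussian coordinates rather than
compressed histology embeddings, and a narrow embedder keeps the model
identifiable on 200-patient cohorts (wider embedders reach similar
concordance but dilute attention across noise channels).

## Phenotype clustering

The clustered variant partitions each patient's instances independently
(never across patients) with k-means (10 restarts, k-means++ seeding,
deterministic given the seed), k = 10 by default — the value with the best
average concordance in the k ∈ {4, 6, 8, 10, 12} sweep. Super-patch
instances are flattened before clustering. Bags smaller than k simply
yield fewer phenotypes (empty clusters are absent; the network consumes
C ≤ k stacks).

## Evaluation statistics

The concordance index (C + R/2)/(C + D + R) is evaluated over permissible
pairs under right-censoring (the shorter observed time must belong to an
observed event; tied observation times are never permissible). On fully
observed data this reduces exactly to the count-based definition over all
time-ordered pairs. The naive all-pairs variant is available behind
`restrict_permissible=False`.

Kaplan–Meier estimation delegates to lifelines. The Cox
proportional-hazards fitter is implemented in-package so that it shares
the partial-likelihood code path with the training loss: Newton–Raphson
with backtracking line search, Breslow ties, convergence at |Δ log L| <
1e-8 within 100 iterations; Wald standard errors, 95% CIs
exp(β ± 1.96 SE), unadjusted Wald p-values. Non-convergence, singular
information (e.g. a constant covariate) or effective separation
(|β| > 50) are flagged, not raised.

The staged analysis mirrors a three-stage protocol: Stage 1 = test split,
Stage 2 = test + validation, Stage 3 = whole cohort; each stage recomputes
the median cutoff *from the patients it includes*, labels high iff
risk > cutoff (so all-equal predictions are all low), fits univariate Cox
on the indicator and, when pre-dichotomized clinical covariates are
supplied, a multivariate model alongside them. Stages with fewer than two
events are skipped with a warning; clinical cutoffs are taken as given,
never re-derived.

## Heatmaps

Attention weights are affinely rescaled to [0, 1] against the global
minimum/maximum over the whole dataset (degenerate bounds map to 0.5;
ranking is preserved), placed on the 256-px patch grid, bilinearly
interpolated to pixel resolution, colour-mapped (default jet) and
alpha-blended (default 0.4) over the core; non-tissue regions stay
untinted when a mask is supplied. Heatmaps are an instance-model feature;
the clustered model exposes per-phenotype weights instead.

## Synthetic cohorts

The generator states the world the recovery experiments assume:

- per-patient signal prevalence p_i ~ Beta(2.5f, 2.5(1−f)) with mean
  f = `signal_fraction` (default 0.2) — strongly right-skewed, reflecting
  that most tumours contain little risk-associated tissue while a minority
  are dominated by it;
- instances are flagged signal i.i.d. with probability p_i; background
  instances are N(0, I_d), signal instances shifted by 2.0 along a fixed
  seed-drawn unit motif;
- true log-risk r_i = `effect_beta` × (realized signal fraction / f), the
  log-hazard per unit of *relative* signal burden (a patient at the
  nominal prevalence has log-risk β, one without signal 0);
- event times are exponential with hazard `baseline_hazard` · exp(r_i)
  (the simplest proportional-hazards-consistent choice; downstream
  statistics depend only on the PH structure, not the baseline shape);
- censoring is independent Uniform(0, c_max), with c_max calibrated by
  bisection so the expected censored share matches `censor_rate`
  (default 0.3, realized within ±0.05 for n ≥ 1000).

Under the defaults the oracle c-index of the true risk is ≈ 0.83–0.85,
which upper-bounds any model trained on the bags. What the generator does
*not* emulate: H&E colour statistics, realistic tissue texture, spatial
correlation between patches, multiple cores per patient, or informative
censoring — so a green recovery test establishes that the pipeline
recovers a planted risk signal under its stated assumptions, not that it
would perform comparably on clinical images.

Toy core images are dark ellipses on a white background with optional
circular holes of specified pixel area, returned together with their
ground-truth mask, for exercising the masking/tiling stages.

## Attention discrimination metric

"Attention concentrates on risk-associated tissue" is quantified as the
within-bag AUC: for each bag containing both classes, the AUC of attention
ranking signal above background instances, averaged over bags — the way a
heatmap is read within one core. A pooled variant (bag-size-normalized
attention a_i·n_i pooled across the cohort) is reported alongside. The
model analysed is the fold with the highest *validation* c-index, applied
to the whole cohort.

## Numerical choices

- Softmax is computed with max subtraction; attention sums to 1 within
  1e-6 by construction.
- NPLL and its gradient use masked log-sum-exp over an O(n²) risk-set
  matrix — exact and fast for cohort-scale n (hundreds).
- Fold plans: uniform random permutation under the seed, no event
  stratification by default (a stratified option exists); test sizes
  differ by ≤ 1; validation takes floor(0.3 · non-test).
- Seeds are passed explicitly everywhere; scikit-learn's k-means receives
  the seed modulo 2³².

## Known limitations

- The synthetic encoder is a stand-in; no trained compression network or
  ImageNet-style baseline is included.
- The recovery experiment's held-out c-index sits a few points below the
  oracle; with 40-patient test folds, single-fold estimates vary by ±0.05
  — the acceptance check therefore uses the mean over the five folds.
- Attention discrimination is meaningful only under the aligned
  orientation enforced by initialization; a sufficiently long training run
  could in principle migrate between basins.
- Cox fitting assumes proportional hazards and provides no diagnostics,
  time-dependent covariates, or competing-risks handling.
- Stage sizes follow mechanically from the fold plan: an 80/20 outer
  split with a 70/30 inner split on n = 243 yields ≈ 49 test and ≈ 58
  validation patients per fold, so Stage 2 covers ≈ 107 patients. The
  staged analysis always reports whatever the configured split yields; it
  does not enforce any externally fixed stage size.
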