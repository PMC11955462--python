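# Methods

## Problem setting

A patient's M2-macrophage infiltration level — estimated from bulk tumor
expression by signature-based deconvolution — is dichotomized at the cohort
mean into *high* vs *low*, and a residual CNN is trained to predict that
patient-level label from 224×224 H&E patches under a multiple-instance
learning (MIL) view: the patient is a bag, patches are unlabeled instances
that inherit the bag label during training, and bag-level predictions pool
instance probabilities. High M2 infiltration is also tested as a prognostic
factor for overall survival.

## Synthetic cohort generator

No patient images or expression ship with the package; a generator
produces cohorts with the statistical couplings the analysis assumes. One
latent variable per patient — the true M2 fraction — drives all three data
modalities:

- **Latent fraction.** Zero-inflated truncated normal: with probability
  `zero_inflation_prob` (default 21/86 ≈ 0.244, the observed rate of
  zero-infiltration patients in the motivating cohort of 86) the fraction is
  exactly 0; otherwise a normal draw (mean 0.25, sd 0.15) truncated to
  (0, 1]. The point mass at 0 reproduces the exclusion pathway: samples
  without M2 infiltration are removed before imaging analysis. The label
  boundary is the cohort-mean fraction; strictly above → high, ties → low
  (so "high" always means strictly above the mean).
- **Tiles.** Near-white background (255), eosin-pink tissue ellipses
  covering ≈ 55% of the tile, purple nuclei (≈ 25 per 224² of tissue) and
  brown macrophage-like blobs with expected count
  `base_density · (1 + visual_effect · m2) ` per 224² of tissue
  (base_density 3). The class signal is blob *density*, not a mean-color
  shift, so texture-sensitive convolution layers, not the color histogram
  alone, carry the signal; `visual_effect` dials the strength. Cells are
  clipped to the tissue mask, so the returned mask is exactly the
  foreground support. What is *not* emulated: stain physics, scanner
  artifacts, pyramidal whole-slide formats, nuclear morphology — passing
  tests show the pipeline's mechanics are correct, not that the model
  would reach any particular accuracy on real slides.
- **Expression.** `signature @ fractions` plus Gaussian noise scaled by the
  mean magnitude of the clean mixture, truncated at 0. The synthetic
  signature gives each cell type a block of ~8× elevated marker genes over
  a lognormal baseline, making the deconvolution problem identifiable but
  not trivial.
- **Survival.** Exponential event times, hazard
  `baseline_hazard · exp(true_log_hr · 1[high])` with baseline 0.02/month
  (median ≈ 35 months in the low group, realistic for advanced serous
  ovarian cancer). The default planted hazard ratio is 4.0, matching the
  better-estimated external-cohort figure (≈ 3.99) rather than the wide-CI
  internal estimate. Censoring is uniform on (0, c) with c solved by root
  finding so the expected censoring fraction equals `censor_rate` — the
  constant-hazard (exponential) baseline is chosen precisely so this
  calibration has a closed form under the mixture of the two groups.

Every artifact is a pure function of (spec, seed); identical runs are
byte-identical, including PNGs and the JSON manifest.

## Patch pipeline

"Background" is operationalized as near-white: a pixel is tissue when its
RGB mean is strictly below 220 (8-bit), and a patch is kept when at least
5% of its pixels are tissue; both numbers are config-exposed. Partial
border windows are dropped rather than padded, to avoid synthetic white
borders in training. Coordinates are 0-based, row-major, half-open pixel
windows. Patches are normalized per channel with the ImageNet constants
(means 0.485/0.456/0.406, sds 0.229/0.224/0.225), matching the input
convention of the residual backbone family. No stain normalization is
applied.

## Immune deconvolution

A simplified CIBERSORT-style core: the mixture and the signature are
globally z-scored (making fractions invariant to the mixture's overall
scale), a linear ν-SVR is fitted for each ν ∈ {0.25, 0.5, 0.75}
(C = 10, tol = 1e-4 — tight enough that noiseless mixtures round-trip to
machine-level accuracy, well inside the 1e-3 contract), the fit whose
reconstruction correlates best (Pearson) with the mixture is selected, and
its coefficients are clamped at 0 and renormalized to sum to one. The
published tool's permutation p-values and quantile normalization are
omitted: only point estimates of the M2 fraction are consumed downstream.
Gene alignment is by exact-ID intersection with a logged count; relative
(not absolute) abundance mode is implemented.

## Patch classifier

The backbone follows the standard 18-layer residual recipe; the
weighted-layer count `1 + stages·blocks_per_stage·2 + 1` counts
convolutional and fully connected layers only, excluding batch-norm and
the 1×1 projection shortcuts — consistent with the way the 18 of
"ResNet18" is conventionally counted. The engine underneath
(`hemil.nn`) is a compact NumPy implementation: im2col + BLAS-matmul
convolutions (the stem conv skips its input gradient — nothing below it
needs one, and the full-resolution transposed convolution would dominate
memory), batch normalization with running statistics (momentum 0.1),
overlapping 3×3/2 max-pooling computed as nine shifted-view maxima,
explicit hand-derived backward passes (validated against central
differences in the test suite), and SGD with momentum. Everything is
float32 NCHW and deterministic given the seeds.

Training choices:

- cross-entropy loss, SGD momentum 0.9, default learning rate 0.001,
  default 25 epochs, batch size 32 (unstated in the motivating recipe;
  32 is the common default);
- training starts from **random initialization**: there is no dependency
  on downloadable pretrained weights. A `pretrained_weights_path` config
  hook loads external checkpoints (shape-checked), and
  `freeze_up_to_stage` reproduces a partial-fine-tuning regime when such
  weights exist. The desk-scale experiments raise the learning rate to
  0.01–0.05 because from-scratch training on small synthetic tasks needs
  it; the fine-tuning default stays 0.001.
- the split is **patient-level and label-stratified** by default (whole
  bags on one side, sizes within 1 of the 80/20 ratio, deterministic per
  seed). A patch-level split is available behind `split_unit="patch"` for
  fidelity experiments, but it leaks patients across the split and
  inflates validation accuracy, so it is not the default.
- the checkpoint is saved only when validation accuracy strictly exceeds
  the running best, so the returned model is the *first* epoch achieving
  the maximum — a deliberate tie-break that favors the earliest best
  model.

## MIL aggregation and metrics

Bag probability = mean / top-10 mean / top-100 mean / max of instance
probabilities. Bags smaller than k use all instances (`k_used = min(k,
n)`): the only convention under which top-k reduces to max at k = 1 and to
the plain mean as k ≥ n, identities the property tests assert exactly.
The bag threshold is 0.5, boundary inclusive (a bag exactly at 0.5 is
called high), config-exposed. AUC uses the tie-aware rank (Mann–Whitney)
formulation — the probability that a random positive bag outscores a
random negative one with ties half-credited — which equals trapezoidal
ROC integration when no ties exist and handles ties cleanly when they do.

## Grad-CAM

Channel weights are the spatial means of the target-class *logit's*
gradient with respect to the feature maps of the last residual stage
(config-exposed layer selector); the heatmap is the rectified weighted
sum, bilinearly upsampled to 224×224 and min-max scaled to [0, 1]. An
all-zero map is returned as-is with a warning rather than divided by
zero. Min-max (not softmax) normalization keeps the map invariant to
positive scaling of the class-head weights, an invariance the tests
assert. Localization quality is verified only against the generator's
planted signal; no spatial ground truth exists for real H&E.

## Survival analysis

Kaplan–Meier estimation and the two-group log-rank test use lifelines;
Cox proportional-hazards fits maximize the Breslow partial likelihood by
Newton iteration (statsmodels' PHReg engine) with 95% Wald intervals.
Breslow rather than Efron tie handling: synthetic continuous times make
ties measure-zero, and on tie-free data the two agree to numerical
precision — the test suite cross-checks the Cox route against lifelines'
independent Efron/Newton implementation, and verifies the asymptotic
identity between the log-rank test and the Cox score test at β = 0.
Categorical covariates (e.g. stage) enter treatment-coded with the
alphabetically first level as reference. Monotone likelihood (perfect
separation) is detected as |log HR| > 10 and reported as a warning with
the fitted (optimizer-clamped) estimate. Univariate and multivariate
fits share the same engine.

## Workflow

A single YAML/JSON config drives eleven stages in fixed canonical order
(simulate → tile → deconvolve → label → split → train → predict →
aggregate → evaluate → gradcam → survival). Each stage derives its own
seed from the global seed plus a stage-name hash (CRC-32, reduced mod
2³¹), so stages are independently reproducible. The run manifest records
the config hash and SHA-256 checksums of every stage input and output;
resuming skips stages whose recorded checksums still match, and a missing
upstream artifact raises a dependency error naming the stage that
produces it. Labels are consumed from deconvolution output by default or
directly from ground truth behind a flag (for pure-imaging experiments).

## Desk-scale study conditions

The shared end-to-end experiment (`hemil.presets`) uses 40 patients with
four 448×448 tiles each (≈ 16 patches per bag after filtering), visual
effect 8.0 (strong), no zero-inflation in this imaging cohort, and a
2-stage width-16 backbone trained 8 epochs at learning rate 0.01 — sized
so the full loop, including the label-shuffled control retrain, completes
in minutes on one CPU while leaving the mechanics identical to the
full-scale recipe. Survival simulations use n = 300 with a planted hazard
ratio of 4 and 20% censoring; deconvolution checks use 50 genes × 5 cell
types at relative noise 0.05. Real whole-slide images are orders of
magnitude larger than these tiles; the tiling and MIL machinery is
unchanged by that scale, but runtimes and the CNN's capacity needs are
not represented.

## Known limitations

- The synthetic visual signal (blob density in distinct colors) is far
  easier than real histomorphology; end-to-end AUCs here demonstrate the
  pipeline's correctness, not expected clinical performance.
- The deconvolution omits permutation significance testing and absolute
  mode; fractions are relative.
- The Cox engine does not implement time-varying covariates, competing
  risks or proportionality diagnostics.
- Training is CPU-only and single-threaded by design; there is no GPU
  path.
- The best-checkpoint rule keys on validation accuracy alone, which on
  very small validation sets is coarse (ties resolved by earliest epoch).
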