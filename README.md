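# hemil — weakly-supervised M2-macrophage infiltration prediction from H&E histology

Tumor-associated M2 macrophages are an immunosuppressive, tumor-supportive
cell population whose infiltration level carries prognostic information in
serous ovarian cancer: patients with high M2 infiltration have worse overall
survival. Measuring that infiltration normally requires bulk expression
profiling (signature-based deconvolution) or immunohistochemistry. `hemil`
implements, as a tested and reusable pipeline, the alternative route:
predicting a patient's M2 infiltration group (**high** vs **low**) directly
from routine H&E histopathology, using

- **patch tiling + background filtering** — slide-scale RGB images are cut
  into 224×224 patches; a patch's tissue content is the fraction of pixels
  whose mean RGB falls below a whiteness cutoff (default 220), and patches
  with < 5% tissue are discarded;
- **an 18-layer residual CNN** — one stem convolution, four stages of two
  basic blocks (two 3×3 convolutions each), global average pooling and a
  two-way fully connected head (1 + 4·4·2 conv layers + 1 FC = 18 weighted
  layers), trained with SGD (momentum 0.9) on cross-entropy with
  best-validation-accuracy checkpointing;
- **multiple-instance learning (MIL)** — the patient is a *bag*, patches are
  *instances*; the bag probability is pooled from instance probabilities by
  one of four strategies: mean, top-10 mean, top-100 mean, maximum
  (`k_used = min(k, bag size)`), thresholded at 0.5;
- **signature-based immune deconvolution** — a simplified CIBERSORT-style
  core: linear ν-support-vector regression of the (z-scored) bulk mixture on
  a gene × cell-type signature matrix over ν ∈ {0.25, 0.5, 0.75}, selecting
  the best-correlating fit, clamping negative coefficients and renormalizing
  to fractions; samples with zero M2 fraction are excluded and the rest are
  dichotomized at the cohort-mean M2 fraction (the label source);
- **Grad-CAM** — channel weights α_k = spatially averaged gradients of the
  class logit at the last residual stage; heatmap = ReLU(Σ α_k A_k),
  bilinearly upsampled and min-max scaled;
- **survival analysis** — Kaplan–Meier curves, the two-group log-rank test,
  and Cox proportional-hazards fits (Breslow ties, Newton iteration, 95%
  Wald intervals) relating the M2 group and covariates to overall survival.

Because real cohorts (whole-slide images with matched bulk expression and
follow-up, e.g. from public tumor archives) cannot ship inside a package,
`hemil` includes a **synthetic cohort generator** that emulates the statistical structure the analysis assumes:
H&E-like tiles whose brown macrophage-like blob density grows with a latent
per-patient M2 fraction, bulk expression = signature·fractions + noise, and
exponential survival with a planted hazard ratio and calibrated uniform
censoring. The whole study loop runs end-to-end on a laptop-scale CPU.

The CNN layers (im2col convolutions, batch-norm, residual blocks, pooling,
SGD with momentum, explicit backward passes) are implemented in NumPy in
`hemil.nn`; the backward passes double as the gradient source for Grad-CAM.

## Worked example

```bash
python analysis/01_simulate_cohort.py  --seed 1 --out results/run
python analysis/02_tile_and_label.py   --seed 1 --out results/run
python analysis/03_train_classifier.py --seed 1 --out results/run
python analysis/04_mil_evaluation.py   --seed 1 --out results/run
python analysis/05_gradcam_maps.py     --seed 1 --out results/run
python analysis/06_survival_analysis.py --seed 1 --out results/run
python analysis/07_control_experiment.py --seed 1 --out results/run
```

With seed 1 this prints (abridged):

```
cohort: 40 patients, 0 with zero M2 infiltration
mean latent M2 fraction (the label boundary): 0.2405
patches kept after background filter: 626 (15.7 per patient)
M2 fraction recovery: mean abs error 0.0060
label boundary (cohort mean M2): 0.2416; agreement with ground-truth labels: 97.50%
split: 32 train / 8 validation patients
best checkpoint: epoch 7 (val accuracy 0.7440)
strategy    AUC    acc   prec    rec     F1   (validation patients)
mean     1.0000 0.8750 0.8333 1.0000 0.9091
top10    0.9333 0.6250 0.6250 1.0000 0.7692
top100   1.0000 0.8750 0.8333 1.0000 0.9091
max      1.0000 0.6250 0.6250 1.0000 0.7692
```

Reading: SVR deconvolution recovers the planted per-patient M2 fractions to
±0.006, so the expression-derived high/low labels almost perfectly match the
latent truth. Patch-level accuracy is modest (0.74 — single patches are
ambiguous), but pooling instances per patient lifts the mean-probability bag
AUC to 1.0 on the eight held-out patients: exactly the weak-supervision
effect the MIL design is meant to show. The label-shuffled control
(script 07) retrains with broken image-label links and drops toward chance
(0.6875 on the eight validation patients in this run), confirming the
signal is real. Script 06 additionally fits Cox models: the imaging
cohort's univariate hazard ratio for high M2 is 4.27 (95% CI 1.84–9.92,
planted truth 4.0), and on a 300-patient calibration cohort the estimate
is 3.31 (95% CI 2.53–4.34), covering the planted value.

The same pipeline is scriptable through a CLI (`hemil run-all --config
cfg.yaml --seed 1 --out run/`, with one subcommand per stage) and resumes
checksum-gated from any completed stage.

## Layout

```
src/hemil/        library (synthetic, patches, deconv, nn, classifier,
                  mil, gradcam, survival, workflow, presets, cli)
analysis/         numbered narrative drivers over the library
scripts/          acceptance recomputation
tests/            pytest suite (unit, property and acceptance tests)
docs/methods.md   models, assumptions, parameter choices, limitations
```
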