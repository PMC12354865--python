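# Methods

This note documents the models, numerical choices and known limitations of
`wsisurv`. It is written for a reader who wants to judge what the package
computes and what its passing tests do and do not establish.

## Problem setting

Surgically resected stage II–IV colorectal cancer has substantial recurrence
risk, and post-operative ctDNA positivity (molecular residual disease, MRD)
is a strong but morphology-blind prognostic marker. The package implements
the complementary route: a deep-learning risk score for disease-free
survival (DFS) learned directly from H&E whole-slide images under
multiple-instance learning (MIL), binarized at a training-cohort median and
combined with the binary MRD label into three joint strata (Double High,
Either High, Double Low). MRD itself is always an input label here; no assay
modeling is attempted.

## Slide preprocessing

* **Tiling.** Tiles have a fixed physical edge of 256 µm; the pixel edge is
  `round(256 / mpp)` at level 0. The grid starts at (0, 0) with stride equal
  to the tile edge and drops partial tiles at the right/bottom borders —
  the simplest convention that makes coordinates reconstructible from
  `(x, y, side_px)` alone. Tiles are resized bilinearly to 224 × 224, i.e.
  an effective resolution of 256/224 ≈ 1.14 µm/px. A missing
  microns-per-pixel value is a hard error; no default is guessed.
* **Background rejection.** The tile is converted to grayscale (0–255), run
  through a Canny detector (Gaussian σ = 1, hysteresis thresholds 40/100 on
  the intensity scale) and scored by the mean of the {0, 255}-coded edge
  map. Tiles scoring below 2 (≈ 0.78 % edge pixels) are discarded as
  background or blur. The hysteresis pair is a package choice — only the
  rejection threshold of 2 is externally fixed — and both are configurable.
  Note that with σ = 1 smoothing a period-4 checkerboard peaks below the
  high threshold; texture at period ≥ 8 px is kept comfortably.
* **Stain normalization (Macenko).** Optical density is
  `OD = −log10((I+1)/255)`. Pixels with any channel at or below
  `od_threshold = 0.15` are treated as background. The two stain directions
  are the 1st/99th-percentile extreme angles of the OD cloud projected onto
  its top-2 principal plane; rows are ordered hematoxylin-first by the
  larger blue-channel OD component (both shipped stain bases respect this
  ordering). Per-pixel concentrations are exact 2-variable non-negative
  least squares; per-stain maxima are 99th percentiles. Normalization
  rescales concentrations by `reference_max / fitted_max` and re-renders
  through the packaged reference basis. Fitting is per tile by default
  (per-slide available); an unfittable tile (< 50 tissue pixels, or a
  near-rank-1 OD cloud such as a grayscale image) falls back to passing the
  tile through unchanged with a logged flag.

## Feature bags and encoders

One HDF5 file per slide holds `feats` (float32, n × d) and `coords`
(int32, n × 2) plus identifying attributes. Multi-slide patients are merged
by row-wise concatenation with per-row slide provenance. Encoders are
pluggable behind a single interface; the shipped `mock` encoder (seeded
random projection of the flattened [0,1] image followed by tanh) is
deterministic and distinguishes distinct tiles, which is all the pipeline
tests require. Adapters for external pretrained pathology encoders raise an
explicit error when the backing package is absent — never a silent
fallback. No pretrained weights are shipped or downloaded.

## MIL risk model

Per tile: linear 1024 → 512 + ReLU. A learnable CLS token (truncated-normal
init, ±2σ) is prepended and the sequence passes through two pre-norm
transformer blocks (8 heads, FFN width 2048, dropout 0.1, residual
connections and layer normalization around both sub-blocks); the final CLS
state goes through LayerNorm → 512 → 256 → ReLU → 256 → 1. Head count, FFN
width, dropout and head depth are package defaults in line with common
ViT-style blocks; all are config-exposed. There are no positional
encodings: a bag is a set, and the forward pass is permutation-invariant to
floating-point accumulation order (tested at atol 1e-5).

With `n_layers=0` the model collapses to a linear surrogate — the bag
representation is the mean tile embedding, optionally with a plain linear
head and no LayerNorm — whose value and gradients can be written down by
hand. It is retained as an analytic oracle and as the reference model for
tile-level attribution checks (below).

The whole network, including training, runs on a purpose-built numpy
reverse-mode autodiff core (float64 throughout). This keeps the package
dependency-light and makes every gradient directly checkable against
central finite differences, which the test suite does for each primitive op
and for the full model.

## Survival training

* **Loss.** Negative Cox partial log-likelihood with Breslow tie handling,
  risk sets formed within the mini-batch of patients; batches with zero
  events are skipped with a warning. The L1 penalty uses the smooth
  approximation `sqrt(w² + 1e-24)`; penalties apply to weight matrices only
  (not LayerNorm parameters, biases or the CLS token).
* **Protocol.** 512 tiles per bag re-sampled without replacement each epoch
  (smaller bags pass through whole); Adam at lr 1e-4, batch 64, L1 = L2 =
  0.001, up to 50 epochs, early-stopping patience 15; patients split 4:4:2
  by largest-remainder apportionment of the shuffled list. Validation
  concordance is computed on full, unsampled bags so checkpoint selection
  is deterministic; the best checkpoint is restored at the end.
  `patience = 0` trains exactly one epoch.
* **Concordance.** Harrell's C with censoring (pairs comparable when the
  earlier time is an event; score ties count ½), delegated to lifelines and
  cross-checked against exhaustive pair enumeration in the tests.

## Risk stratification

The binarization threshold is the median of the training-cohort scores
(midpoint rule for even n); the deployed default, 0.9357855, is the frozen
training-cohort median. Classification is strictly `risk > threshold`, so
exact ties go to the low-risk class — ties are measure-zero in practice but
the rule must be deterministic. Percentages are reported half-up at one
decimal, matching the bookkeeping the published counts use (e.g. 304/1404 →
21.7 %, 81/239 → 33.9 %, 223/1165 → 19.1 %). The threshold travels inside
the checkpoint together with the encoder name and tile size, so external
deployment reuses it verbatim and can never recompute it from the new
cohort.

## Survival statistics

Kaplan-Meier estimation and the log-rank test are delegated to lifelines
(with hand-computed product-limit and Mantel-Cox tables, a permutation
oracle, and a conditional-survival identity as independent test checks).
The Cox proportional-hazards fit is implemented in-package: Newton-Raphson
on the Breslow partial likelihood with step-halving, convergence at step
< 1e-10, at most 100 iterations; Wald 95 % CIs `exp(β ± 1.96 SE)` from the
inverse observed information. Breslow ties are the package-wide convention
because the training loss uses them; Efron is available behind a flag
(delegating to lifelines). Separation (monotone likelihood) is detected by
runaway coefficients, capped at |β| = 20 and flagged. Covariate encoding:
binary 0/1 for sex, ACT, MRD, MSI and pM; ordinal integers for pT/pN; age
continuous. Landmark analysis drops every patient with follow-up shorter
than the landmark and re-origins the remaining times (hazard ratios are
unaffected by the re-origin; Kaplan-Meier displays are).

## Attribution

For one bag, the gradient of the risk score with respect to each tile's
input features is obtained by backpropagation with dropout disabled; the
tile's Grad-CAM-like score is `mean_d(gradient · feature)`. Tile-level
prediction scores come from singleton forward passes, min-max normalized
over the slide (all 0.5 when degenerate; softmax normalization available
behind a flag). The weighted importance is the elementwise product of the
two. Heatmaps paint tiles on a slide thumbnail with a diverging blue-red
map anchored at 0 and symmetric range; top-k extraction breaks ties by
(score, y, x) so shuffled bags give identical panels.

## Synthetic data generator

The generator defines the desk-scale study conditions.

* **Bags.** Background tiles are standard normal in feature space; each
  high-risk patient receives `round(signal_fraction · n)` tiles from a
  cluster shifted by `signal_shift` along one fixed seeded direction.
  The latent risk is binary (z ∈ {0,1}) or continuous (z ~ N(0,1), shift
  scaled by z); a bag with z = 0 contains no planted tiles.
* **Survival.** Weibull proportional hazards with shape defaulting to 1
  (exponential), hazard `baseline · exp(log_hr · z)`, independent
  exponential censoring — so the data-generating hazard ratio is available
  in closed form and Harrell's C of the true z is a computable ceiling.
* **MRD.** Bernoulli(sensitivity) for high-risk patients and
  Bernoulli(1 − specificity) otherwise (defaults 0.8 / 0.9), binarizing
  continuous z at 0; MRD enters the pipeline only as this label.
* **Stain images.** Per-stain concentration fields are Gaussian noise
  smoothed with σ = `smoothness`, clipped at 0 and scaled to the requested
  maxima; images are `255 · 10^(−cᵀM)` quantized to 8 bits before any test,
  matching real inputs. Because the clipped fields leave many near-pure
  pixels of each stain, percentile-extreme estimation is well posed.

What the generator does **not** emulate: tissue texture, nuclei, scanner
artifacts, batch effects between cohorts, informative censoring, or any
correlation between covariates and image content. Passing tests therefore
demonstrate the correctness of the computational pipeline under its own
assumptions, not clinical performance.

### Desk-scale study conditions

Training-dependent checks run on a 200-patient cohort, 16-d features,
40–80 tiles per patient, signal fraction 0.3, and a reduced model
(embed 32, 2 layers, 4 heads, FFN 64); the training recipe is 64 tiles per
bag, batch 64, lr 3e-3, ≤ 40 epochs, patience 15. These sizes keep a full
run in tens of seconds on one CPU while leaving the statistical questions
intact. Two conditions are fixed:

* **Planted signal:** continuous latent risk, `log_hr = 2.5`,
  `signal_shift = 4.0`. A pilot of the data-generating oracle (Cox on the
  true z) puts the achievable C-index near 0.86 on the validation split;
  the trained transformer reaches ≈ 0.84–0.87 across training seeds.
* **No signal:** `signal_shift = 0`. The checkpoint-selection metric (max
  validation C over epochs) is upward-biased under the null — the maximum
  of ~tens of chance draws — so chance-level behavior is asserted on the
  untouched test split of the selected checkpoint, which stays near 0.5.

Tile-level attribution precision is measured on the fully trained 0-layer
linear surrogate over a binary planted-signal cohort: with shift 4 the
planted and background clusters are nearly separable per tile (Bayes
precision ≈ 0.97), and the surrogate's weighted importance reaches
0.92–0.95 precision at k = planted count over 50 bags across seeds. Two
protocol details matter here. Dropout is disabled for the surrogate — on a
linear model it only injects gradient noise — and the *final-epoch* weights
are used (`restore_best=False`): checkpoint selection by bag-level
validation C-index saturates early and on some seeds freezes an epoch whose
tile-level readout is still undertrained, while tile resolution keeps
improving with further training. The 2-layer transformer's tile-level
scores are checked directionally (planted tiles score above background for
high-risk patients and below for protective ones): singleton bags are far
from its training distribution and its per-tile ranking is accordingly
noisier, a property of CLS-attention MIL worth knowing before reading its
heatmaps quantitatively.

## Numerical choices and degenerate inputs

* Float64 everywhere in the model and statistics; bags are stored float32.
* Log-sum-exp stabilization (max-shift) in the Cox loss and softmax.
* Median threshold: numpy median (midpoint of middle two).
* `km_fit` keeps subjects censored exactly at an event time in the risk set.
* An empty risk batch, a bag with zero tiles, a constant covariate, zero
  comparable pairs, or a landmark excluding everyone are all hard errors,
  not silent results.
* Checkpoints embed the model config, threshold and provenance; loading
  validates shapes parameter-by-parameter.

## Limitations

* Slide input is a thin single-level reader (TIFF/PNG via Pillow) with an
  explicit mpp override; pyramidal formats should be converted or brought
  in as pre-extracted feature bags. Pyramid-level selection is therefore
  not exercised.
* The numpy training loop is single-threaded; it is sized for desk-scale
  cohorts (hundreds of patients, reduced dims), not for full-resolution
  1024-d bags at cohort scale.
* Whether the original pipeline fits stain parameters per tile or per
  slide, its exact Canny parameters, its loss and tie handling, and its
  head architecture beyond the stated dimensions are not public; the
  package's choices are documented above and config-exposed.
* Clinical covariates in the synthetic cohort are independent of the
  latent risk (except MRD), so multivariate adjustment on synthetic data
  tests plumbing, not confounding structure.
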