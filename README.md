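# wsisurv

From whole-slide H&E histology to a patient-level deep-learning risk score
for disease-free survival (DFS), and onwards to joint risk strata with
ctDNA-based molecular residual disease (MRD) status.

`wsisurv` is aimed at computational-pathology groups who want a compact,
fully testable re-implementation of the standard transformer-MIL survival
pipeline for colorectal cancer:

1. **Preprocess** — tessellate slides into 256 µm tiles, resize to 224 × 224 px
   (≈ 1.14 µm/px), reject background/blurry tiles whose mean Canny-edge density
   falls below 2, and normalize stain colors with the Macenko method.
2. **Encode** — turn kept tiles into per-slide feature bags
   (`n_tiles × 1024` HDF5 files with tile coordinates) through a pluggable
   encoder interface; a deterministic mock encoder stands in for external
   pathology foundation models.
3. **Train** — a multiple-instance-learning transformer (1024 → 512
   projection with ReLU, learnable CLS token, two pre-norm attention blocks,
   MLP head) maps each bag to a scalar risk. The loss is the negative Cox
   partial log-likelihood (Breslow ties) over in-batch risk sets with L1/L2
   regularization; 512 tiles are re-sampled per bag each epoch; patients are
   split 4:4:2 and the checkpoint with the best validation concordance
   (Harrell's C) is kept, with early stopping.
4. **Stratify** — risk scores are binarized at the training-cohort median
   (the shipped deployment threshold is 0.9357855) and crossed with MRD into
   Double High / Either High / Double Low risk strata.
5. **Analyze** — Kaplan-Meier curves, log-rank tests, uni-/multivariate Cox
   proportional-hazards fits with Wald 95% CIs, t-month DFS rates, and
   landmark analyses.
6. **Explain** — per-tile gradient × feature ("Grad-CAM-like") scores,
   weighted by min-max-normalized tile-level predictions, rendered as
   blue-to-red slide heatmaps and top-k tile panels.

In the core model, a bag $X = \{x_1,\dots,x_n\}$, $x_i \in \mathbb{R}^{1024}$,
is scored as

$$r(X) = \mathrm{MLP}\Big(\mathrm{CLS}\big(\mathrm{TF}^{(2)}[c_0;
\mathrm{ReLU}(W x_1),\dots,\mathrm{ReLU}(W x_n)]\big)\Big),$$

and training minimizes
$-\tfrac1D \sum_{i:\,\delta_i=1}\big[r_i - \log \sum_{j:\,t_j \ge t_i} e^{r_j}\big]
+ \lambda_1\lVert\theta\rVert_1 + \lambda_2\lVert\theta\rVert_2^2 .$

Everything runs on CPU: the transformer and its training are implemented on
a small numpy reverse-mode autodiff core (`wsisurv.nn`), gradient-checked
against finite differences in the test suite. A synthetic-data module
generates feature bags with planted high-risk tiles, proportional-hazards
survival times, MRD labels linked to the latent risk, and H&E-like images
from a known two-stain optical-density model — so the entire pipeline is
exercised end-to-end with known ground truth and no downloads.

## Worked example

Simulate a 200-patient cohort with planted tile signal, train, and read the
headline numbers:

```python
from wsisurv.synth import SynthCohortSpec, generate_cohort
from wsisurv.model import ModelConfig
from wsisurv.training import TrainConfig, train, split_patients
from wsisurv.survstats import labels_from_frame

spec = SynthCohortSpec(n_patients=200, feature_dim=16,
                       tiles_per_patient_range=(40, 80),
                       signal_shift=4.0, signal_fraction=0.3,
                       log_hr_per_risk_unit=2.5, latent_risk="continuous",
                       seed=1)
cohort = generate_cohort(spec)
bags = {b.patient_id: b for b in cohort.bags}
labels = labels_from_frame(cohort.clinical)

model_cfg = ModelConfig(input_dim=16, embed_dim=32, n_layers=2, n_heads=4,
                        ffn_dim=64, head_hidden=(16,), seed=0)
train_cfg = TrainConfig(tiles_per_bag=64, batch_size=64, lr=3e-3,
                        max_epochs=40, patience=15, seed=0)
model, log = train(bags, labels, model_cfg, train_cfg)
print(f"best validation C-index: {log.best_val_cindex:.3f} "
      f"(epoch {log.best_epoch})")
```

```
best validation C-index: 0.837 (epoch 14)
```

A C-index of 0.84 against a data-generating ceiling of ≈ 0.86 on this split
(Harrell's C of the true latent risk itself) says the model has essentially
recovered the risk signal that drives both the planted tiles and the
survival times; with `signal_shift=0` the held-out test C-index stays at
chance (≈ 0.48).

The same flow is available from the shell:

```bash
wsisurv run-all --out runs/demo --seed 1
wsisurv stratify --scores runs/demo/scores.csv \
    --clinical runs/demo/clinical_deploy.csv --out runs/demo/strata.csv
```

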