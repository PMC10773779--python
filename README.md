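# strokefusion

Multimodal prognosis scoring for acute ischemic stroke: a reusable
library and CLI that fuses 2-D brain-MRI slice features with clinical
metadata to predict a binary good / poor prognosis outcome.

The model family consists of:

- **Image branch (ALAM)** — a VGG16-style backbone tapped at three
  scales; at each scale a *global-local attention module* (GLAM)
  combines a pre-norm transformer block over patch tokens (global
  attention, `Fg = X' + MLP(LN(X'))` with `X' = X + MHSA(LN(X))`) with
  sequential channel-then-spatial sigmoid attention (local attention,
  `F' = Att_c(F) o F`, `Fl = Att_s(F') o F'`); joint features propagate
  coarse-to-fine top-down and are average-pooled into the image vector
  `F1`.
- **Metadata encoder (MLP-FE)** — the clinical fields (binary
  comorbidities, one-hot hospital, ordinal consciousness, z-scored age
  and ability score) through two 256-wide dense + BN + ReLU blocks with
  25% dropout after the first, producing `F2`.
- **Cross-modal attention (CMAM)** — `F = Concat(F1, F2)`, sigmoid mask
  `A = sigmoid(FC(ReLU(BN(FC(F)))))`, gated feature `Fo = A o F`, linear
  2-class head.
- **Training / evaluation** — Adam + cross-entropy with a fixed epoch
  budget; accuracy / precision / sensitivity / specificity / F1 with
  positive class = poor prognosis; rank-estimator AUC; patient-level
  stratified cross-validation; a 4-arm nested ablation harness
  (baseline, +multi-scale, +GLAM, +metadata).
- **Explainability** — Grad-CAM over any image-branch layer plus a
  lesion-localization score (mean saliency inside / outside the
  ground-truth mask).
- **Synthetic cohorts** — seeded generation of brain-like slices with
  irregular lesion blobs and ground-truth masks, plus label-correlated
  clinical metadata, including a small-lesion positive subpopulation.

Real clinical data are not required anywhere: the synthetic module
emulates the cohort structure end to end.

The network layer is implemented on a small NumPy reverse-mode autograd
engine (`strokefusion.nn`) so the package runs on a plain scientific
Python stack with no deep-learning framework dependency.

## CLI

```sh
# 1. generate a synthetic cohort (PNG slices + masks + metadata CSV + manifest)
strokefusion simulate --n-patients 60 --slices-per-patient 4 \
    --image-size 32 --seed 1 --out runs/cohort

# 2. train the full model (desk profile; use --no-ms/--no-glam/--no-mlp for arms)
strokefusion train --manifest runs/cohort/manifest.csv \
    --image-size 32 --epochs 15 --out runs/train

# 3. evaluate on the manifest's test split
strokefusion evaluate --manifest runs/cohort/manifest.csv \
    --weights runs/train/weights.npz --image-size 32 --out runs/eval

# 4. the 4-arm ablation table
strokefusion ablate --manifest runs/cohort/manifest.csv \
    --image-size 32 --epochs 15 --n-seeds 3 --out runs/ablation

# 5. Grad-CAM localization scores (+ overlay PNGs)
strokefusion explain --manifest runs/cohort/manifest.csv \
    --weights runs/train/weights.npz --image-size 32 \
    --overlays --out runs/explain
```

`--profile desk` (default) uses reduced channel widths for CPU-scale
runs; `--profile paper` selects the published-scale configuration
(224 px input, full VGG16 widths, 200 epochs) — expect long runtimes on
CPU.

## Layout

```
src/strokefusion/
  nn/                 autograd engine + layers + Adam
  schema.py           clinical metadata schema
  synthetic.py        seeded cohort generator
  alam.py             image branch (patch embed, GAB, LAB, GLAM, multi-scale)
  metadata_encoder.py vectorization + MLP encoder
  cmam_classifier.py  cross-modal attention fusion + classifier
  model.py            arm assembly (ablation flags)
  train_eval.py       training, metrics, cross-validation, ablation
  explain.py          Grad-CAM + localization score
  io.py               PNG/NIfTI/CSV readers-writers (atomic)
  cli.py              simulate / train / evaluate / ablate / explain
tests/                unit + property + acceptance suites
scripts/acceptance.py acceptance report
```
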