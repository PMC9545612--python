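# ctvi-synth

Machine-learned CT ventilation imaging (CTVI): a 2D U-Net maps a pair of
breath-hold CT volumes (exhale + inhale phases) directly to a 3D regional
lung-ventilation map, with no deformable image registration and no
hand-chosen ventilation metric. Ventilation maps guide functional-lung-
avoidance radiotherapy planning: sparing well-ventilated lung lowers the
risk of radiation-induced lung injury, and a CT-derived map avoids the cost
and limited availability of nuclear-medicine ventilation imaging.

The package is aimed at medical-physics researchers who want a fully
reproducible, CPU-only reference pipeline. Since clinical BHCT + ventilation
datasets cannot be redistributed, a synthetic thorax phantom module
generates paired CTs and a known ventilation ground truth, so every stage —
preprocessing, cross-validated training, slice-wise inference, evaluation —
runs and is tested at desk scale.

## Method

* **Input/label.** Each axial slice enters as three channels: exhale CT,
  inhale CT, and their voxelwise mean, all min–max normalized per case. The
  label is the ventilation/activity image, hot-spot-standardized (every
  voxel clipped at μ + 4σ of the lung activity) and normalized to [0, 1].
* **Network.** A 2D U-Net (3×3 ReLU convolutions, He init, 'same' padding;
  2×2 stride-2 max pooling; 2×2 stride-2 transposed-conv upsampling with
  skip concatenation; 1×1 sigmoid head). The full-scale configuration has
  exactly 1,962,901 trainable parameters. Layers, backprop and Adam are
  implemented in NumPy and verified against finite differences.
* **Loss.** Continuous-label focal loss,
  `L = −mean[α·y·(1−p)^γ·ln p + (1−y)·p^γ·ln(1−p)]` with α = 1.5, γ = 5.0:
  underpredicting ventilated voxels costs more than overpredicting the
  (dominant) background, which keeps the model away from blank-image
  solutions.
* **Protocol.** Eightfold cross-validation at clinical scale (15 cases →
  13 train / 2 test per fold, one case tested twice); 10% slice-level
  validation split; ±10° rotation and in-plane translation augmentation;
  Adam, lr 3×10⁻⁴.
* **Evaluation.** Spearman correlation over the exhale lung mask, plus Dice
  overlap of the three equal-volume functional-lung regions (low/medium/
  high, split by ranked ventilation) computed independently for prediction
  and reference: DSC = 2TP/(2TP+FP+FN), reported per region and averaged.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

Run the full experiment — phantom cohort, preprocessing, cross-validated
training, inference, evaluation — from one seeded config:

```bash
ctvi-synth run-all --seed 1 --out runs/demo
```

(equivalently `run_experiment({"seed": 1, "n_cases": 6, "n_folds": 3,
"train": {"epochs": 60}}, "runs/demo")` from Python). With 6 phantom cases,
3 folds and 60 epochs at the 64×64 test scale this takes ≈7 minutes on one
CPU and writes `summary.csv`:

```
metric,mean,sd,n
Spearman correlation,0.867,0.061,6
DSC high functioning lung,0.781,0.057,6
DSC medium functioning lung,0.612,0.098,6
DSC low functioning lung,0.817,0.059,6
DSC average,0.736,0.071,6
```

Each row is the mean ± sample SD across the 6 held-out test cases of the
comparison between the predicted CTVI and its PET-like training label.
`summary_vs_truth.csv` holds the same comparison against the phantom's
noise-free true ventilation field (median Spearman 0.81, median DSC average
0.70 for this run): the network recovers the known field from CT pairs it
never saw. The medium-functioning-lung region shows the weakest overlap —
expected, since it is squeezed between the other two regions by rank
thresholds on both sides. Per-fold weights, training histories, per-case
reports and a rerunnable manifest land under `runs/demo/`.

Individual stages are also exposed: `ctvi-synth phantom | preprocess |
predict | evaluate` (see `--help`).

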