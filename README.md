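# tbseg

Automated temporal-bone CT segmentation at desk scale: preprocessing,
a trainable 3D encoder–decoder segmentation backend, Hounsfield-unit-
constrained post-processing refinement, otic-capsule derivation, and an
objective evaluation suite (Dice, average Hausdorff distance,
volumetric similarity). Because clinical temporal-bone CT data cannot
be shipped, the package includes a procedural phantom generator that
produces CT-like volumes (fluid-filled labyrinth inside a compact-bone
shell, ossicles in an air cavity, a nerve canal, a venous channel,
trabecular background, Gaussian noise) with exact ground-truth labels —
the whole pipeline is exercised end to end on those phantoms.

## Layout

| module | role |
| --- | --- |
| `tbseg.volgrid` | `Volume` / `LabelMap` / `GridSpec` types, NIfTI I/O, FOV-preserving resampling, left–right flips |
| `tbseg.preprocess` | HU windowing to [0,1], right-side standardization, seeded intensity-jitter / flip augmentation |
| `tbseg.segnet` | NumPy 3D U-Net (optional residual blocks) with soft-Dice training, Adam, step LR decay, k-fold cross-validation, checkpoints |
| `tbseg.refine` | HU-constrained shrink/grow margin maximization, island removal, otic-capsule derivation |
| `tbseg.metrics` | DSC, average Hausdorff distance (mm, boundary voxels, spacing-aware), volumetric similarity (%), mean±SD aggregation |
| `tbseg.phantom` | procedural phantom + dataset generator, label corruption for robustness tests |
| `tbseg.pipeline` / `tbseg.cli` | YAML-configured end-to-end orchestration with a reproducible run manifest |

The network backend is implemented directly in NumPy (hand-written
forward/backward passes); no deep-learning framework is required.

## CLI

```bash
# generate 20 phantoms with labels and a manifest CSV
tbseg phantom --n 20 --grid 64 --spacing 0.25 --seed 7 --out data/

# train one binary model per structure
tbseg train --structure inner_ear --data data/ --out inner_ear.ckpt.npz --seed 7

# predict / refine / derive the capsule
tbseg predict --model inner_ear.ckpt.npz --in data/ct_case_0000.nii.gz --out prob.nii.gz
tbseg refine --structure inner_ear --label pred.nii.gz --ct data/ct_case_0000.nii.gz --out refined.nii.gz
tbseg capsule --inner-ear refined.nii.gz --ct data/ct_case_0000.nii.gz --out capsule.nii.gz

# evaluate predictions against references (per-case rows + mean (SD) summary)
tbseg evaluate --pred preds/ --ref data/ --out report.csv

# everything at once: phantoms -> train -> predict -> refine -> capsule -> evaluate
tbseg run --seed 1 --out runs/demo
```

`tbseg run` accepts `--config config.yaml`; keys cover the HU window,
augmentation probabilities, net depth/channels, epochs and learning-rate
schedule, per-structure HU ranges and island policies, and phantom grid
settings. Defaults: window −500..2000 HU, training at 0.5 mm,
refinement at 0.25 mm isotropic, per-structure HU ranges
inner ear / facial nerve / sigmoid sinus −400..550, ossicles 100..2500,
otic capsule 650..2500.

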