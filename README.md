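# chiasmnet

Patch-based 3-D CNN classification of optic-chiasm morphology (normal vs.
albinotic) from small T1w-like image patches, together with the full
evaluation protocol and attribution-based model inspection — exercised
end-to-end on a synthetic chiasm-phantom generator, so no clinical data is
needed anywhere in the pipeline or the tests.

## What is inside

| module | role |
| --- | --- |
| `chiasmnet.phantom` | Synthetic 24×24×8 mm chiasm patches with class-dependent morphology (body width, tract angle, central intensity boost), Rician noise, rigid jitter, vessel distractors and full ground truth |
| `chiasmnet.data_io` | NIfTI volume/patch I/O, world-coordinate patch extraction, robust min-max normalization, chiasm exclusion for pretraining, CSV cohort manifests |
| `chiasmnet.model_core` | Encoder + scoring-head network and the mirrored autoencoder, built on a small numpy layer stack (`chiasmnet.nn`) with exact backprop (input gradients feed the attribution methods) |
| `chiasmnet.training` | Imbalanced 8-fold split construction (TRAIN / DEV_TRAIN / TEST1 / TEST2 per fold), minority upsampling with per-epoch augmentation, autoencoder pretraining, classifier fine-tuning with checkpoint selection |
| `chiasmnet.evaluation` | Confusion counts, accuracy/precision/recall/F1 with explicit undefined markers, ROC/AUROC (Mann–Whitney-equivalent), per-fold Youden thresholds, fold aggregation with fractional confusion matrices |
| `chiasmnet.explain` | Saliency, gradient×input, occlusion maps, attribution-localization scores, class-average difference analysis with binarized masks |
| `chiasmnet.workbench` | YAML-configured experiments, staged orchestration, audit, CLI |

The network is implemented in pure numpy (float64) rather than a deep-learning
framework: the models are small enough for CPU training on 4608-voxel patches,
and exact input gradients come for free.

## CLI

```bash
# full pipeline: simulate -> pretrain -> train -> evaluate -> explain
chiasmnet run-all --config exp.yaml --seed 7 --out results/run1

# individual stages share the same output directory
chiasmnet simulate --out results/run1 --set "cohort.tags={siteA: {n_control: 16, n_albinism: 16, test_group: test1}}"
chiasmnet audit --out results/run1   # recompute summary.json from fold artifacts
```

Configuration is a single YAML file (unknown keys are rejected); any field can
be overridden with `--set dotted.key=value`. Outputs per run: `cohort/`
(patches + manifest + truth sidecars), `pretrain/`, `fold_<i>/` (checkpoint,
history, split id lists, scores, threshold), `metrics.csv`, `summary.json`,
`roc_fold<i>.csv`, `xai/` (attribution NIfTIs, localization scores, class
average maps + montage) and `run_log.json`. Identical config + seed reproduce
`summary.json` byte-for-byte.

## Conventions worth knowing

* Albinism (label 1) is the positive class; a sample is predicted positive
  iff score ≥ threshold; the per-fold threshold maximizes Youden's J on the
  DEV_TRAIN scores, with midpoints between adjacent distinct scores as
  candidates and ties broken toward the fewest positives.
* Undefined metrics (zero denominators, single-class AUROC) are NaN markers,
  excluded from fold means with a logged count — never silently zero.
* Fold standard deviations are population standard deviations.
* All geometry is RAS millimetres at 1 mm isotropic; the 8 mm patch axis is
  inferior–superior; extraction windows are half-open with nearest-voxel
  rounding (ties toward −∞).
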