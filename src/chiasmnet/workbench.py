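"""Experiment orchestration: configuration, staged pipeline, CLI and audit.

A run is fully described by (ExperimentConfig, master seed). Stages write
their artifacts under the output directory and later stages reload them, so
``simulate``/``pretrain``/``train``/``evaluate``/``explain`` can be driven
individually or via ``run-all``. Two runs with identical config + seed
produce identical ``summary.json``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field, fields

import click
import numpy as np
import pandas as pd
import yaml

from . import evaluation, explain, model_core, phantom, training
from .data_io import (
    PatchVolume,
    Volume,
    load_manifest,
    mask_chiasm_out,
    normalize_intensity,
    read_volume,
    write_volume,
)
from .errors import ChiasmNetError, ConfigError
from .evaluation import (
    aggregate_folds,
    as_percent,
    evaluate_scores,
    optimal_threshold,
    roc_and_auroc,
)
from .model_core import EncoderConfig, HeadConfig
from .training import OptimConfig, TrainSample, upsample_minority

log = logging.getLogger("chiasmnet")

SCHEMA_VERSION = 1


def _from_dict(cls, data: dict, path: str):
    """Strict dataclass construction: unknown keys are rejected."""
    data = dict(data or {})
    names = {f.name for f in fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys at {path}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class TagSpec:
    n_control: int = 0
    n_albinism: int = 0
    test_group: str = "test2"
    n_subsets: int = 0  # 0 -> use k


@dataclass
class CohortConfig:
    tags: dict = field(default_factory=lambda: dict(DEFAULT_TAGS))
    effects: dict = field(default_factory=dict)  # overrides of phantom.EffectConfig

    def effect_config(self) -> phantom.EffectConfig:
        return _from_dict(phantom.EffectConfig, {**self.effects}, "cohort.effects")

    def tag_specs(self) -> dict:
        return {tag: _from_dict(TagSpec, spec, f"cohort.tags.{tag}") for tag, spec in self.tags.items()}


@dataclass
class ModelConfig:
    encoder: dict = field(default_factory=dict)
    head: dict = field(default_factory=dict)

    def encoder_config(self) -> EncoderConfig:
        cfg = _from_dict(EncoderConfig, self.encoder, "model.encoder")
        cfg.channels_per_block = tuple(cfg.channels_per_block)
        return cfg

    def head_config(self) -> HeadConfig:
        return _from_dict(HeadConfig, self.head, "model.head")


@dataclass
class TrainingConfig:
    k: int = 8
    pretrain: dict = field(default_factory=lambda: {"epochs": 5})
    finetune: dict = field(default_factory=lambda: {"epochs": 20})

    def pretrain_config(self, seed: int) -> OptimConfig:
        cfg = _from_dict(OptimConfig, self.pretrain, "training.pretrain")
        cfg.seed = seed
        return cfg

    def finetune_config(self, seed: int) -> OptimConfig:
        cfg = _from_dict(OptimConfig, self.finetune, "training.finetune")
        cfg.seed = seed
        return cfg


@dataclass
class XaiConfig:
    enabled: bool = True
    fold: int = 0
    window_voxels: tuple = (4, 4, 2)
    stride_voxels: tuple = (2, 2, 1)
    fill: str = "background_mean"
    top_fraction: float = 0.05
    n_patches: int = 8

    def occlusion_spec(self) -> explain.OcclusionSpec:
        return explain.OcclusionSpec(tuple(self.window_voxels), tuple(self.stride_voxels), self.fill)


# default cohort: paper-like tag structure at roughly 1/8 of the control pool
DEFAULT_TAGS = {
    "ather": {"n_control": 24, "n_albinism": 24, "test_group": "test1"},
    "chiasm": {"n_control": 9, "n_albinism": 8, "test_group": "test1", "n_subsets": 9},
    "public0": {"n_control": 136, "test_group": "test2"},
}


@dataclass
class ExperimentConfig:
    cohort: CohortConfig = field(default_factory=CohortConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    xai: XaiConfig = field(default_factory=XaiConfig)

    @classmethod
    def from_dict(cls, data: dict) -> "ExperimentConfig":
        data = dict(data or {})
        unknown = set(data) - {"cohort", "model", "training", "xai"}
        if unknown:
            raise ConfigError(f"unknown top-level config keys: {sorted(unknown)}")
        config = cls(
            cohort=_from_dict(CohortConfig, data.get("cohort", {}), "cohort"),
            model=_from_dict(ModelConfig, data.get("model", {}), "model"),
            training=_from_dict(TrainingConfig, data.get("training", {}), "training"),
            xai=_from_dict(XaiConfig, data.get("xai", {}), "xai"),
        )
        # eager validation: unknown keys anywhere are rejected up front
        config.cohort.effect_config()
        config.cohort.tag_specs()
        config.model.encoder_config().validate()
        config.model.head_config()
        config.training.pretrain_config(0)
        config.training.finetune_config(0)
        config.xai.occlusion_spec()
        return config

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def composition(self) -> dict:
        tags = {}
        for tag, spec in self.cohort.tag_specs().items():
            entry = {"test_group": spec.test_group}
            if spec.n_subsets:
                entry["n_subsets"] = spec.n_subsets
            tags[tag] = entry
        return {"default_test_group": "test2", "balance_test1": True, "tags": tags}

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# stages


def _cohort_dir(out):
    return os.path.join(out, "cohort")


def stage_simulate(config: ExperimentConfig, seed: int, out) -> None:
    """Generate the phantom cohort (patches, masks, truth, manifest)."""
    samples = []
    for tag, spec in sorted(config.cohort.tag_specs().items()):
        samples.extend((0, tag) for _ in range(spec.n_control))
        samples.extend((1, tag) for _ in range(spec.n_albinism))
    effect = config.cohort.effect_config()
    cdir = _cohort_dir(out)
    manifest, patches, masks, _ = phantom.generate_tagged_cohort(samples, effect, cdir, seed=seed)
    for sid, mask in masks.items():
        write_volume(Volume(mask.astype(float), np.eye(4)), os.path.join(cdir, f"{sid}_mask.nii"))
    log.info("simulate: %d samples under %s", len(manifest), cdir)


def load_cohort(out):
    """Reload manifest, normalized patches and chiasm masks from cohort/."""
    cdir = _cohort_dir(out)
    manifest = load_manifest(os.path.join(cdir, "manifest.csv"), check_paths=False)
    patches, masks = {}, {}
    for row in manifest.df.itertuples():
        vol = read_volume(os.path.join(cdir, f"{row.sample_id}.nii"))
        patch = PatchVolume(vol.voxels, (row.cx, row.cy, row.cz), row.sample_id)
        patches[row.sample_id] = normalize_intensity(patch)
        masks[row.sample_id] = read_volume(os.path.join(cdir, f"{row.sample_id}_mask.nii")).voxels > 0.5
    return manifest, patches, masks


def stage_pretrain(config: ExperimentConfig, seed: int, out) -> None:
    """Autoencoder pretraining on chiasm-excluded patches."""
    manifest, patches, masks = load_cohort(out)
    excluded = [mask_chiasm_out(patches[sid], masks[sid], fill="background_mean") for sid in manifest.sample_ids]
    model = model_core.build_autoencoder(config.model.encoder_config(), seed=seed)
    _, history = training.pretrain_autoencoder(model, excluded, config.training.pretrain_config(seed))
    pdir = os.path.join(out, "pretrain")
    os.makedirs(pdir, exist_ok=True)
    model_core.save_checkpoint(model, os.path.join(pdir, "autoencoder.npz"))
    _write_history(history, os.path.join(pdir, "history.csv"))
    log.info("pretrain: selected epoch %d", history.selected_epoch)


def _write_history(history: training.TrainingHistory, path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in history.records])
    df["selected"] = [int(r.epoch == history.selected_epoch) for r in history.records]
    df.to_csv(path, index=False)


def _fold_dir(out, fold):
    return os.path.join(out, f"fold_{fold}")


def stage_train(config: ExperimentConfig, seed: int, out) -> None:
    """Per-fold classifier fine-tuning, threshold selection and scoring."""
    manifest, patches, masks = load_cohort(out)
    ae = model_core.load_checkpoint(os.path.join(out, "pretrain", "autoencoder.npz"))
    splits = training.make_fold_splits(manifest, k=config.training.k, composition=config.composition(), seed=seed)
    labels = dict(zip(manifest.df["sample_id"], manifest.df["label"]))
    for split in splits:
        fold_seed = seed + split.fold_index
        fdir = _fold_dir(out, split.fold_index)
        os.makedirs(fdir, exist_ok=True)
        for group in ("train", "dev", "test1", "test2"):
            ids = getattr(split, f"{group}_ids")
            with open(os.path.join(fdir, f"split_{group}.txt"), "w") as fh:
                fh.write("\n".join(ids) + "\n")

        up_train = upsample_minority([(s, labels[s]) for s in split.train_ids], seed=fold_seed)
        up_dev = upsample_minority([(s, labels[s]) for s in split.dev_ids], seed=fold_seed + 1)
        to_samples = lambda ups: [
            TrainSample(patches[u.sample_id].voxels, u.label, augment=u.replica_index > 0) for u in ups
        ]
        model = model_core.build_classifier(
            ae.encoder, config.model.head_config(), seed=fold_seed, config=config.model.encoder_config()
        )
        model, history = training.finetune_classifier(
            model, to_samples(up_train), to_samples(up_dev), config.training.finetune_config(fold_seed)
        )
        _write_history(history, os.path.join(fdir, "history.csv"))
        model_core.save_checkpoint(model, os.path.join(fdir, "checkpoint.npz"))

        dev_scores = model.predict_score([patches[s] for s in split.dev_ids])
        dev_labels = np.array([labels[s] for s in split.dev_ids])
        roc, _ = roc_and_auroc(dev_scores, dev_labels)
        threshold = optimal_threshold(roc)
        rows = [
            {"sample_id": s, "group": "dev", "label": labels[s], "score": sc}
            for s, sc in zip(split.dev_ids, dev_scores)
        ]
        for group in ("test1", "test2"):
            ids = getattr(split, f"{group}_ids")
            if not ids:
                continue
            scores = model.predict_score([patches[s] for s in ids])
            rows.extend(
                {"sample_id": s, "group": group, "label": labels[s], "score": sc} for s, sc in zip(ids, scores)
            )
        pd.DataFrame(rows).to_csv(os.path.join(fdir, "scores.csv"), index=False)
        with open(os.path.join(fdir, "threshold.json"), "w") as fh:
            json.dump({"threshold": threshold, "rule": "score >= threshold", "source": "dev Youden"}, fh)
        log.info("train: fold %d done (threshold %.4f)", split.fold_index, threshold)


def _fold_group_eval(scores_df: pd.DataFrame, threshold: float, group: str):
    sub = scores_df[scores_df["group"] == group]
    if sub.empty:
        return None
    scores = sub["score"].to_numpy()
    labels = sub["label"].to_numpy(dtype=int)
    return evaluate_scores(scores, labels, threshold)


def stage_evaluate(config: ExperimentConfig, seed: int, out) -> dict:
    """Fold-averaged metric tables and confusion matrices from scores.csv."""
    per_group = {"test1": [], "test2": []}
    per_fold_rows = []
    for f in range(config.training.k):
        fdir = _fold_dir(out, f)
        scores_df = pd.read_csv(os.path.join(fdir, "scores.csv"))
        with open(os.path.join(fdir, "threshold.json")) as fh:
            threshold = json.load(fh)["threshold"]
        dev = scores_df[scores_df["group"] == "dev"]
        roc, _ = roc_and_auroc(dev["score"].to_numpy(), dev["label"].to_numpy(dtype=int))
        pd.DataFrame({"threshold": roc.thresholds, "tpr": roc.tpr, "fpr": roc.fpr}).to_csv(
            os.path.join(out, f"roc_fold{f}.csv"), index=False
        )
        for group in ("test1", "test2"):
            result = _fold_group_eval(scores_df, threshold, group)
            if result is None:
                continue
            counts, report = result
            per_group[group].append((counts, report))
            row = {"fold": f, "group": group, "threshold": threshold}
            row.update(dataclasses.asdict(counts))
            row.update(report.as_dict())
            per_fold_rows.append(row)
    pd.DataFrame(per_fold_rows).to_csv(os.path.join(out, "metrics.csv"), index=False)

    summary = {"schema_version": SCHEMA_VERSION, "seed": seed, "k": config.training.k, "groups": {}}
    for group, per_fold in per_group.items():
        if not per_fold:
            continue
        agg = aggregate_folds(per_fold)
        summary["groups"][group] = {
            "mean": agg.mean,
            "sd": agg.sd,
            "n_defined": agg.n_defined,
            "mean_percent": {k: as_percent(v) for k, v in agg.mean.items()},
            "confusion_mean": dataclasses.asdict(agg.confusion),
            "n_folds": agg.n_folds,
        }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True, allow_nan=True)
    return summary


def stage_explain(config: ExperimentConfig, seed: int, out) -> None:
    """Attribution maps, localization scores and the class-average analysis."""
    if not config.xai.enabled:
        return
    manifest, patches, masks = load_cohort(out)
    fold = config.xai.fold
    fdir = _fold_dir(out, fold)
    model = model_core.load_checkpoint(os.path.join(fdir, "checkpoint.npz"))
    xdir = os.path.join(out, "xai")
    os.makedirs(xdir, exist_ok=True)
    spec = config.xai.occlusion_spec()

    with open(os.path.join(fdir, "split_test1.txt")) as fh:
        test_ids = [line.strip() for line in fh if line.strip()]
    rows = []
    for sid in test_ids[: config.xai.n_patches]:
        patch = patches[sid]
        occ = explain.occlusion_map(model, patch, spec)
        sal = explain.saliency_map(model, patch, signed=True)
        gxi = explain.gradient_x_input(model, patch)
        for amap in (occ, sal, gxi):
            write_volume(Volume(amap.values, np.eye(4)), os.path.join(xdir, f"{sid}_{amap.method}.nii"))
        rows.append(
            {
                "sample_id": sid,
                "occlusion_in_mask": explain.localization_score(occ, masks[sid], config.xai.top_fraction),
                "saliency_in_mask": explain.localization_score(sal, masks[sid], config.xai.top_fraction),
                "mask_fraction": float(np.mean(masks[sid])),
            }
        )
    pd.DataFrame(rows).to_csv(os.path.join(xdir, "localization.csv"), index=False)

    with open(os.path.join(fdir, "split_train.txt")) as fh:
        train_ids = [line.strip() for line in fh if line.strip()]
    labels = dict(zip(manifest.df["sample_id"], manifest.df["label"]))
    train_patches = [patches[s] for s in train_ids]
    train_labels = [labels[s] for s in train_ids]
    avg_c, avg_a, diff_ca, diff_ac = explain.class_average_and_difference(train_patches, train_labels)
    for name, arr in (
        ("avg_control", avg_c),
        ("avg_albinism", avg_a),
        ("diff_control_minus_albinism", diff_ca),
        ("diff_albinism_minus_control", diff_ac),
        ("mask_control_lt_0p75", explain.threshold_mask(avg_c, 0.75).astype(float)),
        ("mask_albinism_lt_0p60", explain.threshold_mask(avg_a, 0.60).astype(float)),
    ):
        write_volume(Volume(np.asarray(arr, dtype=float), np.eye(4)), os.path.join(xdir, f"{name}.nii"))
    _montage([avg_c, avg_a, diff_ca, diff_ac], ["avg control", "avg albinism", "C - A", "A - C"], os.path.join(xdir, "class_average_montage.png"))
    log.info("explain: wrote attribution maps for %d patches", len(rows))


def _montage(images, titles, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_slices = images[0].shape[2]
    fig, axes = plt.subplots(len(images), n_slices, figsize=(1.6 * n_slices, 1.8 * len(images)))
    axes = np.atleast_2d(axes)
    for r, (img, title) in enumerate(zip(images, titles)):
        for z in range(n_slices):
            ax = axes[r, z]
            ax.imshow(img[:, :, z].T, origin="lower", cmap="coolwarm" if "-" in title else "gray")
            ax.set_xticks([])
            ax.set_yticks([])
            if z == 0:
                ax.set_ylabel(title, fontsize=7)
    fig.suptitle("inferior -> superior slices", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=80)
    plt.close(fig)


def run_experiment(config: ExperimentConfig, seed: int, out) -> dict:
    """Full pipeline: simulate -> pretrain -> train -> evaluate -> explain."""
    os.makedirs(out, exist_ok=True)
    stages = [
        ("simulate", stage_simulate),
        ("pretrain", stage_pretrain),
        ("train", stage_train),
        ("evaluate", stage_evaluate),
        ("explain", stage_explain),
    ]
    summary = None
    for name, fn in stages:
        try:
            result = fn(config, seed, out)
        except Exception as exc:
            with open(os.path.join(out, "INCOMPLETE"), "w") as fh:
                fh.write(f"failed at stage {name}: {exc}\n")
            raise ChiasmNetError(f"stage '{name}' failed: {exc}") from exc
        if name == "evaluate":
            summary = result
    with open(os.path.join(out, "run_log.json"), "w") as fh:
        json.dump(
            {"seed": seed, "fold_seeds": [seed + f for f in range(config.training.k)], "config": config.as_dict()},
            fh,
            indent=1,
            sort_keys=True,
        )
    if os.path.exists(os.path.join(out, "INCOMPLETE")):
        os.remove(os.path.join(out, "INCOMPLETE"))
    return summary


def audit_run(out, k: int, atol: float = 1e-9) -> bool:
    """Recompute summary.json from the persisted per-fold artifacts."""
    with open(os.path.join(out, "summary.json")) as fh:
        summary = json.load(fh)
    per_group = {"test1": [], "test2": []}
    for f in range(k):
        fdir = _fold_dir(out, f)
        scores_df = pd.read_csv(os.path.join(fdir, "scores.csv"))
        with open(os.path.join(fdir, "threshold.json")) as fh:
            threshold = json.load(fh)["threshold"]
        for group in per_group:
            result = _fold_group_eval(scores_df, threshold, group)
            if result is not None:
                per_group[group].append(result)
    for group, per_fold in per_group.items():
        if not per_fold:
            continue
        agg = aggregate_folds(per_fold)
        stored = summary["groups"][group]
        for name, value in agg.mean.items():
            ref = stored["mean"][name]
            if ref is None or (isinstance(ref, float) and np.isnan(ref)):
                if not np.isnan(value):
                    return False
            elif abs(value - ref) > atol:
                return False
    return True


# ---------------------------------------------------------------------------
# CLI


def _apply_overrides(data: dict, overrides) -> dict:
    for item in overrides:
        key, _, raw = item.partition("=")
        if not _:
            raise ConfigError(f"--set expects key=value, got {item!r}")
        node = data
        parts = key.split(".")
        for part in parts[:-1]:
            node = node.setdefault(part, {})
        node[parts[-1]] = yaml.safe_load(raw)
    return data


def _load_config(config_path, overrides) -> ExperimentConfig:
    data = {}
    if config_path:
        with open(config_path) as fh:
            data = yaml.safe_load(fh) or {}
    data = _apply_overrides(data, overrides or ())
    return ExperimentConfig.from_dict(data)


_common = [
    click.option("--config", "config_path", type=click.Path(exists=True), default=None, help="experiment YAML"),
    click.option("--set", "overrides", multiple=True, help="dotted config override, e.g. training.k=4"),
    click.option("--seed", type=int, default=0, show_default=True),
    click.option("--out", "out_dir", type=click.Path(), required=True),
]


def _with_common(fn):
    for opt in reversed(_common):
        fn = opt(fn)
    return fn


@click.group()
@click.option("-v", "--verbose", is_flag=True)
def cli(verbose):
    """Chiasm-patch classification workbench."""
    logging.basicConfig(level=logging.INFO if verbose else logging.WARNING, format="%(levelname)s %(message)s")


def _stage_command(name, fn):
    @cli.command(name=name)
    @_with_common
    def _cmd(config_path, overrides, seed, out_dir, _fn=fn):
        config = _load_config(config_path, overrides)
        _fn(config, seed, out_dir)

    return _cmd


_stage_command("simulate", stage_simulate)
_stage_command("pretrain", stage_pretrain)
_stage_command("train", stage_train)
_stage_command("evaluate", stage_evaluate)
_stage_command("explain", stage_explain)


@cli.command(name="run-all")
@_with_common
def run_all_cmd(config_path, overrides, seed, out_dir):
    config = _load_config(config_path, overrides)
    summary = run_experiment(config, seed, out_dir)
    click.echo(json.dumps({g: v["mean_percent"] for g, v in summary["groups"].items()}, sort_keys=True))


@cli.command(name="audit")
@_with_common
def audit_cmd(config_path, overrides, seed, out_dir):
    config = _load_config(config_path, overrides)
    ok = audit_run(out_dir, k=config.training.k)
    click.echo("audit: OK" if ok else "audit: MISMATCH")
    if not ok:
        raise SystemExit(1)


if __name__ == "__main__":
    cli()
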