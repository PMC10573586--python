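"""Fold construction, minority upsampling, pretraining and fine-tuning.

The eight-fold scheme follows the multi-source recipe: within each
(dataset_tag, class) the samples are seeded-shuffled and cut into
``n_subsets`` near-equal parts (remainder spread over the *last* subsets);
per fold f, subset (f + j) % n_subsets takes role j with

* j < k-2          -> TRAIN          (six subsets when k = 8)
* j = k-2          -> DEV_TRAIN
* j = k-1          -> the tag's test group (TEST1 or TEST2)
* j >= k           -> TEST2          (only when n_subsets = k+1)

TEST1 is then balanced by moving excess majority-class samples to TEST2.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn
from .data_io import CohortManifest, manifest_from_rows
from .errors import (
    ConfigError,
    DataError,
    MonitoringError,
    SplitError,
    UpsamplingError,
)
from .evaluation import UNDEFINED, roc_and_auroc
from .model_core import AutoencoderModel, ClassifierModel
from .errors import UndefinedMetricError


@dataclass
class FoldSplit:
    fold_index: int
    train_ids: list
    dev_ids: list
    test1_ids: list
    test2_ids: list
    upsampling_factor: int

    def validate(self) -> None:
        groups = [self.train_ids, self.dev_ids, self.test1_ids, self.test2_ids]
        seen = set()
        for g in groups:
            s = set(g)
            if s & seen:
                raise SplitError(f"fold {self.fold_index}: overlapping groups: {sorted(s & seen)}")
            seen |= s
        if self.upsampling_factor < 1:
            raise SplitError("upsampling_factor must be >= 1")

    @property
    def all_ids(self) -> set:
        return set(self.train_ids) | set(self.dev_ids) | set(self.test1_ids) | set(self.test2_ids)


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    dev_loss: float
    dev_auroc: float = UNDEFINED


@dataclass
class TrainingHistory:
    records: list = field(default_factory=list)
    selected_epoch: int = -1


DEFAULT_COMPOSITION = {
    "default_test_group": "test2",
    "balance_test1": True,
    "tags": {},
}


def upsampling_factor(n_majority: int, n_minority: int) -> int:
    if n_minority <= 0 or n_majority <= 0:
        raise UpsamplingError("both classes must be present")
    return max(int(np.rint(n_majority / n_minority)), 1)


def _subset_sizes(n: int, n_subsets: int) -> list:
    """Near-equal sizes with the remainder spread over the last subsets."""
    q, r = divmod(n, n_subsets)
    return [q + (1 if i >= n_subsets - r else 0) for i in range(n_subsets)]


def make_fold_splits(manifest: CohortManifest, k: int = 8, composition: dict | None = None, seed: int = 0) -> list:
    """Build k FoldSplits per the rotating multi-source recipe above."""
    comp = dict(DEFAULT_COMPOSITION)
    comp.update(composition or {})
    tag_cfg = comp.get("tags", {})
    if k < 2:
        raise SplitError("k must be >= 2")
    df = manifest.df
    rng = np.random.default_rng(seed)

    # per (tag, class): shuffled ids cut into subsets
    subset_table = {}
    for tag in sorted(df["dataset_tag"].unique()):
        cfg = tag_cfg.get(tag, {})
        n_subsets = int(cfg.get("n_subsets", k))
        if n_subsets not in (k, k + 1):
            raise SplitError(f"tag {tag}: n_subsets must be k or k+1, got {n_subsets}")
        for label in (0, 1):
            ids = df.loc[(df["dataset_tag"] == tag) & (df["label"] == label), "sample_id"].tolist()
            if not ids:
                continue
            if len(ids) < k and tag not in tag_cfg:
                raise SplitError(
                    f"tag {tag} has only {len(ids)} class-{label} samples (< k={k}); "
                    "reassign it explicitly in composition['tags']"
                )
            ids = list(ids)
            rng_tc = np.random.default_rng([seed, zlib.crc32(tag.encode()) & 0x7FFFFFFF, label])
            rng_tc.shuffle(ids)
            sizes = _subset_sizes(len(ids), n_subsets)
            subsets, pos = [], 0
            for size in sizes:
                subsets.append(ids[pos : pos + size])
                pos += size
            subset_table[(tag, label)] = subsets

    labels_by_id = dict(zip(df["sample_id"], df["label"]))
    splits = []
    for f in range(k):
        groups = {"train": [], "dev": [], "test1": [], "test2": []}
        for (tag, label), subsets in sorted(subset_table.items(), key=lambda kv: (kv[0][0], kv[0][1])):
            cfg = tag_cfg.get(tag, {})
            test_group = cfg.get("test_group", comp["default_test_group"])
            n_subsets = len(subsets)
            for j in range(n_subsets):
                subset = subsets[(f + j) % n_subsets]
                if j < k - 2:
                    groups["train"].extend(subset)
                elif j == k - 2:
                    groups["dev"].extend(subset)
                elif j == k - 1:
                    groups[test_group].extend(subset)
                else:  # j >= k, only for n_subsets = k+1
                    groups["test2"].extend(subset)
        if comp.get("balance_test1", True):
            t1 = groups["test1"]
            by_class = {0: [s for s in t1 if labels_by_id[s] == 0], 1: [s for s in t1 if labels_by_id[s] == 1]}
            n_keep = min(len(by_class[0]), len(by_class[1]))
            kept, moved = [], []
            for label in (0, 1):
                kept.extend(by_class[label][:n_keep])
                moved.extend(by_class[label][n_keep:])
            groups["test1"] = kept
            groups["test2"].extend(moved)
        train_labels = np.array([labels_by_id[s] for s in groups["train"]])
        n0, n1 = int((train_labels == 0).sum()), int((train_labels == 1).sum())
        # degenerate TRAIN (possible for k = 2, where no subset takes role j < k-2)
        # keeps the sentinel factor 1; upsampling itself rejects it later
        factor = upsampling_factor(max(n0, n1), min(n0, n1)) if n0 and n1 else 1
        split = FoldSplit(f, groups["train"], groups["dev"], groups["test1"], groups["test2"], factor)
        split.validate()
        if split.all_ids != set(df["sample_id"]):
            raise SplitError(f"fold {f}: groups do not cover the cohort")
        splits.append(split)
    return splits


@dataclass
class UpsampledSample:
    sample_id: str
    label: int
    replica_index: int  # 0 = original; > 0 receives independent augmentation


def upsample_minority(samples, seed: int = 0, shuffle: bool = False) -> list:
    """Repeat each minority sample round(n_maj/n_min) times, replicas inline.

    Order is preserved by default (balanced input comes back unchanged);
    batch samplers shuffle downstream, so ``shuffle`` is opt-in.
    """
    samples = list(samples)
    labels = np.array([label for _, label in samples])
    n0, n1 = int((labels == 0).sum()), int((labels == 1).sum())
    if n0 == 0 or n1 == 0:
        raise UpsamplingError("both classes must be present for upsampling")
    minority = 1 if n1 < n0 else 0
    factor = upsampling_factor(max(n0, n1), min(n0, n1))
    out = []
    for sid, label in samples:
        reps = factor if label == minority and n0 != n1 else 1
        out.extend(UpsampledSample(sid, int(label), r) for r in range(reps))
    if shuffle:
        np.random.default_rng(seed).shuffle(out)
    return out


# ---------------------------------------------------------------------------
# augmentation


def rigid_jitter(patch: np.ndarray, rng, max_translation_mm: float = 2.0, max_rotation_deg: float = 5.0) -> np.ndarray:
    """Small random rigid transform of the patch image (trilinear, edge-padded)."""
    angles = np.deg2rad(rng.uniform(-max_rotation_deg, max_rotation_deg, 3))
    shift = rng.uniform(-max_translation_mm, max_translation_mm, 3)
    cx, sx = np.cos(angles[0]), np.sin(angles[0])
    cy, sy = np.cos(angles[1]), np.sin(angles[1])
    cz, sz = np.cos(angles[2]), np.sin(angles[2])
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = rz @ ry @ rx
    center = (np.array(patch.shape) - 1) / 2.0
    offset = center - rot @ (center + shift)
    return ndimage.affine_transform(patch, rot, offset=offset, order=1, mode="nearest")


@dataclass
class OptimConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    seed: int = 0
    holdout_fraction: float = 0.2  # autoencoder pretraining only
    unfreeze_encoder: bool = True
    selection: str = "max_dev_auroc"  # or "min_dev_loss"
    augment: bool = True
    aug_translation_mm: float = 2.0
    aug_rotation_deg: float = 5.0


def _batches(n: int, batch_size: int, rng) -> list:
    order = rng.permutation(n)
    return [order[i : i + batch_size] for i in range(0, n, batch_size)]


def pretrain_autoencoder(model: AutoencoderModel, patches, config: OptimConfig = OptimConfig()):
    """MSE autoencoder training with a seeded holdout; returns (encoder, history).

    ``patches`` must already be chiasm-excluded (see data_io.mask_chiasm_out).
    """
    arrays = [p.voxels if hasattr(p, "voxels") else np.asarray(p, dtype=float) for p in patches]
    if not arrays:
        raise DataError("no pretraining samples")
    x = np.stack(arrays)[:, None]
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(arrays))
    n_hold = max(1, int(round(config.holdout_fraction * len(arrays)))) if len(arrays) > 1 else 0
    hold, train = order[:n_hold], order[n_hold:]
    if train.size == 0:
        train, hold = hold, train
    x_train, x_hold = x[train], x[hold]

    params = model.all_params
    grads = model.all_grads
    opt = nn.Adam(params, grads, lr=config.learning_rate)
    history = TrainingHistory()
    best = (np.inf, -1, None)
    for epoch in range(config.epochs):
        epoch_losses = []
        for idx in _batches(len(x_train), config.batch_size, rng):
            xb = x_train[idx]
            recon = model.decoder.forward(model.encoder.forward(xb))
            loss, grad = nn.mse_loss(recon, xb)
            for g in grads:
                g[...] = 0.0
            model.encoder.backward(model.decoder.backward(grad))
            opt.step()
            epoch_losses.append(loss)
        if x_hold.size:
            recon = model.decoder.forward(model.encoder.forward(x_hold))
            dev_loss, _ = nn.mse_loss(recon, x_hold)
        else:
            dev_loss = float(np.mean(epoch_losses))
        history.records.append(EpochRecord(epoch, float(np.mean(epoch_losses)), dev_loss))
        if dev_loss < best[0]:
            state = model.encoder.get_state() + model.decoder.get_state()
            best = (dev_loss, epoch, state)
    if best[2] is not None:
        n_enc = len(model.encoder.all_params)
        model.encoder.set_state(best[2][:n_enc])
        model.decoder.set_state(best[2][n_enc:])
        history.selected_epoch = best[1]
    return model.encoder, history


@dataclass
class TrainSample:
    patch: np.ndarray
    label: int
    augment: bool = False  # replicas get independent per-epoch jitter


def _assemble(samples, config, rng, augment: bool):
    xs = []
    for s in samples:
        p = s.patch
        if augment and s.augment and config.augment:
            p = rigid_jitter(p, rng, config.aug_translation_mm, config.aug_rotation_deg)
        xs.append(p)
    x = np.stack(xs)[:, None]
    y = np.array([s.label for s in samples], dtype=float)
    return x, y


def select_checkpoint(history: TrainingHistory, criterion: str = "max_dev_auroc") -> int:
    """Argmax/argmin over epochs; ties broken toward the earliest epoch."""
    if not history.records:
        raise DataError("empty training history")
    if criterion == "max_dev_auroc":
        values = [r.dev_auroc for r in history.records]
        if np.all(np.isnan(values)):
            raise MonitoringError("dev AUROC undefined for every epoch")
        best = np.nanmax(values)
        return int(next(i for i, v in enumerate(values) if v == best))
    if criterion == "min_dev_loss":
        values = [r.dev_loss for r in history.records]
        best = np.nanmin(values)
        return int(next(i for i, v in enumerate(values) if v == best))
    raise ConfigError(f"unknown selection criterion: {criterion}")


def finetune_classifier(model: ClassifierModel, train, dev, config: OptimConfig = OptimConfig()):
    """Binary cross-entropy fine-tuning with checkpoint selection on dev.

    ``train`` and ``dev`` are lists of TrainSample (already upsampled; dev
    replicas are augmented once at setup so monitoring stays stable).
    """
    train = list(train)
    dev = list(dev)
    dev_labels = np.array([s.label for s in dev], dtype=int)
    if dev and len(set(dev_labels.tolist())) < 2:
        raise MonitoringError("dev set must contain both classes")
    rng = np.random.default_rng(config.seed)
    x_dev, y_dev = _assemble(dev, config, rng, augment=True) if dev else (None, None)

    if config.unfreeze_encoder:
        params, grads = model.all_params, model.all_grads
    else:
        params, grads = model.head.all_params, model.head.all_grads
    opt = nn.Adam(params, grads, lr=config.learning_rate)
    history = TrainingHistory()
    snapshots = []
    for epoch in range(config.epochs):
        x, y = _assemble(train, config, rng, augment=True)
        epoch_losses = []
        for idx in _batches(len(train), config.batch_size, rng):
            z = model.head.forward(model.encoder.forward(x[idx]))
            sig = nn.Sigmoid()
            score = sig.forward(z)
            loss, gs = nn.bce_loss(score, y[idx][:, None])
            model.zero_grad()
            model.encoder.backward(model.head.backward(sig.backward(gs)))
            opt.step()
            epoch_losses.append(loss)
        dev_score = model.predict_score(x_dev) if dev else np.array([])
        dev_loss, _ = nn.bce_loss(dev_score, y_dev) if dev else (UNDEFINED, None)
        try:
            _, dev_auroc = roc_and_auroc(dev_score, dev_labels) if dev else (None, UNDEFINED)
        except UndefinedMetricError:
            dev_auroc = UNDEFINED
        history.records.append(EpochRecord(epoch, float(np.mean(epoch_losses)), dev_loss, dev_auroc))
        snapshots.append(model.encoder.get_state() + model.head.get_state())
    if history.records:
        history.selected_epoch = select_checkpoint(history, config.selection)
        state = snapshots[history.selected_epoch]
        n_enc = len(model.encoder.all_params)
        model.encoder.set_state(state[:n_enc])
        model.head.set_state(state[n_enc:])
    return model, history


def build_paper_mirror_manifest() -> CohortManifest:
    """A cohort whose tag structure reproduces the printed fold-0 group sizes.

    Tags: one balanced clinical source (24/24), one small mixed source of
    9 controls + 8 albinism cut into 9 subsets, and five control-only public
    sources (401/322/322/323/307). Fold 0 then yields TRAIN (1274, 23),
    DEV_TRAIN (216, 4), TEST1 (4, 4), TEST2 (214, 1).
    """
    rows = []

    def add(tag, label, count):
        start = len([r for r in rows if r[2] == label])
        for i in range(count):
            rows.append((f"{'c' if label == 0 else 'a'}{start + i:05d}", f"{tag}.nii", label, tag, (0.0, 0.0, 0.0)))

    add("ather", 0, 24)
    add("ather", 1, 24)
    add("chiasm", 0, 9)
    add("chiasm", 1, 8)
    for i, n in enumerate((401, 322, 322, 323, 307)):
        add(f"public{i}", 0, n)
    return manifest_from_rows(rows)


PAPER_MIRROR_COMPOSITION = {
    "default_test_group": "test2",
    "balance_test1": True,
    "tags": {
        "ather": {"test_group": "test1"},
        "chiasm": {"test_group": "test1", "n_subsets": 9},
    },
}
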