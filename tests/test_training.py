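import dataclasses

import numpy as np
import pytest

from chiasmnet.data_io import manifest_from_rows
from chiasmnet.errors import MonitoringError, SplitError, UpsamplingError, DataError
from chiasmnet.model_core import EncoderConfig, build_autoencoder, build_fresh_classifier
from chiasmnet.training import (
    PAPER_MIRROR_COMPOSITION,
    EpochRecord,
    OptimConfig,
    TrainingHistory,
    TrainSample,
    build_paper_mirror_manifest,
    finetune_classifier,
    make_fold_splits,
    pretrain_autoencoder,
    rigid_jitter,
    select_checkpoint,
    upsample_minority,
    upsampling_factor,
)

from conftest import STRONG_EFFECTS, ZERO_EFFECTS, as_train_samples, render_cohort


def group_counts(ids, labels_by_id):
    arr = np.array([labels_by_id[s] for s in ids]) if ids else np.array([])
    return (int((arr == 0).sum()), int((arr == 1).sum()))


@pytest.fixture(scope="module")
def mirror():
    manifest = build_paper_mirror_manifest()
    splits = make_fold_splits(manifest, k=8, composition=PAPER_MIRROR_COMPOSITION, seed=0)
    labels = dict(zip(manifest.df["sample_id"], manifest.df["label"]))
    return manifest, splits, labels


class TestFoldSplits:
    def test_fold0_train_counts_match_printed_composition(self, mirror):
        _, splits, labels = mirror
        assert group_counts(splits[0].train_ids, labels) == (1274, 23)

    def test_fold0_dev_counts(self, mirror):
        _, splits, labels = mirror
        assert group_counts(splits[0].dev_ids, labels) == (216, 4)

    def test_fold0_test_groups(self, mirror):
        _, splits, labels = mirror
        assert group_counts(splits[0].test1_ids, labels) == (4, 4)
        assert group_counts(splits[0].test2_ids, labels) == (214, 1)
        assert splits[0].upsampling_factor == 55

    def test_no_leakage_any_fold(self, mirror):
        manifest, splits, _ = mirror
        for split in splits:
            train_dev = set(split.train_ids) | set(split.dev_ids)
            test = set(split.test1_ids) | set(split.test2_ids)
            assert not train_dev & test
            assert split.all_ids == set(manifest.df["sample_id"])

    def test_test1_balanced_every_fold(self, mirror):
        _, splits, labels = mirror
        for split in splits:
            n0, n1 = group_counts(split.test1_ids, labels)
            assert n0 == n1

    def test_every_sample_tested_at_least_once(self, mirror):
        manifest, splits, _ = mirror
        tested = set()
        for split in splits:
            tested |= set(split.test1_ids) | set(split.test2_ids)
        assert tested == set(manifest.df["sample_id"])

    def test_deterministic_under_seed(self):
        manifest = build_paper_mirror_manifest()
        a = make_fold_splits(manifest, k=8, composition=PAPER_MIRROR_COMPOSITION, seed=5)
        b = make_fold_splits(manifest, k=8, composition=PAPER_MIRROR_COMPOSITION, seed=5)
        for sa, sb in zip(a, b):
            assert sa.train_ids == sb.train_ids and sa.test2_ids == sb.test2_ids

    def test_toy_k4_exhaustive(self):
        rows = [(f"s{i}", "x.nii", i % 2, "t", (0, 0, 0)) for i in range(8)]
        manifest = manifest_from_rows(rows)
        splits = make_fold_splits(manifest, k=4, composition={"tags": {"t": {"test_group": "test1"}}}, seed=1)
        all_ids = {f"s{i}" for i in range(8)}
        for split in splits:
            groups = [set(split.train_ids), set(split.dev_ids), set(split.test1_ids), set(split.test2_ids)]
            for i, g1 in enumerate(groups):
                for g2 in groups[i + 1 :]:
                    assert not g1 & g2
            assert set.union(*groups) == all_ids

    def test_toy_k2_disjoint_and_covering(self):
        rows = [(f"s{i}", "x.nii", i % 2, "t", (0, 0, 0)) for i in range(8)]
        manifest = manifest_from_rows(rows)
        splits = make_fold_splits(manifest, k=2, composition={"tags": {"t": {"test_group": "test1"}}}, seed=1)
        for split in splits:
            assert split.all_ids == {f"s{i}" for i in range(8)}

    def test_small_tag_without_composition_rejected(self):
        rows = [(f"s{i}", "x.nii", i % 2, "tiny", (0, 0, 0)) for i in range(4)]
        manifest = manifest_from_rows(rows)
        with pytest.raises(SplitError):
            make_fold_splits(manifest, k=8, seed=0)


class TestUpsampling:
    def test_printed_train_composition_gives_factor_55(self):
        assert upsampling_factor(1274, 23) == 55  # round(1274/23)

    def test_balanced_input_unchanged(self):
        samples = [(f"s{i}", i % 2) for i in range(20)]
        out = upsample_minority(samples, seed=0)
        assert [(u.sample_id, u.label) for u in out] == samples

    def test_7_vs_2(self):
        samples = [(f"m{i}", 0) for i in range(7)] + [("a", 1), ("b", 1)]
        out = upsample_minority(samples, seed=0)
        minority = [u for u in out if u.label == 1]
        assert upsampling_factor(7, 2) == 4
        assert len(minority) == 8
        assert len([u for u in out if u.label == 0]) == 7

    def test_single_class_rejected(self):
        with pytest.raises(UpsamplingError):
            upsample_minority([("a", 1), ("b", 1)], seed=0)

    def test_preserves_distinct_minority_ids(self):
        samples = [(f"m{i}", 0) for i in range(50)] + [("a", 1), ("b", 1), ("c", 1)]
        out = upsample_minority(samples, seed=3)
        assert {u.sample_id for u in out if u.label == 1} == {"a", "b", "c"}
        # repetition only: every replica points at an existing id
        assert {u.sample_id for u in out} == {s for s, _ in samples}

    def test_post_hoc_ratio_within_factor_two(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n0, n1 = int(rng.integers(1, 200)), int(rng.integers(1, 200))
            samples = [(f"c{i}", 0) for i in range(n0)] + [(f"a{i}", 1) for i in range(n1)]
            out = upsample_minority(samples, seed=0)
            labels = np.array([u.label for u in out])
            hi, lo = max((labels == 0).sum(), (labels == 1).sum()), min((labels == 0).sum(), (labels == 1).sum())
            assert hi / lo <= 2.0


class TestSelectCheckpoint:
    @staticmethod
    def history(aurocs=None, losses=None):
        n = len(aurocs or losses)
        return TrainingHistory(
            records=[
                EpochRecord(i, 0.0, (losses or [0.0] * n)[i], (aurocs or [0.5] * n)[i]) for i in range(n)
            ]
        )

    def test_argmax_auroc(self):
        assert select_checkpoint(self.history(aurocs=[0.5, 0.9, 0.7])) == 1

    def test_tie_goes_to_earliest(self):
        assert select_checkpoint(self.history(aurocs=[0.8, 0.8, 0.8])) == 0

    def test_min_dev_loss(self):
        assert select_checkpoint(self.history(losses=[0.5, 0.2, 0.3]), "min_dev_loss") == 1

    def test_matches_linear_scan(self):
        rng = np.random.default_rng(1)
        values = rng.random(100)
        h = self.history(aurocs=list(values))
        best = 0
        for i, v in enumerate(values):
            if v > values[best]:
                best = i
        assert select_checkpoint(h) == best

    def test_empty_history_rejected(self):
        with pytest.raises(DataError):
            select_checkpoint(TrainingHistory())


@pytest.fixture(scope="module")
def masked_patches():
    from chiasmnet.data_io import PatchVolume, mask_chiasm_out

    cohort = render_cohort(30, 0, ZERO_EFFECTS, seed0=200)
    return [mask_chiasm_out(PatchVolume(p), m).voxels for p, _, m, _ in cohort]


class TestPretrain:
    def test_heldout_loss_decreases(self, masked_patches):
        model = build_autoencoder(EncoderConfig(latent_dim=16), seed=0)
        cfg = OptimConfig(epochs=6, batch_size=8, learning_rate=1e-3, seed=0)
        _, history = pretrain_autoencoder(model, masked_patches, cfg)
        assert history.records[history.selected_epoch].dev_loss < history.records[0].dev_loss

    def test_zero_learning_rate_is_noop(self, masked_patches):
        model = build_autoencoder(EncoderConfig(latent_dim=16), seed=1)
        before = [p.copy() for p in model.all_params]
        cfg = OptimConfig(epochs=3, batch_size=8, learning_rate=0.0, seed=0)
        _, history = pretrain_autoencoder(model, masked_patches, cfg)
        for p, b in zip(model.all_params, before):
            assert np.array_equal(p, b)
        losses = [r.train_loss for r in history.records]
        assert max(losses) - min(losses) < 1e-12

    def test_identical_seeds_identical_curves(self, masked_patches):
        curves = []
        for _ in range(2):
            model = build_autoencoder(EncoderConfig(latent_dim=16), seed=2)
            cfg = OptimConfig(epochs=3, batch_size=8, learning_rate=1e-3, seed=7)
            _, history = pretrain_autoencoder(model, masked_patches, cfg)
            curves.append([(r.train_loss, r.dev_loss) for r in history.records])
        assert curves[0] == curves[1]

    def test_empty_input_rejected(self):
        model = build_autoencoder(EncoderConfig(latent_dim=16), seed=0)
        with pytest.raises(DataError):
            pretrain_autoencoder(model, [], OptimConfig(epochs=1))


class TestFinetune:
    def test_zero_epochs_returns_input_model(self):
        cohort = render_cohort(4, 4, STRONG_EFFECTS, seed0=300)
        model = build_fresh_classifier(seed=0)
        x = cohort[0][0]
        before = float(model.predict_score(x))
        model, history = finetune_classifier(
            model, as_train_samples(cohort), as_train_samples(cohort), OptimConfig(epochs=0)
        )
        assert float(model.predict_score(x)) == before
        assert history.records == []

    def test_single_class_dev_rejected(self):
        cohort = render_cohort(4, 4, STRONG_EFFECTS, seed0=300)
        dev = [s for s in as_train_samples(cohort) if s.label == 0]
        with pytest.raises(MonitoringError):
            finetune_classifier(build_fresh_classifier(seed=0), as_train_samples(cohort), dev, OptimConfig(epochs=1))

    def test_deterministic_history(self):
        cohort = render_cohort(6, 6, STRONG_EFFECTS, seed0=400)
        hists = []
        for _ in range(2):
            model = build_fresh_classifier(seed=3)
            _, h = finetune_classifier(
                model,
                as_train_samples(cohort),
                as_train_samples(cohort),
                OptimConfig(epochs=2, seed=5, batch_size=8),
            )
            hists.append([(r.train_loss, r.dev_loss, r.dev_auroc) for r in h.records])
        assert hists[0] == hists[1]

    def test_strong_effects_reach_high_dev_auroc(self):
        # scaled-down single-seed analogue of the separability contract
        train = render_cohort(24, 24, STRONG_EFFECTS, seed0=500)
        dev = render_cohort(8, 8, STRONG_EFFECTS, seed0=600)
        model = build_fresh_classifier(seed=0)
        _, h = finetune_classifier(
            model, as_train_samples(train), as_train_samples(dev), OptimConfig(epochs=6, seed=0, augment=False)
        )
        assert h.records[h.selected_epoch].dev_auroc >= 0.9

    def test_separability_monotone_in_effect_size(self):
        # mean dev AUROC over the effect grid {0x, 0.5x, 1x} of the strong effects
        def scaled(f):
            return dataclasses.replace(
                STRONG_EFFECTS,
                width_ratio=1.0 - (1.0 - STRONG_EFFECTS.width_ratio) * f,
                tract_angle_offset_deg=STRONG_EFFECTS.tract_angle_offset_deg * f,
                central_boost=STRONG_EFFECTS.central_boost * f,
            )

        aurocs = []
        for f in (0.0, 0.5, 1.0):
            per_seed = []
            for seed in (0, 1):
                train = render_cohort(16, 16, scaled(f), seed0=seed * 10_000)
                dev = render_cohort(8, 8, scaled(f), seed0=seed * 10_000 + 5_000)
                model = build_fresh_classifier(seed=seed)
                _, h = finetune_classifier(
                    model,
                    as_train_samples(train),
                    as_train_samples(dev),
                    OptimConfig(epochs=5, seed=seed, augment=False),
                )
                per_seed.append(h.records[h.selected_epoch].dev_auroc)
            aurocs.append(float(np.mean(per_seed)))
        assert aurocs[0] == pytest.approx(0.5, abs=0.25)
        assert aurocs[2] >= aurocs[0] - 0.05
        assert aurocs[2] >= 0.9


class TestJitterAugment:
    def test_preserves_shape_and_range(self):
        rng = np.random.default_rng(0)
        patch = rng.random((24, 24, 8))
        out = rigid_jitter(patch, rng)
        assert out.shape == patch.shape
        assert out.min() >= patch.min() - 1e-9 and out.max() <= patch.max() + 1e-9

    def test_zero_amplitude_is_identity(self):
        rng = np.random.default_rng(1)
        patch = rng.random((24, 24, 8))
        out = rigid_jitter(patch, rng, max_translation_mm=0.0, max_rotation_deg=0.0)
        assert np.allclose(out, patch, atol=1e-12)
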