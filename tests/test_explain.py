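import numpy as np
import pytest

from chiasmnet import nn
from chiasmnet.data_io import DEFAULT_GEOMETRY, PatchVolume
from chiasmnet.errors import ShapeError, UndefinedMetricError, ValidationError
from chiasmnet.explain import (
    AttributionMap,
    OcclusionSpec,
    class_average_and_difference,
    gradient_x_input,
    localization_score,
    occlusion_map,
    saliency_map,
    threshold_mask,
)
from chiasmnet.model_core import (
    ClassifierModel,
    ConstantScoreModel,
    EncoderConfig,
    HeadConfig,
    build_fresh_classifier,
)
from chiasmnet.phantom import (
    EffectConfig,
    central_crossing_mask,
    lateral_band_mask,
    render_phantom_full,
    sample_phantom_params,
)

SHAPE = DEFAULT_GEOMETRY.shape


def rand_patch(seed=0):
    return np.random.default_rng(seed).random(SHAPE)


class AdditiveModel:
    """score = sum of voxels (identity squash surrogate); exact oracle host."""

    def __init__(self, weights=None):
        self.w = np.ones(SHAPE) if weights is None else np.asarray(weights, dtype=float)

    def predict_score(self, x):
        x = np.asarray(x, dtype=float)
        if x.shape == SHAPE:
            return float((self.w * x).sum())
        if x.ndim == 5:
            x = x[:, 0]
        return (self.w[None] * x).sum(axis=(1, 2, 3))

    def input_gradient(self, x, target="score"):
        return self.w.copy()


def linear_classifier(seed=0):
    """A ClassifierModel that is exactly linear up to the logistic squash."""
    cfg = EncoderConfig(n_blocks=1, channels_per_block=(2,), latent_dim=8, nonlinearity="identity")
    model = build_fresh_classifier(cfg, HeadConfig(hidden=4), seed=seed)
    rng = np.random.default_rng(seed + 100)
    # replace the ELU head with a single dense layer: logit = w . latent + b
    model.head = nn.Sequential([nn.Dense(cfg.latent_dim, 1, rng=rng)])
    return model


class TestSaliency:
    def test_constant_model_zero_map(self):
        amap = saliency_map(ConstantScoreModel(0.7), rand_patch())
        assert not amap.values.any()
        assert amap.method == "saliency"

    def test_unsigned_is_absolute_value(self):
        model = build_fresh_classifier(seed=1)
        x = rand_patch(1)
        signed = saliency_map(model, x, signed=True)
        unsigned = saliency_map(model, x, signed=False)
        assert np.array_equal(unsigned.values, np.abs(signed.values))

    def test_linear_model_gradient_is_input_independent(self):
        model = linear_classifier(seed=0)
        g1 = model.input_gradient(rand_patch(1), target="logit")
        g2 = model.input_gradient(rand_patch(2), target="logit")
        assert np.allclose(g1, g2, atol=1e-12)

    @pytest.mark.parametrize("model_seed", [0, 3])
    def test_matches_central_finite_differences(self, model_seed):
        model = build_fresh_classifier(seed=model_seed)
        x = rand_patch(model_seed)
        amap = saliency_map(model, x, signed=True)
        rng = np.random.default_rng(5)
        h = 1e-3
        for _ in range(20):
            idx = tuple(rng.integers(0, d) for d in SHAPE)
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (float(model.predict_score(xp)) - float(model.predict_score(xm))) / (2 * h)
            assert amap.values[idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)

    def test_trained_model_finite_differences(self, trained_strong_model, strong_test_cohort):
        model = trained_strong_model
        x = strong_test_cohort[0][0]
        amap = saliency_map(model, x, signed=True)
        rng = np.random.default_rng(6)
        h = 1e-3
        for _ in range(20):
            idx = tuple(rng.integers(0, d) for d in SHAPE)
            xp, xm = x.copy(), x.copy()
            xp[idx] += h
            xm[idx] -= h
            fd = (float(model.predict_score(xp)) - float(model.predict_score(xm))) / (2 * h)
            assert amap.values[idx] == pytest.approx(fd, rel=1e-3, abs=1e-9)


class TestGradXInput:
    def test_zero_patch_zero_map(self):
        model = build_fresh_classifier(seed=0)
        amap = gradient_x_input(model, np.zeros(SHAPE))
        assert not amap.values.any()

    def test_constant_model_zero_map(self):
        amap = gradient_x_input(ConstantScoreModel(0.5), rand_patch())
        assert not amap.values.any()

    def test_completeness_for_linear_model(self):
        model = linear_classifier(seed=2)
        x = rand_patch(4)
        amap = gradient_x_input(model, x, target="logit")
        logit_diff = float(model.predict_logit(x)) - float(model.predict_logit(np.zeros(SHAPE)))
        assert amap.values.sum() == pytest.approx(logit_diff, rel=1e-9, abs=1e-12)


class TestOcclusion:
    def test_constant_model_zero_map(self):
        amap = occlusion_map(ConstantScoreModel(0.4), rand_patch(), OcclusionSpec())
        assert not amap.values.any()

    def test_additive_model_window_equals_window_sum(self):
        # window == stride, fill zero: each voxel covered by exactly one window,
        # whose delta equals that window's voxel sum
        x = rand_patch(7)
        spec = OcclusionSpec(window_voxels=(4, 4, 2), stride_voxels=(4, 4, 2), fill="zero")
        amap = occlusion_map(AdditiveModel(), x, spec)
        for i, j, l in [(0, 0, 0), (4, 8, 2), (20, 20, 6)]:
            expected = x[i : i + 4, j : j + 4, l : l + 2].sum()
            assert np.allclose(amap.values[i : i + 4, j : j + 4, l : l + 2], expected)

    def test_full_patch_window_single_delta(self):
        x = rand_patch(8)
        model = AdditiveModel()
        spec = OcclusionSpec(window_voxels=(24, 24, 8), stride_voxels=(1, 1, 1), fill="zero")
        amap = occlusion_map(model, x, spec)
        delta = model.predict_score(x) - model.predict_score(np.zeros(SHAPE))
        assert np.allclose(amap.values, delta)

    def test_ignored_region_gets_exact_zero(self):
        # model reads only the left half; windows inside the right half -> 0
        w = np.zeros(SHAPE)
        w[:12] = 1.0
        amap = occlusion_map(AdditiveModel(w), rand_patch(9), OcclusionSpec((4, 4, 2), (4, 4, 2), "zero"))
        assert not amap.values[16:].any()

    def test_stride_invariance_for_additive_model(self):
        # mean aggregation across overlapping windows keeps additive maps stable
        x = rand_patch(10)
        a = occlusion_map(AdditiveModel(), x, OcclusionSpec((4, 4, 2), (4, 4, 2), "zero"))
        b = occlusion_map(AdditiveModel(), x, OcclusionSpec((4, 4, 2), (2, 2, 1), "zero"))
        assert a.values.sum() == pytest.approx(b.values.sum(), rel=0.05)

    def test_oversized_window_rejected(self):
        with pytest.raises(ValidationError):
            occlusion_map(AdditiveModel(), rand_patch(), OcclusionSpec((25, 4, 2), (1, 1, 1)))

    def test_uncovered_voxels_warn_and_zero(self):
        x = rand_patch(11)
        spec = OcclusionSpec(window_voxels=(23, 23, 7), stride_voxels=(24, 24, 8), fill="zero")
        with pytest.warns(UserWarning, match="uncovered"):
            amap = occlusion_map(AdditiveModel(), x, spec)
        assert amap.values[23, 23, 7] == 0.0


class TestLocalization:
    def test_map_positive_only_inside_mask(self):
        mask = np.zeros(SHAPE, bool)
        mask[8:16, 8:16, 2:6] = True  # 256 voxels > top-5% cut of 230
        values = np.where(mask, 1.0, 0.0) * np.random.default_rng(0).random(SHAPE)
        amap = AttributionMap(values, "occlusion")
        assert localization_score(amap, mask, 0.05) == 1.0

    def test_uniform_random_maps_match_mask_fraction(self):
        rng = np.random.default_rng(1)
        mask = np.zeros(SHAPE, bool)
        mask.ravel()[rng.choice(mask.size, size=mask.size // 10, replace=False)] = True
        scores = [
            localization_score(AttributionMap(rng.random(SHAPE), "occlusion"), mask, 0.05) for _ in range(1000)
        ]
        assert np.mean(scores) == pytest.approx(0.10, abs=0.01)

    def test_all_equal_map_is_deterministic_index_order(self):
        rng = np.random.default_rng(2)
        mask = rng.random(SHAPE) > 0.5
        amap = AttributionMap(np.ones(SHAPE), "saliency")
        m = int(round(0.05 * mask.size))
        expected = mask.ravel()[:m].mean()  # tie rule: flat index order
        assert localization_score(amap, mask, 0.05) == pytest.approx(expected)

    def test_empty_mask_rejected(self):
        with pytest.raises(UndefinedMetricError):
            localization_score(AttributionMap(rand_patch(), "saliency"), np.zeros(SHAPE, bool))

    def test_shape_mismatch(self):
        with pytest.raises(ShapeError):
            localization_score(AttributionMap(rand_patch(), "saliency"), np.ones((2, 2, 2), bool))


class TestClassAverages:
    def test_identical_classes_zero_difference(self):
        patches = [rand_patch(0)] * 3 + [rand_patch(0)] * 3
        labels = [0, 0, 0, 1, 1, 1]
        _, _, diff_ca, diff_ac = class_average_and_difference(patches, labels)
        assert not diff_ca.any() and not diff_ac.any()

    def test_antisymmetry(self):
        patches = [rand_patch(s) for s in range(6)]
        _, _, diff_ca, diff_ac = class_average_and_difference(patches, [0, 1, 0, 1, 0, 1])
        assert np.array_equal(diff_ca, -diff_ac)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            class_average_and_difference([rand_patch(0), rand_patch(1)], [0, 0])

    def test_default_phantoms_central_boost_visible(self):
        effects = EffectConfig(noise_sigma=0.0, vessel_probability=0.0)
        patches, labels = [], []
        for label in (0, 1):
            for seed in range(50):
                try:
                    render = render_phantom_full(sample_phantom_params(label, effects, seed=3_000 * label + seed))
                except Exception:
                    continue
                patches.append(render.noiseless)
                labels.append(label)
        _, _, diff_ca, diff_ac = class_average_and_difference(patches, labels)
        central = central_crossing_mask()
        lateral = lateral_band_mask()
        assert diff_ac[central].mean() > 0  # albinism brighter at the crossing
        assert diff_ca[lateral].mean() > 0  # controls brighter laterally


class TestThresholdMask:
    def test_below_threshold_semantics(self):
        avg = np.linspace(0, 1, DEFAULT_GEOMETRY.n_voxels).reshape(SHAPE)
        mask = threshold_mask(avg, 0.75)
        assert np.array_equal(mask, avg < 0.75)
        assert threshold_mask(avg, 0.6).sum() < mask.sum()

    def test_threshold_below_minimum_all_zero(self):
        mask = threshold_mask(rand_patch() + 5.0, 0.6)
        assert not mask.any()

    def test_unknown_direction_rejected(self):
        with pytest.raises(ValueError):
            threshold_mask(rand_patch(), 0.5, direction="above")


class TestTrainedModelLocalization:
    """Repo analogue of the attribution-localization findings."""

    def test_occlusion_focuses_on_chiasm_not_vessel(self, trained_strong_model, strong_test_cohort):
        spec = OcclusionSpec()
        chiasm_scores, chiasm_null, vessel_scores, vessel_null = [], [], [], []
        for patch, label, chiasm_mask, vessel_mask in strong_test_cohort:
            amap = occlusion_map(trained_strong_model, patch, spec)
            chiasm_scores.append(localization_score(amap, chiasm_mask, 0.05))
            chiasm_null.append(chiasm_mask.mean())
            if vessel_mask.any():
                vessel_scores.append(localization_score(amap, vessel_mask, 0.05))
                vessel_null.append(vessel_mask.mean())
        assert np.median(chiasm_scores) >= 3.0 * np.median(chiasm_null)
        assert np.median(vessel_scores) < 2.0 * np.median(vessel_null)
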