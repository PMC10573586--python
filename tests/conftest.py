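import numpy as np
import pytest
from hypothesis import settings

from chiasmnet.data_io import normalize_intensity
from chiasmnet.model_core import build_fresh_classifier
from chiasmnet.phantom import (
    EffectConfig,
    _render_with_retry,
    render_phantom_full,
    sample_phantom_params,
)
from chiasmnet.training import OptimConfig, TrainSample, finetune_classifier

settings.register_profile("ci", deadline=None, max_examples=50)
settings.load_profile("ci")


STRONG_EFFECTS = EffectConfig(width_ratio=0.6, tract_angle_offset_deg=20.0, central_boost=0.2, noise_sigma=0.05)
ZERO_EFFECTS = EffectConfig(width_ratio=1.0, tract_angle_offset_deg=0.0, central_boost=0.0)


def render_cohort(n_control, n_albinism, effects, seed0, geometry=None):
    """Lists of (normalized patch, label, chiasm_mask, vessel_mask) with retries."""
    from chiasmnet.data_io import DEFAULT_GEOMETRY

    geometry = geometry or DEFAULT_GEOMETRY
    out = []
    for i in range(n_control + n_albinism):
        label = 0 if i < n_control else 1
        params = sample_phantom_params(label, effects, seed=seed0 + i)
        params, render = _render_with_retry(params, label, effects, geometry)
        out.append((normalize_intensity(render.patch).voxels, label, render.chiasm_mask, render.vessel_mask))
    return out


def as_train_samples(cohort):
    return [TrainSample(patch, label, augment=False) for patch, label, _, _ in cohort]


@pytest.fixture(scope="session")
def strong_effects():
    return STRONG_EFFECTS


@pytest.fixture(scope="session")
def trained_strong_model():
    """A classifier fine-tuned on strong-effect phantoms; shared across tests."""
    train = render_cohort(40, 40, STRONG_EFFECTS, seed0=0)
    dev = render_cohort(10, 10, STRONG_EFFECTS, seed0=5000)
    model = build_fresh_classifier(seed=0)
    cfg = OptimConfig(epochs=8, batch_size=32, learning_rate=1e-3, seed=0, augment=False)
    model, history = finetune_classifier(model, as_train_samples(train), as_train_samples(dev), cfg)
    return model


@pytest.fixture(scope="session")
def strong_test_cohort():
    """Held-out strong-effect patches with vessels forced on (for XAI checks)."""
    effects = EffectConfig(
        width_ratio=0.6, tract_angle_offset_deg=20.0, central_boost=0.2, noise_sigma=0.05, vessel_probability=1.0
    )
    return render_cohort(10, 10, effects, seed0=90_000)
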