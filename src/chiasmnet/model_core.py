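"""The two-component network: feature-extraction encoder + scoring head.

The encoder is a compact stack of strided 3-D convolution blocks ending in a
dense latent projection; the autoencoder mirrors it with nearest-neighbour
upsampling; the classifier puts a small dense head plus a logistic squash on
the latent vector, yielding a score in [0, 1] (0 = control, 1 = albinism).
Everything is a pure function of (config, seed) and inference is
deterministic.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import nn
from .data_io import DEFAULT_GEOMETRY, PatchGeometry, PatchVolume
from .errors import ConfigError, ShapeError, ValidationError


@dataclass
class EncoderConfig:
    n_blocks: int = 3
    channels_per_block: tuple = (8, 16, 32)
    kernel_mm: int = 3
    downsample_factor: int = 2
    latent_dim: int = 64
    nonlinearity: str = "elu"  # "elu" or "identity"

    def validate(self, geometry: PatchGeometry = DEFAULT_GEOMETRY) -> None:
        if self.n_blocks < 1:
            raise ConfigError("n_blocks must be >= 1")
        if len(self.channels_per_block) != self.n_blocks:
            raise ConfigError("channels_per_block length must equal n_blocks")
        if self.kernel_mm % 2 != 1:
            raise ConfigError("kernel_mm must be odd")
        if self.nonlinearity not in ("elu", "identity"):
            raise ConfigError(f"unknown nonlinearity: {self.nonlinearity}")
        for dim in geometry.shape:
            for _ in range(self.n_blocks):
                dim = (dim + 2 * (self.kernel_mm // 2) - self.kernel_mm) // self.downsample_factor + 1
            if dim < 1:
                raise ConfigError("downsampling collapses a spatial axis below 1")

    def spatial_shape_after(self, geometry: PatchGeometry = DEFAULT_GEOMETRY) -> tuple:
        dims = list(geometry.shape)
        for _ in range(self.n_blocks):
            dims = [
                (d + 2 * (self.kernel_mm // 2) - self.kernel_mm) // self.downsample_factor + 1 for d in dims
            ]
        return tuple(dims)


@dataclass
class HeadConfig:
    hidden: int = 32


def _nonlinearity(config: EncoderConfig) -> nn.Layer:
    return nn.ELU() if config.nonlinearity == "elu" else nn.Identity()


def _build_encoder_net(config: EncoderConfig, rng, geometry: PatchGeometry) -> nn.Sequential:
    layers = []
    c_in = 1
    for c_out in config.channels_per_block:
        layers.append(
            nn.Conv3d(c_in, c_out, config.kernel_mm, stride=config.downsample_factor, pad=config.kernel_mm // 2, rng=rng)
        )
        layers.append(_nonlinearity(config))
        c_in = c_out
    layers.append(nn.Flatten())
    flat = int(np.prod(config.spatial_shape_after(geometry))) * c_in
    layers.append(nn.Dense(flat, config.latent_dim, rng=rng))
    return nn.Sequential(layers)


def _is_single(x, geometry: PatchGeometry) -> bool:
    """True when the input is one patch rather than a batch."""
    if isinstance(x, PatchVolume):
        return True
    if isinstance(x, (list, tuple)):
        return False
    return np.asarray(x).shape == geometry.shape


def _as_batch(x, geometry: PatchGeometry) -> np.ndarray:
    """Accept PatchVolume, single array or batch array; return (N,1,D,H,W)."""
    if isinstance(x, PatchVolume):
        x = x.voxels
    elif isinstance(x, (list, tuple)):
        x = np.stack([p.voxels if isinstance(p, PatchVolume) else np.asarray(p) for p in x])
    x = np.asarray(x, dtype=float)
    shape = geometry.shape
    if x.shape == shape:
        x = x[None]
    if x.ndim == 4 and x.shape[1:] == shape:
        x = x[:, None]
    if x.ndim != 5 or x.shape[1] != 1 or x.shape[2:] != shape:
        raise ShapeError(f"expected patches shaped {shape}, got {x.shape}")
    if not np.all(np.isfinite(x)):
        raise ValidationError("non-finite values in model input")
    return x


@dataclass
class AutoencoderModel:
    """Encoder plus mirrored decoder; reconstruction has the input's shape."""

    encoder: nn.Sequential
    decoder: nn.Sequential
    config: EncoderConfig
    seed: int
    geometry: PatchGeometry = field(default_factory=PatchGeometry)

    def reconstruct(self, x) -> np.ndarray:
        xb = _as_batch(x, self.geometry)
        out = self.decoder.forward(self.encoder.forward(xb))
        return out[:, 0]

    @property
    def all_params(self):
        return self.encoder.all_params + self.decoder.all_params

    @property
    def all_grads(self):
        return self.encoder.all_grads + self.decoder.all_grads

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.all_params))


def build_autoencoder(config: EncoderConfig = EncoderConfig(), seed: int = 0, geometry: PatchGeometry = DEFAULT_GEOMETRY) -> AutoencoderModel:
    config.validate(geometry)
    rng = np.random.default_rng(seed)
    encoder = _build_encoder_net(config, rng, geometry)
    spatial = config.spatial_shape_after(geometry)
    channels = list(config.channels_per_block)
    flat = int(np.prod(spatial)) * channels[-1]
    layers = [nn.Dense(config.latent_dim, flat, rng=rng), nn.Reshape((channels[-1],) + spatial)]
    c_in = channels[-1]
    for c_out in reversed([channels[0]] + channels[:-1]):
        layers.append(nn.Upsample3d(config.downsample_factor))
        layers.append(nn.Conv3d(c_in, c_out, config.kernel_mm, stride=1, pad=config.kernel_mm // 2, rng=rng))
        layers.append(_nonlinearity(config))
        c_in = c_out
    layers.append(nn.Conv3d(c_in, 1, config.kernel_mm, stride=1, pad=config.kernel_mm // 2, rng=rng))
    decoder = nn.Sequential(layers)
    # sanity: decoder must restore the input grid
    probe = decoder.forward(encoder.forward(np.zeros((1, 1) + geometry.shape)))
    if probe.shape[2:] != geometry.shape:
        raise ConfigError(f"decoder output {probe.shape[2:]} != patch grid {geometry.shape}")
    return AutoencoderModel(encoder, decoder, config, int(seed), geometry)


@dataclass
class ClassifierModel:
    """Encoder + dense head + logistic squash; score(x) in [0, 1]."""

    encoder: nn.Sequential
    head: nn.Sequential
    config: EncoderConfig
    head_config: HeadConfig
    seed: int
    geometry: PatchGeometry = field(default_factory=PatchGeometry)

    def predict_logit(self, x) -> np.ndarray:
        xb = _as_batch(x, self.geometry)
        z = self.head.forward(self.encoder.forward(xb))[:, 0]
        return float(z[0]) if _is_single(x, self.geometry) else z

    def predict_score(self, x) -> np.ndarray:
        z = self.predict_logit(x)
        out = nn.Sigmoid().forward(np.atleast_1d(np.asarray(z, dtype=float)))
        return float(out[0]) if np.isscalar(z) else out

    def input_gradient(self, x, target: str = "score") -> np.ndarray:
        """d(target)/d(input voxels); target is 'score' or 'logit'."""
        xb = _as_batch(x, self.geometry)
        z = self.head.forward(self.encoder.forward(xb))
        self.zero_grad()
        grad = np.ones_like(z)
        if target == "score":
            sig = nn.Sigmoid()
            sig.forward(z)
            grad = sig.backward(grad)
        elif target != "logit":
            raise ValueError(f"unknown gradient target: {target}")
        gx = self.encoder.backward(self.head.backward(grad))
        if not np.all(np.isfinite(gx)):
            raise ValidationError("non-finite input gradient")
        out = gx[:, 0]
        return out[0] if _is_single(x, self.geometry) else out

    def zero_grad(self):
        self.encoder.zero_grad()
        self.head.zero_grad()

    @property
    def all_params(self):
        return self.encoder.all_params + self.head.all_params

    @property
    def all_grads(self):
        return self.encoder.all_grads + self.head.all_grads

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.all_params))

    def copy(self) -> "ClassifierModel":
        clone = build_classifier(self.encoder, self.head_config, seed=self.seed, config=self.config, geometry=self.geometry)
        clone.head.set_state(self.head.get_state())
        return clone


def build_classifier(
    encoder: nn.Sequential,
    head_config: HeadConfig = HeadConfig(),
    seed: int = 0,
    config: EncoderConfig = EncoderConfig(),
    geometry: PatchGeometry = DEFAULT_GEOMETRY,
) -> ClassifierModel:
    """Attach a fresh dense head to a (copied) encoder."""
    config.validate(geometry)
    rng = np.random.default_rng(seed)
    enc_copy = _build_encoder_net(config, np.random.default_rng(seed), geometry)
    if len(enc_copy.all_params) != len(encoder.all_params):
        raise ConfigError("encoder structure does not match the supplied config")
    try:
        enc_copy.set_state(encoder.get_state())
    except Exception as exc:
        raise ConfigError(f"encoder/config dimension mismatch: {exc}") from exc
    head = nn.Sequential(
        [
            nn.Dense(config.latent_dim, head_config.hidden, rng=rng),
            nn.ELU(),
            nn.Dense(head_config.hidden, 1, rng=rng),
        ]
    )
    return ClassifierModel(enc_copy, head, config, head_config, int(seed), geometry)


def build_fresh_classifier(
    config: EncoderConfig = EncoderConfig(),
    head_config: HeadConfig = HeadConfig(),
    seed: int = 0,
    geometry: PatchGeometry = DEFAULT_GEOMETRY,
) -> ClassifierModel:
    config.validate(geometry)
    encoder = _build_encoder_net(config, np.random.default_rng(seed), geometry)
    return build_classifier(encoder, head_config, seed=seed, config=config, geometry=geometry)


class ConstantScoreModel:
    """Input-independent model; the attribution null."""

    def __init__(self, score: float = 0.5, geometry: PatchGeometry = DEFAULT_GEOMETRY):
        if not 0 <= score <= 1:
            raise ValueError("score must be in [0, 1]")
        self.score = float(score)
        self.geometry = geometry

    def predict_score(self, x):
        xb = _as_batch(x, self.geometry)
        return self.score if _is_single(x, self.geometry) else np.full(xb.shape[0], self.score)

    def predict_logit(self, x):
        xb = _as_batch(x, self.geometry)
        p = np.clip(self.score, 1e-12, 1 - 1e-12)
        z = np.log(p / (1 - p))
        return z if _is_single(x, self.geometry) else np.full(xb.shape[0], z)

    def input_gradient(self, x, target: str = "score"):
        xb = _as_batch(x, self.geometry)
        out = np.zeros(xb.shape[0:1] + self.geometry.shape)
        return out[0] if _is_single(x, self.geometry) else out


def predict_score(model: ClassifierModel, patch) -> np.ndarray:
    """Functional alias for model.predict_score (batched, order-preserving)."""
    return model.predict_score(patch)


def save_checkpoint(model, path) -> None:
    """Single-archive checkpoint: weights + full config + seed."""
    meta = {
        "kind": type(model).__name__,
        "config": dataclasses.asdict(model.config),
        "seed": model.seed,
    }
    if isinstance(model, ClassifierModel):
        meta["head_config"] = dataclasses.asdict(model.head_config)
        state = model.encoder.get_state() + model.head.get_state()
    elif isinstance(model, AutoencoderModel):
        state = model.encoder.get_state() + model.decoder.get_state()
    else:
        raise ConfigError(f"cannot checkpoint {type(model)}")
    arrays = {f"param_{i:04d}": p for i, p in enumerate(state)}
    arrays["meta_yaml"] = np.frombuffer(yaml.safe_dump(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    with np.load(path) as data:
        meta = yaml.safe_load(bytes(data["meta_yaml"]).decode())
        state = [data[k] for k in sorted(data.files) if k.startswith("param_")]
    cfg = EncoderConfig(**{**meta["config"], "channels_per_block": tuple(meta["config"]["channels_per_block"])})
    if meta["kind"] == "ClassifierModel":
        model = build_fresh_classifier(cfg, HeadConfig(**meta["head_config"]), seed=meta["seed"])
        n_enc = len(model.encoder.all_params)
        model.encoder.set_state(state[:n_enc])
        model.head.set_state(state[n_enc:])
    else:
        model = build_autoencoder(cfg, seed=meta["seed"])
        n_enc = len(model.encoder.all_params)
        model.encoder.set_state(state[:n_enc])
        model.decoder.set_state(state[n_enc:])
    return model
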