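"""Synthetic T1w-like chiasm patches with known ground truth.

The phantom is an X-shaped union of capsule segments on the fixed 24x24x8 mm
patch grid: a central left-right body bar (width ``body_width_mm``), two
anterior nerve segments converging on its lateral ends and two posterior
tract segments diverging at ``tract_half_angle_deg`` from the midline. All
capsules share a vertical semi-height of ``body_height_mm / 2`` (the chiasm
is flat), realized through a per-capsule anisotropic z-metric. Class effects:
albinism draws shrink the body width and nerve radius, widen the tract
angle and add a Gaussian intensity bump at the crossing.

Rigid jitter is applied exactly by evaluating the canonical scene at
``R^T (p - t)``; an optional vessel-like capsule near a patch corner acts as
a class-independent distractor for attribution-specificity checks.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np

from .data_io import (
    DEFAULT_GEOMETRY,
    CohortManifest,
    PatchGeometry,
    PatchVolume,
    Volume,
    _nearest_voxel,
    manifest_from_rows,
    save_manifest,
    write_patch,
)
from .errors import DataError, InvalidEffectError, PlacementError, RenderClippedError

# fixed geometric constants of the canonical scene (mm / degrees)
BODY_AP_RADIUS_MM = 2.5  # anterior-posterior half-thickness of the body bar
LIMB_ATTACH_MM = 2.0  # |x| where nerve/tract segments attach to the body
LIMB_LENGTH_MM = 4.0
NERVE_HALF_ANGLE_DEG = 25.0  # fixed; only the tract angle carries a class effect
CROSSING_SIGMA_MM = 2.0
CROSSING_Z_SCALE = 2.0
VESSEL_RADIUS_MM = 1.0
VESSEL_CORNER_MM = 8.0


@dataclass
class ChiasmPhantomParams:
    """Ground-truth geometry/intensity/noise parameters of one phantom."""

    class_label: int
    body_width_mm: float = 15.0
    body_height_mm: float = 3.5
    nerve_radius_mm: float = 1.5
    tract_half_angle_deg: float = 30.0
    central_boost: float = 0.0
    wm_intensity: float = 0.75
    bg_intensity: float = 0.35
    vessel_intensity: float = 0.9
    edge_width_mm: float = 1.0
    noise_sigma: float = 0.05
    vessel_probability: float = 0.3
    jitter_translation_mm: tuple = (0.0, 0.0, 0.0)
    jitter_rotation_deg: tuple = (0.0, 0.0, 0.0)
    seed: int = 0

    def validate(self) -> None:
        if self.class_label not in (0, 1):
            raise InvalidEffectError(f"class_label must be 0 or 1, got {self.class_label}")
        if self.body_width_mm <= 0 or self.body_height_mm <= 0 or self.nerve_radius_mm <= 0:
            raise InvalidEffectError("phantom dimensions must be positive")
        if not 0 <= self.tract_half_angle_deg < 90:
            raise InvalidEffectError("tract_half_angle_deg must be in [0, 90)")
        for name in ("wm_intensity", "bg_intensity", "vessel_intensity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise InvalidEffectError(f"{name} must be in [0, 1], got {v}")
        if self.central_boost < 0 or self.noise_sigma < 0:
            raise InvalidEffectError("central_boost and noise_sigma must be >= 0")
        if not 0 <= self.vessel_probability <= 1:
            raise InvalidEffectError("vessel_probability must be in [0, 1]")

    def to_json(self, path) -> None:
        d = dataclasses.asdict(self)
        d["jitter_translation_mm"] = list(d["jitter_translation_mm"])
        d["jitter_rotation_deg"] = list(d["jitter_rotation_deg"])
        with open(path, "w") as fh:
            json.dump(d, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ChiasmPhantomParams":
        with open(path) as fh:
            d = json.load(fh)
        d["jitter_translation_mm"] = tuple(d["jitter_translation_mm"])
        d["jitter_rotation_deg"] = tuple(d["jitter_rotation_deg"])
        return cls(**d)


@dataclass
class EffectConfig:
    """Control-class means, albinism effect sizes and nuisance settings.

    ``variation`` is the relative between-subject standard deviation applied
    to the morphological means; albinism multipliers/offsets are applied to
    the control-level draw, so identity effects reproduce the control draw.
    """

    # control means
    body_width_mm: float = 15.0
    body_height_mm: float = 3.5
    nerve_radius_mm: float = 1.5
    tract_half_angle_deg: float = 30.0
    # albinism effects
    width_ratio: float = 0.7
    tract_angle_offset_deg: float = 15.0
    central_boost: float = 0.15
    # between-subject variation (relative sd of the morphological means)
    variation: float = 0.05
    # intensities / nuisance
    wm_intensity: float = 0.75
    bg_intensity: float = 0.35
    vessel_intensity: float = 0.9
    edge_width_mm: float = 1.0
    noise_sigma: float = 0.05
    noise_model: str = "rician"  # or "gaussian"
    vessel_probability: float = 0.3
    jitter_translation_mm: float = 2.0  # in-plane (x, y)
    jitter_translation_z_mm: float = 1.0  # the 8 mm axis leaves less headroom
    jitter_rotation_deg: float = 5.0

    def validate(self) -> None:
        if self.width_ratio <= 0:
            raise InvalidEffectError(f"width_ratio must be > 0, got {self.width_ratio}")
        if self.body_width_mm * self.width_ratio <= 0 or self.body_width_mm <= 0:
            raise InvalidEffectError("resulting body width must be > 0")
        if self.variation < 0:
            raise InvalidEffectError("variation must be >= 0")
        if self.noise_model not in ("rician", "gaussian"):
            raise InvalidEffectError(f"unknown noise model: {self.noise_model}")


DEFAULT_EFFECTS = EffectConfig()


def sample_phantom_params(class_label: int, effect_config: EffectConfig = DEFAULT_EFFECTS, seed: int = 0) -> ChiasmPhantomParams:
    """Draw one subject's ground-truth parameters; deterministic in (args, seed)."""
    cfg = effect_config
    cfg.validate()
    if class_label not in (0, 1):
        raise InvalidEffectError(f"class_label must be 0 or 1, got {class_label}")
    rng = np.random.default_rng(seed)

    def draw(mean):
        value = mean * (1.0 + cfg.variation * rng.standard_normal())
        return max(value, 1e-3)

    width = draw(cfg.body_width_mm)
    height = draw(cfg.body_height_mm)
    radius = draw(cfg.nerve_radius_mm)
    angle = draw(cfg.tract_half_angle_deg)
    boost = abs(cfg.variation * rng.standard_normal()) * cfg.central_boost
    if class_label == 1:
        width *= cfg.width_ratio
        radius *= cfg.width_ratio
        angle += cfg.tract_angle_offset_deg
        boost = cfg.central_boost * (1.0 + cfg.variation * rng.standard_normal())
        boost = max(boost, 0.0)
    else:
        rng.standard_normal()  # keep stream alignment between classes
    jt = cfg.jitter_translation_mm
    jz = cfg.jitter_translation_z_mm
    jr = cfg.jitter_rotation_deg
    translation = (rng.uniform(-jt, jt), rng.uniform(-jt, jt), rng.uniform(-jz, jz))
    params = ChiasmPhantomParams(
        class_label=class_label,
        body_width_mm=width,
        body_height_mm=height,
        nerve_radius_mm=radius,
        tract_half_angle_deg=min(angle, 89.0),
        central_boost=boost,
        wm_intensity=cfg.wm_intensity,
        bg_intensity=cfg.bg_intensity,
        vessel_intensity=cfg.vessel_intensity,
        edge_width_mm=cfg.edge_width_mm,
        noise_sigma=cfg.noise_sigma,
        vessel_probability=cfg.vessel_probability,
        jitter_translation_mm=translation,
        jitter_rotation_deg=tuple(rng.uniform(-jr, jr, 3)),
        seed=int(seed),
    )
    params.validate()
    return params


def _rotation_matrix(angles_deg) -> np.ndarray:
    ax, ay, az = np.deg2rad(angles_deg)
    cx, sx = np.cos(ax), np.sin(ax)
    cy, sy = np.cos(ay), np.sin(ay)
    cz, sz = np.cos(az), np.sin(az)
    rx = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    ry = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    rz = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    return rz @ ry @ rx


def _grid_points(geometry: PatchGeometry) -> np.ndarray:
    shape = geometry.shape
    axes = [np.arange(n) - (n - 1) / 2.0 for n in shape]
    xs, ys, zs = np.meshgrid(*axes, indexing="ij")
    return np.stack([xs, ys, zs], axis=-1)


def _capsule_distance(points: np.ndarray, a, b, z_scale: float) -> np.ndarray:
    """Distance from grid points to segment a-b in the z-rescaled metric."""
    p = points.copy()
    p[..., 2] *= z_scale
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom < 1e-12:
        closest = a
    else:
        t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
    return np.linalg.norm(p - closest, axis=-1)


@dataclass
class PhantomRender:
    patch: PatchVolume
    chiasm_mask: np.ndarray
    vessel_mask: np.ndarray
    noiseless: np.ndarray


def _chiasm_capsules(params: ChiasmPhantomParams):
    """Canonical (a, b, radius) capsule list of the chiasm scene."""
    half_h = params.body_height_mm / 2.0
    rb = BODY_AP_RADIUS_MM
    x0 = max(params.body_width_mm / 2.0 - rb, 0.1)
    caps = [((-x0, 0, 0), (x0, 0, 0), rb)]
    for sign in (-1.0, 1.0):
        ax = sign * LIMB_ATTACH_MM
        for angle_deg, ydir in ((NERVE_HALF_ANGLE_DEG, 1.0), (params.tract_half_angle_deg, -1.0)):
            ang = np.deg2rad(angle_deg)
            end = (ax + sign * LIMB_LENGTH_MM * np.sin(ang), ydir * LIMB_LENGTH_MM * np.cos(ang), 0.0)
            caps.append(((ax, 0, 0), end, params.nerve_radius_mm))
    return caps, half_h


def render_phantom_full(params: ChiasmPhantomParams, geometry: PatchGeometry = DEFAULT_GEOMETRY) -> PhantomRender:
    params.validate()
    points = _grid_points(geometry)
    rot = _rotation_matrix(params.jitter_rotation_deg)
    t = np.asarray(params.jitter_translation_mm, dtype=float)
    # evaluate the canonical scene at R^T (p - t): exact rigid jitter
    local = (points - t) @ rot

    caps, half_h = _chiasm_capsules(params)
    weight = np.zeros(geometry.shape)
    ew = max(params.edge_width_mm, 1e-6)
    for a, b, r in caps:
        d = _capsule_distance(local, a, b, z_scale=r / half_h)
        weight = np.maximum(weight, np.clip(0.5 + (r - d) / ew, 0.0, 1.0))
    chiasm_mask = weight > 0.5

    field = params.bg_intensity + (params.wm_intensity - params.bg_intensity) * weight
    if params.central_boost > 0:
        q = local.copy()
        q[..., 2] *= CROSSING_Z_SCALE
        rho2 = (q**2).sum(axis=-1)
        field = field + params.central_boost * np.exp(-rho2 / (2.0 * CROSSING_SIGMA_MM**2))

    vessel_mask = np.zeros(geometry.shape, dtype=bool)
    vrng = np.random.default_rng([int(params.seed) & 0x7FFFFFFF, 0xE55E1])
    if vrng.random() < params.vessel_probability:
        corner = vrng.integers(0, 4)
        vx = VESSEL_CORNER_MM * (1 if corner % 2 else -1)
        vy = VESSEL_CORNER_MM * (1 if corner // 2 else -1)
        dv = _capsule_distance(local, (vx, vy, -12.0), (vx, vy, 12.0), z_scale=1.0)
        wv = np.clip(0.5 + (VESSEL_RADIUS_MM - dv) / ew, 0.0, 1.0)
        field = field + (params.vessel_intensity - field) * wv
        vessel_mask = wv > 0.5

    for axis, name in enumerate("xyz"):
        idx = [slice(None)] * 3
        idx[axis] = 0
        if chiasm_mask[tuple(idx)].any():
            raise RenderClippedError(f"{name}_min")
        idx[axis] = -1
        if chiasm_mask[tuple(idx)].any():
            raise RenderClippedError(f"{name}_max")

    out = field
    if params.noise_sigma > 0:
        noisy = add_rician_noise(PatchVolume(field), params.noise_sigma, seed=params.seed)
        out = noisy.voxels
    return PhantomRender(PatchVolume(out), chiasm_mask, vessel_mask, field)


def render_phantom(params: ChiasmPhantomParams, geometry: PatchGeometry = DEFAULT_GEOMETRY):
    """Render a phantom; returns (patch, chiasm_mask). Deterministic given params."""
    r = render_phantom_full(params, geometry)
    return r.patch, r.chiasm_mask


def add_rician_noise(patch: PatchVolume, sigma: float, seed: int = 0) -> PatchVolume:
    """Magnitude-MRI noise: sqrt((x + n1)^2 + n2^2), n1,n2 ~ N(0, sigma)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return patch
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, sigma, patch.voxels.shape)
    n2 = rng.normal(0.0, sigma, patch.voxels.shape)
    out = np.sqrt((patch.voxels + n1) ** 2 + n2**2)
    return PatchVolume(out, patch.center_world_mm, patch.sample_id)


def add_gaussian_noise(patch: PatchVolume, sigma: float, seed: int = 0) -> PatchVolume:
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return patch
    rng = np.random.default_rng(seed)
    return PatchVolume(patch.voxels + rng.normal(0.0, sigma, patch.voxels.shape), patch.center_world_mm, patch.sample_id)


def _render_with_retry(params: ChiasmPhantomParams, class_label, effect_config, geometry, max_retries=50):
    """Re-draw jitter (via a derived seed) until the structure fits the patch."""
    for attempt in range(max_retries):
        try:
            return params, render_phantom_full(params, geometry)
        except RenderClippedError:
            params = sample_phantom_params(class_label, effect_config, seed=params.seed + 10_000_019 * (attempt + 1))
    raise RenderClippedError("unresolvable after retries")


def generate_tagged_cohort(
    samples,
    effect_config: EffectConfig = DEFAULT_EFFECTS,
    out_dir=None,
    seed: int = 0,
    geometry: PatchGeometry = DEFAULT_GEOMETRY,
):
    """Generate phantoms for an explicit list of (class_label, dataset_tag).

    Returns (manifest, patches, chiasm_masks, vessel_masks) where the three
    dicts map sample_id to arrays. If ``out_dir`` is given, patches are
    written as uncompressed NIfTI with JSON truth sidecars plus manifest.csv.
    """
    samples = list(samples)
    if not samples:
        raise DataError("empty cohort requested")
    rng = np.random.default_rng(seed)
    sample_seeds = rng.integers(0, 2**31 - 1, size=len(samples))
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
    rows, truth, patches, masks, vessels = [], {}, {}, {}, {}
    counters = {0: 0, 1: 0}
    for (label, tag), s in zip(samples, sample_seeds):
        sid = f"{'ctl' if label == 0 else 'alb'}_{counters[label]:04d}"
        counters[label] += 1
        params = sample_phantom_params(label, effect_config, seed=int(s))
        params, render = _render_with_retry(params, label, effect_config, geometry)
        patch = render.patch
        patch.sample_id = sid
        path = os.path.join(out_dir, f"{sid}.nii") if out_dir is not None else f"{sid}.nii"
        if out_dir is not None:
            write_patch(patch, path, geometry)
            params.to_json(os.path.splitext(path)[0] + ".json")
        rows.append((sid, path, label, tag, patch.center_world_mm))
        truth[sid] = params
        patches[sid] = patch.voxels
        masks[sid] = render.chiasm_mask
        vessels[sid] = render.vessel_mask
    manifest = manifest_from_rows(rows)
    manifest.truth = truth
    if out_dir is not None:
        save_manifest(manifest, os.path.join(out_dir, "manifest.csv"))
    return manifest, patches, masks, vessels


def generate_cohort(
    n_control: int,
    n_albinism: int,
    effect_config: EffectConfig = DEFAULT_EFFECTS,
    out_dir=None,
    seed: int = 0,
    tags=("siteA", "siteB", "siteC"),
    geometry: PatchGeometry = DEFAULT_GEOMETRY,
) -> CohortManifest:
    """Generate a two-class cohort; dataset tags assigned round-robin."""
    if n_control < 0 or n_albinism < 0:
        raise DataError("sample counts must be >= 0")
    if n_control + n_albinism == 0:
        raise DataError("empty cohort requested")
    labels = [0] * n_control + [1] * n_albinism
    samples = [(label, tags[i % len(tags)]) for i, label in enumerate(labels)]
    manifest, _, _, _ = generate_tagged_cohort(samples, effect_config, out_dir, seed, geometry)
    return manifest


def embed_patch_in_volume(patch: PatchVolume, volume_dims_mm, center_world_mm) -> Volume:
    """Place a patch inside a larger zero volume so extract_patch recovers it."""
    dims = np.asarray(volume_dims_mm, dtype=int)
    shape = np.array(patch.voxels.shape)
    center_voxel = _nearest_voxel(np.asarray(center_world_mm, dtype=float))
    start = center_voxel - shape // 2
    stop = start + shape
    if np.any(start < 0) or np.any(stop > dims):
        raise PlacementError(f"patch window [{start}, {stop}) overflows volume {dims}")
    voxels = np.zeros(tuple(dims))
    voxels[tuple(slice(a, b) for a, b in zip(start, stop))] = patch.voxels
    return Volume(voxels, np.eye(4))


def central_crossing_mask(geometry: PatchGeometry = DEFAULT_GEOMETRY, radius_mm: float = 2.5) -> np.ndarray:
    """Voxels near the canonical crossing center (z compressed like the bump)."""
    q = _grid_points(geometry)
    q = q.copy()
    q[..., 2] *= CROSSING_Z_SCALE
    return (q**2).sum(axis=-1) <= radius_mm**2


def lateral_band_mask(geometry: PatchGeometry = DEFAULT_GEOMETRY) -> np.ndarray:
    """Lateral chiasm/tract band: covered by control-width bodies but not albinotic ones."""
    p = _grid_points(geometry)
    return (
        (np.abs(p[..., 0]) > 4.0)
        & (np.abs(p[..., 0]) <= 8.0)
        & (np.abs(p[..., 1]) <= 3.0)
        & (np.abs(p[..., 2]) <= 1.75)
    )
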