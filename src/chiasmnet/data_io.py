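"""NIfTI volume I/O, patch extraction, normalization and manifest handling.

Conventions (documented because they are easy to get subtly wrong):

* world coordinates are millimetres in RAS, mapped through the NIfTI affine;
* voxel indices are 0-based and extraction windows are half-open;
* the "nearest voxel" to a world coordinate rounds ties toward minus infinity
  (``ceil(v - 0.5)``), shared by :func:`extract_patch` and the phantom
  embedding helper so round-trips are exact.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import (
    CoverageError,
    FormatError,
    OutOfBoundsError,
    ShapeError,
    ValidationError,
)

MANIFEST_COLUMNS = ["sample_id", "path", "label", "dataset_tag", "cx", "cy", "cz"]


@dataclass(frozen=True)
class PatchGeometry:
    """The fixed patch grid: 24 x 24 x 8 mm at 1 mm isotropic spacing.

    Axis order is (left-right, anterior-posterior, inferior-superior); the
    short 8 mm axis is inferior-superior because the chiasm is flat.
    """

    size_mm: tuple = (24, 24, 8)
    voxel_mm: tuple = (1.0, 1.0, 1.0)

    @property
    def shape(self) -> tuple:
        return tuple(int(round(s / v)) for s, v in zip(self.size_mm, self.voxel_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))


DEFAULT_GEOMETRY = PatchGeometry()


@dataclass
class PatchVolume:
    """A single CNN input unit: intensity voxels plus world metadata."""

    voxels: np.ndarray
    center_world_mm: tuple = (0.0, 0.0, 0.0)
    sample_id: str = ""

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if not np.all(np.isfinite(self.voxels)):
            raise ValidationError("patch contains non-finite values")


@dataclass
class Volume:
    """A 3-D image with a voxel-to-world (mm) affine."""

    voxels: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValidationError("affine must be an invertible 4x4 matrix")


def read_volume(path) -> Volume:
    if not os.path.exists(path):
        raise IOError(f"no such file: {path}")
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises a zoo of types for bad files
        raise FormatError(f"not a readable NIfTI file: {path}: {exc}") from exc
    return Volume(np.asarray(img.get_fdata(), dtype=float), np.asarray(img.affine))


def write_volume(volume: Volume, path) -> None:
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32), volume.affine)
    nib.save(img, str(path))


def write_patch(patch: PatchVolume, path, geometry: PatchGeometry = DEFAULT_GEOMETRY) -> None:
    """Write a patch as NIfTI with a 1 mm isotropic affine centred on its world center."""
    shape = np.array(geometry.shape)
    origin = np.asarray(patch.center_world_mm, dtype=float) - (shape - 1) / 2.0
    affine = np.eye(4)
    affine[:3, 3] = origin
    write_volume(Volume(patch.voxels, affine), path)


def _nearest_voxel(v: np.ndarray) -> np.ndarray:
    """Nearest integer with ties toward minus infinity."""
    return np.ceil(np.asarray(v, dtype=float) - 0.5).astype(int)


def voxel_spacing(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((affine[:3, :3] ** 2).sum(axis=0))


def resample_to_1mm(volume: Volume) -> Volume:
    """Trilinear resampling onto a 1 mm isotropic grid with the same origin."""
    spacing = voxel_spacing(volume.affine)
    if np.allclose(spacing, 1.0, atol=1e-6):
        return volume
    new_shape = tuple(int(np.ceil(s * z)) for s, z in zip(volume.voxels.shape, spacing))
    new_affine = volume.affine.copy()
    new_affine[:3, :3] = volume.affine[:3, :3] / spacing  # unit columns
    # voxel_new -> world -> voxel_old
    m = np.linalg.inv(volume.affine) @ new_affine
    voxels = ndimage.affine_transform(
        volume.voxels, m[:3, :3], offset=m[:3, 3], output_shape=new_shape, order=1, mode="constant"
    )
    return Volume(voxels, new_affine)


def extract_patch(
    volume: Volume,
    center_world_mm,
    geometry: PatchGeometry = DEFAULT_GEOMETRY,
    sample_id: str = "",
    max_pad_fraction: float = 0.25,
) -> PatchVolume:
    """Extract the half-open window of ``geometry`` size around a world center.

    Out-of-bounds voxels are zero-padded; more than ``max_pad_fraction`` of
    padding raises :class:`CoverageError`.
    """
    volume = resample_to_1mm(volume)
    center_world_mm = np.asarray(center_world_mm, dtype=float)
    vox = np.linalg.inv(volume.affine) @ np.append(center_world_mm, 1.0)
    center_voxel = _nearest_voxel(vox[:3])
    dims = np.array(volume.voxels.shape)
    if np.any(center_voxel < 0) or np.any(center_voxel >= dims):
        raise OutOfBoundsError(f"center {center_world_mm} maps to voxel {center_voxel} outside volume {dims}")
    shape = np.array(geometry.shape)
    start = center_voxel - shape // 2
    stop = start + shape
    out = np.zeros(tuple(shape))
    src_lo = np.maximum(start, 0)
    src_hi = np.minimum(stop, dims)
    dst_lo = src_lo - start
    dst_hi = dst_lo + (src_hi - src_lo)
    out[tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))] = volume.voxels[
        tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    ]
    n_pad = geometry.n_voxels - int(np.prod(np.maximum(src_hi - src_lo, 0)))
    if n_pad > max_pad_fraction * geometry.n_voxels:
        raise CoverageError(
            f"{n_pad}/{geometry.n_voxels} voxels padded (> {max_pad_fraction:.0%}) at center {center_world_mm}"
        )
    return PatchVolume(out, tuple(center_world_mm), sample_id)


def normalize_intensity(patch: PatchVolume, method: str = "robust_minmax") -> PatchVolume:
    """Clip to the [1st, 99th] percentile range and map linearly to [0, 1].

    Percentiles use ``method="lower"`` / ``"higher"`` so that clipping piles at
    least 1% of the mass exactly onto each bound, which makes the operation
    exactly idempotent. Constant patches map to all-zeros by convention.
    """
    if method != "robust_minmax":
        raise ValueError(f"unknown normalization method: {method}")
    v = patch.voxels
    lo = float(np.percentile(v, 1, method="lower"))
    hi = float(np.percentile(v, 99, method="higher"))
    if hi <= lo:
        out = np.zeros_like(v)
    else:
        out = (np.clip(v, lo, hi) - lo) / (hi - lo)
    return PatchVolume(out, patch.center_world_mm, patch.sample_id)


def mask_chiasm_out(patch: PatchVolume, chiasm_mask: np.ndarray, fill: str = "background_mean") -> PatchVolume:
    """Replace masked voxels by a fill value, leaving all others untouched."""
    mask = np.asarray(chiasm_mask).astype(bool)
    if mask.shape != patch.voxels.shape:
        raise ShapeError(f"mask shape {mask.shape} != patch shape {patch.voxels.shape}")
    out = patch.voxels.copy()
    if fill == "zero":
        value = 0.0
    elif fill == "background_mean":
        outside = ~mask
        value = float(out[outside].mean()) if outside.any() else 0.0
    else:
        raise ValueError(f"unknown fill: {fill}")
    out[mask] = value
    return PatchVolume(out, patch.center_world_mm, patch.sample_id)


@dataclass
class CohortManifest:
    """Sample bookkeeping: one row per patch, optional ground-truth sidecars."""

    df: pd.DataFrame
    truth: dict = field(default_factory=dict)  # sample_id -> ChiasmPhantomParams

    def __post_init__(self):
        self.validate()

    def validate(self, check_paths: bool = False) -> None:
        missing = [c for c in MANIFEST_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValidationError(f"manifest missing columns: {missing}")
        dup = self.df["sample_id"][self.df["sample_id"].duplicated()].tolist()
        if dup:
            raise ValidationError(f"duplicate sample_id rows: {sorted(set(dup))}")
        bad = self.df.loc[~self.df["label"].isin([0, 1]), "sample_id"].tolist()
        if bad:
            raise ValidationError(f"labels outside {{0,1}} for rows: {bad}")
        if check_paths:
            unresolved = [
                row.sample_id for row in self.df.itertuples() if not os.path.exists(row.path)
            ]
            if unresolved:
                raise ValidationError(f"unresolvable patch paths for rows: {unresolved}")

    def __len__(self):
        return len(self.df)

    @property
    def sample_ids(self):
        return self.df["sample_id"].tolist()

    @property
    def labels(self):
        return self.df["label"].to_numpy(dtype=int)

    def class_counts(self) -> tuple:
        labels = self.labels
        return int((labels == 0).sum()), int((labels == 1).sum())


def save_manifest(manifest: CohortManifest, path) -> None:
    manifest.df.to_csv(path, index=False, columns=MANIFEST_COLUMNS)


def load_manifest(path, check_paths: bool = True) -> CohortManifest:
    df = pd.read_csv(path)
    manifest = CohortManifest(df)
    manifest.validate(check_paths=check_paths)
    truth = {}
    for row in df.itertuples():
        sidecar = os.path.splitext(str(row.path))[0] + ".json"
        if os.path.exists(sidecar):
            from .phantom import ChiasmPhantomParams  # local import, avoids cycle

            truth[row.sample_id] = ChiasmPhantomParams.from_json(sidecar)
    manifest.truth = truth
    return manifest


def manifest_from_rows(rows) -> CohortManifest:
    """Build a manifest from (sample_id, path, label, dataset_tag, (cx,cy,cz)) tuples."""
    records = [
        {
            "sample_id": sid,
            "path": path,
            "label": int(label),
            "dataset_tag": tag,
            "cx": float(center[0]),
            "cy": float(center[1]),
            "cz": float(center[2]),
        }
        for sid, path, label, tag, center in rows
    ]
    return CohortManifest(pd.DataFrame.from_records(records, columns=MANIFEST_COLUMNS))
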