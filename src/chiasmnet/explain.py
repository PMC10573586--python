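"""Attribution methods and the class-average difference analysis.

Models are any object exposing ``predict_score(batch) -> scores`` (occlusion)
and ``input_gradient(patch, target) -> array`` (gradient methods). Signed
maps are canonical: positive values push the score toward albinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .data_io import PatchVolume
from .errors import ShapeError, UndefinedMetricError, ValidationError


@dataclass
class AttributionMap:
    values: np.ndarray
    method: str  # saliency | grad_x_input | occlusion
    sample_id: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("attribution map contains non-finite values")


@dataclass
class OcclusionSpec:
    window_voxels: tuple = (4, 4, 2)
    stride_voxels: tuple = (2, 2, 1)
    fill: str = "background_mean"  # or "zero"

    def validate(self, patch_shape) -> None:
        for w, s, d in zip(self.window_voxels, self.stride_voxels, patch_shape):
            if w < 1 or s < 1:
                raise ValidationError("window and stride must be >= 1 per axis")
            if w > d:
                raise ValidationError(f"occlusion window {self.window_voxels} exceeds patch {patch_shape}")
        if self.fill not in ("zero", "background_mean"):
            raise ValidationError(f"unknown occlusion fill: {self.fill}")


def _voxels(patch) -> np.ndarray:
    return patch.voxels if isinstance(patch, PatchVolume) else np.asarray(patch, dtype=float)


def _sample_id(patch) -> str:
    return patch.sample_id if isinstance(patch, PatchVolume) else ""


def saliency_map(model, patch, signed: bool = True) -> AttributionMap:
    """Gradient of the albinism score with respect to each input voxel."""
    grad = np.asarray(model.input_gradient(_voxels(patch), target="score"), dtype=float)
    if not signed:
        grad = np.abs(grad)
    return AttributionMap(grad, "saliency", _sample_id(patch))


def gradient_x_input(model, patch, target: str = "score") -> AttributionMap:
    """Elementwise product of the signed gradient and the input.

    Zero voxels always receive zero attribution; for linear models with a
    zero baseline the attributions sum to the logit difference from the zero
    input (completeness), which is why ``target="logit"`` is offered.
    """
    x = _voxels(patch)
    grad = np.asarray(model.input_gradient(x, target=target), dtype=float)
    return AttributionMap(grad * x, "grad_x_input", _sample_id(patch))


def occlusion_map(model, patch, spec: OcclusionSpec = OcclusionSpec(), batch_size: int = 128) -> AttributionMap:
    """Mean score drop over all sliding windows covering each voxel.

    attribution(v) = mean over windows W containing v of
    score(patch) - score(patch with W replaced by fill). Voxels covered by no
    window get 0 with a coverage warning.
    """
    x = _voxels(patch)
    spec.validate(x.shape)
    fill_value = 0.0 if spec.fill == "zero" else float(x.mean())
    starts = [list(range(0, d - w + 1, s)) for d, w, s in zip(x.shape, spec.window_voxels, spec.stride_voxels)]
    windows = [(i, j, l) for i in starts[0] for j in starts[1] for l in starts[2]]
    base = float(np.asarray(model.predict_score(x)).reshape(-1)[0])

    deltas = np.empty(len(windows))
    for lo in range(0, len(windows), batch_size):
        chunk = windows[lo : lo + batch_size]
        batch = np.repeat(x[None], len(chunk), axis=0)
        for m, (i, j, l) in enumerate(chunk):
            wi, wj, wl = spec.window_voxels
            batch[m, i : i + wi, j : j + wj, l : l + wl] = fill_value
        scores = np.asarray(model.predict_score(batch)).reshape(-1)
        deltas[lo : lo + len(chunk)] = base - scores

    total = np.zeros(x.shape)
    count = np.zeros(x.shape)
    wi, wj, wl = spec.window_voxels
    for (i, j, l), d in zip(windows, deltas):
        total[i : i + wi, j : j + wj, l : l + wl] += d
        count[i : i + wi, j : j + wj, l : l + wl] += 1
    uncovered = count == 0
    if uncovered.any():
        warnings.warn(f"occlusion grid leaves {int(uncovered.sum())} voxels uncovered; attributions set to 0")
    values = np.divide(total, count, out=np.zeros_like(total), where=~uncovered)
    return AttributionMap(values, "occlusion", _sample_id(patch))


def localization_score(attribution: AttributionMap, mask: np.ndarray, top_fraction: float = 0.05) -> float:
    """Fraction of the top-|attribution| voxels that fall inside the mask.

    The top set holds round(top_fraction * n) voxels (at least 1); ties at
    the cutoff are broken by flat voxel index order (stable sort).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.shape != attribution.values.shape:
        raise ShapeError(f"mask shape {mask.shape} != map shape {attribution.values.shape}")
    if not 0 < top_fraction <= 1:
        raise ValidationError("top_fraction must be in (0, 1]")
    if not mask.any():
        raise UndefinedMetricError("empty mask: localization score undefined")
    flat = np.abs(attribution.values).ravel()
    m = max(1, int(round(top_fraction * flat.size)))
    order = np.argsort(-flat, kind="stable")
    return float(mask.ravel()[order[:m]].mean())


def class_average_and_difference(patches, labels):
    """Voxelwise class means and both signed difference maps.

    Returns (avg_control, avg_albinism, diff_c_minus_a, diff_a_minus_c);
    the two differences are exact negations of each other.
    """
    arrays = np.stack([_voxels(p) for p in patches])
    labels = np.asarray(labels, dtype=int)
    if arrays.shape[0] != labels.shape[0]:
        raise ValidationError("patches and labels must have equal length")
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValidationError("both classes required for the class-average analysis")
    avg_control = arrays[labels == 0].mean(axis=0)
    avg_albinism = arrays[labels == 1].mean(axis=0)
    diff = avg_control - avg_albinism
    return avg_control, avg_albinism, diff, -diff


def threshold_mask(avg: np.ndarray, threshold: float, direction: str = "below") -> np.ndarray:
    """Binary mask of voxels below (the only supported direction) a threshold."""
    avg = np.asarray(avg, dtype=float)
    if not np.all(np.isfinite(avg)):
        raise ValidationError("average image contains non-finite values")
    if direction != "below":
        raise ValueError(f"unsupported direction: {direction}")
    return avg < threshold
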