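"""Grad-CAM heatmaps plus an occlusion-sensitivity map as independent probe.

Grad-CAM: the gradient of the target-class score with respect to the last
convolutional layer's activation maps is spatially averaged into one weight
per channel; the weighted sum of activation maps is rectified, bilinearly
upsampled to image resolution and min-max normalized to [0, 1]. By default
the target class is the model's predicted label.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize

__all__ = ["SaliencyMap", "gradcam", "gradcam_from_activations", "occlusion_map",
           "normalize01", "overlay", "save_heatmap", "load_heatmap"]


@dataclass
class SaliencyMap:
    """An H x W attention map in [0, 1] aligned with its source image."""

    values: np.ndarray
    model_id: str = ""
    image_id: str = ""
    target_class: int = -1
    layer_id: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.min() < 0 or self.values.max() > 1:
            raise ValueError("saliency values must lie in [0, 1]")


def normalize01(v: np.ndarray) -> np.ndarray:
    """Min-max normalize to [0, 1]; a constant map maps to all zeros."""
    v = np.asarray(v, dtype=np.float64)
    lo, hi = v.min(), v.max()
    if hi - lo < 1e-12:
        return np.zeros_like(v)
    return (v - lo) / (hi - lo)


def gradcam_from_activations(
    activations: np.ndarray, gradients: np.ndarray, out_shape: tuple[int, int]
) -> np.ndarray:
    """Core Grad-CAM arithmetic on (H', W', C) activation/gradient arrays."""
    weights = gradients.mean(axis=(0, 1))          # one weight per channel
    cam = np.tensordot(activations, weights, axes=([2], [0]))
    cam = np.maximum(cam, 0.0)                     # rectify
    cam = resize(cam, out_shape, order=1, mode="edge", anti_aliasing=False)
    return normalize01(cam)


def gradcam(model, image: np.ndarray, target_class: int | None = None) -> SaliencyMap:
    """Grad-CAM heatmap for one image; defaults to the predicted label."""
    image = np.asarray(image, dtype=np.float64)
    if target_class is None:
        target_class = int(model.predict(image[None])[0])
    acts, grads, _ = model.class_score_gradients(image, target_class)
    values = gradcam_from_activations(acts, grads, image.shape[:2])
    return SaliencyMap(values, model_id=model.config.variant,
                       target_class=target_class, layer_id=model.layer_id)


def occlusion_map(
    model,
    image: np.ndarray,
    patch_size: int,
    stride: int,
    target_class: int | None = None,
) -> SaliencyMap:
    """Occlusion sensitivity: per-pixel average drop in the target-class
    probability when a sliding black patch covers the pixel."""
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape[:2]
    if patch_size > min(h, w):
        raise ValueError("patch_size exceeds image size")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    probs = model.predict_proba(image[None])[0]
    if target_class is None:
        target_class = int(np.argmax(probs))
    base = probs[target_class]

    drops = np.zeros((h, w))
    cover = np.zeros((h, w))
    tops = sorted({*range(0, h - patch_size + 1, stride)} | {h - patch_size})
    lefts = sorted({*range(0, w - patch_size + 1, stride)} | {w - patch_size})
    for top in tops:
        batch = []
        for left in lefts:
            occluded = image.copy()
            occluded[top : top + patch_size, left : left + patch_size] = 0.0
            batch.append(occluded)
        p = model.predict_proba(np.stack(batch))[:, target_class]
        for left, p_occ in zip(lefts, p):
            drops[top : top + patch_size, left : left + patch_size] += base - p_occ
            cover[top : top + patch_size, left : left + patch_size] += 1.0
    values = normalize01(np.maximum(drops / cover, 0.0))
    return SaliencyMap(values, model_id=getattr(model, "config", None) and model.config.variant or "",
                       target_class=target_class, layer_id="occlusion")


def overlay(image: np.ndarray, sal: SaliencyMap, alpha: float = 0.4,
            cmap: str = "jet") -> np.ndarray:
    """Heatmap blended over the RGB image, for human inspection only; the
    raw normalized map, not this overlay, is what gets scored."""
    from matplotlib import colormaps

    colors = colormaps[cmap](sal.values)[..., :3]
    return np.clip((1 - alpha) * np.asarray(image) + alpha * colors, 0, 1)


# ---- persistence: 16-bit grayscale PNG + JSON sidecar ------------------

def save_heatmap(sal: SaliencyMap, path: str | Path) -> None:
    path = Path(path)
    iio.imwrite(path, np.round(sal.values * 65535).astype(np.uint16))
    sidecar = {
        "model_id": sal.model_id,
        "image_id": sal.image_id,
        "target_class": sal.target_class,
        "layer_id": sal.layer_id,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_heatmap(path: str | Path) -> SaliencyMap:
    path = Path(path)
    values = iio.imread(path).astype(np.float64) / 65535.0
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return SaliencyMap(values, model_id=meta.get("model_id", ""),
                       image_id=meta.get("image_id", ""),
                       target_class=meta.get("target_class", -1),
                       layer_id=meta.get("layer_id", ""))
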