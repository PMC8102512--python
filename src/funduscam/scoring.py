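"""Score binarized saliency maps against ocular-component ground truth.

The pipeline's central statistic: a heatmap is binarized with Otsu's
method, and its intersection-over-union

    IoU(X, f, c) = |D_f(X) n M_c(X)| / |D_f(X) u M_c(X)|

is computed against the binary annotation mask M_c of each ocular
component c (microaneurysm, hemorrhage, exudate, optic disc, vessels,
other). Aggregations: mean IoU per (model, component), pairwise
inter-model agreement, and the fraction of ground-truth lesions the
binarized map misses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.measure import label as cc_label

__all__ = [
    "BinaryMap", "IoURecord", "MissedPathologyRecord",
    "otsu_threshold", "binarize_otsu", "iou", "mean_iou_by_component",
    "pairwise_agreement", "missed_pathology", "permutation_null_iou",
]

N_BINS = 256  # 8-bit convention for Otsu on [0, 1] float maps


@dataclass
class BinaryMap:
    """Otsu-binarized saliency map D_f(X) with its recorded threshold."""

    values: np.ndarray
    model_id: str = ""
    image_id: str = ""
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)


@dataclass
class IoURecord:
    image_id: str
    model_id: str
    component: str
    score: float | None  # None when both sets are empty (undefined)


@dataclass
class MissedPathologyRecord:
    image_id: str
    model_id: str
    lesions_total: int
    lesions_missed: int
    percent_missed: float | None
    percent_pixels_missed: float | None


def otsu_threshold(values: np.ndarray, n_bins: int = N_BINS) -> float:
    """Threshold maximizing between-class variance on an n-bin histogram
    of [0, 1] values. Candidate thresholds are the interior bin edges;
    the first argmax wins. A constant map returns that constant."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.min() < 0 or v.max() > 1:
        raise ValueError("map values must lie in [0, 1]")
    if v.max() - v.min() < 1e-12:
        return float(v.flat[0])
    hist, edges = np.histogram(v, bins=n_bins, range=(0.0, 1.0))
    p = hist / hist.sum()
    bin_mid = (edges[:-1] + edges[1:]) / 2
    w0 = np.cumsum(p)[:-1]                       # classes split after bin k
    w1 = 1.0 - w0
    mu = np.cumsum(p * bin_mid)
    mu_t = mu[-1]
    with np.errstate(invalid="ignore", divide="ignore"):
        mu0 = mu[:-1] / w0
        mu1 = (mu_t - mu[:-1]) / w1
        sigma_b = w0 * w1 * (mu0 - mu1) ** 2
    sigma_b = np.nan_to_num(sigma_b, nan=-1.0)
    k = int(np.argmax(sigma_b))
    return float(edges[k + 1])


def binarize_otsu(sal, model_id: str = "", image_id: str = "") -> BinaryMap:
    """Binarize a saliency map; pixels strictly above the Otsu threshold
    are foreground. A constant map yields an all-zero map."""
    values = sal.values if hasattr(sal, "values") else np.asarray(sal)
    model_id = model_id or getattr(sal, "model_id", "")
    image_id = image_id or getattr(sal, "image_id", "")
    thr = otsu_threshold(values)
    return BinaryMap(values > thr, model_id=model_id, image_id=image_id, threshold=thr)


def iou(detection, mask) -> float | None:
    """|A n B| / |A u B| as an exact count ratio; None when both empty."""
    a = detection.values if isinstance(detection, BinaryMap) else np.asarray(detection).astype(bool)
    b = mask.values if isinstance(mask, BinaryMap) else np.asarray(mask).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return None
    return int(np.count_nonzero(a & b)) / union


def mean_iou_by_component(records: list[IoURecord]) -> pd.DataFrame:
    """Mean IoU per (model_id, component) over *defined* scores.

    Groups whose scores are all undefined get mean NaN, never zero; the
    defined and total counts are reported alongside each mean.
    """
    if not records:
        raise ValueError("no IoU records to aggregate")
    df = pd.DataFrame([r.__dict__ for r in records])
    df["score"] = pd.to_numeric(df["score"])  # undefined markers -> NaN
    out = (
        df.groupby(["model_id", "component"], sort=True)
        .agg(mean_iou=("score", "mean"),
             n_defined=("score", "count"),
             n_total=("score", "size"))
        .reset_index()
    )
    return out


def pairwise_agreement(
    maps_by_model: dict[str, list[BinaryMap]],
    component_masks: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Mean-over-images pairwise IoU of binarized maps between models.

    Optionally stratified by one component: each map is intersected with
    that image's component mask first. Undefined pairs (both maps empty on
    an image) are excluded from the mean. Diagonal is 1 by definition.
    """
    model_ids = sorted(maps_by_model)
    n_images = {m: len(v) for m, v in maps_by_model.items()}
    if len(set(n_images.values())) != 1:
        raise ValueError(f"models cover different image sets: {n_images}")
    n = next(iter(n_images.values()))

    def detection(model, i):
        d = maps_by_model[model][i].values
        if component_masks is not None:
            d = d & np.asarray(component_masks[i]).astype(bool)
        return d

    mat = pd.DataFrame(np.eye(len(model_ids)), index=model_ids, columns=model_ids)
    for ai, a in enumerate(model_ids):
        for b in model_ids[ai + 1:]:
            scores = [iou(detection(a, i), detection(b, i)) for i in range(n)]
            defined = [s for s in scores if s is not None]
            value = float(np.mean(defined)) if defined else np.nan
            mat.loc[a, b] = mat.loc[b, a] = value
    return mat


def missed_pathology(
    detection: BinaryMap,
    pathology_masks: dict[str, np.ndarray],
    tau: float = 0.0,
    image_id: str = "",
) -> MissedPathologyRecord:
    """Fraction of ground-truth lesions the detection map misses.

    Lesions are 4-connected components of the union of the pathology
    masks. A lesion counts as detected when its overlap with the
    detection map is at least ``tau`` of its area (any overlap when
    tau = 0). The pixel-level missed fraction is reported alongside.
    """
    union = np.zeros(detection.values.shape, dtype=bool)
    for m in pathology_masks.values():
        m = np.asarray(m).astype(bool)
        if m.shape != union.shape:
            raise ValueError("mask shape mismatch")
        union |= m
    labels = cc_label(union, connectivity=1)
    n_lesions = int(labels.max())
    det = detection.values
    missed = 0
    for lesion_id in range(1, n_lesions + 1):
        pix = labels == lesion_id
        overlap = int(np.count_nonzero(pix & det))
        area = int(np.count_nonzero(pix))
        hit = overlap >= tau * area and overlap > 0 if tau > 0 else overlap > 0
        if not hit:
            missed += 1
    if n_lesions == 0:
        pct = pct_pix = None
    else:
        pct = 100.0 * missed / n_lesions
        total_pix = int(np.count_nonzero(union))
        pct_pix = 100.0 * int(np.count_nonzero(union & ~det)) / total_pix
    return MissedPathologyRecord(
        image_id=image_id or detection.image_id,
        model_id=detection.model_id,
        lesions_total=n_lesions,
        lesions_missed=missed,
        percent_missed=pct,
        percent_pixels_missed=pct_pix,
    )


# ---- permutation null for saliency-recovery experiments ----------------

def _random_mask_placement(mask: np.ndarray, fov: np.ndarray, rng: np.random.Generator,
                           max_tries: int = 50) -> np.ndarray:
    """Randomly rotate and translate a mask while keeping it inside the FOV."""
    if not mask.any():
        return mask
    for _ in range(max_tries):
        angle = rng.uniform(0, 360)
        rotated = ndimage.rotate(mask.astype(np.uint8), angle, order=0, reshape=False) > 0
        rows, cols = np.nonzero(rotated)
        h, w = mask.shape
        dy = int(rng.integers(-rows.min(), h - 1 - rows.max() + 1))
        dx = int(rng.integers(-cols.min(), w - 1 - cols.max() + 1))
        shifted = np.zeros_like(rotated)
        shifted[rows + dy, cols + dx] = True
        if not shifted.any():
            continue
        if (shifted & fov).sum() / shifted.sum() > 0.95:
            return shifted
    return shifted


def permutation_null_iou(
    detections: list[BinaryMap],
    masks: list[np.ndarray],
    fovs: list[np.ndarray],
    n_permutations: int = 99,
    seed: int = 0,
) -> tuple[float, np.ndarray, float]:
    """Observed mean IoU vs a null of randomly re-placed masks.

    For each permutation every image's mask is independently rotated and
    translated within the field of view and the mean IoU is recomputed.
    Returns (observed, null_means, p) with the add-one permutation p-value
    for observed > null.
    """
    rng = np.random.default_rng(seed)

    def mean_iou(mask_list):
        scores = [iou(d, m) for d, m in zip(detections, mask_list)]
        defined = [s for s in scores if s is not None]
        return float(np.mean(defined)) if defined else np.nan

    observed = mean_iou(masks)
    null = np.empty(n_permutations)
    for b in range(n_permutations):
        permuted = [_random_mask_placement(np.asarray(m).astype(bool), f, rng)
                    for m, f in zip(masks, fovs)]
        null[b] = mean_iou(permuted)
    p = (1 + int(np.sum(null >= observed))) / (n_permutations + 1)
    return observed, null, p
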