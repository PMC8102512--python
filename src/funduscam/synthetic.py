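"""Seeded synthetic fundus-like images with exact component ground truth.

Each image is a circular field of view (FOV) on black, with a bright optic
disc, a branching dark-red vessel tree grown from the disc, and lesions
drawn according to per-class count ranges: microaneurysms (tiny dark
dots), hemorrhages (larger dark blots), exudates (bright yellow-white
deposits) and, for proliferative disease, neovascular tufts (tangles of
fine new vessels, recorded in the vessel mask). Every drawn element is
recorded in its component's binary mask, so the masks are exact ground
truth by construction rather than the output of a segmenter.

The DR grade is a deterministic function of lesion burden:

    0  no lesions
    1  microaneurysms only
    2  1..K hemorrhages+exudates (any microaneurysms)
    3  more than K hemorrhages
    4  neovascular tufts present

with K configurable (default 5). This gives the saliency-recovery
experiments a known causal signal: nothing but the lesions carries grade
information. A watermark mode instead encodes the grade as a block count
stamped near the top of the FOV, with lesion burden drawn independently
of the label — the falsification control for saliency scoring.

The module also implements the dataset-preparation protocol: per-class
rebalancing to a fixed cap (undersample above, oversample with repetition
below), grade-stratified 80/10/10 splitting that never lets duplicates of
one source image straddle splits, and random rotation / shift / zoom /
flip augmentation applied identically to image and masks.
"""

from __future__ import annotations

import dataclasses
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import draw as skdraw
from skimage import morphology
from skimage.transform import AffineTransform, warp

logger = logging.getLogger(__name__)

COMPONENTS = ("microaneurysm", "hemorrhage", "exudate", "optic_disc", "vessels", "other")
PATHOLOGY_COMPONENTS = ("microaneurysm", "hemorrhage", "exudate")
LESION_CLASSES = ("microaneurysm", "hemorrhage", "exudate", "neovascular_tuft")
SPLITS = ("train", "val", "test")

_COLORS = {
    "background": np.array([0.62, 0.30, 0.12]),
    "optic_disc": np.array([0.95, 0.82, 0.55]),
    "vessels": np.array([0.38, 0.10, 0.06]),
    "microaneurysm": np.array([0.30, 0.06, 0.04]),
    "hemorrhage": np.array([0.27, 0.05, 0.04]),
    "exudate": np.array([0.97, 0.92, 0.45]),
    "tuft": np.array([0.30, 0.07, 0.05]),
    "watermark": np.array([1.0, 1.0, 1.0]),
}


def _default_lesion_counts() -> dict:
    return {c: (0, 0) for c in LESION_CLASSES}


def _default_lesion_sizes() -> dict:
    return {"microaneurysm": (1, 2), "hemorrhage": (3, 6),
            "exudate": (2, 5), "neovascular_tuft": (6, 10)}


@dataclass
class SceneSpec:
    """Parameters of the synthetic scene; sizes in pixels unless noted."""

    image_size: int = 128
    fov_radius_fraction: float = 0.95
    optic_disc_offset_fraction: float = 0.45   # of FOV radius, from center
    optic_disc_radius_range: tuple = (0.07, 0.10)  # fraction of image_size
    vessel_branch_count: int = 6
    vessel_depth: int = 3
    vessel_width_range: tuple = (1, 2)
    lesion_counts: dict = field(default_factory=_default_lesion_counts)
    lesion_size_ranges: dict = field(default_factory=_default_lesion_sizes)
    noise_sd: float = 0.02
    grade_threshold_k: int = 5
    seed: int = 0

    def validate(self) -> None:
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if not 0 < self.fov_radius_fraction <= 1:
            raise ValueError("fov_radius_fraction must be in (0, 1]")
        for name, rng_ in self.lesion_counts.items():
            if name not in LESION_CLASSES:
                raise ValueError(f"lesion_counts: unknown class {name!r}")
            lo, hi = rng_
            if lo < 0 or hi < lo:
                raise ValueError(f"lesion_counts[{name!r}] must be a non-negative range")
        for name, rng_ in self.lesion_size_ranges.items():
            lo, hi = rng_
            if lo < 0 or hi < lo:
                raise ValueError(f"lesion_size_ranges[{name!r}] must be a non-negative range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        disc_extent = (self.optic_disc_offset_fraction * self.fov_radius_fraction / 2
                       + self.optic_disc_radius_range[1]) * self.image_size
        if disc_extent > self.fov_radius_fraction * self.image_size / 2:
            raise ValueError("optic_disc does not fit inside the field of view")

    def replace(self, **kw) -> "SceneSpec":
        return dataclasses.replace(self, **kw)


@dataclass
class AnnotatedFundus:
    """An image, its exact component masks, and its grade label."""

    image: np.ndarray                   # H x W x 3 in [0, 1]
    masks: dict                         # component -> H x W bool
    grade: int
    image_id: str = ""

    def fov(self) -> np.ndarray:
        named = np.zeros(self.image.shape[:2], dtype=bool)
        for m in self.masks.values():
            named |= m
        return named

    def pathology_masks(self) -> dict:
        return {c: self.masks[c] for c in PATHOLOGY_COMPONENTS}


def classify_grade(counts: dict, k: int = 5) -> int:
    """Deterministic lesion-burden grade rule (see module docstring)."""
    if counts.get("neovascular_tuft", 0) > 0:
        return 4
    if counts.get("hemorrhage", 0) > k:
        return 3
    if counts.get("hemorrhage", 0) + counts.get("exudate", 0) > 0:
        return 2
    if counts.get("microaneurysm", 0) > 0:
        return 1
    return 0


def spec_for_grade(spec: SceneSpec, grade: int) -> SceneSpec:
    """Lesion-count ranges that force the given grade under the grade rule."""
    k = spec.grade_threshold_k
    table = {
        0: {"microaneurysm": (0, 0), "hemorrhage": (0, 0),
            "exudate": (0, 0), "neovascular_tuft": (0, 0)},
        1: {"microaneurysm": (2, 6), "hemorrhage": (0, 0),
            "exudate": (0, 0), "neovascular_tuft": (0, 0)},
        2: {"microaneurysm": (0, 4), "hemorrhage": (1, min(3, k)),
            "exudate": (1, 3), "neovascular_tuft": (0, 0)},
        3: {"microaneurysm": (0, 4), "hemorrhage": (k + 1, k + 5),
            "exudate": (0, 3), "neovascular_tuft": (0, 0)},
        4: {"microaneurysm": (0, 4), "hemorrhage": (k + 1, k + 5),
            "exudate": (1, 3), "neovascular_tuft": (1, 2)},
    }
    if grade not in table:
        raise ValueError("grade must be in 0..4")
    return spec.replace(lesion_counts=table[grade])


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def _disk(center, radius, shape):
    rr, cc = skdraw.disk(center, radius, shape=shape)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _paint(image, mask, color, alpha=1.0):
    image[mask] = (1 - alpha) * image[mask] + alpha * color


def _random_point_in_fov(rng, center, fov_r, margin):
    r = (fov_r - margin) * np.sqrt(rng.uniform())
    theta = rng.uniform(0, 2 * np.pi)
    return center[0] + r * np.sin(theta), center[1] + r * np.cos(theta)


def _grow_vessel_tree(rng, shape, start, fov_r, center, n_branches, depth, width_range):
    """Random-walk branching tree on a bool canvas; returns the vessel mask."""
    mask = np.zeros(shape, dtype=bool)
    size = shape[0]
    step = max(4, size // 16)

    def walk(pos, direction, level):
        canvas = np.zeros(shape, dtype=bool)
        n_steps = rng.integers(3, 7)
        for _ in range(n_steps):
            direction += rng.normal(0, 0.45)
            nxt = (pos[0] + step * np.sin(direction), pos[1] + step * np.cos(direction))
            if (nxt[0] - center[0]) ** 2 + (nxt[1] - center[1]) ** 2 > (0.97 * fov_r) ** 2:
                break
            rr, cc = skdraw.line(int(round(pos[0])), int(round(pos[1])),
                                 int(round(nxt[0])), int(round(nxt[1])))
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[keep], cc[keep]] = True
            pos = nxt
            if level < depth and rng.uniform() < 0.35:
                walk(pos, direction + rng.choice([-1, 1]) * rng.uniform(0.5, 1.2),
                     level + 1)
        width = int(rng.integers(width_range[0], width_range[1] + 1))
        thick = morphology.dilation(canvas, morphology.disk(max(0, width - 1)))
        mask[thick] = True

    for _ in range(n_branches):
        walk(start, rng.uniform(0, 2 * np.pi), 1)
    return mask


def _draw_tuft(rng, shape, center_pt, radius):
    canvas = np.zeros(shape, dtype=bool)
    size = shape[0]
    for _ in range(6):
        pos = np.array(center_pt, dtype=float)
        direction = rng.uniform(0, 2 * np.pi)
        for _ in range(8):
            direction += rng.normal(0, 0.9)
            nxt = pos + radius / 3 * np.array([np.sin(direction), np.cos(direction)])
            if np.hypot(*(nxt - center_pt)) > radius:
                break
            rr, cc = skdraw.line(int(round(pos[0])), int(round(pos[1])),
                                 int(round(nxt[0])), int(round(nxt[1])))
            keep = (rr >= 0) & (rr < size) & (cc >= 0) & (cc < size)
            canvas[rr[keep], cc[keep]] = True
            pos = nxt
    return morphology.dilation(canvas, morphology.disk(1))


def generate_image(spec: SceneSpec, seed: int, watermark: int | None = None) -> AnnotatedFundus:
    """Render one annotated fundus; deterministic given (spec, seed).

    With ``watermark`` set, the grade equals the watermark value and is
    encoded as watermark+1 bright blocks near the top of the FOV; lesion
    burden is then unrelated to the label, and the stamped region is
    returned under an extra ``watermark`` mask key.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    size = spec.image_size
    shape = (size, size)
    center = ((size - 1) / 2, (size - 1) / 2)
    fov_r = spec.fov_radius_fraction * size / 2
    fov = _disk(center, fov_r, shape)

    # background with radial vignette and sensor-like noise
    yy, xx = np.mgrid[0:size, 0:size]
    r2 = ((yy - center[0]) ** 2 + (xx - center[1]) ** 2) / fov_r**2
    shade = 1.0 - 0.25 * np.clip(r2, 0, 1)
    image = _COLORS["background"] * shade[..., None]
    image += rng.normal(0, spec.noise_sd, size=image.shape)
    image = np.clip(image, 0, 1)
    image[~fov] = 0.0

    masks = {c: np.zeros(shape, dtype=bool) for c in COMPONENTS}

    # optic disc
    disc_r = rng.uniform(*spec.optic_disc_radius_range) * size
    angle = rng.uniform(0, 2 * np.pi)
    dist = spec.optic_disc_offset_fraction * fov_r
    disc_c = (center[0] + dist * np.sin(angle), center[1] + dist * np.cos(angle))
    masks["optic_disc"] = _disk(disc_c, disc_r, shape) & fov
    _paint(image, masks["optic_disc"], _COLORS["optic_disc"], alpha=0.9)

    # vessel tree from the disc
    masks["vessels"] = _grow_vessel_tree(
        rng, shape, disc_c, fov_r, center, spec.vessel_branch_count,
        spec.vessel_depth, spec.vessel_width_range) & fov
    _paint(image, masks["vessels"], _COLORS["vessels"], alpha=0.85)

    # lesions
    counts = {c: int(rng.integers(lo, hi + 1))
              for c, (lo, hi) in spec.lesion_counts.items()}
    for _ in range(counts.get("neovascular_tuft", 0)):
        radius = rng.uniform(*spec.lesion_size_ranges["neovascular_tuft"])
        pt = _random_point_in_fov(rng, center, fov_r, radius + 2)
        tuft = _draw_tuft(rng, shape, pt, radius) & fov
        masks["vessels"] |= tuft
        _paint(image, tuft, _COLORS["tuft"], alpha=0.9)
    for _ in range(counts.get("hemorrhage", 0)):
        r_a = rng.uniform(*spec.lesion_size_ranges["hemorrhage"])
        r_b = r_a * rng.uniform(0.6, 1.0)
        pt = _random_point_in_fov(rng, center, fov_r, r_a + 2)
        rr, cc = skdraw.ellipse(pt[0], pt[1], r_a, r_b, shape=shape,
                                rotation=rng.uniform(0, np.pi))
        blob = np.zeros(shape, dtype=bool)
        blob[rr, cc] = True
        blob &= fov
        masks["hemorrhage"] |= blob
        _paint(image, blob, _COLORS["hemorrhage"], alpha=0.9)
    for _ in range(counts.get("exudate", 0)):
        radius = rng.uniform(*spec.lesion_size_ranges["exudate"])
        pt = _random_point_in_fov(rng, center, fov_r, radius + 2)
        blob = _disk(pt, radius, shape) & fov
        masks["exudate"] |= blob
        _paint(image, blob, _COLORS["exudate"], alpha=0.95)
    for _ in range(counts.get("microaneurysm", 0)):
        radius = rng.uniform(*spec.lesion_size_ranges["microaneurysm"])
        pt = _random_point_in_fov(rng, center, fov_r, radius + 2)
        blob = _disk(pt, radius, shape) & fov
        masks["microaneurysm"] |= blob
        _paint(image, blob, _COLORS["microaneurysm"], alpha=0.9)

    if watermark is not None:
        grade = int(watermark)
        wm = np.zeros(shape, dtype=bool)
        block = max(3, size // 24)
        top = int(center[0] - fov_r + 3)
        left0 = int(center[1] - 2.5 * 1.4 * block)
        for b in range(grade + 1):
            left = left0 + int(b * 1.4 * block)
            wm[top : top + block, left : left + block] = True
        wm &= fov
        masks["watermark"] = wm
        _paint(image, wm, _COLORS["watermark"])
    else:
        grade = classify_grade(counts, spec.grade_threshold_k)

    named = np.zeros(shape, dtype=bool)
    for c, m in masks.items():
        if c != "other":
            named |= m
    masks["other"] = fov & ~named
    return AnnotatedFundus(image=image, masks=masks, grade=grade)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

@dataclass
class AugmentParams:
    """Sampling ranges for random augmentation (defaults: full rotation,
    0.15 shift fraction, 0.1 zoom fraction, both flips)."""

    rotation: float = 360.0
    shift: float = 0.15
    zoom: float = 0.1
    hflip: bool = True
    vflip: bool = True

    def validate(self) -> None:
        if self.rotation < 0 or self.shift < 0 or self.zoom < 0:
            raise ValueError("augmentation ranges must be non-negative")


@dataclass
class FundusTransform:
    """One concrete sampled transform, applied identically to image and masks."""

    rotation_deg: float = 0.0
    shift_y: float = 0.0     # fraction of image height
    shift_x: float = 0.0
    zoom: float = 1.0
    hflip: bool = False
    vflip: bool = False

    def is_identity(self) -> bool:
        return (self.rotation_deg == 0 and self.shift_y == 0 and self.shift_x == 0
                and self.zoom == 1.0 and not self.hflip and not self.vflip)


def sample_transform(params: AugmentParams, rng: np.random.Generator) -> FundusTransform:
    params.validate()
    return FundusTransform(
        rotation_deg=rng.uniform(-params.rotation, params.rotation),
        shift_y=rng.uniform(-params.shift, params.shift),
        shift_x=rng.uniform(-params.shift, params.shift),
        zoom=rng.uniform(1 - params.zoom, 1 + params.zoom),
        hflip=params.hflip and rng.uniform() < 0.5,
        vflip=params.vflip and rng.uniform() < 0.5,
    )


def _forward_matrix(t: FundusTransform, size: int) -> np.ndarray:
    # homogeneous (x, y) coordinates; rotate/zoom/flip about the pixel center
    c = (size - 1) / 2.0

    def trans(tx, ty):
        m = np.eye(3)
        m[0, 2], m[1, 2] = tx, ty
        return m

    theta = np.deg2rad(t.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1]])
    scale = np.diag([t.zoom, t.zoom, 1.0])
    flip = np.diag([-1.0 if t.hflip else 1.0, -1.0 if t.vflip else 1.0, 1.0])
    shift = trans(t.shift_x * size, t.shift_y * size)
    return shift @ trans(c, c) @ rot @ scale @ flip @ trans(-c, -c)


def apply_transform(item: AnnotatedFundus, t: FundusTransform) -> AnnotatedFundus:
    """Warp image (bilinear) and masks (nearest-neighbour) by one transform;
    pixels leaving the frame become black / background-free."""
    if t.is_identity():
        return AnnotatedFundus(image=item.image.copy(),
                               masks={c: m.copy() for c, m in item.masks.items()},
                               grade=item.grade, image_id=item.image_id)
    size = item.image.shape[0]
    inv = AffineTransform(matrix=np.linalg.inv(_forward_matrix(t, size)))
    image = warp(item.image, inv, order=1, cval=0.0, preserve_range=True)
    masks = {c: warp(m.astype(np.float64), inv, order=0, cval=0.0,
                     preserve_range=True) > 0.5
             for c, m in item.masks.items()}
    return AnnotatedFundus(image=np.clip(image, 0, 1), masks=masks,
                           grade=item.grade, image_id=item.image_id)


def augment(item: AnnotatedFundus, params: AugmentParams, seed: int) -> AnnotatedFundus:
    """Randomly transform an annotated image; deterministic given seed."""
    rng = np.random.default_rng(seed)
    return apply_transform(item, sample_transform(params, rng))


# ---------------------------------------------------------------------------
# dataset manifest: generation, rebalancing, splitting, I/O
# ---------------------------------------------------------------------------

def _mask_cols(masks: dict) -> list[str]:
    return [f"mask_{c}" for c in masks]


def write_item(item: AnnotatedFundus, out_dir: Path) -> dict:
    """Write PNG image + per-component PNG masks; return a manifest row."""
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    img_path = out_dir / "images" / f"{item.image_id}.png"
    iio.imwrite(img_path, np.round(item.image * 255).astype(np.uint8))
    row = {"image_id": item.image_id, "path": str(img_path),
           "grade": item.grade, "split": "unassigned"}
    for c, m in item.masks.items():
        mpath = out_dir / "masks" / f"{item.image_id}_{c}.png"
        iio.imwrite(mpath, (m.astype(np.uint8) * 255))
        row[f"mask_{c}"] = str(mpath)
    logger.info("wrote %s (grade %d)", img_path, item.grade)
    return row


def load_item(row: pd.Series) -> AnnotatedFundus:
    image = iio.imread(row["path"]).astype(np.float64) / 255.0
    masks = {}
    for col in row.index:
        if col.startswith("mask_") and isinstance(row[col], str) and row[col]:
            masks[col[len("mask_"):]] = iio.imread(row[col]) > 127
    return AnnotatedFundus(image=image, masks=masks,
                           grade=int(row["grade"]), image_id=str(row["image_id"]))


def generate_dataset(
    spec: SceneSpec,
    n_per_grade: int,
    seed: int,
    out_dir: str | Path,
    watermark: bool = False,
) -> pd.DataFrame:
    """Generate n_per_grade images per grade, write files + manifest CSV.

    In watermark mode the grade is stamped into the image and lesion
    counts are drawn from a grade-independent distribution (the spec's
    grade-2 ranges), severing the lesion-label link.
    """
    if n_per_grade < 1:
        raise ValueError("n_per_grade must be >= 1")
    out_dir = Path(out_dir)
    rows = []
    for grade in range(5):
        grade_spec = spec_for_grade(spec, 2 if watermark else grade)
        for i in range(n_per_grade):
            item_seed = int(np.random.SeedSequence([seed, grade, i]).generate_state(1)[0])
            item = generate_image(grade_spec, item_seed,
                                  watermark=grade if watermark else None)
            item.image_id = f"g{grade}_{i:04d}"
            rows.append(write_item(item, out_dir))
    manifest = pd.DataFrame(rows)
    save_manifest(manifest, out_dir / "manifest.csv")
    return manifest


def _path_columns(manifest: pd.DataFrame) -> list[str]:
    return [c for c in manifest.columns
            if c == "path" or c.startswith("mask_")]


def save_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    """Write the manifest CSV with file paths relative to its location,
    so a dataset directory can be moved or compared across runs."""
    path = Path(path)
    out = manifest.copy()
    base = path.parent.resolve()
    for col in _path_columns(out):
        out[col] = [os.path.relpath(Path(p).resolve(), base) if isinstance(p, str) and p
                    else p for p in out[col]]
    out.to_csv(path, index=False)
    logger.info("wrote manifest %s (%d rows)", path, len(manifest))


def read_manifest(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    manifest = pd.read_csv(path)
    base = path.parent.resolve()
    for col in _path_columns(manifest):
        manifest[col] = [str(base / p) if isinstance(p, str) and p and not os.path.isabs(p)
                         else p for p in manifest[col]]
    return manifest


def rebalance(manifest: pd.DataFrame, cap: int, seed: int = 0) -> pd.DataFrame:
    """Under/oversample every grade to exactly ``cap`` rows.

    Classes above the cap are sampled without replacement; classes below
    it repeat rows (duplicates are legitimate manifest rows, de-duplicated
    in effect by downstream random augmentation).
    """
    if manifest.empty:
        raise ValueError("empty manifest")
    if cap < 1:
        raise ValueError("cap must be >= 1")
    rng = np.random.default_rng(seed)
    parts = []
    for grade in sorted(manifest["grade"].unique()):
        grp = manifest[manifest["grade"] == grade]
        n = len(grp)
        if n == 0:
            raise ValueError(f"grade {grade} has no images; cannot oversample")
        if n >= cap:
            idx = rng.choice(n, size=cap, replace=False)
        else:
            reps = np.tile(np.arange(n), cap // n)
            extra = rng.choice(n, size=cap - len(reps), replace=False)
            idx = np.concatenate([reps, extra])
            rng.shuffle(idx)
        parts.append(grp.iloc[idx])
    missing = set(range(5)) - set(manifest["grade"].unique())
    if missing:
        raise ValueError(f"grades {sorted(missing)} have no images; cannot oversample")
    return pd.concat(parts, ignore_index=True)


def split(
    manifest: pd.DataFrame,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> pd.DataFrame:
    """Grade-stratified train/val/test assignment.

    All rows sharing one source image_id (oversampling duplicates) are
    assigned as a group to a single split, so duplicates never leak
    between training and evaluation.
    """
    fractions = tuple(float(f) for f in fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    out = manifest.copy()
    out["split"] = "unassigned"
    for grade in sorted(out["grade"].unique()):
        grp = out[out["grade"] == grade]
        groups = grp.groupby("image_id").size()
        if len(groups) < len(SPLITS):
            raise ValueError(
                f"grade {grade} has {len(groups)} distinct images; "
                f"need at least {len(SPLITS)} to fill every split")
        ids = groups.index.to_numpy()
        rng.shuffle(ids)
        total = len(grp)
        targets = {s: f * total for s, f in zip(SPLITS, fractions)}
        assigned = {s: 0 for s in SPLITS}
        order = sorted(SPLITS, key=lambda s: -targets[s])
        # guarantee every split is non-empty, then fill by largest deficit
        for s, image_id in zip(SPLITS, ids):
            out.loc[(out["grade"] == grade) & (out["image_id"] == image_id),
                    "split"] = s
            assigned[s] += int(groups[image_id])
        for image_id in ids[len(SPLITS):]:
            s = max(order, key=lambda s: targets[s] - assigned[s])
            out.loc[(out["grade"] == grade) & (out["image_id"] == image_id),
                    "split"] = s
            assigned[s] += int(groups[image_id])
    return out


def load_split_arrays(manifest: pd.DataFrame, split_name: str) -> tuple[np.ndarray, np.ndarray]:
    """Stack a split's images into an NHWC array with its grade labels."""
    rows = manifest[manifest["split"] == split_name]
    images = np.stack([load_item(r).image for _, r in rows.iterrows()])
    labels = rows["grade"].to_numpy(dtype=int)
    return images, labels


def diaretdb1_like_manifest(spec: SceneSpec | None = None, seed: int = 0,
                            out_dir: str | Path | None = None) -> pd.DataFrame:
    """A fixture mirroring the published DIARETDB1 per-grade composition:
    27 normal, 7 mild, 28 moderate-and-severe (split 14/14 across grades
    2 and 3), 27 proliferative — 89 images in total. The source reports
    these grade counts alongside a partially inconsistent count of
    sign-free images; the fixture mirrors the per-grade numbers."""
    counts = {0: 27, 1: 7, 2: 14, 3: 14, 4: 27}
    if out_dir is None:
        rows = [{"image_id": f"g{g}_{i:04d}", "path": "", "grade": g,
                 "split": "unassigned"} for g, n in counts.items() for i in range(n)]
        return pd.DataFrame(rows)
    spec = spec or SceneSpec(image_size=64)
    rows = []
    for grade, n in counts.items():
        grade_spec = spec_for_grade(spec, grade)
        for i in range(n):
            item_seed = int(np.random.SeedSequence([seed, grade, i]).generate_state(1)[0])
            item = generate_image(grade_spec, item_seed)
            item.image_id = f"g{grade}_{i:04d}"
            rows.append(write_item(item, Path(out_dir)))
    manifest = pd.DataFrame(rows)
    save_manifest(manifest, Path(out_dir) / "manifest.csv")
    return manifest
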