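"""Scene-to-crop preprocessing for seed photographs on a dark background.

The pipeline mirrors a standard imaging-rig workflow: seeds are laid out in
a grid on black light-absorbing cloth, photographed, and individual seeds
are recovered by global threshold segmentation followed by connected
component / contour extraction:

1. grayscale conversion (Rec. 601 luma),
2. fixed-threshold binarization (default 0.3 on [0, 1] intensities),
3. pixelwise masking of the original image,
4. per-component bounding-box cropping with padding,
5. quality filtering (foreground area, Laplacian-variance sharpness),
6. a per-class 6:2:2 train/validation/test split.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import measure

LUMA_WEIGHTS = (0.299, 0.587, 0.114)  # Rec. 601


@dataclass
class SeedScene:
    """RGB scene, channel-first (3, H, W), intensities in [0, 1]."""

    rgb: np.ndarray
    label: str | None = None

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb, dtype=np.float32)
        if self.rgb.ndim != 3 or self.rgb.shape[0] != 3:
            raise ValueError(f"expected (3, H, W) image, got {self.rgb.shape}")

    @property
    def shape(self):
        return self.rgb.shape[1:]


@dataclass
class BinaryMask:
    mask: np.ndarray
    threshold: float

    def __post_init__(self):
        self.mask = np.asarray(self.mask)
        vals = np.unique(self.mask)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask values must be 0 or 1")


@dataclass
class SeedCrop:
    rgb: np.ndarray                       # (3, h, w) masked crop
    box: tuple[int, int, int, int]        # x0, y0, x1, y1 (half-open)
    label: str | None = None
    area: int = 0                         # foreground pixel count
    sharpness: float = 0.0                # Laplacian variance
    contour: np.ndarray | None = None     # (n, 2) outer contour (row, col)
    flags: list[str] = field(default_factory=list)


def to_grayscale(scene: SeedScene | np.ndarray) -> np.ndarray:
    """Rec. 601 luma 0.299 R + 0.587 G + 0.114 B of a [0, 1] RGB image."""
    rgb = scene.rgb if isinstance(scene, SeedScene) else np.asarray(scene)
    if rgb.min() < 0 or rgb.max() > 1:
        raise ValueError("intensities must be normalized to [0, 1]")
    r, g, b = LUMA_WEIGHTS
    return r * rgb[0] + g * rgb[1] + b * rgb[2]


def threshold_segment(gray: np.ndarray, t: float = 0.3) -> BinaryMask:
    """Foreground where luma >= t (pixels exactly at t count as foreground)."""
    if not 0.0 < t < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {t}")
    gray = np.asarray(gray)
    return BinaryMask((gray >= t).astype(np.uint8), t)


def apply_mask(scene: SeedScene, mask: BinaryMask) -> SeedScene:
    """Pixelwise product of scene and mask; background goes to exact zero."""
    if scene.shape != mask.mask.shape:
        raise ValueError(
            f"scene extent {scene.shape} != mask extent {mask.mask.shape}")
    return SeedScene(scene.rgb * mask.mask[None, :, :], scene.label)


def extract_seed_crops(scene: SeedScene, mask: BinaryMask,
                       pad: int = 4) -> list[SeedCrop]:
    """Crop each 8-connected foreground component of the masked scene.

    Boxes are the components' tight bounding boxes expanded by ``pad`` pixels
    and clipped to the scene; crops are ordered row-major by box top-left.
    """
    labels = measure.label(mask.mask, connectivity=2)
    masked = apply_mask(scene, mask)
    H, W = scene.shape
    crops = []
    for region in measure.regionprops(labels):
        y0, x0, y1, x1 = region.bbox
        y0, x0 = max(0, y0 - pad), max(0, x0 - pad)
        y1, x1 = min(H, y1 + pad), min(W, x1 + pad)
        rgb = masked.rgb[:, y0:y1, x0:x1]
        component = (labels[y0:y1, x0:x1] == region.label)
        contours = measure.find_contours(
            np.pad(component.astype(float), 1), 0.5)
        contour = (max(contours, key=len) - 1.0) if contours else None
        gray = to_grayscale(rgb)
        lap = ndimage.laplace(gray.astype(np.float64))
        crops.append(SeedCrop(
            rgb=rgb, box=(x0, y0, x1, y1), label=scene.label,
            area=int(region.area), sharpness=float(lap.var()),
            contour=contour))
    crops.sort(key=lambda c: (c.box[1], c.box[0]))
    return crops


def filter_crops(crops: list[SeedCrop], min_area: int = 50,
                 max_area: int = 100_000,
                 min_sharpness: float = 0.0) -> list[SeedCrop]:
    """Drop crops outside the area band or below the sharpness floor."""
    if min_area > max_area:
        raise ValueError(f"min_area {min_area} > max_area {max_area}")
    kept, removed = [], {"area": 0, "sharpness": 0}
    for c in crops:
        if not min_area <= c.area <= max_area:
            c.flags.append("area")
            removed["area"] += 1
        elif c.sharpness < min_sharpness:
            c.flags.append("blurred")
            removed["sharpness"] += 1
        else:
            kept.append(c)
    if any(removed.values()):
        warnings.warn(
            f"filter_crops removed {removed['area']} by area, "
            f"{removed['sharpness']} by sharpness", stacklevel=2)
    return kept


def letterbox(rgb: np.ndarray, size: int = 224) -> np.ndarray:
    """Aspect-preserving resize onto a black size x size canvas."""
    from PIL import Image

    c, h, w = rgb.shape
    scale = size / max(h, w)
    nh, nw = max(1, round(h * scale)), max(1, round(w * scale))
    img = Image.fromarray(
        (np.clip(rgb, 0, 1).transpose(1, 2, 0) * 255).astype(np.uint8))
    img = img.resize((nw, nh), Image.BILINEAR)
    out = np.zeros((size, size, 3), dtype=np.uint8)
    y0, x0 = (size - nh) // 2, (size - nw) // 2
    out[y0:y0 + nh, x0:x0 + nw] = np.asarray(img)
    return out.transpose(2, 0, 1).astype(np.float32) / 255.0


@dataclass
class DatasetSplit:
    """Per-class partition into train / validation / test item lists."""

    ratios: tuple[float, float, float]
    seed: int
    train: dict[str, list] = field(default_factory=dict)
    val: dict[str, list] = field(default_factory=dict)
    test: dict[str, list] = field(default_factory=dict)

    def counts(self) -> dict[str, tuple[int, int, int]]:
        return {k: (len(self.train[k]), len(self.val[k]), len(self.test[k]))
                for k in self.train}

    def totals(self) -> tuple[int, int, int]:
        c = self.counts().values()
        return tuple(sum(x[i] for x in c) for i in range(3))


def split_counts(n: int, ratios=(0.6, 0.2, 0.2)) -> tuple[int, int, int]:
    """Train count = round(r_train * N), remainder split floor/ceil."""
    n_train = math.floor(ratios[0] * n + 0.5)
    rem = n - n_train
    n_val = rem // 2
    return n_train, n_val, rem - n_val


def split_dataset(items: dict[str, list], ratios=(0.6, 0.2, 0.2),
                  seed: int = 0) -> DatasetSplit:
    """Per-class shuffled partition at the given ratios (default 6:2:2)."""
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"ratios must sum to 1, got {ratios}")
    split = DatasetSplit(tuple(ratios), seed)
    for ci, cls in enumerate(sorted(items)):
        lst = list(items[cls])
        if len(lst) < 3:
            raise ValueError(
                f"class {cls!r} has {len(lst)} items; need >= 3 to populate "
                "train/val/test")
        rng = np.random.Generator(np.random.PCG64(
            np.random.SeedSequence([seed, ci])))
        order = rng.permutation(len(lst))
        n_train, n_val, n_test = split_counts(len(lst), ratios)
        shuffled = [lst[i] for i in order]
        split.train[cls] = shuffled[:n_train]
        split.val[cls] = shuffled[n_train:n_train + n_val]
        split.test[cls] = shuffled[n_train + n_val:]
    return split


def segment_scene(scene: SeedScene, threshold: float = 0.3, pad: int = 4,
                  min_area: int = 50, max_area: int = 100_000,
                  min_sharpness: float = 0.0) -> list[SeedCrop]:
    """Full scene -> filtered crops convenience pipeline."""
    mask = threshold_segment(to_grayscale(scene), threshold)
    crops = extract_seed_crops(scene, mask, pad=pad)
    return filter_crops(crops, min_area, max_area, min_sharpness)


def write_dataset(split: DatasetSplit, out_dir: str | Path,
                  crop_size: int = 224) -> Path:
    """Write crops as PNG in a dataset/{train,val,test}/<class>/ layout plus
    a manifest CSV; returns the manifest path."""
    from PIL import Image

    out = Path(out_dir)
    manifest = out / "manifest.csv"
    out.mkdir(parents=True, exist_ok=True)
    with open(manifest, "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["crop_id", "class", "split", "x0", "y0", "x1", "y1",
                     "area", "sharpness", "flags"])
        for part_name, part in (("train", split.train), ("val", split.val),
                                ("test", split.test)):
            for cls, crops in part.items():
                d = out / part_name / str(cls)
                d.mkdir(parents=True, exist_ok=True)
                for i, crop in enumerate(crops):
                    cid = f"{cls}_{part_name}_{i:05d}"
                    arr = letterbox(crop.rgb, crop_size)
                    img = (arr.transpose(1, 2, 0) * 255).astype(np.uint8)
                    Image.fromarray(img).save(d / f"{cid}.png")
                    wr.writerow([cid, cls, part_name, *crop.box,
                                 crop.area, f"{crop.sharpness:.6g}",
                                 ";".join(crop.flags)])
    return manifest
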