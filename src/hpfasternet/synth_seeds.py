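"""Synthetic seed-scene generator.

Emulates the imaging rig the classifier is built for: bright ellipsoidal
seeds laid out in a non-overlapping grid (default 10 x 20, i.e. 200 seeds
per photograph) on a dark light-absorbing background.  Seeds are rendered
as rotated super-ellipses with multiplicative speckle texture, which is the
simplest shape family exhibiting the length / width / color / texture cues
that distinguish real seed varieties.

Two difficulty regimes are provided: ``separated`` phenotypes differ
strongly in size and color (a mean-color + area nearest-centroid classifier
already separates them), while ``hard`` phenotypes overlap by construction
(between-class mean differences below the within-class spread).

All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` so scenes are byte-identical across runs.
"""

from __future__ import annotations

import colorsys
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import preprocess as pp

BACKGROUND_LEVEL = 0.05
BACKGROUND_NOISE = 0.02
DEFAULT_PITCH = 80  # px between grid cells; 10 x 20 grid -> 800 x 1600 canvas


@dataclass(frozen=True)
class SeedPhenotype:
    """Per-class appearance model for rendered seeds (pixel units)."""

    class_id: int
    length_mean: float
    length_sd: float
    width_mean: float
    width_sd: float
    color: tuple[float, float, float]     # base RGB, all well above threshold
    speckle_density: float = 1.5          # smoothing sigma of the texture
    speckle_amp: float = 0.08
    blur_sigma: float = 0.0
    shape_power: float = 2.5              # super-ellipse exponent

    def __post_init__(self):
        if self.length_mean <= self.width_mean:
            raise ValueError("seed length must exceed width")
        luma = sum(w * c for w, c in zip(pp.LUMA_WEIGHTS, self.color))
        if luma < 0.4:
            raise ValueError(
                f"expected seed-body luma > threshold + margin, got {luma:.3f}")


@dataclass
class Instance:
    class_id: int
    center: tuple[float, float]           # (row, col)
    axes: tuple[float, float]             # (semi-length, semi-width)
    angle: float                          # radians
    box: tuple[int, int, int, int]        # x0, y0, x1, y1 half-open


@dataclass
class SyntheticScene:
    scene: pp.SeedScene
    instances: list[Instance]
    instance_mask: np.ndarray             # int label image, 0 = background
    seed: int


def sample_phenotypes(K: int, seed: int = 0,
                      mode: str = "separated") -> list[SeedPhenotype]:
    """K pairwise-distinct phenotypes; deterministic in ``seed``."""
    if K < 1:
        raise ValueError(f"need at least one class, got K={K}")
    if mode not in ("separated", "hard"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence([seed])))
    phenos = []
    for k in range(K):
        if mode == "separated":
            # sizes and hues spread far apart relative to within-class sd
            length = 36.0 + 24.0 * (k / max(1, K - 1)) + rng.uniform(-1, 1)
            width = 14.0 + 10.0 * ((k * 7 % K) / max(1, K - 1)) \
                + rng.uniform(-0.5, 0.5)
            hue = (k * 0.618034) % 1.0
            sat = 0.35 + 0.3 * ((k * 3 % K) / max(1, K))
            rgb = colorsys.hsv_to_rgb(hue, sat, 0.85)
            length_sd, width_sd = 1.5, 0.8
            amp = 0.05 + 0.1 * ((k * 5 % K) / max(1, K))
        else:
            # between-class mean gaps below the within-class sd
            length_sd, width_sd = 4.0, 2.0
            length = 48.0 + rng.uniform(-1.5, 1.5)
            width = 20.0 + rng.uniform(-0.8, 0.8)
            rgb = colorsys.hsv_to_rgb(0.12 + rng.uniform(-0.01, 0.01), 0.4, 0.8)
            amp = 0.08
        width = min(width, length - 6.0)
        phenos.append(SeedPhenotype(
            class_id=k, length_mean=length, length_sd=length_sd,
            width_mean=width, width_sd=width_sd,
            color=tuple(round(c, 4) for c in rgb),
            speckle_amp=round(float(amp), 4)))
    return phenos


def _render_instance(canvas, rng, pheno: SeedPhenotype, cy: float, cx: float):
    """Draw one speckled super-ellipse; returns (alpha patch, y0, x0)."""
    a = max(4.0, rng.normal(pheno.length_mean, pheno.length_sd)) / 2.0
    b = max(2.5, rng.normal(pheno.width_mean, pheno.width_sd)) / 2.0
    b = min(b, a - 1.0)
    theta = rng.uniform(0, np.pi)
    half = int(np.ceil(max(a, b))) + 3
    y0, x0 = int(round(cy)) - half, int(round(cx)) - half
    n = 2 * half + 1
    yy, xx = np.mgrid[0:n, 0:n]
    dy, dx = yy + y0 - cy, xx + x0 - cx
    u = dx * np.cos(theta) + dy * np.sin(theta)
    v = -dx * np.sin(theta) + dy * np.cos(theta)
    p = pheno.shape_power
    f = (np.abs(u) / a) ** p + (np.abs(v) / b) ** p
    alpha = 1.0 / (1.0 + np.exp(np.clip((f - 1.0) / 0.04, -60.0, 60.0)))
    speckle = ndimage.gaussian_filter(rng.standard_normal((n, n)),
                                      pheno.speckle_density)
    speckle = 1.0 + pheno.speckle_amp * speckle / max(1e-9, speckle.std())
    patch = np.empty((3, n, n))
    for c in range(3):
        patch[c] = np.clip(pheno.color[c] * speckle, 0.45, 1.0)
    if pheno.blur_sigma > 0:
        alpha = ndimage.gaussian_filter(alpha, pheno.blur_sigma)
        patch = ndimage.gaussian_filter(patch, (0, pheno.blur_sigma,
                                                pheno.blur_sigma))
    H, W = canvas.shape[1:]
    if y0 < 0 or x0 < 0 or y0 + n > H or x0 + n > W:
        raise ValueError("seed does not fit inside the canvas")
    region = canvas[:, y0:y0 + n, x0:x0 + n]
    canvas[:, y0:y0 + n, x0:x0 + n] = alpha * patch + (1 - alpha) * region
    return alpha, y0, x0, (a, b, theta)


def render_scene(phenotype: SeedPhenotype, rows: int = 10, cols: int = 20,
                 seed: int = 0, pitch: int = DEFAULT_PITCH) -> SyntheticScene:
    """Render a rows x cols grid of one variety on a dark noisy background."""
    max_dim = phenotype.length_mean + 4 * phenotype.length_sd
    if max_dim + 10 > pitch:
        raise ValueError(
            f"pitch {pitch} too small for seeds up to {max_dim:.0f} px; "
            "instances could overlap")
    rng = np.random.Generator(np.random.PCG64(
        np.random.SeedSequence([seed, phenotype.class_id])))
    H, W = rows * pitch, cols * pitch
    canvas = np.full((3, H, W), BACKGROUND_LEVEL)
    canvas += BACKGROUND_NOISE * rng.standard_normal((3, H, W))
    canvas = np.clip(canvas, 0.0, 0.25)
    jitter = max(0.0, (pitch - max_dim) / 2.0 - 3.0)
    instances, masks = [], np.zeros((H, W), dtype=np.int32)
    for r in range(rows):
        for c in range(cols):
            cy = (r + 0.5) * pitch + rng.uniform(-jitter, jitter)
            cx = (c + 0.5) * pitch + rng.uniform(-jitter, jitter)
            alpha, y0, x0, geom = _render_instance(canvas, rng, phenotype,
                                                   cy, cx)
            sel = alpha > 0.5
            ys, xs = np.nonzero(sel)
            box = (x0 + xs.min(), y0 + ys.min(),
                   x0 + xs.max() + 1, y0 + ys.max() + 1)
            masks[y0:y0 + sel.shape[0], x0:x0 + sel.shape[1]][sel] = \
                len(instances) + 1
            instances.append(Instance(
                class_id=phenotype.class_id, center=(cy, cx),
                axes=(geom[0], geom[1]), angle=float(geom[2]),
                box=tuple(int(v) for v in box)))
    scene = pp.SeedScene(np.clip(canvas, 0.0, 1.0),
                         label=f"class{phenotype.class_id:02d}")
    return SyntheticScene(scene, instances, masks, seed)


def make_dataset(K: int, scenes_per_class: int = 1, seed: int = 0,
                 rows: int = 10, cols: int = 20, mode: str = "separated",
                 pitch: int = DEFAULT_PITCH, min_area: int = 50,
                 apply_filter: bool = True):
    """Render scenes for K classes, run the crop pipeline, and return
    ``(per-class crop lists, phenotypes)``.  Fully deterministic in ``seed``."""
    if K < 2:
        raise ValueError("need at least two classes for a dataset")
    phenos = sample_phenotypes(K, seed, mode)
    per_class: dict[str, list[pp.SeedCrop]] = {}
    for pheno in phenos:
        crops: list[pp.SeedCrop] = []
        for s in range(scenes_per_class):
            sc = render_scene(pheno, rows, cols,
                              seed=seed * 1000 + s, pitch=pitch)
            got = pp.segment_scene(sc.scene, min_area=min_area) \
                if apply_filter else pp.extract_seed_crops(
                    sc.scene, pp.threshold_segment(
                        pp.to_grayscale(sc.scene)))
            for crop in got:
                crop.label = sc.scene.label
            crops.extend(got)
        per_class[f"class{pheno.class_id:02d}"] = crops
    return per_class, phenos


def make_arrays(K: int, scenes_per_class: int = 1, seed: int = 0,
                rows: int = 10, cols: int = 20, mode: str = "separated",
                input_size: int = 64, pitch: int = DEFAULT_PITCH):
    """Dataset as arrays ready for training: letterboxed crops + labels,
    already split 6:2:2 per class.  Returns a dict of (X, y) pairs."""
    per_class, phenos = make_dataset(K, scenes_per_class, seed, rows, cols,
                                     mode, pitch)
    split = pp.split_dataset(per_class, seed=seed)
    out = {}
    names = sorted(per_class)
    for part_name, part in (("train", split.train), ("val", split.val),
                            ("test", split.test)):
        X, y = [], []
        for ci, cls in enumerate(names):
            for crop in part[cls]:
                X.append(pp.letterbox(crop.rgb, input_size))
                y.append(ci)
        out[part_name] = (np.stack(X).astype(np.float32),
                          np.array(y, dtype=np.int64))
    return out, phenos


def write_scene(syn: SyntheticScene, out_dir: str | Path, name: str) -> None:
    """PNG image + JSON ground-truth sidecar + instance-mask PNG."""
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img = (syn.scene.rgb.transpose(1, 2, 0) * 255).astype(np.uint8)
    Image.fromarray(img).save(out / f"{name}.png")
    Image.fromarray(syn.instance_mask.astype(np.uint16)).save(
        out / f"{name}_mask.png")
    meta = {"seed": syn.seed, "label": syn.scene.label,
            "instances": [asdict(i) for i in syn.instances]}
    (out / f"{name}.json").write_text(json.dumps(meta, indent=1))
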