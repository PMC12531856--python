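"""Synthetic pest-scene generation, augmentation and dataset plumbing.

The generator emulates the statistical structure of field imagery of maize
pests: small elongated or oval textured targets (13 classes) rendered on
cluttered leaf/soil backgrounds.  Class appearance is controlled by a
per-class morphology (elongation, body hue, segmentation banding, scale
range).  Two deliberate pathologies of real pest data are built in:

* *inter-class similarity* — two pairs of classes share near-identical
  morphologies and differ only in subtle hue/banding shifts (the cutworm
  problem: different species, nearly identical larvae);
* *intra-class heterogeneity* — one class has two distinct morphology modes
  (larva vs adult of the same species).

Augmentation implements five operators: vertical flip, random brightness,
Gaussian blur, motion blur, and popcorn (salt-and-pepper impulse) noise.
Only the flip is geometric; the photometric operators leave labels untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, InputError, ParseError

CLASS_NAMES = [
    "grub", "mole_cricket", "wireworm", "white_margined_moth", "black_cutworm",
    "large_cutworm", "yellow_cutworm", "red_spider", "corn_borer", "army_worm",
    "aphid", "flower_chafer", "peach_borer",
]
NUM_CLASSES = len(CLASS_NAMES)


@dataclass
class BoxLabel:
    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self):
        if not 0 <= self.class_id:
            raise InputError("class_id must be nonnegative")
        if self.w <= 0 or self.h <= 0:
            raise InputError("box width/height must be positive")

    def as_tuple(self):
        return (self.class_id, self.cx, self.cy, self.w, self.h)

    def to_xyxy(self, width, height):
        return ((self.cx - self.w / 2) * width, (self.cy - self.h / 2) * height,
                (self.cx + self.w / 2) * width, (self.cy + self.h / 2) * height)


@dataclass
class Morphology:
    elongation: float      # major/minor axis ratio of the body ellipse
    hue: tuple             # base RGB of the body, 0..1
    banding: float         # amplitude of segmentation bands along the body
    band_freq: float       # bands per body length
    scale: tuple           # (lo, hi) target length as fraction of image size


def default_morphologies():
    """One morphology per class; classes 4/5 and 6 share a near-identical
    larval shape (inter-class similarity), class 8 carries two modes
    (larva + winged adult, intra-class heterogeneity)."""
    m = {
        0: [Morphology(1.6, (0.85, 0.82, 0.70), 0.25, 5, (0.18, 0.30))],
        1: [Morphology(2.8, (0.45, 0.32, 0.18), 0.15, 7, (0.20, 0.34))],
        2: [Morphology(4.5, (0.80, 0.62, 0.30), 0.30, 9, (0.16, 0.28))],
        3: [Morphology(1.9, (0.88, 0.86, 0.80), 0.10, 4, (0.18, 0.30))],
        4: [Morphology(3.6, (0.35, 0.32, 0.28), 0.35, 8, (0.18, 0.30))],
        5: [Morphology(3.6, (0.37, 0.33, 0.27), 0.35, 8, (0.18, 0.30))],  # near-twin of 4
        6: [Morphology(3.5, (0.42, 0.36, 0.24), 0.33, 8, (0.18, 0.30))],  # near-twin of 4/5
        7: [Morphology(1.1, (0.75, 0.20, 0.15), 0.05, 2, (0.10, 0.18))],
        8: [Morphology(3.8, (0.90, 0.83, 0.62), 0.40, 10, (0.16, 0.28)),   # larva
            Morphology(1.5, (0.62, 0.52, 0.38), 0.12, 3, (0.20, 0.32))],  # adult
        9: [Morphology(3.4, (0.55, 0.48, 0.30), 0.30, 9, (0.18, 0.30))],
        10: [Morphology(1.2, (0.55, 0.70, 0.35), 0.05, 2, (0.08, 0.14))],
        11: [Morphology(1.4, (0.30, 0.40, 0.22), 0.20, 4, (0.20, 0.32))],
        12: [Morphology(2.6, (0.80, 0.55, 0.45), 0.25, 6, (0.16, 0.28))],
    }
    return m


@dataclass
class SceneSpec:
    image_size: int = 160
    n_targets: tuple = (1, 3)
    class_morphologies: dict = field(default_factory=default_morphologies)
    background_clutter: float = 0.35
    class_ids: tuple = tuple(range(NUM_CLASSES))
    seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ConfigurationError("image_size too small")
        if self.n_targets[0] < 0 or self.n_targets[1] < self.n_targets[0]:
            raise ConfigurationError("invalid n_targets range")


@dataclass
class AnnotatedImage:
    image: np.ndarray       # (H, W, 3) uint8
    labels: list            # list[BoxLabel]


def _background(rng, size, clutter):
    """Leaf/soil-like clutter: smoothed low-frequency blobs + streaks."""
    base = np.empty((size, size, 3), dtype=np.float32)
    soil = np.array([0.35, 0.28, 0.18], dtype=np.float32)
    leaf = np.array([0.25, 0.45, 0.18], dtype=np.float32)
    mix = ndimage.gaussian_filter(rng.standard_normal((size, size)), size / 10)
    mix = (mix - mix.min()) / (np.ptp(mix) + 1e-9)
    base = soil[None, None] * (1 - mix[..., None]) + leaf[None, None] * mix[..., None]
    noise = ndimage.gaussian_filter(rng.standard_normal((size, size, 3)), (2, 2, 0))
    veins = np.sin(np.linspace(0, 20 * np.pi, size))[None, :, None] * 0.03
    img = base + clutter * 0.25 * noise + veins
    return np.clip(img, 0, 1)


def _render_target(rng, img, cid, morph, size):
    """Draw one banded-ellipse pest body; returns its tight BoxLabel."""
    length = rng.uniform(*morph.scale) * size
    width = max(length / morph.elongation, 3.0)
    angle = rng.uniform(0, np.pi)
    half_w = (abs(np.cos(angle)) * length + abs(np.sin(angle)) * width) / 2
    half_h = (abs(np.sin(angle)) * length + abs(np.cos(angle)) * width) / 2
    cx = rng.uniform(half_w + 1, size - half_w - 1)
    cy = rng.uniform(half_h + 1, size - half_h - 1)
    yy, xx = np.mgrid[0:size, 0:size]
    xr = (xx - cx) * np.cos(angle) + (yy - cy) * np.sin(angle)
    yr = -(xx - cx) * np.sin(angle) + (yy - cy) * np.cos(angle)
    body = (xr / (length / 2)) ** 2 + (yr / (width / 2)) ** 2 <= 1.0
    if not body.any():
        return None
    bands = 1.0 + morph.banding * np.sin(morph.band_freq * np.pi * xr / (length / 2))
    shade = 1.0 - 0.4 * (yr / (width / 2 + 1e-9)) ** 2
    hue = np.array(morph.hue, dtype=np.float32) * (1 + rng.normal(0, 0.03, 3))
    tex = (bands * shade)[..., None] * hue[None, None]
    tex += rng.normal(0, 0.02, tex.shape)
    img[body] = np.clip(tex[body], 0, 1)
    ys, xs = np.nonzero(body)
    x1, x2 = xs.min(), xs.max() + 1
    y1, y2 = ys.min(), ys.max() + 1
    return BoxLabel(cid, (x1 + x2) / 2 / size, (y1 + y2) / 2 / size,
                    (x2 - x1) / size, (y2 - y1) / size)


def generate_scene(spec: SceneSpec, rng=None):
    """Render one annotated scene; deterministic for a fixed spec.seed."""
    rng = rng or np.random.default_rng(spec.seed)
    size = spec.image_size
    n = int(rng.integers(spec.n_targets[0], spec.n_targets[1] + 1))
    max_len = max(max(m.scale[1] for modes in spec.class_morphologies.values()
                      for m in modes), 0.0)
    if n > 0 and max_len * size >= size - 4:
        raise InputError("image too small for requested target scale")
    img = _background(rng, size, spec.background_clutter)
    labels = []
    for _ in range(n):
        cid = int(rng.choice(spec.class_ids))
        modes = spec.class_morphologies[cid]
        morph = modes[int(rng.integers(len(modes)))]
        label = _render_target(rng, img, cid, morph, size)
        if label is not None:
            labels.append(label)
    return AnnotatedImage(image=(img * 255).astype(np.uint8), labels=labels)


def generate_dataset(spec: SceneSpec, n_images, seed=None):
    """n_images deterministic scenes; scene i uses a child seed of ``seed``."""
    seed = spec.seed if seed is None else seed
    out = []
    for i in range(n_images):
        rng = np.random.default_rng((seed, i))
        out.append(generate_scene(spec, rng=rng))
    return out


# -- augmentation -------------------------------------------------------------

AUGMENT_OPERATORS = ("vflip", "brightness", "gaussian_blur", "motion_blur",
                     "popcorn_noise")


@dataclass
class AugmentationSpec:
    operator: str
    seed: int = 0
    brightness_range: tuple = (0.6, 1.4)
    blur_sigma: tuple = (0.5, 2.0)
    motion_lengths: tuple = (5, 7, 9)
    noise_fraction: float = 0.02

    def __post_init__(self):
        if self.operator not in AUGMENT_OPERATORS:
            raise ConfigurationError(f"unknown operator {self.operator!r}")
        if not 0 <= self.noise_fraction <= 1:
            raise ConfigurationError("noise_fraction must be in [0, 1]")


def augment(image, labels, spec: AugmentationSpec):
    """Apply one operator; returns (image', labels').  Geometric operators
    remap label coordinates, photometric ones copy them unchanged."""
    rng = np.random.default_rng(spec.seed)
    img = np.asarray(image)
    op = spec.operator
    if op == "vflip":
        out = img[::-1].copy()
        new_labels = [replace(l, cy=1.0 - l.cy) for l in labels]
        return out, new_labels
    new_labels = [replace(l) for l in labels]
    if op == "brightness":
        factor = rng.uniform(*spec.brightness_range)
        out = np.clip(img.astype(np.float32) * factor, 0, 255).astype(img.dtype)
    elif op == "gaussian_blur":
        sigma = rng.uniform(*spec.blur_sigma)
        out = ndimage.gaussian_filter(img.astype(np.float32), (sigma, sigma, 0))
        out = np.clip(out, 0, 255).astype(img.dtype)
    elif op == "motion_blur":
        length = int(rng.choice(spec.motion_lengths))
        angle = rng.uniform(0, np.pi)
        kernel = _line_kernel(length, angle)
        out = np.stack([ndimage.convolve(img[..., c].astype(np.float32), kernel,
                                         mode="nearest")
                        for c in range(img.shape[2])], axis=-1)
        out = np.clip(out, 0, 255).astype(img.dtype)
    elif op == "popcorn_noise":
        out = img.copy()
        h, w = img.shape[:2]
        n_pix = int(round(spec.noise_fraction * h * w))
        ys = rng.integers(0, h, n_pix)
        xs = rng.integers(0, w, n_pix)
        vals = rng.integers(0, 2, n_pix) * 255
        out[ys, xs] = vals[:, None]
    else:  # pragma: no cover - guarded by AugmentationSpec
        raise ConfigurationError(op)
    return out, new_labels


def _line_kernel(length, angle):
    k = np.zeros((length, length), dtype=np.float32)
    c = (length - 1) / 2
    for t in np.linspace(-c, c, 4 * length):
        y = int(round(c + t * math.sin(angle)))
        x = int(round(c + t * math.cos(angle)))
        if 0 <= y < length and 0 <= x < length:
            k[y, x] = 1.0
    return k / k.sum()


def random_augment(image, labels, seed, operators=AUGMENT_OPERATORS, **params):
    """Pick one of the operators uniformly at random and apply it."""
    rng = np.random.default_rng(seed)
    op = operators[int(rng.integers(len(operators)))]
    return augment(image, labels, AugmentationSpec(operator=op, seed=int(rng.integers(2 ** 31)), **params))


# -- splitting and label I/O --------------------------------------------------

def split_dataset(items, ratios=(8, 1, 1), seed=0):
    """Random disjoint exhaustive split with sizes proportional to ``ratios``
    (within one item), deterministic remainder assignment."""
    items = list(items)
    n = len(items)
    if n < len(ratios) or n < 10 and sum(1 for r in ratios if r > 0) > n:
        raise InputError("fewer items than splits")
    if n < 10:
        raise InputError("need at least 10 items for a meaningful split")
    order = np.random.default_rng(seed).permutation(n)
    total = sum(ratios)
    sizes = [int(round(n * sum(ratios[:i + 1]) / total)) for i in range(len(ratios))]
    bounds = [0] + sizes
    bounds[-1] = n
    subsets = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        subsets.append([items[i] for i in order[a:b]])
    return tuple(subsets)


def write_yolo_labels(path, labels):
    """One `class cx cy w h` line per box, normalised floats."""
    with open(path, "w") as fh:
        for l in labels:
            fh.write(f"{l.class_id} {l.cx:.6f} {l.cy:.6f} {l.w:.6f} {l.h:.6f}\n")


def read_yolo_labels(path):
    labels = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 5:
                raise ParseError(f"expected 5 fields, got {len(parts)}", line=ln)
            try:
                cid = int(parts[0])
                cx, cy, w, h = (float(p) for p in parts[1:])
            except ValueError as exc:
                raise ParseError(str(exc), line=ln) from None
            labels.append(BoxLabel(cid, cx, cy, w, h))
    return labels


def write_dataset_dir(root, scenes, ratios=(8, 1, 1), seed=0, class_names=None):
    """images/{train,val,test} + labels/{train,val,test} + dataset YAML."""
    import os

    import yaml
    from PIL import Image
    class_names = class_names or CLASS_NAMES
    splits = split_dataset(list(range(len(scenes))), ratios, seed)
    names = ("train", "val", "test")
    counts = {}
    for split_name, idxs in zip(names, splits):
        img_dir = os.path.join(root, "images", split_name)
        lbl_dir = os.path.join(root, "labels", split_name)
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(lbl_dir, exist_ok=True)
        for i in idxs:
            stem = f"scene_{i:05d}"
            Image.fromarray(scenes[i].image).save(os.path.join(img_dir, stem + ".png"))
            write_yolo_labels(os.path.join(lbl_dir, stem + ".txt"), scenes[i].labels)
        counts[split_name] = len(idxs)
    doc = {"path": ".", "names": {i: n for i, n in enumerate(class_names)},
           "nc": len(class_names),
           "train": "images/train", "val": "images/val", "test": "images/test"}
    import os as _os
    with open(_os.path.join(root, "dataset.yaml"), "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return counts


def load_dataset_dir(root, split="train"):
    """Returns list of (image array, list[BoxLabel]) for one split."""
    import os

    from PIL import Image
    img_dir = os.path.join(root, "images", split)
    lbl_dir = os.path.join(root, "labels", split)
    out = []
    for name in sorted(os.listdir(img_dir)):
        stem = os.path.splitext(name)[0]
        img = np.asarray(Image.open(os.path.join(img_dir, name)).convert("RGB"))
        labels = read_yolo_labels(os.path.join(lbl_dir, stem + ".txt"))
        out.append((img, labels))
    return out
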