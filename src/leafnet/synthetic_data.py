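"""Synthetic leaf-image generator emulating field photographs.

Real field data for this task (phone photographs of tobacco leaves at
nine position x ripeness classes) is not publicly available, so this
module fabricates leaf-like scenes with the same label structure and the
color/texture cues the task relies on:

* maturity drives foreground hue along the ripening trajectory —
  under-mature leaves are green, mature leaves yellow-green, over-mature
  leaves yellow-brown with necrotic spots;
* stalk position drives leaf size and aspect (lower leaves largest);
* backgrounds are cluttered with soil texture and weed-like green blobs
  so that attention/explanation failure modes (focus on background
  vegetation) can be probed.

Everything is deterministic given (class, seed, size); the default
per-class counts mirror the field collection this generator stands in
for (they sum to 2,159).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .datapipe import Dataset
from .utils import derive_seed

POSITIONS = ("lower", "middle", "upper")
MATURITIES = ("under", "mature", "over")


@dataclass(frozen=True)
class LeafClass:
    """One of the nine (stalk position, ripeness stage) labels."""

    position: str
    maturity: str

    def __post_init__(self):
        if self.position not in POSITIONS or self.maturity not in MATURITIES:
            raise ValueError(f"unknown leaf class {self.position}/{self.maturity}")

    @property
    def name(self) -> str:
        return f"{self.position}_{self.maturity}"


#: Canonical ordering: position (lower, middle, upper) x maturity
#: (under, mature, over); class indices elsewhere refer to this list.
CLASSES = [LeafClass(p, m) for p in POSITIONS for m in MATURITIES]
CLASS_NAMES = [c.name for c in CLASSES]

#: Field-collection per-class counts in canonical order
#: (lower u/m/o, middle u/m/o, upper u/m/o); they sum to 2,159.
FIELD_COUNTS = (215, 298, 200, 248, 279, 194, 251, 255, 219)


def class_index(cls: LeafClass) -> int:
    return CLASSES.index(cls)


@dataclass
class SyntheticConfig:
    """Generation parameters for a full labeled dataset.

    ``variation`` selects the appearance-variability regime: "field"
    (default) jitters leaf geometry and color the way field photographs
    vary; "low" produces the deliberately easy regime used for smoke
    training — tight hue bands, near-fixed leaf geometry.
    """

    per_class_counts: tuple = FIELD_COUNTS
    image_size: int = 224
    seed: int = 0
    clutter_level: float = 0.2
    variation: str = "field"

    def __post_init__(self):
        counts = tuple(int(c) for c in self.per_class_counts)
        if len(counts) != len(CLASSES) or any(c < 0 for c in counts):
            raise ValueError(f"need {len(CLASSES)} non-negative per-class counts")
        self.per_class_counts = counts
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if not 0.0 <= self.clutter_level <= 1.0:
            raise ValueError("clutter_level must lie in [0, 1]")
        if self.variation not in ("field", "low"):
            raise ValueError("variation must be 'field' or 'low'")


def easy_config(n_per_class: int = 50, image_size: int = 96, seed: int = 0) -> SyntheticConfig:
    """The easy smoke-training regime: clutter-free backgrounds and
    low appearance variation, so short training runs can succeed."""
    return SyntheticConfig(
        per_class_counts=(n_per_class,) * len(CLASSES),
        image_size=image_size,
        seed=seed,
        clutter_level=0.0,
        variation="low",
    )


# hue/saturation/value center per ripeness stage (HSV in [0,1]);
# hue decreases green -> yellow-brown as the leaf ripens; blades are kept
# brighter than the soil so the leaf outline (the position cue) stays
# recoverable even for yellow-brown over-mature blades
_MATURITY_HSV = {
    "under": (0.33, 0.80, 0.52),
    "mature": (0.20, 0.75, 0.58),
    "over": (0.10, 0.70, 0.55),
}
# semi-major axis as a fraction of image size per stalk position
_POSITION_SCALE = {"lower": 0.44, "middle": 0.33, "upper": 0.24}


def _soil_background(rng, size: int) -> np.ndarray:
    base = np.array([0.28, 0.21, 0.14])
    coarse = rng.normal(0.0, 0.08, size=(8, 8, 3))
    reps = int(np.ceil(size / 8))
    texture = np.kron(coarse, np.ones((reps, reps, 1)))[:size, :size]
    return np.clip(base + texture + rng.normal(0, 0.02, (size, size, 3)), 0, 1)


def _paint_blob(img, rng, cx, cy, a, b, theta, color, soft=0.15):
    size = img.shape[0]
    y, x = np.mgrid[0:size, 0:size]
    u = np.cos(theta) * (x - cx) + np.sin(theta) * (y - cy)
    v = -np.sin(theta) * (x - cx) + np.cos(theta) * (y - cy)
    r2 = (u / a) ** 2 + (v / b) ** 2
    mask = np.clip((1.0 - r2) / soft, 0.0, 1.0)[..., None]
    img[...] = img * (1 - mask) + np.asarray(color) * mask
    return u, v, r2


def generate_leaf_image(cls: LeafClass, seed: int, size: int,
                        clutter_level: float = 0.2,
                        variation: str = "field") -> np.ndarray:
    """One [size,size,3] float32 scene in [0,1], deterministic in its args."""
    rng = np.random.default_rng(derive_seed(seed, "leaf", class_index(cls), size))
    low_var = variation == "low"
    img = _soil_background(rng, size)

    # weed-like background clutter: small green blobs
    n_weeds = int(round(clutter_level * 10))
    for _ in range(n_weeds):
        hue = rng.uniform(0.28, 0.38)
        color = hsv_to_rgb([hue, rng.uniform(0.5, 0.8), rng.uniform(0.25, 0.45)])
        _paint_blob(
            img, rng,
            cx=rng.uniform(0, size), cy=rng.uniform(0, size),
            a=rng.uniform(0.02, 0.07) * size, b=rng.uniform(0.02, 0.07) * size,
            theta=rng.uniform(0, np.pi), color=color,
        )

    # the leaf: rotated ellipse, size/aspect set by stalk position
    h0, s0, v0 = _MATURITY_HSV[cls.maturity]
    hue = h0 + rng.normal(0, 0.004 if low_var else 0.012)
    a = _POSITION_SCALE[cls.position] * size * (
        rng.uniform(0.97, 1.03) if low_var else rng.uniform(0.9, 1.1)
    )
    b = a * (rng.uniform(0.52, 0.58) if low_var else rng.uniform(0.45, 0.62))
    theta = rng.uniform(0, np.pi)
    jitter = 0.02 if low_var else 0.06
    cx = size / 2 + rng.uniform(-jitter, jitter) * size
    cy = size / 2 + rng.uniform(-jitter, jitter) * size
    color = hsv_to_rgb([np.clip(hue, 0, 1), s0, v0])
    u, v, r2 = _paint_blob(img, rng, cx, cy, a, b, theta, color, soft=0.08)
    inside = r2 < 1.0

    # value gradient across the blade plus vein structure: a dark midrib
    # along the major axis and oblique secondary veins branching off it
    shade = 1.0 - 0.25 * np.abs(v) / max(b, 1.0)
    vein_w = max(0.8, 0.02 * size)
    midrib = np.abs(v) < vein_w * 0.6
    secondary = (np.abs(np.sin(u / a * 4.0 * np.pi + np.sign(v) * np.abs(v) / b * 2.2)) < 0.10) & (
        np.abs(v) > vein_w * 0.5
    )
    vein = (midrib | secondary) & inside
    img[inside] *= shade[inside, None]
    img[vein] *= 0.55

    # necrotic brown spots on over-mature blades
    if cls.maturity == "over":
        for _ in range(rng.integers(4, 8)):
            su = rng.uniform(-0.7, 0.7) * a
            sv = rng.uniform(-0.7, 0.7) * b
            scx = cx + np.cos(theta) * su - np.sin(theta) * sv
            scy = cy + np.sin(theta) * su + np.cos(theta) * sv
            _paint_blob(
                img, rng, scx, scy,
                a=rng.uniform(0.015, 0.035) * size, b=rng.uniform(0.015, 0.035) * size,
                theta=rng.uniform(0, np.pi), color=[0.30, 0.18, 0.08],
            )

    img += rng.normal(0, 0.005 if low_var else 0.01, img.shape)
    return np.clip(img, 0.0, 1.0).astype(np.float32)


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """The full labeled set: exact per-class counts, shuffled by the seed."""
    images, labels = [], []
    for ci, count in enumerate(config.per_class_counts):
        cls = CLASSES[ci]
        for j in range(count):
            images.append(
                generate_leaf_image(
                    cls,
                    seed=derive_seed(config.seed, "image", ci, j),
                    size=config.image_size,
                    clutter_level=config.clutter_level,
                    variation=config.variation,
                )
            )
            labels.append(ci)
    order = np.random.default_rng(derive_seed(config.seed, "shuffle")).permutation(len(images))
    return Dataset([images[i] for i in order], np.asarray(labels, dtype=np.int64)[order])
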