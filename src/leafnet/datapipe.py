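"""Dataset container, stratified splitting, offline augmentation, resizing.

The split reproduces the study protocol: a 7:2:1 stratified division in
which each class of size n contributes round-half-to-even(0.7n) images
to training and round-half-to-even(0.2n) to validation, the remainder to
test.  Offline augmentation expands every training image into six items
(original, 90 and 270 degree rotations, horizontal mirror, a brightness
rescale drawn from U(0.8, 1.2), and Gaussian pixel noise at sigma 0.02).
"""

from __future__ import annotations

import csv
import hashlib
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np

from .utils import derive_seed, resize_plane


@dataclass
class Dataset:
    """Labeled image collection; labels are canonical class indices."""

    images: list = field(default_factory=list)          # [H,W,3] float arrays in [0,1]
    labels: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=np.int64))
    split: list | None = None                            # per-item tag in {train,val,test}

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if len(self.images) != len(self.labels):
            raise ValueError(
                f"{len(self.images)} images but {len(self.labels)} labels"
            )
        if self.split is not None and len(self.split) != len(self.images):
            raise ValueError("split tags do not cover the dataset")

    def __len__(self) -> int:
        return len(self.images)

    def subset(self, indices, split_tag: str | None = None) -> "Dataset":
        indices = np.asarray(indices, dtype=np.int64)
        tags = [split_tag] * len(indices) if split_tag else (
            [self.split[i] for i in indices] if self.split else None
        )
        return Dataset([self.images[i] for i in indices], self.labels[indices], tags)

    def class_counts(self, n_classes: int | None = None) -> np.ndarray:
        n = n_classes or (int(self.labels.max()) + 1 if len(self) else 0)
        return np.bincount(self.labels, minlength=n)

    def stacked(self) -> np.ndarray:
        return np.stack([np.asarray(im, dtype=np.float32) for im in self.images])


def _round_half_even(n: int, ratio: float) -> int:
    """round-half-to-even of ratio*n, computed in exact rational arithmetic
    so that e.g. 0.7*25 = 17.5 rounds to 18 rather than being spoiled by
    binary representation of 0.7."""
    return round(Fraction(ratio).limit_denominator(10**6) * n)


def stratified_split(ds: Dataset, ratios=(0.7, 0.2, 0.1), seed: int = 0):
    """Class-stratified split into (train, val, test) Datasets.

    Within each class, items are ordered by a content digest (so the
    split is invariant to input ordering) and shuffled with a seed
    derived from (seed, class); counts follow the rounding rule above.
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError(f"split ratios {ratios} do not sum to 1")
    if len(ds) == 0:
        raise ValueError("cannot split an empty dataset")
    classes = np.unique(ds.labels)
    picks = {"train": [], "val": [], "test": []}
    for cls in classes:
        idx = np.flatnonzero(ds.labels == cls)
        if len(idx) == 0:
            raise ValueError(f"class {cls} has no items")
        keys = [hashlib.sha1(np.ascontiguousarray(ds.images[i]).tobytes()).digest() for i in idx]
        idx = idx[np.argsort([k.hex() for k in keys], kind="stable")]
        rng = np.random.default_rng(derive_seed(seed, "split", int(cls)))
        idx = idx[rng.permutation(len(idx))]
        n = len(idx)
        n_train = _round_half_even(n, ratios[0])
        n_val = _round_half_even(n, ratios[1])
        picks["train"].extend(idx[:n_train])
        picks["val"].extend(idx[n_train : n_train + n_val])
        picks["test"].extend(idx[n_train + n_val :])
    out = []
    for tag in ("train", "val", "test"):
        indices = np.sort(np.asarray(picks[tag], dtype=np.int64))
        out.append(ds.subset(indices, split_tag=tag))
    return tuple(out)


def _brightness(im: np.ndarray, factor: float) -> np.ndarray:
    return np.clip(im * factor, 0.0, 1.0).astype(im.dtype)


def augment(ds: Dataset, seed: int = 0) -> Dataset:
    """Sixfold offline expansion of a training dataset.

    Each image yields: itself, rot90, rot270, horizontal mirror, a
    brightness rescale by u ~ U(0.8, 1.2), and Gaussian noise at
    sigma 0.02 (clipped to [0,1]).  Per-image randomness is seeded from
    (seed, index) so the expansion is fully reproducible.
    """
    if ds.split is not None and any(tag != "train" for tag in ds.split):
        raise ValueError("augmentation is applied to the training split only")
    images, labels = [], []
    for i, (im, lab) in enumerate(zip(ds.images, ds.labels)):
        im = np.asarray(im, dtype=np.float32)
        rng = np.random.default_rng(derive_seed(seed, "augment", i))
        u = rng.uniform(0.8, 1.2)
        noise = rng.normal(0.0, 0.02, size=im.shape).astype(np.float32)
        variants = [
            im,
            np.ascontiguousarray(np.rot90(im, 1)),
            np.ascontiguousarray(np.rot90(im, 3)),
            np.ascontiguousarray(im[:, ::-1]),
            _brightness(im, u),
            np.clip(im + noise, 0.0, 1.0),
        ]
        images.extend(variants)
        labels.extend([lab] * len(variants))
    tags = ["train"] * len(images) if ds.split is not None else None
    return Dataset(images, np.asarray(labels, dtype=np.int64), tags)


def resize_to_input(image: np.ndarray, size: int = 224) -> np.ndarray:
    """Bilinear resize of one [H,W,3] image to size x size x 3.

    Interpolation weights are convex, so values stay inside the input
    range; the half-pixel-center convention matches the network's
    internal upsampler.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an [H,W,3] RGB image, got shape {image.shape}")
    if image.shape[0] == size and image.shape[1] == size:
        return image.astype(np.float32, copy=True)
    return resize_plane(image.astype(np.float32), size, size)


def resize_dataset(ds: Dataset, size: int) -> Dataset:
    return Dataset([resize_to_input(im, size) for im in ds.images], ds.labels, ds.split)


# -- manifest I/O ---------------------------------------------------------

def save_dataset(ds: Dataset, root, class_names: list[str]) -> Path:
    """Write PNGs into class-per-directory tree plus a CSV manifest."""
    from PIL import Image

    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = root / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["path", "label", "split"])
        counters: dict[int, int] = {}
        for i, (im, lab) in enumerate(zip(ds.images, ds.labels)):
            name = class_names[int(lab)]
            k = counters.get(int(lab), 0)
            counters[int(lab)] = k + 1
            rel = Path(name) / f"{name}_{k:05d}.png"
            (root / name).mkdir(exist_ok=True)
            arr = (np.clip(np.asarray(im), 0, 1) * 255).round().astype(np.uint8)
            Image.fromarray(arr).save(root / rel)
            writer.writerow([rel.as_posix(), name, ds.split[i] if ds.split else ""])
    return manifest


def load_dataset(root, class_names: list[str]) -> Dataset:
    """Read a class-directory tree back through its CSV manifest."""
    from PIL import Image

    root = Path(root)
    images, labels, tags = [], [], []
    with open(root / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            arr = np.asarray(Image.open(root / row["path"]).convert("RGB"), dtype=np.float32) / 255.0
            images.append(arr)
            labels.append(class_names.index(row["label"]))
            tags.append(row["split"] or None)
    split = tags if any(tags) else None
    return Dataset(images, np.asarray(labels, dtype=np.int64), split)
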