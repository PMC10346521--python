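"""Perturbation operators and the robustness experiment grid.

Three disturbance families emulate field conditions: additive Gaussian
pixel noise (raindrops, mud), global brightness rescaling (ambient
light), and a single black square occluder (overlapping leaves).  Each
experiment perturbs a class-stratified fraction of the evaluation set
(30%, 70% or 100%), classifies the union of perturbed and untouched
images, and reports per-class accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datapipe import Dataset
from .utils import derive_seed

KINDS = ("gaussian_noise", "brightness", "occlusion")

#: The study's experiment grid: intensities per kind x perturbed fraction.
DEFAULT_INTENSITIES = {
    "gaussian_noise": (0.1, 0.5),
    "brightness": (0.8, 1.2),
    "occlusion": (0.3, 0.5),
}
DEFAULT_PROPORTIONS = (0.3, 0.7, 1.0)


@dataclass
class PerturbationSpec:
    """One cell of the robustness grid.

    intensity is the noise standard deviation in [0,1] pixel units, the
    multiplicative brightness factor, or the occluded area ratio,
    depending on ``kind``; ``proportion`` is the fraction of the
    evaluation set perturbed.
    """

    kind: str
    intensity: float
    proportion: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")
        if self.kind == "occlusion" and self.intensity > 1:
            raise ValueError("occlusion ratio cannot exceed 1")
        if not 0.0 < self.proportion <= 1.0:
            raise ValueError("proportion must lie in (0, 1]")

    def apply(self, image: np.ndarray, seed: int | None = None) -> np.ndarray:
        seed = self.seed if seed is None else seed
        if self.kind == "gaussian_noise":
            return add_gaussian_noise(image, self.intensity, seed)
        if self.kind == "brightness":
            return adjust_brightness(image, self.intensity)
        return occlude(image, self.intensity, seed)


def add_gaussian_noise(image: np.ndarray, sigma: float, seed: int = 0) -> np.ndarray:
    """i.i.d. N(0, sigma^2) per pixel and channel, clipped to [0,1]."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    image = np.asarray(image, dtype=np.float32)
    if sigma == 0:
        return image.copy()
    noise = np.random.default_rng(seed).normal(0.0, sigma, image.shape)
    return np.clip(image + noise, 0.0, 1.0).astype(np.float32)


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """Multiplicative brightness change, clipped to [0,1]."""
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    return np.clip(np.asarray(image, dtype=np.float32) * factor, 0.0, 1.0)


def occlude(image: np.ndarray, ratio: float, seed: int = 0) -> np.ndarray:
    """Black out one axis-aligned square covering ``ratio`` of the area.

    The side is round(sqrt(ratio*H*W)) (clamped to the image), placed
    uniformly at random fully inside the image.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("occlusion ratio must lie in [0, 1]")
    image = np.asarray(image, dtype=np.float32).copy()
    if ratio == 0:
        return image
    h, w = image.shape[:2]
    side = min(int(round(np.sqrt(ratio * h * w))), h, w)
    rng = np.random.default_rng(seed)
    top = int(rng.integers(0, h - side + 1))
    left = int(rng.integers(0, w - side + 1))
    image[top : top + side, left : left + side] = 0.0
    return image


def stratified_subset(labels: np.ndarray, proportion: float, seed: int) -> np.ndarray:
    """Indices of a per-class random subset of the given proportion
    (per-class count = round(proportion * n_class))."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    chosen = []
    for cls in np.unique(labels):
        idx = np.flatnonzero(labels == cls)
        k = int(round(proportion * len(idx)))
        chosen.extend(rng.choice(idx, size=k, replace=False))
    return np.sort(np.asarray(chosen, dtype=np.int64))


def run_robustness(model, eval_ds: Dataset, specs, class_names: list | None = None) -> pd.DataFrame:
    """Per-class accuracy under each perturbation spec.

    For every spec a stratified ``proportion`` of the evaluation set is
    perturbed (per-image seeds derived from the spec seed), the rest
    left intact, and the model classifies the union.  Output is a tidy
    table with columns kind, intensity, proportion, class, accuracy, n.
    """
    if len(eval_ds) == 0:
        raise ValueError("evaluation set is empty")
    rows = []
    for spec in specs:
        perturb = set(stratified_subset(eval_ds.labels, spec.proportion,
                                        derive_seed(spec.seed, "subset")))
        images = [
            spec.apply(im, seed=derive_seed(spec.seed, "image", i)) if i in perturb else im
            for i, im in enumerate(eval_ds.images)
        ]
        pred = model.predict(images)
        for cls in np.unique(eval_ds.labels):
            sel = eval_ds.labels == cls
            rows.append(
                {
                    "kind": spec.kind,
                    "intensity": spec.intensity,
                    "proportion": spec.proportion,
                    "class": class_names[int(cls)] if class_names else int(cls),
                    "accuracy": float((pred[sel] == cls).mean()),
                    "n": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)


def default_grid(seed: int = 0) -> list[PerturbationSpec]:
    """The full study grid: every (kind, intensity, proportion) cell."""
    specs = []
    for kind, intensities in DEFAULT_INTENSITIES.items():
        for intensity in intensities:
            for prop in DEFAULT_PROPORTIONS:
                specs.append(PerturbationSpec(kind, intensity, prop, seed=seed))
    return specs
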