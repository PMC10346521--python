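"""Gradient-free model explanations: Score-CAM and max-activation overlays.

Score-CAM weights a layer's activation channels by the class scores the
model assigns to channel-masked copies of the input: each channel is
upsampled to input size, min-max normalized into a soft mask, multiplied
into the input, and forward-passed; a softmax over the resulting
target-class scores gives the channel weights, and the heatmap is the
ReLU of the weighted channel sum.  No gradients are involved, so the
whole procedure runs in inference mode.

The max-activation overlay is the simpler diagnostic: the per-position
maximum over channels, upsampled, colormapped and alpha-blended with the
input image.
"""

from __future__ import annotations

import numpy as np
from matplotlib import colormaps

from . import autodiff as ad
from .utils import minmax_normalize, resize_plane


def _activation(model, image: np.ndarray, layer: str) -> np.ndarray:
    act = model.features(np.asarray(image, dtype=np.float32)[None], layer=layer)
    return act[0]  # [h, w, K]


def score_cam(model, image: np.ndarray, target_class: int, layer: str = "head_in",
              batch_size: int = 16) -> np.ndarray:
    """Class-activation heatmap in [0,1] at input resolution.

    ``layer`` names a captured feature map of the model (default: the
    final pre-pooling map).  The result is min-max normalized; a
    constant raw map yields all zeros.  The masked forward passes are
    batched; results are independent of ``batch_size``.
    """
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    n_classes = model.config.n_classes
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} outside [0, {n_classes})")
    act = _activation(model, image, layer)          # [h', w', K]
    k = act.shape[-1]
    masks = np.stack(
        [minmax_normalize(resize_plane(act[..., c], h, w)) for c in range(k)]
    ).astype(np.float32)                            # [K, H, W]
    masked = image[None] * masks[..., None]         # [K, H, W, 3]
    scores = np.empty(k, dtype=np.float64)
    with ad.no_grad():
        for s in range(0, k, batch_size):
            logits = model.forward(masked[s : s + batch_size]).data
            scores[s : s + batch_size] = logits[:, target_class]
    alpha = ad.softmax(scores)
    cam = np.maximum(np.tensordot(act, alpha, axes=([-1], [0])), 0.0)
    return minmax_normalize(resize_plane(cam, h, w))


def blend_heatmap(image: np.ndarray, heatmap: np.ndarray, alpha: float = 0.5,
                  colormap: str = "jet") -> np.ndarray:
    """(1-alpha)*image + alpha*colormapped(heatmap), clipped to [0,1].

    The jet-style map renders strong evidence warm (red) and weak
    evidence cool (blue).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    image = np.asarray(image, dtype=np.float64)
    heatmap = np.asarray(heatmap, dtype=np.float64)
    if image.shape[:2] != heatmap.shape[:2]:
        raise ValueError(
            f"image {image.shape[:2]} and heatmap {heatmap.shape[:2]} sizes differ"
        )
    colored = colormaps[colormap](heatmap)[..., :3]
    return np.clip((1.0 - alpha) * image + alpha * colored, 0.0, 1.0)


def max_activation_overlay(model, image: np.ndarray, layer: str = "head_in",
                           alpha: float = 0.5, colormap: str = "jet") -> np.ndarray:
    """Blend of the input with the per-position channel-max activation map."""
    image = np.asarray(image, dtype=np.float32)
    act = _activation(model, image, layer)
    peak = act.max(axis=-1)
    heat = minmax_normalize(resize_plane(peak, image.shape[0], image.shape[1]))
    return blend_heatmap(image, heat, alpha=alpha, colormap=colormap)
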