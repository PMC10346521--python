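"""Standalone channel (squeeze-excitation) and spatial attention operators.

Pure NumPy forward functions over explicit weight arrays, independent of
the autodiff graph — usable on their own and as the reference behaviour
for the trainable blocks in `leafnet.layers`.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import convolve


def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def se_block(x: np.ndarray, w1: np.ndarray, w2: np.ndarray) -> np.ndarray:
    """Squeeze-and-excitation channel attention on one [H,W,C] feature map.

    Squeeze: spatial mean per channel. Excitation: bias-free dense
    ``C -> C/ratio`` with ReLU (``w1``), then dense ``C/ratio -> C`` with
    sigmoid (``w2``), producing per-channel weights in (0,1). Scale:
    channelwise multiplication of ``x`` by those weights.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected [H,W,C] feature map, got shape {x.shape}")
    c = x.shape[-1]
    w1, w2 = np.asarray(w1, dtype=np.float64), np.asarray(w2, dtype=np.float64)
    if w1.shape[0] != c or w2.shape != (w1.shape[1], c):
        raise ValueError(
            f"weight shapes {w1.shape}, {w2.shape} inconsistent with {c} channels"
        )
    if c % w1.shape[1] != 0:
        raise ValueError(f"bottleneck width {w1.shape[1]} does not divide {c} channels")
    squeeze = x.mean(axis=(0, 1))                 # [C]
    excite = _sigmoid(np.maximum(squeeze @ w1, 0.0) @ w2)
    return x * excite


def sp_block(x: np.ndarray, kernel: np.ndarray, bias: float = 0.0) -> np.ndarray:
    """Spatial attention on one [H,W,C] feature map.

    The per-location channel mean and channel max (each H x W) are
    stacked, convolved with a ``[kh,kw,2]`` kernel (zero padding, same
    output size) plus ``bias``, and squashed by a sigmoid into an H x W
    weight map in (0,1) that multiplies every channel of ``x``.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 3:
        raise ValueError(f"expected [H,W,C] feature map, got shape {x.shape}")
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 3 or kernel.shape[-1] != 2:
        raise ValueError(f"expected [kh,kw,2] kernel, got shape {kernel.shape}")
    stats = np.stack([x.mean(axis=-1), x.max(axis=-1)], axis=-1)  # [H,W,2]
    # correlation (conv without kernel flip), matching the network's conv layers
    response = sum(
        convolve(stats[..., k], kernel[::-1, ::-1, k], mode="constant", cval=0.0)
        for k in range(2)
    )
    weight = _sigmoid(response + bias)
    return x * weight[..., None]
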