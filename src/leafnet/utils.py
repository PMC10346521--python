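"""Small shared helpers: seed fan-out and array image resizing."""

from __future__ import annotations

import zlib

import numpy as np

from .autodiff import resize_matrix


def derive_seed(*keys) -> int:
    """Deterministically fan one global seed out to per-purpose seeds.

    Keys may be ints or strings (strings are crc32-hashed); the result is
    a non-negative int below 2**31 suitable for `numpy.random.default_rng`.
    """
    ints = [k if isinstance(k, (int, np.integer)) else zlib.crc32(str(k).encode()) for k in keys]
    return int(np.random.SeedSequence([int(i) & 0xFFFFFFFF for i in ints]).generate_state(1)[0] % (2**31))


def resize_plane(arr: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable bilinear resize of [H,W] or [H,W,C] plain arrays
    (half-pixel-center convention, matching the network upsampler)."""
    arr = np.asarray(arr)
    squeeze = arr.ndim == 2
    if squeeze:
        arr = arr[..., None]
    ah = resize_matrix(arr.shape[0], out_h, dtype=np.float64)
    aw = resize_matrix(arr.shape[1], out_w, dtype=np.float64)
    out = np.einsum("oh,pw,hwc->opc", ah, aw, arr.astype(np.float64), optimize=True)
    out = out.astype(arr.dtype) if np.issubdtype(arr.dtype, np.floating) else out
    return out[..., 0] if squeeze else out


def minmax_normalize(arr: np.ndarray, eps: float = 1e-12) -> np.ndarray:
    """Map to [0,1]; a (near-)constant array maps to all zeros."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo < eps:
        return np.zeros_like(arr)
    return (arr - lo) / (hi - lo)
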