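"""Score-CAM and overlay visualizations: closed-form single-channel case,
naive-loop oracle equivalence, symmetry, batching invariance, the
gradient-free guarantee, and blending arithmetic."""

import numpy as np
import pytest

from leafnet import autodiff as ad
from leafnet.explain import blend_heatmap, max_activation_overlay, score_cam
from leafnet.utils import minmax_normalize, resize_plane


class StubModel:
    """Minimal model surface for the explanation tools: a fixed feature
    map plus a deterministic forward pass over (masked) images."""

    class _Config:
        n_classes = 3

    config = _Config()

    def __init__(self, activation):
        self.activation = np.asarray(activation, dtype=np.float32)
        self.forward_batches = []

    def features(self, images, layer="head_in", batch_size=32):
        assert layer == "head_in"
        return np.repeat(self.activation[None], len(images), axis=0)

    def forward(self, batch, training=False, capture=None):
        assert not ad.grad_enabled(), "explanations must not build a tape"
        self.forward_batches.append(len(batch))
        arr = np.asarray(batch, dtype=np.float64)
        means = arr.mean(axis=(1, 2, 3))
        logits = np.stack([means, means**2, np.cos(means)], axis=1)
        return ad.Tensor(logits)


def naive_score_cam(model, image, target_class, layer="head_in"):
    """Independent one-channel-at-a-time re-implementation."""
    image = np.asarray(image, dtype=np.float32)
    h, w = image.shape[:2]
    act = model.features(image[None], layer)[0]
    scores = []
    for c in range(act.shape[-1]):
        mask = minmax_normalize(resize_plane(act[..., c], h, w))
        with ad.no_grad():
            logits = model.forward((image * mask[..., None].astype(np.float32))[None]).data
        scores.append(float(logits[0, target_class]))
    alpha = np.exp(scores - np.max(scores))
    alpha /= alpha.sum()
    cam = np.maximum((act * alpha).sum(axis=-1), 0.0)
    return minmax_normalize(resize_plane(cam, h, w))


RNG = np.random.default_rng(21)


class TestScoreCam:
    def test_single_channel_reduces_to_normalized_activation(self):
        """K = 1: the softmax weight is 1, so the heatmap is the
        normalized positive part of the lone channel, scores ignored."""
        act = RNG.standard_normal((4, 4, 1)).astype(np.float32)
        model = StubModel(act)
        image = RNG.random((16, 16, 3)).astype(np.float32)
        heat = score_cam(model, image, target_class=0)
        expected = minmax_normalize(resize_plane(np.maximum(act[..., 0], 0.0), 16, 16))
        assert np.allclose(heat, expected, atol=1e-6)

    def test_matches_naive_loop_oracle(self):
        """Vectorized/batched implementation vs the one-channel-at-a-time
        loop on an 8-channel toy model."""
        model = StubModel(RNG.standard_normal((5, 5, 8)))
        image = RNG.random((20, 20, 3)).astype(np.float32)
        for cls in range(3):
            assert np.allclose(
                score_cam(model, image, cls),
                naive_score_cam(model, image, cls),
                atol=1e-5,
            )

    def test_batch_size_invariance(self):
        model = StubModel(RNG.standard_normal((4, 4, 16)))
        image = RNG.random((12, 12, 3)).astype(np.float32)
        a = score_cam(model, image, 1, batch_size=3)
        b = score_cam(model, image, 1, batch_size=16)
        assert np.allclose(a, b, atol=1e-7)

    def test_channel_permutation_invariance(self):
        act = RNG.standard_normal((4, 4, 6))
        image = RNG.random((12, 12, 3)).astype(np.float32)
        base = score_cam(StubModel(act), image, 2)
        perm = RNG.permutation(6)
        permuted = score_cam(StubModel(act[..., perm]), image, 2)
        assert np.allclose(base, permuted, atol=1e-6)

    def test_range_contract_and_constant_map(self):
        heat = score_cam(StubModel(RNG.standard_normal((4, 4, 4))),
                         RNG.random((8, 8, 3)).astype(np.float32), 0)
        assert heat.min() == pytest.approx(0.0) and heat.max() == pytest.approx(1.0)
        assert not np.isnan(heat).any()
        # all-negative activation -> ReLU zeroes the map -> all-zero heatmap
        flat = score_cam(StubModel(-np.ones((3, 3, 2), np.float32)),
                         RNG.random((6, 6, 3)).astype(np.float32), 0)
        assert np.array_equal(flat, np.zeros((6, 6)))

    def test_on_real_network_with_small_tap(self, tiny_model, tiny_images):
        """End-to-end equivalence on the actual classifier using the
        16-channel C1 tap."""
        image = tiny_images[0]
        ours = score_cam(tiny_model, image, target_class=3, layer="C1")
        oracle = naive_score_cam(tiny_model, image, target_class=3, layer="C1")
        assert np.allclose(ours, oracle, atol=1e-5)
        assert ours.shape == image.shape[:2]

    def test_invalid_target_rejected(self, tiny_model, tiny_images):
        with pytest.raises(ValueError, match="target_class"):
            score_cam(tiny_model, tiny_images[0], target_class=9)

    def test_unknown_layer_rejected(self, tiny_model, tiny_images):
        with pytest.raises(KeyError, match="unknown layer"):
            score_cam(tiny_model, tiny_images[0], 0, layer="P99")


class TestBlend:
    def test_alpha_zero_returns_image(self):
        im = RNG.random((6, 6, 3))
        heat = RNG.random((6, 6))
        assert np.allclose(blend_heatmap(im, heat, alpha=0.0), im)

    def test_alpha_one_returns_colormap(self):
        from matplotlib import colormaps

        heat = RNG.random((5, 5))
        out = blend_heatmap(np.zeros((5, 5, 3)), heat, alpha=1.0)
        assert np.allclose(out, colormaps["jet"](heat)[..., :3])

    def test_midpoint_arithmetic_on_constants(self):
        from matplotlib import colormaps

        im = np.full((4, 4, 3), 0.2)
        heat = np.full((4, 4), 0.5)
        expected = 0.5 * im + 0.5 * colormaps["jet"](heat)[..., :3]
        assert np.allclose(blend_heatmap(im, heat, alpha=0.5), expected)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sizes differ"):
            blend_heatmap(np.zeros((4, 4, 3)), np.zeros((5, 5)))


class TestMaxActivationOverlay:
    def test_constant_activation_uniform_overlay(self):
        model = StubModel(np.full((4, 4, 3), 2.0, dtype=np.float32))
        image = np.full((8, 8, 3), 0.5, dtype=np.float32)
        out = max_activation_overlay(model, image)
        assert np.allclose(out, out[:1, :1, :], atol=1e-12)  # spatially uniform

    def test_hot_pixel_is_warmest_point(self):
        act = np.zeros((4, 4, 2), dtype=np.float32)
        act[1, 2, 1] = 5.0
        model = StubModel(act)
        image = np.zeros((16, 16, 3), dtype=np.float32)
        out = max_activation_overlay(model, image, alpha=1.0)
        # warmth ~ red minus blue; peak must sit at the upsampled hot cell
        warmth = out[..., 0] - out[..., 2]
        iy, ix = np.unravel_index(warmth.argmax(), warmth.shape)
        assert (1 * 4 <= iy < 2 * 4) and (2 * 4 <= ix < 3 * 4)

    def test_alpha_zero_keeps_image(self, tiny_model, tiny_images):
        out = max_activation_overlay(tiny_model, tiny_images[0], alpha=0.0)
        assert np.allclose(out, tiny_images[0], atol=1e-6)
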