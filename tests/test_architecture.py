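"""Architecture contracts: tap/pyramid shapes, exact parameter accounting,
variant assembly rules and the fusion arithmetic of the pyramid."""

import numpy as np
import pytest

from leafnet import ConfigError, ModelConfig, build_backbone, build_fpn, build_variant, count_parameters
from leafnet import autodiff as ad
from leafnet.architecture import FPNTop, STAGE_SCHEDULE
from leafnet.layers import Dense, SEBlock, SPBlock, BatchNorm2D

# Printed reference sizes for the two headline builds.
BASELINE_PARAMS = 3_238_089
FULL_PARAMS = 3_357_276


def variant_config(use_fpn, use_sp, use_se, **kw):
    return ModelConfig(use_fpn=use_fpn, use_sp=use_sp, use_se=use_se, **kw)


class TestParameterAccounting:
    def test_baseline_parameter_count(self):
        model = build_variant(variant_config(False, False, False))
        assert count_parameters(model) == BASELINE_PARAMS

    def test_full_variant_parameter_count(self):
        assert count_parameters(build_variant(ModelConfig())) == FULL_PARAMS

    def test_dense_layer_counts(self):
        rng = np.random.default_rng(0)
        assert sum(a.size for _, a in Dense(rng, 1024, 9).named_state()) == 9_225
        assert sum(a.size for _, a in Dense(rng, 64, 9).named_state()) == 585

    def test_component_decomposition(self):
        """full = headless backbone + laterals + SP + SE + head BN + dense."""
        rng = np.random.default_rng(0)
        backbone_headless = BASELINE_PARAMS - 9_225
        laterals = sum((c + 1) * 64 for c in (64, 128, 256, 512, 1024))
        assert laterals == 127_296
        sp = sum(a.size for _, a in SPBlock(rng, 3).named_state())
        assert sp == 19
        se = sum(a.size for _, a in SEBlock(rng, 64, 32).named_state())
        assert se == 256
        bn = sum(a.size for _, a in BatchNorm2D(64).named_state())
        assert bn == 256
        head = 585
        assert backbone_headless + laterals + sp + se + bn + head == FULL_PARAMS

    def test_variant_structural_monotonicity(self):
        counts = [
            count_parameters(build_variant(variant_config(*flags)))
            for flags in [(False, False, False), (True, False, False),
                          (True, False, True), (True, True, True)]
        ]
        assert counts[0] < counts[1] < counts[2] <= counts[3]


class TestShapeContracts:
    def test_tap_shapes_at_full_resolution(self):
        backbone = build_backbone(ModelConfig())
        x = np.random.default_rng(0).random((1, 224, 224, 3), dtype=np.float32)
        with ad.no_grad():
            _, acts = backbone(x)
        expected = {1: (112, 64), 3: (56, 128), 5: (28, 256), 11: (14, 512), 13: (7, 1024)}
        for stage, (hw, c) in expected.items():
            assert acts[stage].data.shape == (1, hw, hw, c)

    def test_tap_shapes_small_narrow(self):
        backbone = build_backbone(ModelConfig(input_size=96, width_multiplier=0.25))
        x = np.random.default_rng(0).random((1, 96, 96, 3), dtype=np.float32)
        with ad.no_grad():
            _, acts = backbone(x)
        assert acts[13].data.shape == (1, 3, 3, 256)

    @pytest.mark.parametrize("width", [0.25, 0.5, 1.0])
    @pytest.mark.parametrize("size", [32, 64])
    def test_pyramid_contract_across_widths_and_sizes(self, width, size):
        cfg = ModelConfig(input_size=size, width_multiplier=width)
        model = build_variant(cfg)
        x = np.random.default_rng(1).random((1, size, size, 3), dtype=np.float32)
        capture = {}
        with ad.no_grad():
            model.forward(x, capture=capture)
        for level in range(1, 6):
            c_shape = capture[f"C{level}"].data.shape
            p_shape = capture[f"P{level}"].data.shape
            assert p_shape[1:3] == c_shape[1:3]
            assert p_shape[3] == cfg.pyramid_channels
        assert capture["P2"].data.shape[1:3] == (size // 4, size // 4)

    def test_probability_output(self, tiny_model, tiny_images):
        probs = tiny_model.predict_proba(tiny_images)
        assert probs.shape == (len(tiny_images), 9)
        assert (probs >= 0).all()
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_inference_is_deterministic(self, tiny_model, tiny_images):
        p1 = tiny_model.predict_proba(tiny_images)
        p2 = tiny_model.predict_proba(tiny_images)
        assert np.array_equal(p1, p2)


class TestFPNFusion:
    def _identity_fpn(self, channels=64, levels=2):
        """Laterals configured as identity maps with controllable bias."""
        cfg = ModelConfig(pyramid_channels=channels, se_ratio=channels)
        fpn = FPNTop(cfg, [channels] * levels, np.random.default_rng(0))
        for lat in fpn.laterals:
            lat.w.data[:] = 0.0
            lat.w.data[0, 0] = np.eye(channels, dtype=np.float32)
            lat.b.data[:] = 0.0
        return fpn

    def test_zero_taps_yield_broadcast_biases(self):
        """With all-zero taps each P level is the accumulated lateral biases,
        constant over space (fusion is linear)."""
        cfg = ModelConfig()
        rng = np.random.default_rng(3)
        channels = [8, 16, 32]
        fpn = FPNTop(cfg, channels, rng)
        taps = [np.zeros((1, 2 ** (3 - i), 2 ** (3 - i), c), dtype=np.float32)
                for i, c in enumerate(channels)]
        pyramid = build_fpn(taps, cfg, fpn=fpn)
        for i, fused in enumerate(pyramid.fused):
            expected = sum(lat.b.data for lat in fpn.laterals[i:])
            assert np.allclose(fused, expected, atol=1e-6)
            assert np.allclose(fused, fused[:, :1, :1, :], atol=1e-6)  # spatially constant

    def test_single_fusion_step_hand_trace(self):
        """With identity laterals and C-top = 0, the lower level equals its
        own tap plus the broadcast upsampled bias of the top lateral."""
        fpn = self._identity_fpn(channels=4, levels=2)
        fpn.laterals[1].b.data[:] = np.array([1.0, -2.0, 0.5, 0.0], dtype=np.float32)
        c_low = np.arange(4 * 4 * 4, dtype=np.float32).reshape(1, 4, 4, 4)
        c_top = np.zeros((1, 2, 2, 4), dtype=np.float32)
        pyramid = build_fpn([c_low, c_top], ModelConfig(), fpn=fpn)
        # upsampling a constant stays constant, so P_low = C_low + bias_top
        assert np.allclose(pyramid.fused[0], c_low + fpn.laterals[1].b.data, atol=1e-5)

    def test_mismatched_levels_error_names_the_level(self):
        cfg = ModelConfig()
        taps = [np.zeros((1, 9, 9, 8), np.float32), np.zeros((1, 4, 4, 8), np.float32)]
        with pytest.raises(ValueError, match="P1"):
            build_fpn(taps, cfg)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kw",
        [
            dict(input_size=100),
            dict(tap_points=(3, 1, 5, 11, 13)),
            dict(tap_points=(0, 3, 5, 11, 13)),
            dict(pyramid_channels=0),
            dict(pyramid_channels=48, se_ratio=32),
            dict(use_fpn=False, use_se=True),
            dict(use_fpn=False, use_sp=True),
        ],
    )
    def test_invalid_configurations_rejected(self, kw):
        with pytest.raises(ConfigError):
            ModelConfig(**kw)

    def test_forward_rejects_bad_input_shape(self, tiny_model):
        with pytest.raises(ValueError, match=r"\[N,H,W,3\]"):
            tiny_model.forward(np.zeros((32, 32, 3), dtype=np.float32))
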