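"""Network construction: depthwise-separable backbone, feature pyramid,
attention-augmented variants, and exact parameter accounting.

The backbone is the standard 13-stage depthwise-separable design: a
strided 3x3 stem, then thirteen (depthwise 3x3 -> BN -> ReLU ->
pointwise 1x1 -> BN -> ReLU) stages with the canonical channel/stride
schedule.  Five pointwise-ReLU activations are tapped as C1..C5 and
fused top-down through 1x1 lateral projections into a feature pyramid
P1..P5 at a common width.  Spatial attention is applied to P2 before it
is fused downward; squeeze-excitation recalibrates the fused P1; the
head is BatchNorm -> global average pool -> dense softmax.

Every design choice that affects the parameter count is deliberate and
pinned by tests: parameter-free additive fusion and bilinear upsampling,
biased 1x1 laterals, a biased 3x3 spatial-attention conv, a bias-free
squeeze-excitation bottleneck at ratio 32.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .layers import BatchNorm2D, Conv2D, Dense, DepthwiseConv2D, Module, SEBlock, SPBlock

#: (output channels, stride) for the thirteen depthwise-separable stages
#: at width multiplier 1.0; the stem is a 3x3 stride-2 conv to 32 channels.
STAGE_SCHEDULE = [
    (64, 1),
    (128, 2), (128, 1),
    (256, 2), (256, 1),
    (512, 2), (512, 1), (512, 1), (512, 1), (512, 1), (512, 1),
    (1024, 2), (1024, 1),
]

CLASS_COUNT_DEFAULT = 9


class ConfigError(ValueError):
    """Inconsistent or invalid model configuration."""


@dataclass
class ModelConfig:
    """Architectural hyperparameters for one classifier variant.

    tap_points index the pointwise-ReLU activations (1-based, 1..13)
    exposed as C1..C5; with the defaults at 224 px input their spatial
    sizes are 112, 56, 28, 14, 7 and widths 64, 128, 256, 512, 1024.
    """

    input_size: int = 224
    width_multiplier: float = 1.0
    n_classes: int = CLASS_COUNT_DEFAULT
    pyramid_channels: int = 64
    tap_points: tuple = (1, 3, 5, 11, 13)
    se_ratio: int = 32
    se_bias: bool = False
    sp_kernel: int = 3
    use_fpn: bool = True
    use_sp: bool = True
    use_se: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.input_size % 32 != 0:
            raise ConfigError(
                f"input_size {self.input_size} not divisible by 32 (stride chain breaks)"
            )
        taps = tuple(self.tap_points)
        if list(taps) != sorted(set(taps)) or not all(1 <= t <= 13 for t in taps):
            raise ConfigError(f"tap_points {taps} must be strictly increasing within [1, 13]")
        self.tap_points = taps
        if self.pyramid_channels <= 0:
            raise ConfigError("pyramid_channels must be positive")
        if self.pyramid_channels % self.se_ratio != 0:
            raise ConfigError(
                f"se_ratio {self.se_ratio} does not divide pyramid_channels {self.pyramid_channels}"
            )
        if (self.use_sp or self.use_se) and not self.use_fpn:
            raise ConfigError("spatial/channel attention requires the feature pyramid (use_fpn)")

    @property
    def variant_name(self) -> str:
        name = "base"
        if self.use_fpn:
            name = "fpn"
            if self.use_sp:
                name += "+sp"
            if self.use_se:
                name += "+se"
        return name

    def stage_channels(self) -> list[int]:
        return [max(1, int(round(c * self.width_multiplier))) for c, _ in STAGE_SCHEDULE]

    def to_dict(self) -> dict:
        d = dict(vars(self))
        d["tap_points"] = list(self.tap_points)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if "tap_points" in d:
            d["tap_points"] = tuple(d["tap_points"])
        return cls(**d)


@dataclass
class FeaturePyramid:
    """Backbone taps C1..C5 and fused maps P1..P5 (ascending resolution
    order: index 0 is the highest-resolution level C1/P1)."""

    taps: list = field(default_factory=list)     # C1..C5 arrays [N,H,W,Ci]
    fused: list = field(default_factory=list)    # P1..P5 arrays [N,H,W,pyramid_channels]


class Backbone(Module):
    """Stem plus thirteen depthwise-separable stages; exposes every
    pointwise-ReLU activation so any subset can serve as pyramid taps."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        self.config = config
        stem_out = max(1, int(round(32 * config.width_multiplier)))
        self.stem = Conv2D(rng, 3, 3, 3, stem_out, stride=2, padding=1, bias=False)
        self.stem_bn = BatchNorm2D(stem_out)
        self.dw, self.dw_bn, self.pw, self.pw_bn = [], [], [], []
        cin = stem_out
        for cout, stride in zip(config.stage_channels(), (s for _, s in STAGE_SCHEDULE)):
            self.dw.append(DepthwiseConv2D(rng, 3, 3, cin, stride=stride, padding=1))
            self.dw_bn.append(BatchNorm2D(cin))
            self.pw.append(Conv2D(rng, 1, 1, cin, cout, stride=1, padding=0, bias=False))
            self.pw_bn.append(BatchNorm2D(cout))
            cin = cout

    def __call__(self, x, training=False):
        """Returns (final activation, {stage index 1..13: pointwise-ReLU output})."""
        h = ad.relu(self.stem_bn(self.stem(x), training))
        acts = {}
        for i in range(13):
            h = ad.relu(self.dw_bn[i](self.dw[i](h), training))
            h = ad.relu(self.pw_bn[i](self.pw[i](h), training))
            acts[i + 1] = h
        return h, acts


def build_backbone(config: ModelConfig) -> Backbone:
    """Construct the backbone alone (taps accessible via its forward pass)."""
    return Backbone(config, np.random.default_rng(config.seed))


class FPNTop(Module):
    """Lateral projections and the top-down fusion path.

    P5 = lateral(C5); Pi = lateral(Ci) + upsample2x(P_{i+1}); the spatial
    attention hook, when present, reweights P2 before it is fused into P1.
    """

    def __init__(self, config: ModelConfig, tap_channels: list[int], rng: np.random.Generator):
        pc = config.pyramid_channels
        self.laterals = [
            Conv2D(rng, 1, 1, c, pc, stride=1, padding=0, bias=True) for c in tap_channels
        ]

    def __call__(self, taps, sp: SPBlock | None = None):
        """taps: C1..C5 tensors in ascending-resolution order; returns P1..P5."""
        lats = [lateral(t) for lateral, t in zip(self.laterals, taps)]
        fused = [None] * len(lats)
        fused[-1] = lats[-1]
        for i in range(len(lats) - 2, -1, -1):
            above = fused[i + 1]
            if sp is not None and i == 0:
                # attention on P2 just before its fusion into P1
                above = sp(above)
            n, h, w, _ = above.data.shape
            up = ad.bilinear_resize(above, 2 * h, 2 * w)
            if up.data.shape != lats[i].data.shape:
                raise ValueError(
                    f"FPN level P{i + 1}: upsampled map {up.data.shape[1:3]} does not match "
                    f"lateral {lats[i].data.shape[1:3]}"
                )
            fused[i] = ad.add(lats[i], up)
        return fused


def build_fpn(taps, config: ModelConfig, fpn: FPNTop | None = None) -> FeaturePyramid:
    """Fuse raw tap arrays C1..C5 into a feature pyramid.

    `taps` are arrays of shape [N,H,W,Ci] (or [H,W,Ci], auto-batched) in
    ascending resolution order C1..C5. A freshly seeded `FPNTop` is
    created unless one is supplied (tests inject identity laterals).
    """
    arrays = []
    for t in taps:
        a = np.asarray(t, dtype=np.float32)
        if a.ndim == 3:
            a = a[None]
        arrays.append(a)
    if fpn is None:
        fpn = FPNTop(config, [a.shape[-1] for a in arrays], np.random.default_rng(config.seed))
    with ad.no_grad():
        fused = fpn([Tensor(a) for a in reversed(arrays)][::-1])
    return FeaturePyramid(taps=arrays, fused=[f.data for f in fused])


class LeafClassifier(Module):
    """A full classifier variant: backbone, optional pyramid and attention,
    BatchNorm/GAP/dense-softmax head."""

    def __init__(self, config: ModelConfig):
        config = config if isinstance(config, ModelConfig) else ModelConfig(**config)
        self.config = config
        rng = np.random.default_rng(config.seed)
        self.backbone = Backbone(config, rng)
        stage_channels = config.stage_channels()
        if config.use_fpn:
            tap_channels = [stage_channels[i - 1] for i in config.tap_points]
            self.fpn = FPNTop(config, tap_channels, rng)
            self.sp = SPBlock(rng, config.sp_kernel) if config.use_sp else None
            self.se = SEBlock(rng, config.pyramid_channels, config.se_ratio) if config.use_se else None
            self.head_bn = BatchNorm2D(config.pyramid_channels)
            self.head = Dense(rng, config.pyramid_channels, config.n_classes, bias=True)
        else:
            self.head = Dense(rng, stage_channels[-1], config.n_classes, bias=True)

    # -- forward ----------------------------------------------------------
    def forward(self, x, training=False, capture: dict | None = None):
        """Logits for a [N,H,W,3] batch; `capture` collects named features.

        Captured names: C1..C5 (taps), P1..P5 (fused pyramid, post
        attention where applicable) and `head_in`, the final pre-pooling
        feature map the explanation tools read.
        """
        x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 4 or x.data.shape[-1] != 3:
            raise ValueError(f"expected [N,H,W,3] input, got {x.data.shape}")
        cfg = self.config
        final, acts = self.backbone(x, training)
        if not cfg.use_fpn:
            feat = final
            if capture is not None:
                capture["head_in"] = feat
            pooled = ad.global_avg_pool(feat)
        else:
            taps = [acts[i] for i in cfg.tap_points]
            if capture is not None:
                for k, t in enumerate(taps):
                    capture[f"C{k + 1}"] = t
            fused = self.fpn(taps, sp=self.sp)
            p1 = fused[0]
            if self.se is not None:
                p1 = self.se(p1)
            if capture is not None:
                capture["P1"] = p1
                for k in range(1, len(fused)):
                    capture[f"P{k + 1}"] = fused[k]
                capture["head_in"] = p1
            pooled = ad.global_avg_pool(self.head_bn(p1, training))
        return self.head(pooled)

    __call__ = forward

    # -- inference conveniences -------------------------------------------
    def predict_proba(self, images, batch_size: int = 32) -> np.ndarray:
        """Class probabilities for a stack/list of [H,W,3] images."""
        if len(images) == 0:
            return np.zeros((0, self.config.n_classes), dtype=np.float32)
        out = []
        with ad.no_grad():
            for start in range(0, len(images), batch_size):
                batch = np.stack(
                    [np.asarray(im, dtype=np.float32) for im in images[start : start + batch_size]]
                )
                out.append(ad.softmax(self.forward(batch).data))
        return np.concatenate(out, axis=0)

    def predict(self, images, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(images, batch_size=batch_size).argmax(axis=1)

    def features(self, images, layer: str = "head_in", batch_size: int = 32) -> np.ndarray:
        """Named intermediate activation for a stack of images (inference)."""
        out = []
        with ad.no_grad():
            for start in range(0, len(images), batch_size):
                batch = np.stack(
                    [np.asarray(im, dtype=np.float32) for im in images[start : start + batch_size]]
                )
                capture: dict = {}
                self.forward(batch, capture=capture)
                if layer not in capture:
                    raise KeyError(
                        f"unknown layer {layer!r}; available: {sorted(capture)}"
                    )
                out.append(capture[layer].data)
        return np.concatenate(out, axis=0)


def build_variant(config: ModelConfig) -> LeafClassifier:
    """Assemble a classifier variant (base / +FPN / +FPN+SE / +FPN+SP / full)."""
    return LeafClassifier(config)


def count_parameters(model: Module) -> int:
    """Total parameters, trainable plus non-trainable (BN moving stats)."""
    return model.n_parameters()
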