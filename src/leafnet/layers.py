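"""Parameterized building blocks: convolutions, batch norm, dense, attention.

Every module owns its weights as `Tensor`s with `requires_grad=True` and
exposes them via `parameters()` (trainable) and `state_arrays()` (all
arrays including batch-norm moving statistics, used for checkpointing
and parameter accounting).  Weights are He-normal initialized from a
caller-supplied `numpy.random.Generator` so whole networks are
reproducible from one seed.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Module:
    """Base class: recursive parameter/state discovery over attributes."""

    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self):
        """Trainable tensors, depth-first, deterministic order."""
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                yield value
        for _, child in self._children():
            yield from child.parameters()

    def named_state(self, prefix=""):
        """All weight arrays including non-trainable moving statistics."""
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                yield prefix + name, value.data
            elif isinstance(value, np.ndarray):
                yield prefix + name, value
        for name, child in self._children():
            yield from child.named_state(prefix + name + ".")

    def n_parameters(self) -> int:
        """Total parameter count, trainable plus non-trainable."""
        return int(sum(arr.size for _, arr in self.named_state()))

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def load_state(self, state: dict):
        for name, arr in self.named_state():
            if name not in state:
                raise KeyError(f"checkpoint missing weight {name!r}")
            src = np.asarray(state[name])
            if src.shape != arr.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: checkpoint {src.shape} vs model {arr.shape}"
                )
            arr[...] = src

    def state_dict(self) -> dict:
        return {name: arr.copy() for name, arr in self.named_state()}


def _glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int) -> np.ndarray:
    """Glorot/Xavier uniform initialization (the ecosystem default); keeps
    pre-sigmoid gate logits small enough that attention gates start soft."""
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


class Conv2D(Module):
    """kh x kw standard convolution, optional bias (NHWC)."""

    def __init__(self, rng, kh, kw, cin, cout, stride=1, padding=0, bias=False):
        self.stride, self.padding = stride, padding
        self.w = Tensor(
            _glorot_uniform(rng, (kh, kw, cin, cout), kh * kw * cin, kh * kw * cout),
            requires_grad=True,
        )
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x):
        return ad.conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class DepthwiseConv2D(Module):
    def __init__(self, rng, kh, kw, channels, stride=1, padding=0):
        self.stride, self.padding = stride, padding
        self.w = Tensor(
            _glorot_uniform(rng, (kh, kw, channels), kh * kw, kh * kw), requires_grad=True
        )

    def __call__(self, x):
        return ad.depthwise_conv2d(x, self.w, stride=self.stride, padding=self.padding)


class BatchNorm2D(Module):
    """Per-channel batch norm; moving mean/var are non-trainable state."""

    def __init__(self, channels, momentum=0.9, eps=1e-3):
        self.momentum, self.eps = momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.moving_mean = np.zeros(channels, dtype=np.float32)
        self.moving_var = np.ones(channels, dtype=np.float32)

    def __call__(self, x, training=False):
        return ad.batch_norm(
            x, self.gamma, self.beta, self.moving_mean, self.moving_var,
            training=training, momentum=self.momentum, eps=self.eps,
        )


class Dense(Module):
    def __init__(self, rng, cin, cout, bias=True):
        self.w = Tensor(_glorot_uniform(rng, (cin, cout), cin, cout), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x):
        out = ad.matmul(x, self.w)
        if self.b is not None:
            out = ad.add(out, self.b)
        return out


class SEBlock(Module):
    """Squeeze-and-excitation channel attention.

    Squeeze: global average pool to a length-C descriptor. Excitation: a
    bias-free bottleneck (C -> C/ratio, ReLU) and expansion
    (C/ratio -> C, sigmoid). Scale: channelwise reweighting of the map.
    """

    def __init__(self, rng, channels, ratio):
        if channels % ratio != 0:
            raise ValueError(f"SE ratio {ratio} does not divide {channels} channels")
        self.fc1 = Dense(rng, channels, channels // ratio, bias=False)
        self.fc2 = Dense(rng, channels // ratio, channels, bias=False)

    def __call__(self, x):
        s = ad.global_avg_pool(x)                      # [N,C]
        e = ad.sigmoid(self.fc2(ad.relu(self.fc1(s)))) # [N,C] in (0,1)
        n, c = e.data.shape
        return ad.mul(x, ad.reshape(e, (n, 1, 1, c)))


class SPBlock(Module):
    """Spatial attention: per-location channel mean and max, concatenated,
    passed through a small conv with sigmoid, then broadcast-multiplied."""

    def __init__(self, rng, kernel=3):
        self.conv = Conv2D(rng, kernel, kernel, 2, 1, stride=1, padding=kernel // 2, bias=True)

    def __call__(self, x):
        stats = ad.concat([ad.channel_mean(x), ad.channel_max(x)], axis=-1)
        weight = ad.sigmoid(self.conv(stats))          # [N,H,W,1]
        return ad.mul(x, weight)
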