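"""High-level modelling interface: build a classifier from datasets,
fit it, and interrogate the fitted result.

`LeafMaturityClassifier` bundles the data with an architectural
configuration; `fit()` runs the training protocol and returns a
`FitResults` object carrying the fitted network, its history and
diagnostics, with `summary()`, evaluation, robustness and explanation
methods hanging off it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import explain as _explain
from . import metrics as _metrics
from . import robustness as _robustness
from .architecture import LeafClassifier, ModelConfig, build_variant, count_parameters
from .datapipe import Dataset, augment, resize_dataset, stratified_split
from .synthetic_data import CLASS_NAMES, SyntheticConfig, generate_dataset
from .training import TrainConfig, train


class LeafMaturityClassifier:
    """A leaf-maturity model specified by datasets plus configuration."""

    def __init__(self, train_ds: Dataset, val_ds: Dataset,
                 config: ModelConfig | None = None,
                 class_names: list | None = None):
        self.train_ds = train_ds
        self.val_ds = val_ds
        self.config = config or ModelConfig()
        self.class_names = class_names or CLASS_NAMES

    @classmethod
    def from_synthetic(cls, synth_config: SyntheticConfig | None = None,
                       model_config: ModelConfig | None = None,
                       augment_train: bool = False, split_seed: int = 0):
        """Generate a synthetic dataset, split it 7:2:1 and wrap the model.

        Returns (classifier, test_ds); the generated images are resized
        to the model input size if they differ.
        """
        synth = synth_config or SyntheticConfig()
        model_config = model_config or ModelConfig()
        ds = generate_dataset(synth)
        if synth.image_size != model_config.input_size:
            ds = resize_dataset(ds, model_config.input_size)
        train_ds, val_ds, test_ds = stratified_split(ds, seed=split_seed)
        if augment_train:
            train_ds = augment(train_ds, seed=split_seed)
        return cls(train_ds, val_ds, model_config), test_ds

    def fit(self, train_config: TrainConfig | None = None) -> "FitResults":
        cfg = train_config or TrainConfig()
        network = build_variant(self.config)
        network, history = train(network, self.train_ds, self.val_ds, cfg)
        return FitResults(network, history, self.config, cfg, self.class_names)


#: The five architecture rows of the ablation grid, in presentation order.
ABLATION_VARIANTS = {
    "base": dict(use_fpn=False, use_sp=False, use_se=False),
    "fpn": dict(use_fpn=True, use_sp=False, use_se=False),
    "fpn+se": dict(use_fpn=True, use_sp=False, use_se=True),
    "fpn+sp": dict(use_fpn=True, use_sp=True, use_se=False),
    "fpn+sp+se": dict(use_fpn=True, use_sp=True, use_se=True),
}


def ablation_study(train_ds: Dataset, val_ds: Dataset, test_ds: Dataset | None,
                   base_model_config: ModelConfig | None = None,
                   train_config: TrainConfig | None = None):
    """Train each architecture variant and tabulate val/test accuracy.

    Returns (DataFrame with one row per variant, {variant: FitResults}).
    """
    import pandas as pd

    base = base_model_config or ModelConfig()
    base_kw = base.to_dict()
    rows, fits = [], {}
    for name, flags in ABLATION_VARIANTS.items():
        cfg = ModelConfig.from_dict({**base_kw, **flags})
        results = LeafMaturityClassifier(train_ds, val_ds, cfg).fit(train_config)
        fits[name] = results
        test_acc = (
            float((results.predict(test_ds.images) == test_ds.labels).mean())
            if test_ds is not None and len(test_ds)
            else float("nan")
        )
        rows.append(
            {
                "variant": name,
                "parameters": results.n_parameters,
                "val_accuracy": results.history.val_acc[-1],
                "test_accuracy": test_acc,
            }
        )
    return pd.DataFrame(rows), fits


class FitResults:
    """A fitted classifier with its training trajectory and diagnostics."""

    def __init__(self, network: LeafClassifier, history, model_config: ModelConfig,
                 train_config: TrainConfig, class_names: list):
        self.network = network
        self.history = history
        self.model_config = model_config
        self.train_config = train_config
        self.class_names = class_names

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.network)

    # -- evaluation -------------------------------------------------------
    def predict(self, images) -> np.ndarray:
        return self.network.predict(images)

    def predict_proba(self, images) -> np.ndarray:
        return self.network.predict_proba(images)

    def evaluate(self, ds: Dataset) -> _metrics.MetricsReport:
        return _metrics.evaluate_model(self.network, ds, class_names=self.class_names)

    def confusion(self, ds: Dataset) -> _metrics.ConfusionMatrix:
        pred = self.predict(ds.images)
        return _metrics.confusion(ds.labels, pred, n_classes=self.model_config.n_classes,
                                  class_names=self.class_names)

    def robustness(self, ds: Dataset, specs=None):
        specs = specs if specs is not None else _robustness.default_grid(self.train_config.seed)
        return _robustness.run_robustness(self.network, ds, specs, class_names=self.class_names)

    def score_cam(self, image, target_class: int, layer: str = "head_in") -> np.ndarray:
        return _explain.score_cam(self.network, image, target_class, layer=layer)

    def max_activation_overlay(self, image, layer: str = "head_in") -> np.ndarray:
        return _explain.max_activation_overlay(self.network, image, layer=layer)

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        """Text summary of the fit: architecture, size, and trajectory."""
        h = self.history
        lines = [
            "Leaf maturity classifier — fit summary",
            "=" * 46,
            f"variant:            {self.model_config.variant_name}",
            f"input size:         {self.model_config.input_size}",
            f"width multiplier:   {self.model_config.width_multiplier}",
            f"parameters:         {self.n_parameters:,}",
            f"optimizer:          {self.train_config.optimizer} (lr {self.train_config.learning_rate:g})",
            f"epochs:             {len(h.train_loss)}",
            f"optimizer steps:    {h.n_steps}",
            f"final train loss:   {h.train_loss[-1]:.4f}   acc: {h.train_acc[-1]:.4f}",
            f"final val loss:     {h.val_loss[-1]:.4f}   acc: {h.val_acc[-1]:.4f}",
            f"final lr:           {h.lr[-1]:g}",
        ]
        return "\n".join(lines)

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Checkpoint: npz weights alongside a JSON config sidecar."""
        path = Path(path)
        np.savez_compressed(path, **self.network.state_dict())
        sidecar = {
            "model_config": self.model_config.to_dict(),
            "train_config": dict(vars(self.train_config)),
            "class_names": self.class_names,
            "history": {
                "train_loss": self.history.train_loss,
                "train_acc": self.history.train_acc,
                "val_loss": self.history.val_loss,
                "val_acc": self.history.val_acc,
                "lr": self.history.lr,
                "n_steps": self.history.n_steps,
            },
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "FitResults":
        from .training import TrainHistory

        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        model_config = ModelConfig.from_dict(sidecar["model_config"])
        network = build_variant(model_config)
        with np.load(path if path.suffix else path.with_suffix(".npz")) as npz:
            network.load_state(dict(npz))
        history = TrainHistory(**sidecar["history"])
        return cls(network, history, model_config,
                   TrainConfig(**sidecar["train_config"]), sidecar["class_names"])
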