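"""Perturbation operators and the robustness experiment harness."""

import numpy as np
import pytest

from leafnet.robustness import (
    PerturbationSpec,
    add_gaussian_noise,
    adjust_brightness,
    default_grid,
    occlude,
    run_robustness,
    stratified_subset,
)

from conftest import make_random_dataset


class TestNoise:
    def test_zero_sigma_is_identity(self):
        im = np.random.default_rng(0).random((16, 16, 3)).astype(np.float32)
        assert np.array_equal(add_gaussian_noise(im, 0.0, seed=1), im)

    def test_sample_std_matches_sigma(self):
        """sigma 0.1 on a mid-gray 64x64 image: clipping is negligible,
        so the sample standard deviation estimates sigma."""
        im = np.full((64, 64, 3), 0.5, dtype=np.float32)
        noisy = add_gaussian_noise(im, 0.1, seed=2)
        assert abs(float((noisy - im).std()) - 0.1) < 0.01

    def test_deterministic_given_seed(self):
        im = np.full((8, 8, 3), 0.5, dtype=np.float32)
        assert np.array_equal(add_gaussian_noise(im, 0.3, 7), add_gaussian_noise(im, 0.3, 7))
        assert not np.array_equal(add_gaussian_noise(im, 0.3, 7), add_gaussian_noise(im, 0.3, 8))

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            add_gaussian_noise(np.zeros((4, 4, 3)), -0.1)


class TestBrightness:
    def test_unit_factor_identity(self):
        im = np.random.default_rng(1).random((8, 8, 3)).astype(np.float32)
        assert np.allclose(adjust_brightness(im, 1.0), im)

    def test_dimming_arithmetic(self):
        im = np.full((4, 4, 3), 0.5, dtype=np.float32)
        assert np.allclose(adjust_brightness(im, 0.8), 0.4)

    def test_clipping_at_one(self):
        im = np.full((4, 4, 3), 0.9, dtype=np.float32)
        assert np.allclose(adjust_brightness(im, 1.2), 1.0)


class TestOcclusion:
    def test_zero_ratio_identity(self):
        im = np.random.default_rng(2).random((12, 12, 3)).astype(np.float32)
        assert np.array_equal(occlude(im, 0.0, seed=0), im)

    def test_half_area_at_full_resolution(self):
        """ratio 0.5 on 224x224: side = round(sqrt(0.5*224^2)) = 158, so
        exactly 158^2 = 24,964 pixels are zeroed (fraction within 0.01)."""
        im = np.full((224, 224, 3), 0.5, dtype=np.float32)
        occluded = occlude(im, 0.5, seed=3)
        zeroed = int((occluded[..., 0] == 0.0).sum())
        assert zeroed == 158**2 == 24_964
        assert abs(zeroed / 224**2 - 0.5) < 0.01

    @pytest.mark.parametrize("ratio", [0.1, 0.3, 0.5, 0.9])
    def test_area_fraction_within_tolerance(self, ratio):
        im = np.full((100, 100, 3), 0.7, dtype=np.float32)
        zeroed = (occlude(im, ratio, seed=4)[..., 0] == 0.0).mean()
        assert abs(zeroed - ratio) < 0.01

    def test_full_ratio_blacks_out(self):
        im = np.random.default_rng(3).random((20, 20, 3)).astype(np.float32) * 0.5 + 0.25
        assert np.array_equal(occlude(im, 1.0, seed=5), np.zeros_like(im))

    def test_patch_inside_image(self):
        for seed in range(5):
            out = occlude(np.ones((30, 30, 3), np.float32), 0.3, seed=seed)
            assert out.min() == 0.0 and out.max() == 1.0


class TestSpecAndHarness:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            PerturbationSpec("melt", 0.1)
        with pytest.raises(ValueError):
            PerturbationSpec("occlusion", 1.5)
        with pytest.raises(ValueError):
            PerturbationSpec("brightness", 0.8, proportion=0.0)

    def test_stratified_subset_counts(self):
        labels = np.repeat(np.arange(4), 25)
        sel = stratified_subset(labels, 0.3, seed=1)
        counts = np.bincount(labels[sel], minlength=4)
        assert np.array_equal(counts, [8, 8, 8, 8])  # round(0.3*25) = 8 each
        assert len(sel) == 32

    def test_subset_reproducible_and_stratified_within_one(self):
        labels = np.repeat(np.arange(3), [10, 17, 23])
        a = stratified_subset(labels, 0.7, seed=2)
        b = stratified_subset(labels, 0.7, seed=2)
        assert np.array_equal(a, b)
        for cls, n in zip(range(3), [10, 17, 23]):
            got = (labels[a] == cls).sum()
            assert abs(got - 0.7 * n) < 1.0

    class _MeanProbe:
        """Deterministic stand-in classifier: bins mean intensity."""

        def predict(self, images):
            return np.array([int(np.asarray(im).mean() * 3) % 3 for im in images])

    def test_identity_spec_reproduces_clean_accuracy(self):
        ds = make_random_dataset([6, 6, 6], size=8, seed=5)
        model = self._MeanProbe()
        clean_pred = model.predict(ds.images)
        table = run_robustness(
            model, ds, [PerturbationSpec("gaussian_noise", 0.0, 1.0, seed=0)]
        )
        for cls in range(3):
            sel = ds.labels == cls
            expected = float((clean_pred[sel] == cls).mean())
            row = table[table["class"] == cls].iloc[0]
            assert row["accuracy"] == pytest.approx(expected)
            assert row["n"] == int(sel.sum())

    def test_two_specs_two_rows_per_class(self):
        ds = make_random_dataset([4, 4], size=8, seed=6)
        specs = [
            PerturbationSpec("brightness", 0.8, 1.0, seed=0),
            PerturbationSpec("brightness", 1.2, 1.0, seed=0),
        ]
        table = run_robustness(self._MeanProbe(), ds, specs)
        assert len(table) == 4
        assert set(table["intensity"]) == {0.8, 1.2}

    def test_exact_perturbed_count(self):
        """proportion 0.3 on 100 items: exactly 30 perturbed (stratified)."""
        ds = make_random_dataset([50, 50], size=8, seed=7)
        originals = [im.copy() for im in ds.images]

        class Recorder:
            def __init__(self):
                self.changed = 0

            def predict(self, images):
                self.changed = sum(
                    not np.array_equal(im, orig) for im, orig in zip(images, originals)
                )
                return np.zeros(len(images), dtype=int)

        recorder = Recorder()
        run_robustness(recorder, ds, [PerturbationSpec("brightness", 0.5, 0.3, seed=1)])
        assert recorder.changed == 30

    def test_empty_eval_set_rejected(self):
        from leafnet.datapipe import Dataset

        with pytest.raises(ValueError, match="empty"):
            run_robustness(self._MeanProbe(), Dataset([], np.zeros(0)), [])

    def test_default_grid_covers_study_cells(self):
        grid = default_grid(seed=0)
        assert len(grid) == 18  # 3 kinds x 2 intensities x 3 proportions
        kinds = {(s.kind, s.intensity) for s in grid}
        assert ("gaussian_noise", 0.5) in kinds and ("occlusion", 0.3) in kinds


class TestRangeAndShapeInvariants:
    @pytest.mark.parametrize("op", ["noise", "brightness", "occlusion"])
    def test_operators_preserve_shape_and_range(self, op):
        rng = np.random.default_rng(8)
        im = rng.random((17, 13, 3)).astype(np.float32)
        if op == "noise":
            out = add_gaussian_noise(im, 0.4, seed=0)
        elif op == "brightness":
            out = adjust_brightness(im, 1.2)
        else:
            out = occlude(im, 0.4, seed=0)
        assert out.shape == im.shape
        assert out.min() >= 0.0 and out.max() <= 1.0
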