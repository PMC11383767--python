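"""Training loop, checkpoint selection, prediction and Grad-CAM."""

import numpy as np
import pytest

from resswin import autodiff as ad
from resswin.autodiff import Tensor
from resswin.harness import (Checkpoint, TrainConfig, cross_entropy, evaluate,
                             grad_cam, predict, select_best_epoch, train)
from resswin.nn import Adam, Module, Parameter
from resswin.residual import ImprovedModelConfig, ResidualSwinClassifier
from resswin.swin import SwinClassifier, SwinConfig

from conftest import SMALL_CFG, SMALL_IMPROVED

#: minimal single-stage backbone for optimiser wiring checks
TINY_CFG = SwinConfig(img_size=28, embed_dim=16, depths=(1,), num_heads=(2,))


def tiny_improved():
    return ResidualSwinClassifier(ImprovedModelConfig(backbone=TINY_CFG))


class TestTraining:
    def test_same_seed_gives_identical_first_epoch(self, synth_dataset):
        losses = []
        for _ in range(2):
            model = ResidualSwinClassifier(SMALL_IMPROVED, backbone_seed=3)
            hist, _ = train(model, synth_dataset, TrainConfig(epochs=1, seed=1,
                                                              batch_size=15))
            losses.append(hist[0]["train_loss"])
        assert losses[0] == losses[1]

    def test_history_length_matches_epochs(self, synth_dataset):
        model = ResidualSwinClassifier(SMALL_IMPROVED, backbone_seed=3)
        hist, best = train(model, synth_dataset, TrainConfig(epochs=2, seed=1,
                                                             batch_size=15))
        assert len(hist) == 2
        assert best.epoch == hist[select_best_epoch(hist)]["epoch"]

    def test_empty_split_rejected(self, synth_dataset):
        empty = synth_dataset[synth_dataset["split"] == "train"]
        model = ResidualSwinClassifier(SMALL_IMPROVED)
        with pytest.raises(ValueError, match="no records"):
            train(model, empty, TrainConfig(epochs=1))

    def test_loss_decreases_over_first_adam_steps(self, rng):
        """On a one-sample batch a freshly initialised model must reduce its
        loss within five optimiser steps, across seeds."""
        improvements = 0
        for seed in range(10):
            model = ResidualSwinClassifier(
                ImprovedModelConfig(backbone=TINY_CFG), backbone_seed=seed,
                residual_seed=seed + 100)
            x = np.random.default_rng(seed).normal(
                size=(1, 28, 28, 3)).astype(np.float32)
            y = np.array([seed % 3])
            opt = Adam(model.parameters(), lr=1e-3)
            first = last = None
            for _ in range(5):
                loss = cross_entropy(model(Tensor(x)), y)
                opt.zero_grad()
                loss.backward()
                opt.step()
                first = loss.item() if first is None else first
                last = loss.item()
            improvements += last < first
        assert improvements == 10

    def test_checkpoint_selection_invariant(self):
        history = [
            dict(epoch=1, val_accuracy=0.5, val_loss=0.9),
            dict(epoch=2, val_accuracy=0.8, val_loss=0.5),
            dict(epoch=3, val_accuracy=0.8, val_loss=0.4),  # tie -> lower loss
            dict(epoch=4, val_accuracy=0.8, val_loss=0.4),  # tie -> earlier
        ]
        assert select_best_epoch(history) == 2

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            TrainConfig(epochs=0)
        assert TrainConfig().learning_rate == 1e-3
        assert TrainConfig().epochs == 100


class TestEvaluatePredict:
    def test_constant_predictor_on_balanced_split_scores_one_third(self, synth_dataset):
        model = SwinClassifier(SMALL_CFG, 0)
        model.head.weight.data[:] = 0.0
        model.head.bias.data[:] = np.array([1.0, 0.0, 0.0])
        report, cm = evaluate(model, synth_dataset, "test")
        assert report.accuracy == pytest.approx(1 / 3)
        assert cm.counts[:, 0].sum() == cm.total

    def test_evaluate_is_side_effect_free_on_weights(self, synth_dataset):
        model = SwinClassifier(SMALL_CFG, 0)
        before = {k: v.copy() for k, v in model.state_dict().items()}
        evaluate(model, synth_dataset, "val")
        after = model.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)

    def test_report_class_order_matches_manifest_order(self, synth_dataset):
        model = SwinClassifier(SMALL_CFG, 0)
        report, cm = evaluate(model, synth_dataset, "test")
        manifest_order = list(dict.fromkeys(synth_dataset["label"]))
        assert list(report.labels) == manifest_order
        assert list(cm.labels) == manifest_order

    def test_predict_probabilities(self, synth_dataset):
        model = SwinClassifier(SMALL_CFG, 0)
        path = synth_dataset["path"].iloc[0]
        label, probs, latency = predict(model, path, classes=["a", "b", "c"])
        assert probs.sum() == pytest.approx(1.0, abs=1e-6)
        assert label == ["a", "b", "c"][int(np.argmax(probs))]
        assert latency > 0
        _, probs2, _ = predict(model, path, classes=["a", "b", "c"])
        assert np.array_equal(probs, probs2)

    def test_missing_file_reported(self, synth_dataset):
        model = SwinClassifier(SMALL_CFG, 0)
        broken = synth_dataset.copy()
        broken.loc[broken.index[0], "path"] = "/nonexistent/x.png"
        with pytest.raises(FileNotFoundError, match="nonexistent"):
            evaluate(model, broken, broken.loc[broken.index[0], "split"])


class _ToyCamModel(Module):
    """Class-0 score = mean of feature channel 0; class-1 score constant."""

    def __init__(self, size=8):
        super().__init__()
        self.cfg = SwinConfig(img_size=size)
        self.scale = Parameter(np.ones(1))
        self.cache = {}

    def forward(self, x):
        feat = (x * self.scale).transpose(0, 3, 1, 2)  # (1, 3, H, W)
        self.cache["toy"] = feat
        score0 = feat[:, 0].mean(axis=(1, 2)).reshape(1, 1)
        score1 = (feat * 0.0).sum(axis=(1, 2, 3)).reshape(1, 1)
        return ad.concatenate([score0, score1], axis=1)


class TestGradCam:
    def test_toy_model_heatmap_proportional_to_channel0(self, rng):
        model = _ToyCamModel()
        img = rng.normal(size=(8, 8, 3)).astype(np.float32)
        cam = grad_cam(model, img, target_class=0, target_layer="toy",
                       channels_first=True)
        act0 = np.maximum(img[..., 0], 0.0)  # channel weights = (1/HW, 0, 0)
        expected = (act0 - act0.min()) / (act0.max() - act0.min())
        assert cam.shape == (8, 8)
        assert np.allclose(cam, expected, atol=1e-5)

    def test_zero_gradient_guard_returns_zeros(self, rng):
        model = _ToyCamModel()
        img = rng.normal(size=(8, 8, 3)).astype(np.float32)
        cam = grad_cam(model, img, target_class=1, target_layer="toy",
                       channels_first=True)
        assert np.array_equal(cam, np.zeros((8, 8)))

    def test_heatmap_in_unit_interval_and_input_resolution(self, synth_dataset):
        from resswin.imaging import read_image
        model = ResidualSwinClassifier(SMALL_IMPROVED, backbone_seed=0,
                                       zero_init="none")
        img = read_image(synth_dataset["path"].iloc[0])
        cam = grad_cam(model, img, target_class=0)
        assert cam.shape == (56, 56)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_baseline_and_zero_init_improved_give_identical_maps(self, rng):
        base = SwinClassifier(SMALL_CFG, 7)
        imp = ResidualSwinClassifier(
            ImprovedModelConfig(backbone=SMALL_CFG, skip_stages=()),
            backbone_seed=7)
        img = rng.normal(size=(56, 56, 3)).astype(np.float32)
        cam_base = grad_cam(base, img, 0, target_layer="stage2_output")
        cam_imp = grad_cam(imp, img, 0, target_layer="stage2_module2_input")
        assert np.allclose(cam_base, cam_imp, atol=1e-4)

    def test_non_spatial_layer_rejected(self, rng):
        model = SwinClassifier(SMALL_CFG, 0)
        img = rng.normal(size=(56, 56, 3)).astype(np.float32)
        with pytest.raises(ValueError, match="no cached activation"):
            grad_cam(model, img, 0, target_layer="does_not_exist")
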