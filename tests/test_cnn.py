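import math

import numpy as np
import pytest

from venmorph import cnn, rendering
from venmorph.cnn import (
    TrainConfig,
    bce_loss,
    build_model,
    compose_cam,
    cross_validate,
    grad_cam,
    images_to_tensor,
    train,
)
from venmorph.synthetic import soma_signal_cohort


@pytest.fixture(scope="module")
def small_dataset():
    """40 soma-signal images at 32 px — separable by construction."""
    trees, labels = soma_signal_cohort(20, seed=2)
    imgs, y = rendering.render_dataset(
        trees, labels, style="soma_focused", size=32,
        common_scale=True, center_on_soma=True,
    )
    return imgs, y


class TestBuildModel:
    def test_desk_profile_forward_shape(self):
        cfg = TrainConfig(profile="desk_small_cnn", input_size=64, seed=0)
        model = build_model(cfg)
        x = np.zeros((5, 3, 64, 64), dtype=np.float32)
        assert model.forward(x).shape == (5,)

    def test_paper_profile_accepts_224(self):
        cfg = TrainConfig(profile="paper_vgg16bn_pretrained", seed=0)
        assert cfg.resolved_input_size == 224
        model = build_model(cfg)
        n_conv = sum(1 for l in model.layers if isinstance(l, cnn.Conv2D))
        assert n_conv == 13
        x = np.random.default_rng(0).random((1, 3, 224, 224)).astype(np.float32)
        assert model.forward(x).shape == (1,)

    def test_same_seed_identical_parameters(self):
        cfg = TrainConfig(input_size=32, seed=4)
        a, b = build_model(cfg), build_model(cfg)
        for (pa, _), (pb, _) in zip(a.parameters(), b.parameters()):
            np.testing.assert_array_equal(pa, pb)

    def test_pretrained_fallback_warns(self):
        cfg = TrainConfig(input_size=32, seed=0, pretrained=True)
        with pytest.warns(UserWarning, match="random initialization"):
            build_model(cfg)

    def test_unknown_profile_rejected(self):
        with pytest.raises(ValueError):
            TrainConfig(profile="resnet")


class TestLossAndBackprop:
    def test_bce_closed_forms(self):
        # y=1, p=1 → 0 ; y=1, p=0.5 → ln 2
        big = np.array([50.0])
        loss, _ = bce_loss(big, np.array([1]))
        assert loss == pytest.approx(0.0, abs=1e-12)
        loss, _ = bce_loss(np.array([0.0]), np.array([1]))
        assert loss == pytest.approx(math.log(2))

    def test_gradients_match_numerics(self):
        cfg = TrainConfig(input_size=8, seed=0)
        model = build_model(cfg)
        rng = np.random.default_rng(1)
        X = rng.standard_normal((4, 3, 8, 8)).astype(np.float32)
        y = np.array([0, 1, 1, 0])
        logits = model.forward(X, train=True)
        _, dlogit = bce_loss(logits, y)
        model.backward(dlogit)
        eps = 1e-3
        for layer in model.layers:
            for p, g in layer.params():
                idx = tuple(0 for _ in p.shape)
                orig = p[idx]
                p[idx] = orig + eps
                lp, _ = bce_loss(model.forward(X, train=True), y)
                p[idx] = orig - eps
                lm, _ = bce_loss(model.forward(X, train=True), y)
                p[idx] = orig
                assert g[idx] == pytest.approx((lp - lm) / (2 * eps), abs=2e-3)


class TestTrain:
    def test_single_class_labels_rejected(self, small_dataset):
        imgs, _ = small_dataset
        cfg = TrainConfig(input_size=32, seed=0, epochs=1)
        model = build_model(cfg)
        X = images_to_tensor(imgs[:4])
        with pytest.raises(ValueError, match="single class"):
            train(model, X, np.zeros(4, dtype=int), cfg)

    def test_separable_images_learned(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(
            input_size=32, seed=0, epochs=30, learning_rate=1e-2
        )
        model = build_model(cfg)
        log = train(model, images_to_tensor(imgs), y, cfg)
        assert log[-1]["train_accuracy"] >= 0.9
        assert len(log) == cfg.epochs
        assert log[0]["lr"] == pytest.approx(cfg.learning_rate)

    def test_cosine_schedule_decays(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=0, epochs=4)
        model = build_model(cfg)
        log = train(model, images_to_tensor(imgs), y, cfg)
        lrs = [e["lr"] for e in log]
        assert all(a >= b for a, b in zip(lrs, lrs[1:]))

    def test_training_reproducible(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=3, epochs=3, learning_rate=1e-3)
        X = images_to_tensor(imgs)
        log1 = train(build_model(cfg), X, y, cfg)
        log2 = train(build_model(cfg), X, y, cfg)
        assert log1 == log2


class TestCrossValidate:
    def test_fold_contract(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=1, epochs=2)
        out = cross_validate(imgs, y, cfg, k=2)
        assert len(out["folds"]) == 2
        assert 0.0 <= out["mean_accuracy"] <= 1.0

    def test_k_exceeding_class_size_rejected(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=1, epochs=1)
        with pytest.raises(ValueError, match="class size"):
            cross_validate(imgs[:4], y[:4], cfg, k=5)

    def test_identical_seed_identical_folds(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=2, epochs=2, learning_rate=1e-3)
        a = cross_validate(imgs, y, cfg, k=2)
        b = cross_validate(imgs, y, cfg, k=2)
        assert a["folds"] == b["folds"]


class TestGradCam:
    def test_compose_single_map_collapses(self):
        A = np.random.default_rng(0).random((1, 4, 4))
        dA = np.ones((1, 4, 4))
        np.testing.assert_allclose(compose_cam(A, dA), A[0])

    def test_all_negative_gradients_zero_map(self):
        A = np.random.default_rng(0).random((2, 4, 4))
        dA = -np.ones((2, 4, 4))
        assert compose_cam(A, dA).max() == 0.0

    def test_weight_selection(self):
        rng = np.random.default_rng(1)
        A = rng.random((2, 3, 3))
        dA = np.stack([np.ones((3, 3)), np.zeros((3, 3))])
        np.testing.assert_allclose(compose_cam(A, dA), A[0])

    def test_cam_map_contract(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=0, epochs=5, learning_rate=3e-3)
        model = build_model(cfg)
        train(model, images_to_tensor(imgs), y, cfg)
        cam = grad_cam(model, imgs[0], target_class=1)
        assert cam.relevance.shape == (32, 32)
        assert cam.relevance.min() >= 0.0 and cam.relevance.max() <= 1.0
        if cam.defined:
            assert 0.0 <= cam.soma_region_mean <= 1.0
            assert 0.0 <= cam.dendrite_region_mean <= 1.0


class TestMaskingExperimentContract:
    def test_none_condition_matches_plain_cv(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=5, epochs=2, learning_rate=1e-3)
        plain = cross_validate(imgs, y, cfg, k=2)
        masked = cnn.masking_experiment(
            imgs, y, cfg, k=2, conditions=("none",)
        )
        assert masked["none"]["folds"] == plain["folds"]

    def test_premasked_inputs_rejected(self, small_dataset):
        imgs, y = small_dataset
        bad = [rendering.apply_mask(imgs[0], "soma_masked")] + list(imgs[1:])
        cfg = TrainConfig(input_size=32, seed=0, epochs=1)
        with pytest.raises(ValueError, match="unmasked"):
            cnn.masking_experiment(bad, y, cfg, k=2)

    def test_unknown_condition_rejected(self, small_dataset):
        imgs, y = small_dataset
        cfg = TrainConfig(input_size=32, seed=0, epochs=1)
        with pytest.raises(ValueError, match="mask condition"):
            cnn.masking_experiment(imgs, y, cfg, conditions=("blur",))
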