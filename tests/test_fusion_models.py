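"""Architecture accounting, training semantics, prediction, Grad-CAM.

Full-size parameter/shape regression for every strategy lives in the
acceptance suite; here one full-size build is checked and the rest of
the behavior is exercised on width-scaled models (same topology)."""

import numpy as np
import pytest

from ecgfusion._nn import Dense, Sequential, softmax_cross_entropy
from ecgfusion.fusion_models import (CLASSES, FusionModelSpec, TrainConfig,
                                     build_model, count_parameters, grad_cam,
                                     layer_summary, predict_proba,
                                     train_model)

SMALL = dict(input_size=96, width_scale=0.125)


def small_spec(strategy="S1", seed=0):
    return FusionModelSpec(strategy=strategy, seed=seed, **SMALL)


def make_separable_images(n, size=96, channels=1, seed=0, n_classes=5):
    """Class-coded blob position: trivially separable 0-255 images."""
    rng = np.random.default_rng(seed)
    y = rng.integers(0, n_classes, n)
    X = rng.uniform(0, 30, size=(n, size, size, channels)).astype(np.float32)
    step = size // n_classes
    for i in range(n):
        lo = y[i] * step
        X[i, lo:lo + step, lo:lo + step] += 200.0
    return np.clip(X, 0, 255), np.array([CLASSES[c] for c in y])


class TestArchitecture:
    def test_full_size_base_matches_published_accounting(self):
        model = build_model(FusionModelSpec(strategy="S1"))
        total, trainable, non_trainable = count_parameters(model)
        assert (total, trainable, non_trainable) == (46749765, 46747013,
                                                     2752)
        expected_rows = {
            "Conv1": ((54, 54, 96), 11712), "BN1": ((54, 54, 96), 384),
            "Pool1": ((26, 26, 96), 0), "Conv2": ((26, 26, 256), 614656),
            "BN2": ((26, 26, 256), 1024), "Pool2": ((12, 12, 256), 0),
            "Conv3": ((12, 12, 384), 885120), "BN3": ((12, 12, 384), 1536),
            "Conv4": ((12, 12, 384), 1327488), "BN4": ((12, 12, 384), 1536),
            "Conv5": ((12, 12, 256), 884992), "BN5": ((12, 12, 256), 1024),
            "Pool5": ((5, 5, 256), 0), "Flatten": ((6400,), 0),
            "FC6": ((4096,), 26218496), "FC7": ((4096,), 16781312),
            "FC8": ((5,), 20485),
        }
        rows = {name: (shape, n) for name, shape, n in layer_summary(model)}
        for name, expected in expected_rows.items():
            assert rows[name] == expected, name

    def test_s3_differs_from_base_by_one_input_channel(self):
        base = count_parameters(build_model(small_spec("S1")))[0]
        early = count_parameters(build_model(small_spec("S3")))[0]
        conv1_extra = 11 * 11 * round(96 * SMALL["width_scale"])
        assert early - base == conv1_extra

    @pytest.mark.parametrize("strategy", ["S4", "S5", "S6"])
    def test_intermediate_fusion_totals_from_decomposition(self, strategy):
        """Two-branch totals must equal 2x prefix + widened tail, computed
        independently from the per-layer counts of the base model."""
        base = build_model(small_spec("S1"))
        fused = build_model(small_spec(strategy))
        base_rows = {n: p for n, _, p in layer_summary(base)}
        cut_layers = {
            "S4": ["Conv1", "BN1", "Conv2", "BN2", "Conv3", "BN3",
                   "Conv4", "BN4"],
            "S5": ["Conv1", "BN1", "Conv2", "BN2", "Conv3", "BN3",
                   "Conv4", "BN4", "Conv5", "BN5"],
            "S6": ["Conv1", "BN1", "Conv2", "BN2", "Conv3", "BN3",
                   "Conv4", "BN4", "Conv5", "BN5", "FC6"],
        }[strategy]
        prefix = sum(base_rows[n] for n in cut_layers)
        tail_names = [n for n in base_rows
                      if n not in cut_layers and base_rows[n] > 0]
        # the first tail layer consumes doubled features -> recompute
        doubled = {"S4": "Conv5", "S5": "FC6", "S6": "FC7"}[strategy]
        expected_tail = 0
        for n in tail_names:
            if n == doubled:
                continue
            expected_tail += base_rows[n]
        # doubled layer: weights scale with doubled input dimension
        w = SMALL["width_scale"]
        if strategy == "S4":
            cout = round(256 * w)
            doubled_params = 3 * 3 * (2 * round(384 * w)) * cout + cout
        elif strategy == "S5":
            base_fc6_in = [s for n, s, _ in layer_summary(base)
                           if n == "Flatten"][0][0]
            cout = round(4096 * w)
            doubled_params = (2 * base_fc6_in) * cout + cout
        else:
            cout = round(4096 * w)
            doubled_params = (2 * cout) * cout + cout
        assert count_parameters(fused)[0] == (2 * prefix + expected_tail
                                              + doubled_params)

    def test_toy_dense_parameter_count(self):
        rng = np.random.default_rng(0)
        net = Sequential([Dense(5, name="d")], (5,), rng)
        assert sum(l.n_trainable for l in net.layers) == 30

    def test_invalid_strategy_rejected(self):
        with pytest.raises(ValueError):
            FusionModelSpec(strategy="S9")


class TestTraining:
    def test_loss_decreases_on_separable_data(self):
        X, y = make_separable_images(120, seed=1)
        model = build_model(small_spec("S1", seed=1))
        cfg = TrainConfig(max_epochs=2, patience_epochs=2, seed=1)
        model, history = train_model(model, X, y, cfg)
        assert history["loss"][-1] < history["loss"][0]

    def test_determinism_same_seed_same_first_epoch(self):
        X, y = make_separable_images(60, seed=2)
        losses = []
        for _ in range(2):
            model = build_model(small_spec("S1", seed=7))
            cfg = TrainConfig(max_epochs=1, patience_epochs=1, seed=7)
            _, history = train_model(model, X, y, cfg)
            losses.append(history["loss"][0])
        assert losses[0] == losses[1]

    def test_missing_class_rejected(self):
        X, y = make_separable_images(40, seed=3)
        y = np.array(["N"] * len(y))
        model = build_model(small_spec("S1"))
        with pytest.raises(ValueError, match="absent"):
            train_model(model, X, y, TrainConfig(max_epochs=1,
                                                 patience_epochs=1))

    def test_early_stopping_restores_best_weights(self, monkeypatch):
        """Validation losses [1.0, .9, .95, .96, .97, .98, .99] with
        patience 5 stop after epoch 7 and restore the epoch-2 weights."""
        import ecgfusion.fusion_models as fm

        X, y = make_separable_images(60, seed=4)
        seq = iter([1.0, 0.9, 0.95, 0.96, 0.97, 0.98, 0.99, 0.5, 0.4])

        def fake_eval(model, images, yy, batch_size):
            return next(seq), 0.0

        monkeypatch.setattr(fm, "_evaluate_loss", fake_eval)
        model = build_model(small_spec("S1", seed=5))
        cfg = TrainConfig(max_epochs=30, patience_epochs=5, seed=5)
        model, history = train_model(model, X, y, cfg)
        assert len(history["val_loss"]) == 7  # stopped after epoch 7
        assert history["val_loss"][1] == 0.9  # epoch-2 loss was the best

    def test_invalid_train_config(self):
        with pytest.raises(ValueError):
            TrainConfig(max_epochs=3, patience_epochs=5)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=0.0)


class TestPredict:
    def test_rows_sum_to_one(self):
        model = build_model(small_spec("S1"))
        X = np.random.default_rng(0).uniform(0, 255, (7, 96, 96, 1))
        proba = predict_proba(model, X)
        assert proba.shape == (7, 5)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-5)

    def test_duplicate_rows_identical(self):
        model = build_model(small_spec("S1"))
        x = np.random.default_rng(1).uniform(0, 255, (1, 96, 96, 1))
        X = np.repeat(x, 3, axis=0)
        proba = predict_proba(model, X)
        np.testing.assert_allclose(proba[0], proba[1], atol=1e-7)
        np.testing.assert_allclose(proba[0], proba[2], atol=1e-7)

    def test_zeroed_final_layer_gives_uniform(self):
        model = build_model(small_spec("S1"))
        fc8 = [l for l in model.iter_layers() if l.name == "FC8"][0]
        fc8.params["W"][:] = 0.0
        fc8.params["b"][:] = 0.0
        proba = predict_proba(
            model, np.random.default_rng(2).uniform(0, 255, (3, 96, 96, 1)))
        np.testing.assert_allclose(proba, 0.2, atol=1e-6)


class TestGradCam:
    def test_zero_gradients_give_zero_heatmap(self):
        model = build_model(small_spec("S1"))
        fc8 = [l for l in model.iter_layers() if l.name == "FC8"][0]
        fc8.params["W"][:] = 0.0  # class score independent of activations
        img = np.random.default_rng(3).uniform(0, 255, (96, 96, 1))
        cam = grad_cam(model, img, target_class=0, layer="Conv5")
        assert cam.shape == (96, 96)
        assert np.all(cam == 0.0)

    def test_heatmap_range_and_shape(self):
        model = build_model(small_spec("S1", seed=9))
        img = np.random.default_rng(4).uniform(0, 255, (96, 96, 1))
        cam = grad_cam(model, img, target_class=2, layer="Conv5")
        assert cam.shape == (96, 96)
        assert cam.min() >= 0.0 and cam.max() <= 1.0

    def test_unknown_layer_rejected(self):
        model = build_model(small_spec("S1"))
        with pytest.raises(KeyError):
            grad_cam(model, np.zeros((96, 96, 1)), 0, layer="Conv9")

    def test_manual_weighted_activation_map(self):
        """The captured-gradient CAM equals the hand-computed channel-mean
        weighted activation sum on a one-conv toy chain."""
        from ecgfusion._nn import Conv2D, Flatten

        rng = np.random.default_rng(0)
        net = Sequential([Conv2D(2, 3, padding="same", activation=None,
                                 name="C"),
                          Flatten(name="fl"),
                          Dense(5, name="out")], (4, 4, 1), rng)
        x = rng.standard_normal((1, 4, 4, 1)).astype(np.float32)
        out = net.forward(x, training=False, capture={"C"})
        acts = net._captured["C"]
        dlogits = np.zeros((1, 5), dtype=np.float32)
        dlogits[0, 3] = 1.0
        net.backward(dlogits, capture={"C"})
        grads = net._grad_captured["C"]
        cam = np.maximum(
            (acts * grads.mean(axis=(1, 2))[:, None, None, :]).sum(-1)[0], 0)
        # oracle: d logit_3 / d act = Dense W column reshaped through Flatten
        W = net.layers[2].params["W"]
        manual_grads = W[:, 3].reshape(1, 4, 4, 2)
        manual = np.maximum(
            (acts * manual_grads.mean(axis=(1, 2))[:, None, None, :]
             ).sum(-1)[0], 0)
        np.testing.assert_allclose(cam, manual, atol=1e-6)


class TestNumericalGradients:
    def test_backprop_matches_finite_differences(self):
        """End-to-end gradient check of the layer stack on a tiny model."""
        from ecgfusion._nn import BatchNorm, Conv2D, Flatten, MaxPool2D

        rng = np.random.default_rng(0)
        net = Sequential([Conv2D(2, 3, stride=1, padding="same", name="c1"),
                          BatchNorm(name="b1"),
                          MaxPool2D(3, 2, name="p1"),
                          Flatten(name="f"),
                          Dense(3, name="d")], (7, 7, 1), rng)
        x = rng.standard_normal((4, 7, 7, 1)).astype(np.float64)
        y = np.eye(3, dtype=np.float64)[rng.integers(0, 3, 4)]

        def loss_value():
            logits = net.forward(x, training=True)
            loss, _ = softmax_cross_entropy(logits, y)
            return loss

        logits = net.forward(x, training=True)
        loss, dlog = softmax_cross_entropy(logits, y)
        net.backward(dlog)
        for layer in net.layers:
            for key, p in layer.params.items():
                g = layer.grads[key]
                flat = p.reshape(-1)
                for idx in rng.choice(flat.size, size=min(4, flat.size),
                                      replace=False):
                    eps = 1e-3
                    orig = flat[idx]
                    flat[idx] = orig + eps
                    lp = loss_value()
                    flat[idx] = orig - eps
                    lm = loss_value()
                    flat[idx] = orig
                    fd = (lp - lm) / (2 * eps)
                    assert g.reshape(-1)[idx] == pytest.approx(
                        fd, rel=2e-2, abs=2e-4), (layer.name, key)
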